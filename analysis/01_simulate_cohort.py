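#!/usr/bin/env python
"""Simulate the study cohort at mesh level.

Builds two synthetic structures with shared-topology subject surfaces for
35 subjects (21 healthy comparison, 9 lithium responders, 5 non-responders):

  left_hippocampus : sphere template of hippocampal surface area
                     (~1345 mm² -> 9 patches), with a 15% atrophy effect
                     injected into one patch of the non-responder group;
  left_amygdala    : sphere template of amygdalar area (~600 mm² ->
                     4 patches), with no group effect (negative control).

Subject meshes go to scratch/cohort/ (bulky, regenerable); the covariate
table and the ground-truth manifest go to results/.
"""

import json
import os
import sys

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch", "cohort")
RESULTS = os.path.join(ROOT, "results")

from patchmorph.mesh import write_mesh
from patchmorph.simulate import SimulationSpec, simulate_cohort

STRUCTURES = {
    "left_hippocampus": SimulationSpec(radius=10.37, subdivisions=3, atrophy=0.15, seed=2026),
    "left_amygdala": SimulationSpec(radius=6.91, subdivisions=3, atrophy=0.0, seed=2026),
}


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    truths = {}
    for name, spec in STRUCTURES.items():
        out = os.path.join(SCRATCH, name)
        os.makedirs(out, exist_ok=True)
        cohort = simulate_cohort(spec, mode="mesh")
        write_mesh(cohort.template, os.path.join(out, "template.ply"))
        cohort.parcellation.save(
            os.path.join(out, "parcellation.csv"), os.path.join(out, "parcellation.json")
        )
        for sid, mesh in cohort.meshes.items():
            write_mesh(mesh, os.path.join(out, f"{sid}.ply"))
        truths[name] = cohort.truth
        # one covariate table serves both structures (same subjects)
        cohort.covariates.save(os.path.join(RESULTS, "covariates.csv"))
        print(f"{name}: {len(cohort.meshes)} subject surfaces, "
              f"{cohort.parcellation.k} patches, atrophy {spec.atrophy:.0%} "
              f"in patch {spec.target_patch}" if spec.atrophy else
              f"{name}: {len(cohort.meshes)} subject surfaces, "
              f"{cohort.parcellation.k} patches, no injected effect")
    with open(os.path.join(RESULTS, "truth.json"), "w") as fh:
        json.dump(truths, fh, indent=1)
    print(f"meshes under {SCRATCH}; covariates and truth under {RESULTS}")


if __name__ == "__main__":
    sys.exit(main())
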