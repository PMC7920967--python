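#!/usr/bin/env python
"""Surface-Jacobian expansion features for the simulated cohort.

Reads the subject surfaces written by 01_simulate_cohort.py, computes the
per-vertex expansion factor of every subject against its structure's
template, patch-averages with the stored parcellation, and writes one
patches x subjects feature table per structure to results/.
"""

import glob
import os
import sys

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch", "cohort")
RESULTS = os.path.join(ROOT, "results")

from patchmorph.mesh import read_mesh
from patchmorph.morphometry import assemble_feature_matrix, surface_jacobian
from patchmorph.parcellate import Parcellation


def main() -> None:
    structures = sorted(os.listdir(SCRATCH)) if os.path.isdir(SCRATCH) else []
    if not structures:
        print("no cohort found; run 01_simulate_cohort.py first", file=sys.stderr)
        return 1
    for name in structures:
        d = os.path.join(SCRATCH, name)
        template = read_mesh(os.path.join(d, "template.ply"))
        parc = Parcellation.load(
            os.path.join(d, "parcellation.csv"), os.path.join(d, "parcellation.json")
        )
        fields = {}
        for p in sorted(glob.glob(os.path.join(d, "sub*.ply"))):
            sid = os.path.splitext(os.path.basename(p))[0]
            fields[sid] = surface_jacobian(template, read_mesh(p))
        fm = assemble_feature_matrix(parc, fields)
        out = os.path.join(RESULTS, f"features_{name}.tsv")
        fm.save(out)
        span = fm.values.min(), fm.values.max()
        print(f"{name}: {fm.values.shape[0]} patches x {fm.values.shape[1]} subjects, "
              f"expansion factors in [{span[0]:.3f}, {span[1]:.3f}] -> {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
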