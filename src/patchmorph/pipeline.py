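"""End-to-end orchestration: inputs -> template -> patches -> features -> tests.

A run is described by a :class:`RunConfig` (loadable from YAML). Every run
writes, per structure, the template surface, the parcellation, the feature
matrix, and per-contrast permutation results, plus a summary table of
minimum adjusted p-values and a JSON manifest sufficient to re-run the
analysis bit-identically.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mask import load_mask, mesh_from_mask
from .mesh import TriangleMesh, read_mesh, surface_area, write_mesh
from .morphometry import FeatureMatrix, assemble_feature_matrix, build_template, surface_jacobian
from .parcellate import choose_patch_count, spectral_parcellate
from .simulate import SimulationSpec, simulate_cohort
from .stats import CONTRASTS, Contrast, CovariateTable, max_stat_permutation, percent_atrophy

log = logging.getLogger("patchmorph")


@dataclass
class RunConfig:
    mode: str = "simulate"                  # simulate | meshes | masks | features
    out_dir: str = "patchmorph_out"
    structures: dict = field(default_factory=dict)  # name -> path list / spec overrides
    covariates_path: str | None = None
    target_area: float = 150.0
    contrasts: list = field(default_factory=lambda: list(CONTRASTS))
    timepoints: list | None = None
    n_perm: int = 10_000
    seed: int = 0
    scheme: str = "shuffle_features"
    simulation: dict = field(default_factory=dict)  # SimulationSpec overrides

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute all stages; returns the summary table (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(asctime)s %(message)s")
    features: dict[str, FeatureMatrix] = {}
    truths: dict[str, dict] = {}
    cov: CovariateTable | None = None

    if config.mode == "simulate":
        structures = config.structures or {"left_hippocampus": {}}
        for i, (name, overrides) in enumerate(structures.items()):
            spec = SimulationSpec(**{"seed": config.seed + i, **config.simulation, **(overrides or {})})
            log.info("simulating structure %s (mesh mode)", name)
            cohort = simulate_cohort(spec, mode="mesh")
            cov = cohort.covariates
            truths[name] = cohort.truth
            features[name] = _mesh_cohort_features(cohort, name, config)
    elif config.mode in ("meshes", "masks"):
        if config.covariates_path is None:
            raise ValueError(f"mode {config.mode!r} requires covariates_path")
        cov = CovariateTable.load(config.covariates_path)
        for name, paths in config.structures.items():
            log.info("loading structure %s (%d surfaces)", name, len(paths))
            meshes = {}
            for sid, p in zip(cov.subject_ids, paths):
                if config.mode == "masks":
                    meshes[sid] = mesh_from_mask(load_mask(p))
                else:
                    meshes[sid] = read_mesh(p)
            ms = list(meshes.values())
            for m in ms[1:]:
                if not m.same_topology(ms[0]):
                    raise ValueError(
                        f"structure {name}: subject surfaces do not share vertex "
                        "topology; this pipeline requires pre-established "
                        "correspondence (e.g. surfaces mapped to a common "
                        "template). Independently meshed segmentations cannot "
                        "be analyzed without a registration step."
                    )
            features[name] = _features_from_meshes(meshes, cov, name, config)
    elif config.mode == "features":
        if config.covariates_path is None:
            raise ValueError("mode 'features' requires covariates_path")
        cov = CovariateTable.load(config.covariates_path)
        for name, path in config.structures.items():
            features[name] = FeatureMatrix.load(path)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    timepoints = config.timepoints
    if timepoints is None:
        timepoints = ["acute"]
        if "group_long" in cov.frame.columns:
            timepoints.append("long")

    rows = []
    detail_rows = []
    for name, fm in features.items():
        for cname in config.contrasts:
            for tp in timepoints:
                res = max_stat_permutation(
                    fm.values, cov, Contrast(cname, timepoint=tp),
                    n_perm=config.n_perm, seed=config.seed, scheme=config.scheme,
                )
                for p in range(len(res.statistic)):
                    detail_rows.append(
                        {
                            "structure": name, "contrast": cname, "timepoint": tp,
                            "patch": p, "s_p": res.statistic[p],
                            "p_adj": res.p_adjusted[p],
                            "significant": bool(res.significant[p]),
                        }
                    )
                best = int(np.argmin(res.p_adjusted))
                row = {
                    "structure": name, "contrast": cname, "timepoint": tp,
                    "patch": best, "s_p": res.statistic[best],
                    "min_p_adj": res.p_adjusted[best],
                    "significant": bool(res.significant[best]),
                }
                if res.significant[best]:
                    row["percent_atrophy"] = percent_atrophy(fm.values, cov, best, tp)
                rows.append(row)
                log.info(
                    "%s %s %s: min p_adj = %.4g at patch %d%s", name, cname, tp,
                    res.p_adjusted[best], best, " *" if res.significant[best] else "",
                )
    summary = pd.DataFrame(rows)
    detail = pd.DataFrame(detail_rows)
    summary.to_csv(os.path.join(config.out_dir, "summary.tsv"), sep="\t", index=False, float_format="%.6g")
    detail.to_csv(os.path.join(config.out_dir, "results.tsv"), sep="\t", index=False, float_format="%.6g")
    cov.save(os.path.join(config.out_dir, "covariates.csv"))
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "timepoints": timepoints,
        "truth": truths or None,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return summary


def _mesh_cohort_features(cohort, name: str, config: RunConfig) -> FeatureMatrix:
    """Template/parcellation/features for a simulated mesh cohort, with
    per-structure artifacts written to the output directory."""
    out = os.path.join(config.out_dir, name)
    os.makedirs(out, exist_ok=True)
    write_mesh(cohort.template, os.path.join(out, "template.ply"))
    cohort.parcellation.save(
        os.path.join(out, "parcellation.csv"), os.path.join(out, "parcellation.json")
    )
    fields = {
        sid: surface_jacobian(cohort.template, m) for sid, m in cohort.meshes.items()
    }
    fm = assemble_feature_matrix(cohort.parcellation, fields, cohort.covariates.subject_ids)
    fm.save(os.path.join(out, "features.tsv"))
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return fm


def _features_from_meshes(meshes: dict, cov: CovariateTable, name: str, config: RunConfig) -> FeatureMatrix:
    out = os.path.join(config.out_dir, name)
    os.makedirs(out, exist_ok=True)
    template = build_template(list(meshes.values()))
    write_mesh(template, os.path.join(out, "template.ply"))
    k = choose_patch_count(surface_area(template), config.target_area)
    parc = spectral_parcellate(template, k, seed=config.seed)
    parc.save(os.path.join(out, "parcellation.csv"), os.path.join(out, "parcellation.json"))
    fields = {sid: surface_jacobian(template, m) for sid, m in meshes.items()}
    fm = assemble_feature_matrix(parc, fields, cov.subject_ids)
    fm.save(os.path.join(out, "features.tsv"))
    return fm
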