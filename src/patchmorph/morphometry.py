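"""Template construction and surface-Jacobian expansion factors.

Subjects are assumed to share vertex topology with the template (the
synthetic generator provides this by construction; meshes from independent
segmentations do not have it, and the pipeline refuses them rather than
pretending a correspondence exists). The expansion factor at a vertex is
the ratio of the subject's barycentric vertex area to the template's — a
local area-change measure: >1 means expansion, <1 atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, face_areas, surface_area, vertex_areas
from .parcellate import Parcellation, patch_mean_features


@dataclass
class ExpansionField:
    """Per-vertex expansion factors (dimensionless, strictly positive)."""

    values: np.ndarray
    template_id: str = "template"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or not np.all(self.values > 0):
            raise ValueError("expansion factors must be finite and strictly positive")

    def save(self, path: str) -> None:
        pd.DataFrame(
            {"vertex_index": np.arange(len(self.values)), "value": self.values}
        ).to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """Patch-averaged expansion factors, patches x subjects.

    Column order is the subject order of the covariate table it will be
    modelled against.
    """

    values: np.ndarray
    subject_ids: list[str]
    parcellation_id: str = "parcellation"
    scale: str = "raw"  # raw expansion factors (positive) or log-Jacobians

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (patches x subjects)")
        if self.values.shape[1] != len(self.subject_ids):
            raise ValueError("column count does not match number of subject ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix entries must be finite")
        if self.scale == "raw" and not np.all(self.values > 0):
            raise ValueError("raw expansion-factor features must be positive")

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.subject_ids)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def load(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(), [str(c) for c in df.columns])


def rigid_align(mesh: TriangleMesh, reference: TriangleMesh) -> TriangleMesh:
    """Least-squares rigid superposition (rotation + translation, no scaling)
    of ``mesh`` onto ``reference`` over corresponding vertices.

    Scaling is deliberately excluded: overall size is signal (handled by the
    ICV covariate downstream), not nuisance.
    """
    if not mesh.same_topology(reference):
        raise ValueError("rigid_align requires shared vertex topology")
    R, t = _kabsch(mesh.vertices, reference.vertices)
    return TriangleMesh(mesh.vertices @ R.T + t, mesh.faces.copy())


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||P R^T + t - Q||²."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cq - cp @ R.T


def build_template(
    meshes: list[TriangleMesh], tol: float = 1e-4, max_iter: int = 20
) -> TriangleMesh:
    """Iterative vertex-wise mean surface after rigid alignment.

    Each round aligns every subject to the running mean and re-averages,
    until the mean vertex displacement of the template drops below ``tol``
    mm or ``max_iter`` rounds. With one input this returns a copy of it.
    """
    if not meshes:
        raise ValueError("need at least one mesh")
    faces = meshes[0].faces
    for m in meshes[1:]:
        if not m.same_topology(meshes[0]):
            raise ValueError(
                "mixed vertex topologies: template construction requires "
                "meshes with identical face lists (shared correspondence)"
            )
    template = TriangleMesh(np.mean([m.vertices for m in meshes], axis=0), faces.copy())
    for _ in range(max_iter):
        aligned = [rigid_align(m, template).vertices for m in meshes]
        new_vertices = np.mean(aligned, axis=0)
        shift = float(np.linalg.norm(new_vertices - template.vertices, axis=1).mean())
        template = TriangleMesh(new_vertices, faces.copy())
        if shift < tol:
            break
    return template


def surface_jacobian(
    template: TriangleMesh, subject: TriangleMesh, method: str = "vertex_area"
) -> ExpansionField:
    """Per-vertex expansion factor of the subject relative to the template.

    ``vertex_area`` (default): ratio of barycentric vertex areas. The
    template-vertex-area-weighted mean of the field equals the total area
    ratio exactly. ``one_ring``: ratio of summed incident face areas —
    identical weighting, kept as an alternative estimator.
    """
    if not template.same_topology(subject):
        raise ValueError("surface_jacobian requires shared vertex topology")
    if method == "vertex_area":
        at, asub = vertex_areas(template), vertex_areas(subject)
    elif method == "one_ring":
        at = _one_ring_areas(template)
        asub = _one_ring_areas(subject)
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.any(at <= 0):
        raise ValueError("template has a vertex with zero area")
    return ExpansionField(asub / at)


def _one_ring_areas(mesh: TriangleMesh) -> np.ndarray:
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa, 3))
    return out


def assemble_feature_matrix(
    parc: Parcellation,
    fields: dict[str, ExpansionField],
    subject_ids: list[str] | None = None,
    log: bool = False,
) -> FeatureMatrix:
    """Patch-average each subject's expansion field into a patches x subjects
    matrix, columns in the given subject order.

    ``log=True`` averages log-Jacobians instead of raw factors (a documented
    deviation from the raw-scale default; symmetric in expansion/atrophy).
    """
    if subject_ids is None:
        subject_ids = list(fields)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    cols = []
    for sid in subject_ids:
        field = fields[sid]
        if len(field.values) != parc.n_vertices:
            raise ValueError(
                f"subject {sid}: field length {len(field.values)} != "
                f"parcellation vertex count {parc.n_vertices}"
            )
        vals = np.log(field.values) if log else field.values
        cols.append(patch_mean_features(parc, vals))
    return FeatureMatrix(
        np.column_stack(cols), list(subject_ids), scale="log" if log else "raw"
    )
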