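"""Discrete Laplace–Beltrami operator on triangle meshes.

Discretization: linear-FEM cotangent stiffness matrix with barycentric
lumped mass — the standard faithful discretization of the smooth operator.
Eigenpairs come from the generalized symmetric problem S v = λ M v, solved
shift-inverted near zero so the constant kernel vector is recovered
robustly. On a sphere of radius r the spectrum approximates l(l+1)/r² with
multiplicity 2l+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh

from .mesh import MeshInvariantError, TriangleMesh, n_components, surface_area, vertex_areas


@dataclass
class LaplaceOperator:
    """Cotangent stiffness (sparse symmetric PSD, rows sum to zero) and
    barycentric lumped mass (per-vertex mm², sums to total surface area)."""

    stiffness: sparse.csr_matrix
    mass: np.ndarray

    @property
    def n(self) -> int:
        return self.stiffness.shape[0]


def laplace_beltrami(mesh: TriangleMesh) -> LaplaceOperator:
    """Assemble the cotangent-weight Laplace–Beltrami operator.

    Raises :class:`MeshInvariantError` naming the face if a degenerate
    triangle yields a non-finite cotangent.
    """
    if n_components(mesh) != 1:
        raise MeshInvariantError("Laplace-Beltrami requires a connected mesh")
    v, f = mesh.vertices, mesh.faces
    n = mesh.n_vertices
    i0, i1, i2 = f[:, 0], f[:, 1], f[:, 2]
    # cot at corner c is opposite edge (a, b)
    rows, cols, vals = [], [], []
    corners = [(i0, i1, i2), (i1, i2, i0), (i2, i0, i1)]
    for c, a, b in corners:
        u = v[a] - v[c]
        w = v[b] - v[c]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cot = np.einsum("ij,ij->i", u, w) / cross
        bad = ~np.isfinite(cot)
        if bad.any():
            raise MeshInvariantError(
                f"degenerate triangle: non-finite cotangent at face {int(np.flatnonzero(bad)[0])}"
            )
        half = 0.5 * cot
        rows += [a, b]
        cols += [b, a]
        vals += [-half, -half]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    S = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    S = S - sparse.diags(np.asarray(S.sum(axis=1)).ravel())
    return LaplaceOperator(S.tocsr(), vertex_areas(mesh))


def lb_eigendecomposition(op: LaplaceOperator, k: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``k`` eigenpairs of S v = λ M v, eigenvalues ascending.

    Eigenvectors are mass-orthonormal (V.T @ diag(mass) @ V = I); the first
    eigenvalue of a connected mesh is 0 with a constant eigenvector. Small
    negative round-off eigenvalues are clipped to zero.
    """
    n = op.n
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    M = sparse.diags(op.mass)
    if k > n - 2 or n < 200:
        # dense fallback: eigsh cannot return k close to n
        from scipy.linalg import eigh

        w, V = eigh(op.stiffness.toarray(), np.diag(op.mass))
        w, V = w[:k], V[:, :k]
    else:
        try:
            # fixed start vector: degenerate eigenspaces (e.g. on spheres)
            # would otherwise come out in a run-dependent basis
            v0 = np.ones(n) / np.sqrt(n)
            w, V = eigsh(op.stiffness, k=k, M=M, sigma=-1e-8, which="LM", v0=v0)
        except Exception as e:  # pragma: no cover - solver trouble is rare
            raise ArithmeticError(
                "sparse eigensolver failed to converge; retry with a dense "
                f"solve or a different shift ({e})"
            ) from e
    order = np.argsort(w)
    w, V = w[order], V[:, order]
    return np.clip(w, 0.0, None), V


def check_operator(op: LaplaceOperator, mesh: TriangleMesh, tol: float = 1e-8) -> None:
    """Assert the operator invariants (row sums ~0, symmetry, mass = area)."""
    scale = float(abs(op.stiffness).max())
    rowsum = np.asarray(op.stiffness.sum(axis=1)).ravel()
    if np.abs(rowsum).max() > tol * max(scale, 1.0):
        raise AssertionError("stiffness rows do not sum to zero")
    if abs(op.stiffness - op.stiffness.T).max() > tol * max(scale, 1.0):
        raise AssertionError("stiffness not symmetric")
    if not np.isclose(op.mass.sum(), surface_area(mesh), rtol=1e-9):
        raise AssertionError("lumped mass does not sum to surface area")
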