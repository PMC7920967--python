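"""Triangle-mesh data model, geometric measures, and PLY/OFF I/O.

All coordinates are in world millimetres; vertex and face indices are
0-based throughout the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class MeshFormatError(ValueError):
    """A mesh file could not be parsed (message names the offending line)."""


class MeshInvariantError(ValueError):
    """A mesh violates a structural invariant (degenerate face, bad index...)."""


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int.

    Invariants checked by :meth:`validate`: face indices in range, strictly
    positive face areas, and edge-manifoldness (each edge shared by at most
    two faces).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshInvariantError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshInvariantError("faces must be an (m, 3) array of vertex triples")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    # -- validation ---------------------------------------------------------

    def validate(self, require_connected: bool = False) -> "TriangleMesh":
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshInvariantError("mesh has no vertices or no faces")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshInvariantError(
                f"face index out of range (max {self.faces.max()}, "
                f"{self.n_vertices} vertices)"
            )
        areas = face_areas(self)
        if not np.all(areas > 0):
            bad = int(np.argmin(areas))
            raise MeshInvariantError(f"face {bad} has zero area")
        # edge-manifold: each undirected edge on <= 2 faces
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if counts.max() > 2:
            raise MeshInvariantError("mesh is not edge-manifold (edge on >2 faces)")
        if require_connected and n_components(self) != 1:
            raise MeshInvariantError("mesh is not a single connected component")
        return self

    def same_topology(self, other: "TriangleMesh") -> bool:
        return self.faces.shape == other.faces.shape and bool(
            np.array_equal(self.faces, other.faces)
        )


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-triangle areas in mm²."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm² (sum of triangle areas)."""
    return float(face_areas(mesh).sum())


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric vertex areas: each triangle assigns 1/3 of its area to each
    corner. Sums exactly to :func:`surface_area` (up to float summation)."""
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return out


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted, unit vertex normals."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    fn = np.cross(b - a, c - a)  # length = 2 * area
    out = np.zeros_like(v)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fn)
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    return out / norms[:, None]


def edges_unique(mesh: TriangleMesh) -> np.ndarray:
    """Undirected unique edges, (e, 2) sorted low-high."""
    e = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    return np.unique(e, axis=0)


def n_components(mesh: TriangleMesh) -> int:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    e = edges_unique(mesh)
    n = mesh.n_vertices
    g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, _ = connected_components(g, directed=False)
    return int(ncomp)


def largest_component(mesh: TriangleMesh) -> TriangleMesh:
    """Restrict the mesh to its largest connected component (vertices reindexed)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    e = edges_unique(mesh)
    n = mesh.n_vertices
    g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, labels = connected_components(g, directed=False)
    if ncomp == 1:
        return mesh
    keep = labels == np.bincount(labels).argmax()
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(keep.sum())
    fkeep = keep[mesh.faces].all(axis=1)
    return TriangleMesh(mesh.vertices[keep], remap[mesh.faces[fkeep]])


def transform_rigid(mesh: TriangleMesh, rotation: np.ndarray, translation: np.ndarray) -> TriangleMesh:
    """Apply v -> v @ R.T + t."""
    return TriangleMesh(mesh.vertices @ np.asarray(rotation).T + np.asarray(translation), mesh.faces.copy())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Signed-tetrahedron volume of a closed surface, in mm³ (absolute value)."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


# -- file I/O ---------------------------------------------------------------

_FORMATS = ("ply", "off")


def _format_from_path(path: str, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = os.path.splitext(path)[1].lstrip(".").lower()
    if f not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {f!r}; expected one of {_FORMATS}")
    return f


def read_mesh(path: str, fmt: str | None = None) -> TriangleMesh:
    """Read a PLY-ascii or OFF mesh file.

    Raises :class:`MeshFormatError` naming the line on malformed input and on
    non-triangular faces (this reader does not silently triangulate).
    """
    f = _format_from_path(path, fmt)
    with open(path) as fh:
        lines = fh.read().splitlines()
    return _parse_ply(lines, path) if f == "ply" else _parse_off(lines, path)


def write_mesh(mesh: TriangleMesh, path: str, fmt: str | None = None) -> None:
    """Write a mesh as PLY-ascii or OFF. Coordinates keep full double precision."""
    f = _format_from_path(path, fmt)
    v, fc = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        if f == "ply":
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(v)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                f"element face {len(fc)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
        else:
            fh.write(f"OFF\n{len(v)} {len(fc)} 0\n")
        for p in v:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for t in fc:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _err(path: str, lineno: int, msg: str) -> MeshFormatError:
    return MeshFormatError(f"{path}:{lineno}: {msg}")


def _parse_counts_body(
    lines: list[str], start: int, nv: int, nf: int, path: str
) -> TriangleMesh:
    verts = np.empty((nv, 3))
    faces = np.empty((nf, 3), dtype=np.int64)
    i = start
    for k in range(nv):
        while i < len(lines) and not lines[i].split():
            i += 1
        if i >= len(lines):
            raise _err(path, i + 1, "unexpected end of file in vertex list")
        tok = lines[i].split()
        if len(tok) < 3:
            raise _err(path, i + 1, f"expected 3 vertex coordinates, got {len(tok)}")
        try:
            verts[k] = [float(t) for t in tok[:3]]
        except ValueError:
            raise _err(path, i + 1, f"invalid vertex coordinate in {lines[i]!r}") from None
        i += 1
    for k in range(nf):
        while i < len(lines) and not lines[i].split():
            i += 1
        if i >= len(lines):
            raise _err(path, i + 1, "unexpected end of file in face list")
        tok = lines[i].split()
        try:
            cnt = int(tok[0])
            idx = [int(t) for t in tok[1 : 1 + cnt]]
        except (ValueError, IndexError):
            raise _err(path, i + 1, f"invalid face record {lines[i]!r}") from None
        if cnt != 3:
            raise _err(path, i + 1, f"unsupported element: face with {cnt} vertices (triangles only)")
        if len(idx) != 3:
            raise _err(path, i + 1, "face record shorter than its declared count")
        if min(idx) < 0 or max(idx) >= nv:
            raise _err(path, i + 1, f"face index {max(idx)} out of range for {nv} vertices")
        faces[k] = idx
        i += 1
    return TriangleMesh(verts, faces)


def _parse_off(lines: list[str], path: str) -> TriangleMesh:
    body = [(n, ln) for n, ln in enumerate(lines, 1) if ln.split() and not ln.lstrip().startswith("#")]
    if not body:
        raise _err(path, 1, "empty OFF file")
    i = 0
    first = body[i][1].strip()
    if first.upper().startswith("OFF"):
        rest = first[3:].strip()
        i += 1
    else:
        rest = first
    if rest:
        tok = rest.split()
    else:
        if i >= len(body):
            raise _err(path, body[-1][0], "missing OFF count line")
        tok = body[i][1].split()
        i += 1
    try:
        nv, nf = int(tok[0]), int(tok[1])
    except (ValueError, IndexError):
        raise _err(path, body[min(i, len(body) - 1)][0], "invalid OFF count line") from None
    # rebuild a flat line list from the remaining body entries
    flat = [ln for _, ln in body[i:]]
    mesh = _parse_counts_body(flat, 0, nv, nf, path)
    return mesh


def _parse_ply(lines: list[str], path: str) -> TriangleMesh:
    if not lines or lines[0].strip() != "ply":
        raise _err(path, 1, "not a PLY file (missing 'ply' magic)")
    nv = nf = None
    i = 1
    current = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise _err(path, i + 1, f"only ascii PLY supported, got {tok[1]!r}")
        elif tok[0] == "element":
            current = tok[1]
            if tok[1] == "vertex":
                nv = int(tok[2])
            elif tok[1] == "face":
                nf = int(tok[2])
            else:
                raise _err(path, i + 1, f"unsupported element {tok[1]!r}")
        elif tok[0] == "end_header":
            i += 1
            break
        i += 1
    else:
        raise _err(path, len(lines), "missing end_header")
    if nv is None or nf is None:
        raise _err(path, i, "header missing vertex or face element")
    return _parse_counts_body(lines[i:], 0, nv, nf, path)
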