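"""Binary segmentation masks and isosurface extraction.

Masks are NIfTI-1 volumes of {0,1}; the voxel-to-world affine carries the
surface into world millimetres. Surface extraction uses marching cubes at
level 0.5 followed by largest-connected-component selection — a standard,
dependency-light stand-in for restricted Delaunay meshing; the downstream
pipeline is agnostic to the mesher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh, largest_component


class EmptyMaskError(ValueError):
    pass


@dataclass
class BinaryMask:
    """A binary voxel grid with its voxel-to-world affine (homogeneous 4x4)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D voxel grid")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def foreground_volume(self) -> float:
        """Total foreground volume in mm³."""
        return float(self.data.sum()) * self.voxel_volume


def load_mask(path: str) -> BinaryMask:
    """Read a NIfTI-1 mask (.nii/.nii.gz); any non-zero voxel is foreground."""
    import nibabel as nib

    img = nib.load(path)
    return BinaryMask(np.asanyarray(img.dataobj) > 0, img.affine)


def mesh_from_mask(mask: BinaryMask, level: float = 0.5, smooth_iters: int = 0) -> TriangleMesh:
    """Extract the foreground isosurface as a triangle mesh in world mm.

    The marching-cubes surface is computed in voxel index space and mapped
    through the mask's affine; only the largest connected component is kept.
    ``smooth_iters`` > 0 applies that many Taubin smoothing passes
    (shrink-free low-pass filtering; off by default).

    Raises
    ------
    EmptyMaskError
        if the mask has no foreground voxels.
    ValueError
        if foreground touches the grid boundary (pad the volume first —
        marching cubes cannot close a surface clipped by the grid).
    """
    from skimage.measure import marching_cubes

    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not mask.data.any():
        raise EmptyMaskError("mask has no foreground voxels")
    d = mask.data
    if (
        d[0].any() or d[-1].any()
        or d[:, 0].any() or d[:, -1].any()
        or d[:, :, 0].any() or d[:, :, -1].any()
    ):
        raise ValueError(
            "foreground touches the grid boundary; pad the mask with a layer "
            "of background voxels (e.g. np.pad(data, 1)) before meshing"
        )
    verts, faces, _, _ = marching_cubes(d.astype(np.float32), level=level)
    world = verts @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    mesh = largest_component(TriangleMesh(world, faces.astype(np.int64)))
    if smooth_iters > 0:
        mesh = taubin_smooth(mesh, n_iter=smooth_iters)
    return mesh.validate()


def taubin_smooth(mesh: TriangleMesh, n_iter: int = 10, lamb: float = 0.5, mu: float = -0.53) -> TriangleMesh:
    """Taubin λ|μ smoothing: alternating positive/negative umbrella steps,
    which low-passes the surface without the shrinkage of plain Laplacian
    smoothing."""
    from scipy.sparse import coo_matrix

    from .mesh import edges_unique

    e = edges_unique(mesh)
    n = mesh.n_vertices
    A = coo_matrix(
        (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n),
    ).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()[:, None]
    v = mesh.vertices.copy()
    for _ in range(n_iter):
        for step in (lamb, mu):
            v = v + step * (A @ v / deg - v)
    return TriangleMesh(v, mesh.faces.copy())
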