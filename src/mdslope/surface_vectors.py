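"""Surface-normal vector fields on binary tumour masks.

The macroscopic tumour boundary is the set of mask voxels with at least
one face-adjacent background neighbour.  At each boundary voxel the local
surface topology is sampled with a fixed, centred kernel (5x5 voxels in
2D, 5x5x5 in 3D): the boundary voxels falling inside the kernel are
converted to world millimetres and their scatter matrix about the
centroid is eigendecomposed.  The leading eigenvector(s) span the local
tangent line/plane; the eigenvector of the smallest eigenvalue is the
surface normal.  Normals are oriented outward (centrifugally) using the
gradient of a Gaussian-smoothed mask indicator, so the same code path
serves convex and irregular regions, and 2D and 3D data alike.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_core import ScalarVolume

__all__ = [
    "SurfaceVectorField",
    "EmptyROIError",
    "refine_roi",
    "extract_boundary",
    "estimate_normals",
    "overlap_map",
]


class EmptyROIError(ValueError):
    """Raised when an operation receives an empty region of interest."""


def _face_structure(ndim: int) -> np.ndarray:
    return ndimage.generate_binary_structure(ndim, 1)


def _ball_structure(radius: int, ndim: int) -> np.ndarray:
    """Euclidean ball structuring element of the given voxel radius."""
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    dist2 = sum(g.astype(float) ** 2 for g in grids)
    return dist2 <= radius**2 + 1e-9


@dataclasses.dataclass
class SurfaceVectorField:
    """Unit outward normals anchored at boundary voxels of a refined ROI.

    ``base_points`` are world-mm coordinates of boundary voxel centres;
    ``directions`` are unit vectors pointing from mask to background.
    """

    base_points: np.ndarray  # (n, ndim) world mm
    directions: np.ndarray  # (n, ndim) unit outward
    ids: np.ndarray  # (n,)
    component_ids: np.ndarray  # (n,) label of the enhancing focus
    grid_shape: tuple[int, ...]
    affine: np.ndarray
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self):
        import pandas as pd

        cols = {"id": self.ids, "component_id": self.component_ids}
        axes = "xyz"[: self.base_points.shape[1]]
        for i, ax in enumerate(axes):
            cols[ax] = self.base_points[:, i]
        for i, ax in enumerate(axes):
            cols[f"n{ax}"] = self.directions[:, i]
        return pd.DataFrame(cols)


def refine_roi(
    mask: np.ndarray,
    closing_radius_vox: int = 1,
    min_component_vox: int = 5,
) -> np.ndarray:
    """Regularize a raw tumour mask before boundary extraction.

    Morphological closing (Euclidean ball of ``closing_radius_vox``),
    hole filling, then removal of components smaller than
    ``min_component_vox`` voxels.  All remaining components are kept:
    multifocal disease contributes every focus to the vector field.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("empty ROI")
    out = mask
    if closing_radius_vox > 0:
        pad = closing_radius_vox + 1
        padded = np.pad(out, pad)
        padded = ndimage.binary_closing(
            padded, structure=_ball_structure(closing_radius_vox, mask.ndim)
        )
        out = padded[tuple(slice(pad, -pad) for _ in range(mask.ndim))]
    out = ndimage.binary_fill_holes(out)
    labels, n = ndimage.label(out, structure=_face_structure(mask.ndim))
    if n:
        sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_vox) + 1
        out = np.isin(labels, keep)
    if not out.any():
        raise EmptyROIError(
            f"empty ROI after refinement (no component with >= {min_component_vox} voxels)"
        )
    return out


def extract_boundary(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundary voxels of a refined mask, with their component labels.

    A voxel is boundary iff it is in the mask and has at least one
    face-adjacent (4-connectivity in 2D, 6-connectivity in 3D) background
    neighbour.  Voxels at the array edge are not treated as boundary
    (out-of-grid space is not background), so a mask clipped by the field
    of view does not seed normals along the clipping plane.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("empty ROI")
    eroded = ndimage.binary_erosion(
        mask, structure=_face_structure(mask.ndim), border_value=1
    )
    boundary = mask & ~eroded
    idx = np.argwhere(boundary)
    labels, _ = ndimage.label(mask, structure=_face_structure(mask.ndim))
    comp = labels[tuple(idx.T)]
    return idx, comp


def estimate_normals(
    mask: np.ndarray,
    affine: np.ndarray,
    kernel_vox: int = 5,
    boundary: tuple[np.ndarray, np.ndarray] | None = None,
    smoothing_sigma_vox: float = 1.0,
) -> SurfaceVectorField:
    """Estimate a unit outward normal at every boundary voxel.

    Parameters
    ----------
    mask:
        refined binary ROI.
    affine:
        voxel -> world transform; the eigen-decomposition is performed on
        world-mm coordinates so anisotropic voxels are handled correctly.
    kernel_vox:
        odd kernel edge length (>= 3) used to collect the local boundary
        neighbourhood.
    boundary:
        optionally the precomputed ``(indices, component_ids)`` pair from
        :func:`extract_boundary`.

    Boundary voxels whose kernel contains fewer than 3 boundary points
    are degenerate and skipped; the count is reported on the returned
    field (``n_skipped``).
    """
    mask = np.asarray(mask, dtype=bool)
    if kernel_vox < 3 or kernel_vox % 2 == 0:
        raise ValueError("kernel_vox must be odd and >= 3")
    if boundary is None:
        boundary = extract_boundary(mask)
    idx, comp = boundary
    if len(idx) == 0:
        raise EmptyROIError("empty boundary")
    ndim = mask.ndim
    affine = np.asarray(affine, dtype=float)
    lin = affine[:ndim, :ndim]
    trans = affine[:ndim, ndim]
    lin_inv_t = np.linalg.inv(lin).T

    bmask = np.zeros(mask.shape, dtype=bool)
    bmask[tuple(idx.T)] = True

    # Outward orientation: the gradient of the smoothed indicator points
    # from background toward mask, so outward is its negation.
    smoothed = ndimage.gaussian_filter(mask.astype(np.float64), sigma=smoothing_sigma_vox)
    grads = np.gradient(smoothed)
    if ndim == 1:  # pragma: no cover - masks are 2D/3D by construction
        grads = [grads]

    # Fallback orientation for flat gradients: away from the component centroid.
    labels, n_comp = ndimage.label(mask, structure=_face_structure(ndim))
    centroids_idx = ndimage.center_of_mass(mask, labels, index=np.arange(1, n_comp + 1))
    centroids_world = {
        i + 1: np.asarray(c) @ lin.T + trans for i, c in enumerate(centroids_idx)
    }

    half = kernel_vox // 2
    bases, dirs, keep_ids, keep_comp = [], [], [], []
    n_skipped = 0
    for vec_id, (vox, cid) in enumerate(zip(idx, comp)):
        sl = tuple(
            slice(max(0, v - half), min(s, v + half + 1))
            for v, s in zip(vox, mask.shape)
        )
        local = np.argwhere(bmask[sl])
        if len(local) < 3:
            n_skipped += 1
            continue
        pts = (local + [s.start for s in sl]) @ lin.T + trans
        centred = pts - pts.mean(axis=0)
        cov = centred.T @ centred
        _, eigvecs = np.linalg.eigh(cov)
        normal = eigvecs[:, 0]  # smallest eigenvalue: orthogonal to the tangent(s)

        g_idx = np.array([g[tuple(vox)] for g in grads])
        g_world = lin_inv_t @ g_idx
        if np.linalg.norm(g_world) > 1e-12:
            if normal @ g_world > 0:  # gradient points inward
                normal = -normal
        else:
            base = vox @ lin.T + trans
            away = base - centroids_world.get(int(cid), base)
            if normal @ away < 0:
                normal = -normal
        dirs.append(normal / np.linalg.norm(normal))
        bases.append(vox @ lin.T + trans)
        keep_ids.append(vec_id)
        keep_comp.append(int(cid))

    if not bases:
        raise EmptyROIError("all boundary neighbourhoods were degenerate")
    return SurfaceVectorField(
        base_points=np.asarray(bases, dtype=float),
        directions=np.asarray(dirs, dtype=float),
        ids=np.asarray(keep_ids, dtype=int),
        component_ids=np.asarray(keep_comp, dtype=int),
        grid_shape=mask.shape,
        affine=affine,
        n_skipped=n_skipped,
    )


def overlap_map(
    field: SurfaceVectorField,
    grid_shape: Sequence[int] | None = None,
    affine: np.ndarray | None = None,
    window_mm: tuple[float, float] = (-2.0, 6.0),
    rate_per_mm: float = 2.0,
) -> ScalarVolume:
    """Count, per voxel, how many profile samples fall inside it.

    Uses the same window/rate as profile sampling, so regions probed by
    several overlapping vectors (concave surface patches) show counts
    above 1 and can be flagged for multiple sampling.
    """
    shape = tuple(grid_shape) if grid_shape is not None else field.grid_shape
    aff = np.asarray(affine, dtype=float) if affine is not None else field.affine
    ndim = len(shape)
    counts = np.zeros(shape, dtype=np.int64)
    if len(field) == 0:
        return ScalarVolume(data=counts.astype(float), affine=aff, units="arbitrary")
    n = int(round((window_mm[1] - window_mm[0]) * rate_per_mm)) + 1
    arcs = window_mm[0] + np.arange(n) / rate_per_mm
    lin_inv = np.linalg.inv(aff[:ndim, :ndim])
    trans = aff[:ndim, ndim]
    for base, direction in zip(field.base_points, field.directions):
        pts = base[None, :] + arcs[:, None] * direction[None, :]
        vox = np.rint((pts - trans) @ lin_inv.T).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        for v in vox[inside]:
            counts[tuple(v)] += 1
    return ScalarVolume(data=counts.astype(float), affine=aff, units="arbitrary")
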