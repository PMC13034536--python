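"""Centrifugal ADC profiling and marginal-diffusion-slope estimation.

Each surface-normal vector is sampled at regular arc positions across a
fixed window straddling the enhancing-tumour boundary (default -2 mm
inside to +6 mm outside, 2 samples per mm).  Values are interpolated
tri-/bi-linearly in world space.  A profile contributes to the
patient-level statistic only if its samples lie within the combined
tumour-abnormality volume (enhancing + non-enhancing core + FLAIR
abnormality) over a contiguous run longer than 4 mm that contains the
boundary crossing.  The marginal diffusion slope (MDS) of a profile is
the ordinary-least-squares slope of value against distance over that
run; regression is performed against the sample index and converted to
per-mm units by multiplying by the sampling rate, which is numerically
identical to regressing on the arc position directly.  The patient-level
MDS is the unweighted mean of all valid profile slopes, in
(mm^2/s)/mm for ADC input.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_core import ScalarVolume, SegmentationVolume, assert_same_grid
from .surface_vectors import (
    EmptyROIError,
    SurfaceVectorField,
    estimate_normals,
    extract_boundary,
    refine_roi,
)

__all__ = [
    "MDSParams",
    "Profile",
    "MDSResult",
    "sample_profile",
    "apply_validity_filter",
    "fit_slope",
    "compute_mds",
    "profile_correlation_map",
]


@dataclasses.dataclass(frozen=True)
class MDSParams:
    """Tunable parameters of the MDS pipeline.

    ``window_mm`` is relative to the enhancing boundary (negative =
    inside the tumour); ``rate_per_mm`` is the sampling frequency;
    ``min_contiguous_mm`` is the strict lower bound on the length of the
    contiguous measurable run for a profile to be valid.
    """

    window_mm: tuple[float, float] = (-2.0, 6.0)
    rate_per_mm: float = 2.0
    min_contiguous_mm: float = 4.0
    closing_radius_vox: int = 1
    min_component_vox: int = 5
    kernel_vox: int = 5

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class Profile:
    """Sampled values along one surface-normal vector.

    ``arc_mm`` is strictly increasing with constant step ``1/rate``;
    negative positions are inside the tumour.  ``missing`` flags samples
    outside the image volume (never zero-filled or imputed).  After
    validity filtering, ``run`` holds the index range (inclusive) of the
    contiguous in-abnormality stretch containing the boundary crossing,
    and ``valid`` whether that run exceeds the minimum contiguous length.
    """

    vector_id: int
    arc_mm: np.ndarray
    values: np.ndarray
    missing: np.ndarray
    world_points: np.ndarray
    in_abnormality: np.ndarray | None = None
    run: tuple[int, int] | None = None
    n_contiguous_mm: float = 0.0
    valid: bool = False
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    n_samples_used: int = 0

    @property
    def rate_per_mm(self) -> float:
        return 1.0 / float(self.arc_mm[1] - self.arc_mm[0])

    def used_samples(self) -> np.ndarray:
        """Boolean mask of samples inside the fitted contiguous run."""
        used = np.zeros(len(self.arc_mm), dtype=bool)
        if self.valid and self.run is not None:
            used[self.run[0] : self.run[1] + 1] = True
        return used


@dataclasses.dataclass
class MDSResult:
    per_profile: pd.DataFrame
    mean_mds: float  # NaN sentinel when no profile is valid (never 0)
    n_valid: int
    n_total: int
    params: MDSParams
    field: SurfaceVectorField | None = None
    profiles: list[Profile] = dataclasses.field(default_factory=list)


def _sample_arcs(window_mm: tuple[float, float], rate_per_mm: float) -> np.ndarray:
    n = int(round((window_mm[1] - window_mm[0]) * rate_per_mm)) + 1
    return window_mm[0] + np.arange(n) / rate_per_mm


def sample_profile(
    volume: ScalarVolume,
    base_point: np.ndarray,
    direction: np.ndarray,
    vector_id: int = 0,
    window_mm: tuple[float, float] = (-2.0, 6.0),
    rate_per_mm: float = 2.0,
) -> Profile:
    """Sample ``volume`` along one normal vector by linear interpolation.

    Sample positions are ``window_start + k / rate``; positions whose
    fractional voxel coordinate falls outside the volume are marked
    missing (NaN value), not zero-filled.
    """
    arcs = _sample_arcs(window_mm, rate_per_mm)
    base = np.asarray(base_point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    pts = base[None, :] + arcs[:, None] * direction[None, :]
    vox = volume.world_to_voxel(pts)
    upper = np.asarray(volume.shape, dtype=float) - 1.0
    missing = ~np.all((vox >= 0.0) & (vox <= upper), axis=1)
    values = np.full(len(arcs), np.nan)
    if np.any(~missing):
        values[~missing] = ndimage.map_coordinates(
            np.asarray(volume.data, dtype=np.float64),
            vox[~missing].T,
            order=1,
            mode="nearest",
        )
    return Profile(
        vector_id=int(vector_id),
        arc_mm=arcs,
        values=values,
        missing=missing,
        world_points=pts,
    )


def apply_validity_filter(
    profile: Profile,
    seg: SegmentationVolume,
    min_contiguous_mm: float = 4.0,
) -> Profile:
    """Flag in-abnormality samples and locate the contiguous valid run.

    A sample is "in abnormality" when its containing voxel carries the
    enhancing, non-enhancing-core, or FLAIR-abnormality role (the
    combined whole-tumour mask: the inner part of the window lies in
    enhancing tumour, which the FLAIR class alone would exclude).  The
    run is the longest consecutive stretch of in-abnormality,
    non-missing samples containing the boundary crossing (arc = 0);
    missing samples break contiguity.  The profile is valid iff the run
    spans strictly more than ``min_contiguous_mm`` millimetres.
    """
    abn = seg.abnormality_mask()
    vox = np.rint(seg.world_to_voxel(profile.world_points)).astype(int)
    shape = np.asarray(seg.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    in_abn = np.zeros(len(profile.arc_mm), dtype=bool)
    if inside.any():
        in_abn[inside] = abn[tuple(vox[inside].T)]
    ok = in_abn & ~profile.missing

    profile.in_abnormality = in_abn
    k0 = int(np.argmin(np.abs(profile.arc_mm)))
    if abs(profile.arc_mm[k0]) > 1e-9 or not ok[k0]:
        profile.run = None
        profile.n_contiguous_mm = 0.0
        profile.valid = False
        return profile
    i0 = k0
    while i0 > 0 and ok[i0 - 1]:
        i0 -= 1
    i1 = k0
    while i1 < len(ok) - 1 and ok[i1 + 1]:
        i1 += 1
    profile.run = (i0, i1)
    profile.n_contiguous_mm = (i1 - i0) / profile.rate_per_mm
    profile.valid = profile.n_contiguous_mm > min_contiguous_mm
    return profile


def fit_slope(profile: Profile) -> dict:
    """OLS slope of the profile over its contiguous run, in per-mm units.

    The regression runs on the integer sample index; the slope is then
    multiplied by the sampling rate (samples per mm) to express it per
    millimetre.  This equals regressing on the arc position directly up
    to floating-point round-off.  Requires at least 3 usable samples.
    """
    if profile.run is None:
        raise ValueError("profile has no contiguous run; apply the validity filter first")
    i0, i1 = profile.run
    y = profile.values[i0 : i1 + 1]
    x_idx = np.arange(i0, i1 + 1, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"profile {profile.vector_id}: fewer than 3 usable samples ({n})")
    xm = x_idx.mean()
    ym = y.mean()
    sxx = np.sum((x_idx - xm) ** 2)
    slope_idx = np.sum((x_idx - xm) * (y - ym)) / sxx
    rate = profile.rate_per_mm
    slope = slope_idx * rate
    arc = profile.arc_mm[i0 : i1 + 1]
    intercept = ym - slope * arc.mean()  # value extrapolated to the boundary (arc 0)
    resid = y - (intercept + slope * arc)
    sst = np.sum((y - ym) ** 2)
    r2 = float("nan") if sst == 0 else 1.0 - float(np.sum(resid**2) / sst)
    profile.slope = float(slope)
    profile.intercept = float(intercept)
    profile.r_squared = r2
    profile.n_samples_used = n
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": r2,
        "n_samples_used": n,
    }


def compute_mds(
    adc: ScalarVolume,
    seg: SegmentationVolume,
    params: MDSParams = MDSParams(),
) -> MDSResult:
    """Run the full MDS pipeline on one subject.

    refine ROI -> extract boundary -> estimate normals -> sample
    profiles -> validity filter -> per-profile OLS slopes -> unweighted
    mean over valid profiles.  Deterministic for fixed inputs and
    parameters.  When no profile is valid the patient-level MDS is NaN
    (an explicit sentinel: 0 is a meaningful slope).
    """
    assert_same_grid(adc, seg)
    enhancing = seg.mask("enhancing")
    if not enhancing.any():
        raise EmptyROIError("empty ROI: no enhancing voxels in segmentation")
    refined = refine_roi(
        enhancing,
        closing_radius_vox=params.closing_radius_vox,
        min_component_vox=params.min_component_vox,
    )
    field = estimate_normals(refined, seg.affine, kernel_vox=params.kernel_vox)
    profiles: list[Profile] = []
    rows = []
    for base, direction, vid in zip(field.base_points, field.directions, field.ids):
        p = sample_profile(
            adc,
            base,
            direction,
            vector_id=vid,
            window_mm=params.window_mm,
            rate_per_mm=params.rate_per_mm,
        )
        apply_validity_filter(p, seg, min_contiguous_mm=params.min_contiguous_mm)
        if p.valid:
            try:
                fit = fit_slope(p)
            except ValueError:
                p.valid = False
            else:
                rows.append({"vector_id": p.vector_id, **fit})
        profiles.append(p)
    per_profile = pd.DataFrame(
        rows, columns=["vector_id", "slope", "intercept", "r_squared", "n_samples_used"]
    )
    n_valid = len(per_profile)
    mean_mds = float(per_profile["slope"].mean()) if n_valid else float("nan")
    return MDSResult(
        per_profile=per_profile,
        mean_mds=mean_mds,
        n_valid=n_valid,
        n_total=len(profiles),
        params=params,
        field=field,
        profiles=profiles,
    )


def profile_correlation_map(
    vol_a: ScalarVolume,
    vol_b: ScalarVolume,
    field: SurfaceVectorField,
    window_mm: tuple[float, float] = (-2.0, 6.0),
    rate_per_mm: float = 2.0,
    seg: SegmentationVolume | None = None,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Per-vector Spearman correlation between two co-registered volumes.

    Both volumes are sampled along every vector with the same window and
    rate; rho and the two-sided p-value are computed over the usable
    samples (non-missing in both; restricted to the contiguous
    in-abnormality run when a segmentation is supplied).  Vectors with
    fewer than ``min_samples`` usable samples are flagged undefined.
    Used preclinically to map the ADC-vs-tumour-cell-density correlation
    along each vectorial direction (and 1-p as a significance surface).
    """
    assert_same_grid(vol_a, vol_b)
    rows = []
    for base, direction, vid in zip(field.base_points, field.directions, field.ids):
        pa = sample_profile(vol_a, base, direction, vid, window_mm, rate_per_mm)
        pb = sample_profile(vol_b, base, direction, vid, window_mm, rate_per_mm)
        usable = ~pa.missing & ~pb.missing
        if seg is not None:
            apply_validity_filter(pa, seg)
            if pa.run is not None:
                run_mask = np.zeros(len(usable), dtype=bool)
                run_mask[pa.run[0] : pa.run[1] + 1] = True
                usable &= run_mask
            else:
                usable[:] = False
        if int(usable.sum()) < min_samples:
            rows.append(
                {"vector_id": int(vid), "rho": np.nan, "p": np.nan,
                 "one_minus_p": np.nan, "n_samples": int(usable.sum()), "defined": False}
            )
            continue
        rho, p = stats.spearmanr(pa.values[usable], pb.values[usable])
        rows.append(
            {"vector_id": int(vid), "rho": float(rho), "p": float(p),
             "one_minus_p": 1.0 - float(p), "n_samples": int(usable.sum()),
             "defined": True}
        )
    return pd.DataFrame(rows)


def paint_vector_values(
    field: SurfaceVectorField,
    values: Sequence[float],
    fill: float = np.nan,
) -> ScalarVolume:
    """Render per-vector scalars (e.g. rho) at their base voxels."""
    ndim = len(field.grid_shape)
    out = np.full(field.grid_shape, fill, dtype=float)
    lin_inv = np.linalg.inv(field.affine[:ndim, :ndim])
    trans = field.affine[:ndim, ndim]
    vox = np.rint((field.base_points - trans) @ lin_inv.T).astype(int)
    for v, val in zip(vox, values):
        out[tuple(v)] = val
    return ScalarVolume(data=out, affine=field.affine, units="arbitrary")
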