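"""Synthetic fixtures with built-in ground truth.

Every generator returns its truth alongside the data and draws all
randomness from one explicit seed, so each pipeline stage is testable
end to end without any external dataset:

* a synthetic patient — an enhancing core surrounded by a FLAIR-like
  abnormality shell, with ADC rising linearly across the margin at a
  known slope;
* a synthetic rodent — paired ADC / tumour-cell-density maps with an
  imposed monotone negative relation and a solid core plus Gaussian
  infiltration skirt, so the infiltration index has a known ordering in
  the skirt width;
* a synthetic survival cohort drawn from an exponential baseline with a
  known log-hazard per SD of MDS.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import ScalarVolume, SegmentationVolume, affine_from_spacing

__all__ = [
    "SyntheticPatientSpec",
    "SyntheticPatient",
    "SyntheticRodent",
    "make_synthetic_patient",
    "make_synthetic_rodent",
    "make_synthetic_cohort",
]


@dataclasses.dataclass(frozen=True)
class SyntheticPatientSpec:
    """Specification of the synthetic-patient phantom.

    The ADC field is a function of the signed normal distance ``d`` from
    the enhancing-core surface (negative inside): constant ``adc_core``
    deep inside, a linear ramp of width ``transition_width_mm`` starting
    at ``ramp_start_mm``, and ``adc_plateau`` outside.  The ground-truth
    slope is ``(adc_plateau - adc_core) / transition_width_mm``.

    The ramp default begins 3 mm inside the boundary and spans 9 mm, so
    that the profile window of the standard pipeline (-2 to +6 mm,
    anchored at boundary voxel centres which sit up to one voxel inside
    the continuous surface) falls entirely on the linear section of the
    ramp and the truth is exact for a linear-fit estimator.  Narrower
    ramps are supported to study the linear-fit bias when the linear
    component does not cover the window (a sigmoid option exists for the
    same purpose).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    core_semi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    centre_mm: tuple[float, float, float] | None = None
    flair_margin_mm: float = 7.0
    adc_core: float = 6e-4
    adc_plateau: float = 8e-4
    transition_width_mm: float = 9.0
    ramp_start_mm: float = -3.0
    profile_shape: str = "linear"  # or "sigmoid"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adc_plateau <= self.adc_core:
            raise ValueError("adc_plateau must exceed adc_core")
        if self.transition_width_mm <= 0:
            raise ValueError("transition_width_mm must be positive")
        if self.profile_shape not in ("linear", "sigmoid"):
            raise ValueError("profile_shape must be 'linear' or 'sigmoid'")

    @property
    def true_slope(self) -> float:
        return (self.adc_plateau - self.adc_core) / self.transition_width_mm

    @property
    def ramp_end_mm(self) -> float:
        return self.ramp_start_mm + self.transition_width_mm


@dataclasses.dataclass
class SyntheticPatient:
    adc: ScalarVolume
    seg: SegmentationVolume
    true_slope: float
    signed_distance_mm: np.ndarray
    spec: SyntheticPatientSpec


def _signed_distance_ellipsoid(
    shape: Sequence[int],
    spacing: np.ndarray,
    centre: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    """First-order signed distance to an ellipsoid surface (exact for spheres).

    ``d = (|y| - 1) / |grad |y||`` with ``y = (x - c) / a``; for equal
    semi-axes this is the exact Euclidean distance ``r - a``, and for
    mildly anisotropic cores a close approximation whose gradient has
    near-unit norm along the surface normal.
    """
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, centre)]
    grids = np.meshgrid(*axes, indexing="ij")
    y2 = sum((g / a) ** 2 for g, a in zip(grids, semi_axes))
    f = np.sqrt(y2)
    with np.errstate(invalid="ignore", divide="ignore"):
        grad2 = sum((g / (a**2)) ** 2 for g, a in zip(grids, semi_axes)) / np.where(
            y2 > 0, y2, 1.0
        )
        d = (f - 1.0) / np.sqrt(np.where(grad2 > 0, grad2, 1.0))
    d[f == 0] = -float(np.min(semi_axes))
    return d


def make_synthetic_patient(spec: SyntheticPatientSpec) -> SyntheticPatient:
    """Build the ADC + segmentation phantom with a known marginal slope.

    Refuses specifications whose ramp extends beyond the FLAIR margin:
    the valid run would then truncate the ramp and the nominal truth
    would not be recoverable by construction.
    """
    if spec.ramp_end_mm > spec.flair_margin_mm:
        raise ValueError(
            f"ramp ends {spec.ramp_end_mm} mm outside the boundary but the "
            f"abnormality shell is only {spec.flair_margin_mm} mm thick: "
            "the ground-truth transition would be truncated"
        )
    shape = tuple(spec.shape)
    spacing = np.full(3, float(spec.spacing_mm))
    extent = (np.asarray(shape) - 1) * spacing
    centre = (
        np.asarray(spec.centre_mm, dtype=float)
        if spec.centre_mm is not None
        else extent / 2.0
    )
    semi = np.asarray(spec.core_semi_axes_mm, dtype=float)
    d = _signed_distance_ellipsoid(shape, spacing, centre, semi)

    span = spec.adc_plateau - spec.adc_core
    t = np.clip((d - spec.ramp_start_mm) / spec.transition_width_mm, 0.0, 1.0)
    if spec.profile_shape == "sigmoid":
        # smoothstep: same endpoints, sigmoidal interior (linear-fit bias study)
        t = t * t * (3.0 - 2.0 * t)
    adc_clean = spec.adc_core + span * t

    rng = np.random.default_rng(spec.seed)
    adc_data = adc_clean
    if spec.noise_sd > 0:
        adc_data = adc_clean + rng.normal(0.0, spec.noise_sd, size=shape)

    labels = np.zeros(shape, dtype=np.int16)
    labels[(d > 0) & (d <= spec.flair_margin_mm)] = 3
    labels[d <= 0] = 1
    affine = affine_from_spacing(spacing)
    return SyntheticPatient(
        adc=ScalarVolume(adc_data, affine, units="mm2_per_s"),
        seg=SegmentationVolume(labels, affine),
        true_slope=spec.true_slope,
        signed_distance_mm=d,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# rodent fixture
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticRodent:
    adc: ScalarVolume
    tcd: ScalarVolume
    adc_roi_mask: np.ndarray
    tcd_mask: np.ndarray
    adc_clean: np.ndarray
    true_adc_roi_radius_mm: float
    true_tcd_radius_mm: float
    relation: Callable[[np.ndarray], np.ndarray]


def default_adc_tcd_relation(
    adc_far: float = 8e-4, adc_dense: float = 4e-4
) -> Callable[[np.ndarray], np.ndarray]:
    """Affine decreasing map from normalized cell density to ADC."""

    def relation(tcd: np.ndarray) -> np.ndarray:
        return adc_far + (adc_dense - adc_far) * tcd

    return relation


def make_synthetic_rodent(
    shape: tuple[int, int] = (96, 96),
    spacing_mm: float = 0.1,
    core_radius_mm: float = 1.5,
    sigma_mm: float = 0.55,
    lobulation: float = 0.2,
    relation: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 1.2e-5,
    seed: int = 0,
    adc_roi_level: float = 0.3,
    tcd_mask_level: float = 0.1,
) -> SyntheticRodent:
    """Paired 2D ADC / tumour-cell-density maps with known geometry.

    The cell-density map is a solid core (density 1) with a Gaussian
    infiltration skirt of width ``sigma_mm``; the core radius is
    angularly modulated, ``R(theta) = R0 (1 + lobulation * cos 2theta)``,
    because orthotopic xenografts grow lobulated rather than circular —
    perifocal bands then mix a range of densities instead of sampling
    thin iso-density annuli.  ADC is a monotone decreasing function of
    density plus seeded Gaussian noise.  The ADC ROI thresholds the
    *noiseless* ADC at the density level ``adc_roi_level`` and the TCD
    footprint at the lower ``tcd_mask_level``; both level sets sit at a
    fixed multiple of ``sigma_mm`` beyond the core surface, so the
    infiltration ratio ROI_TCD / ROI_ADC strictly increases with the
    skirt width.
    """
    if relation is None:
        relation = default_adc_tcd_relation()
    levels = np.linspace(0.0, 1.0, 101)
    if np.any(np.diff(relation(levels)) >= 0):
        raise ValueError("relation must be strictly monotone decreasing in density")

    spacing = np.full(2, float(spacing_mm))
    centre = (np.asarray(shape) - 1) * spacing / 2.0
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, centre)]
    gx, gy = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(gx**2 + gy**2)
    theta = np.arctan2(gy, gx)
    core_r = core_radius_mm * (1.0 + lobulation * np.cos(2.0 * theta))
    tcd = np.where(
        r <= core_r,
        1.0,
        np.exp(-((r - core_r) ** 2) / (2.0 * sigma_mm**2)),
    )
    adc_clean = relation(tcd)
    rng = np.random.default_rng(seed)
    adc = adc_clean + (rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else 0.0)

    adc_roi_mask = adc_clean <= float(relation(np.asarray(adc_roi_level)))
    tcd_mask = tcd >= tcd_mask_level
    affine = affine_from_spacing(spacing)
    return SyntheticRodent(
        adc=ScalarVolume(adc, affine, units="mm2_per_s"),
        tcd=ScalarVolume(tcd, affine, units="normalized_density"),
        adc_roi_mask=adc_roi_mask,
        tcd_mask=tcd_mask,
        adc_clean=adc_clean,
        true_adc_roi_radius_mm=core_radius_mm
        + sigma_mm * np.sqrt(-2.0 * np.log(adc_roi_level)),
        true_tcd_radius_mm=core_radius_mm
        + sigma_mm * np.sqrt(-2.0 * np.log(tcd_mask_level)),
        relation=relation,
    )


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------


def make_synthetic_cohort(
    n: int,
    beta_log_hr_per_sd: float,
    baseline_rate_per_day: float = 1.0 / 400.0,
    seed: int = 0,
    mds_mean: float = 2.0e-5,
    mds_sd: float = 1.0e-5,
    age_mean: float = 54.0,
    age_sd: float = 10.0,
) -> pd.DataFrame:
    """Survival cohort with a known hazard model.

    MDS per patient is normal with the stated mean/SD; overall survival
    is exponential with rate ``baseline * exp(beta * z)`` where ``z`` is
    the standardized MDS, so ``exp(beta)`` is the true hazard ratio per
    1 SD.  Age is drawn independently (it carries no hazard, mirroring a
    homogeneous cohort).  All events are observed; fully reproducible
    from the seed.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    mds = mds_mean + mds_sd * z
    rate = baseline_rate_per_day * np.exp(beta_log_hr_per_sd * z)
    os_days = np.maximum(1, np.ceil(rng.exponential(1.0 / rate))).astype(int)
    age = rng.normal(age_mean, age_sd, size=n)
    return pd.DataFrame(
        {
            "patient_id": [f"S{i:04d}" for i in range(n)],
            "mds": mds,
            "os_days": os_days,
            "age_years": age,
            "event": np.ones(n, dtype=int),
        }
    )
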