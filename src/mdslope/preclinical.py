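"""Rodent-validation analyses: perifocal bands and infiltration index.

These mirror the histopathologic assessment of the diffusion biomarker
in an orthotopic glioblastoma xenograft: voxelwise ADC-vs-tumour-cell-
density (TCD) fits inside perifocal bands of increasing thickness placed
around the ADC-visible tumour, the infiltration index
ROI_TCD / ROI_ADC (how far the histology-visible tumour footprint
extends beyond the imaging-visible abnormality), and the relation of the
mean marginal diffusion slope to that index across animals.  The 2D
rodent data run through the identical profile/MDS code path as the 3D
clinical data.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_core import ScalarVolume

__all__ = [
    "BandFitResult",
    "InfiltrationIndex",
    "perifocal_bands",
    "voxelwise_fit",
    "infiltration_index",
    "mds_vs_infiltration",
]


@dataclasses.dataclass(frozen=True)
class BandFitResult:
    """Voxelwise ADC-against-cellularity fit inside one perifocal band."""

    thickness_vox: int
    n_voxels: int
    slope: float  # ADC units per normalized-density unit
    intercept: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


@dataclasses.dataclass(frozen=True)
class InfiltrationIndex:
    """Volume ratio of the TCD footprint to the ADC-visible abnormality.

    A ratio above 1 indicates tumour infiltration beyond the
    imaging-visible margin (expected, but reported rather than
    enforced)."""

    roi_tcd_volume_vox: int
    roi_adc_volume_vox: int
    ratio: float
    roi_tcd_volume_mm: float = float("nan")
    roi_adc_volume_mm: float = float("nan")


def perifocal_bands(roi_mask: np.ndarray, max_thickness_vox: int) -> list[np.ndarray]:
    """Bands of increasing thickness placed around the ROI.

    ``band_k = dilate(roi, k) \\ roi`` with a Euclidean structuring
    element of radius k voxels (realized through the Euclidean distance
    transform, which gives exactly nested bands).  Bands reaching the
    grid edge are clipped with a warning.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI mask")
    if max_thickness_vox < 1:
        raise ValueError("max_thickness_vox must be >= 1")
    dist = ndimage.distance_transform_edt(~roi)
    bands = []
    edge = np.zeros(roi.shape, dtype=bool)
    for ax in range(roi.ndim):
        sl = [slice(None)] * roi.ndim
        for end in (0, -1):
            sl[ax] = end
            edge[tuple(sl)] = True
    for k in range(1, max_thickness_vox + 1):
        band = (dist > 0) & (dist <= k + 1e-9)
        if np.any(band & edge):
            warnings.warn(
                f"perifocal band of thickness {k} voxels reaches the grid edge; "
                "it is clipped to the field of view",
                stacklevel=2,
            )
        bands.append(band)
    return bands


def voxelwise_fit(
    adc: ScalarVolume,
    tcd: ScalarVolume,
    band_mask: np.ndarray,
    thickness_vox: int = 0,
    min_voxels: int = 10,
) -> BandFitResult:
    """Paired voxelwise ADC-vs-TCD fit over one band.

    OLS regression of ADC on normalized TCD, plus Pearson and Spearman
    coefficients with two-sided p-values.  Refuses bands with fewer than
    ``min_voxels`` voxels.
    """
    band = np.asarray(band_mask, dtype=bool)
    x = np.asarray(tcd.data, dtype=float)[band]
    y = np.asarray(adc.data, dtype=float)[band]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < min_voxels:
        raise ValueError(f"band has {len(x)} voxels; at least {min_voxels} required")
    fit = stats.linregress(x, y)
    rho, sp = stats.spearmanr(x, y)
    return BandFitResult(
        thickness_vox=int(thickness_vox),
        n_voxels=int(len(x)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        pearson_p=float(fit.pvalue),
        spearman_rho=float(rho),
        spearman_p=float(sp),
    )


def band_fit_curve(
    adc: ScalarVolume,
    tcd: ScalarVolume,
    roi_mask: np.ndarray,
    max_thickness_vox: int = 8,
) -> pd.DataFrame:
    """Slope-vs-thickness curve over perifocal bands 1..max_thickness."""
    rows = []
    for k, band in enumerate(perifocal_bands(roi_mask, max_thickness_vox), start=1):
        try:
            fit = voxelwise_fit(adc, tcd, band, thickness_vox=k)
        except ValueError:
            continue
        rows.append(dataclasses.asdict(fit))
    return pd.DataFrame(rows)


def infiltration_index(
    tcd_mask: np.ndarray,
    adc_mask: np.ndarray,
    spacing_mm: np.ndarray | None = None,
) -> InfiltrationIndex:
    """ROI_TCD / ROI_ADC volume ratio (in voxels, and mm^n if spacing given)."""
    tcd_mask = np.asarray(tcd_mask, dtype=bool)
    adc_mask = np.asarray(adc_mask, dtype=bool)
    n_adc = int(adc_mask.sum())
    if n_adc == 0:
        raise ValueError("empty ADC ROI mask")
    n_tcd = int(tcd_mask.sum())
    voxel_volume = float(np.prod(spacing_mm)) if spacing_mm is not None else float("nan")
    return InfiltrationIndex(
        roi_tcd_volume_vox=n_tcd,
        roi_adc_volume_vox=n_adc,
        ratio=n_tcd / n_adc,
        roi_tcd_volume_mm=n_tcd * voxel_volume,
        roi_adc_volume_mm=n_adc * voxel_volume,
    )


def mds_vs_infiltration(per_animal: pd.DataFrame) -> dict:
    """Correlate mean MDS with the infiltration index across animals.

    ``per_animal`` needs columns ``mean_mds`` and ``ratio``; an optional
    boolean ``exclude`` column removes annotated outliers (e.g. an
    animal whose vectors leave the brain) before fitting.  Returns
    Pearson r and p plus the OLS line.
    """
    df = per_animal.copy()
    if "exclude" in df.columns:
        df = df[~df["exclude"].astype(bool)]
    if len(df) < 3:
        raise ValueError(f"need at least 3 animals, got {len(df)}")
    x = df["ratio"].to_numpy(dtype=float)
    y = df["mean_mds"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ratio or mean_mds")
    fit = stats.linregress(x, y)
    return {
        "pearson_r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(df)),
    }
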