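"""Volume containers and I/O.

All downstream geometry (profile windows, kernel scatter matrices, band
thicknesses) is computed in world millimetres through the voxel-to-world
affine, so anisotropic grids are handled transparently.  Volumes are
exchanged as single-volume NIfTI-1 files; tabular outputs are plain CSV.

Conventions
-----------
* voxel indices are 0-based; ``world = affine @ [i, j, k, 1]``
* 2D volumes (used by the in-silico cellularity model and the rodent
  analyses) carry a 3x3 homogeneous affine; on disk they are stored as a
  single-slice 3D NIfTI.
* 4D NIfTI inputs are rejected: an ADC map is a single volume by
  definition, and silently squeezing a time axis would hide upstream
  conversion errors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ScalarVolume",
    "SegmentationVolume",
    "DEFAULT_SCHEME",
    "ABNORMALITY_ROLES",
    "GridMismatchError",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_segmentation",
    "write_segmentation",
    "assert_same_grid",
    "write_profiles_table",
    "read_profiles_table",
    "validate_cohort",
    "affine_from_spacing",
]

#: Default label scheme. The class names follow the standard 6-class
#: segmentation of contrast-enhancing brain tumours (enhancing tumour,
#: non-enhancing cystic/necrotic core, non-enhancing FLAIR abnormality,
#: plus normal-appearing GM/WM/CSF); numeric codes are a package
#: convention and can be overridden per file.
DEFAULT_SCHEME: dict[str, int] = {
    "background": 0,
    "enhancing": 1,
    "nonenhancing_core": 2,
    "flair_abnormality": 3,
    "gm": 4,
    "wm": 5,
    "csf": 6,
}

#: Roles forming the combined tumour-abnormality mask used by the
#: profile validity filter (the whole-tumour mask: enhancing tumour,
#: enclosed non-enhancing core, and surrounding FLAIR abnormality).
ABNORMALITY_ROLES: tuple[str, ...] = (
    "enhancing",
    "nonenhancing_core",
    "flair_abnormality",
)

VALID_UNITS = ("mm2_per_s", "normalized_density", "arbitrary")


class GridMismatchError(ValueError):
    """Two volumes do not share shape and affine."""


def affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    """Axis-aligned voxel->world affine with the given mm spacing."""
    spacing = np.asarray(spacing, dtype=float)
    aff = np.eye(len(spacing) + 1)
    aff[: len(spacing), : len(spacing)] = np.diag(spacing)
    return aff


def _check_grid_fields(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D array, got rank {data.ndim}")
    affine = np.asarray(affine, dtype=float)
    d = data.ndim
    if affine.shape != (d + 1, d + 1):
        raise ValueError(
            f"affine must be {(d + 1, d + 1)} for a {d}D volume, got {affine.shape}"
        )


@dataclasses.dataclass
class ScalarVolume:
    """A scalar field (ADC in mm^2/s, or a normalized density) on a grid.

    Parameters
    ----------
    data:
        2D or 3D array of scalar values (no infinities).
    affine:
        ``(ndim+1, ndim+1)`` voxel-index -> world-mm transform.
    units:
        one of ``mm2_per_s``, ``normalized_density``, ``arbitrary``.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_grid_fields(self.data, self.affine)
        if np.isinf(self.data).any():
            raise ValueError("volume contains infinite values")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive along every axis")

    # -- grid geometry -------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel per axis (column norms of the linear part)."""
        lin = self.affine[: self.ndim, : self.ndim]
        return np.linalg.norm(lin, axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, ndim) voxel indices to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        lin = self.affine[: self.ndim, : self.ndim]
        trans = self.affine[: self.ndim, self.ndim]
        return idx @ lin.T + trans

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, ndim) world-mm points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lin = self.affine[: self.ndim, : self.ndim]
        trans = self.affine[: self.ndim, self.ndim]
        return (pts - trans) @ np.linalg.inv(lin).T


@dataclasses.dataclass
class SegmentationVolume:
    """Integer label field bound to the grid of a reference volume."""

    labels: np.ndarray
    affine: np.ndarray
    scheme: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SCHEME)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_grid_fields(self.labels, self.affine)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("segmentation volume is not integer-valued")
            self.labels = self.labels.astype(np.int32)
        known = set(int(v) for v in self.scheme.values())
        present = set(int(v) for v in np.unique(self.labels))
        unknown = sorted(present - known)
        if unknown:
            raise ValueError(
                f"labels {unknown} present in data but absent from scheme "
                f"{dict(self.scheme)}"
            )

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def spacing(self) -> np.ndarray:
        lin = self.affine[: self.ndim, : self.ndim]
        return np.linalg.norm(lin, axis=0)

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of voxels carrying the given role."""
        if role not in self.scheme:
            raise KeyError(f"role {role!r} not in scheme {sorted(self.scheme)}")
        return self.labels == int(self.scheme[role])

    def abnormality_mask(self) -> np.ndarray:
        """Combined tumour-abnormality mask (enhancing + core + FLAIR)."""
        out = np.zeros(self.shape, dtype=bool)
        for role in ABNORMALITY_ROLES:
            if role in self.scheme:
                out |= self.mask(role)
        return out

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        lin = self.affine[: self.ndim, : self.ndim]
        trans = self.affine[: self.ndim, self.ndim]
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - trans) @ np.linalg.inv(lin).T


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"{path} is not a NIfTI volume: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        raise ValueError(
            f"{path} is a 4D volume (axis 3 has length {data.shape[3]}); "
            "expected a single 3D volume"
        )
    if data.ndim not in (2, 3):
        raise ValueError(f"{path} has rank {data.ndim}; expected 2 or 3")
    return data, np.asarray(img.affine, dtype=float)


def read_scalar_volume(path: str | Path, units: str = "arbitrary") -> ScalarVolume:
    """Read a single-volume NIfTI file; spacing/affine come from the header."""
    data, affine = _load_nifti(path)
    return ScalarVolume(data=data.astype(np.float64), affine=affine, units=units)


def _as_3d(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Embed a 2D grid as a single-slice 3D NIfTI grid."""
    if data.ndim == 3:
        return data, affine
    aff3 = np.eye(4)
    aff3[:2, :2] = affine[:2, :2]
    aff3[:2, 3] = affine[:2, 2]
    return data[..., np.newaxis], aff3


def write_scalar_volume(volume: ScalarVolume, path: str | Path) -> None:
    data, aff = _as_3d(volume.data, volume.affine)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff), str(path))


def read_segmentation(
    path: str | Path, scheme: Mapping[str, int] | None = None
) -> SegmentationVolume:
    """Read an integer label volume and validate it against the scheme."""
    data, affine = _load_nifti(path)
    return SegmentationVolume(
        labels=np.asarray(np.round(data), dtype=np.int32),
        affine=affine,
        scheme=dict(scheme) if scheme is not None else dict(DEFAULT_SCHEME),
    )


def write_segmentation(seg: SegmentationVolume, path: str | Path) -> None:
    data, aff = _as_3d(seg.labels, seg.affine)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.int16), aff), str(path))


# ---------------------------------------------------------------------------
# grid compatibility
# ---------------------------------------------------------------------------

def assert_same_grid(
    a: ScalarVolume | SegmentationVolume,
    b: ScalarVolume | SegmentationVolume,
    atol_mm: float = 1e-4,
) -> None:
    """Raise :class:`GridMismatchError` unless both volumes share one grid.

    Shapes must match exactly; affines must agree within ``atol_mm``
    (absolute, in mm). The check is symmetric in its arguments.
    """
    if a.shape != b.shape:
        for axis, (na, nb) in enumerate(zip(a.shape, b.shape)):
            if na != nb:
                raise GridMismatchError(f"shape mismatch axis {axis}: {na} vs {nb}")
        raise GridMismatchError(f"shape mismatch: rank {len(a.shape)} vs {len(b.shape)}")
    if not np.allclose(a.affine, b.affine, atol=atol_mm, rtol=0.0):
        raise GridMismatchError(
            "affine mismatch: max |difference| = "
            f"{np.max(np.abs(a.affine - b.affine)):.6g} mm"
        )


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["vector_id", "sample_index", "arc_mm", "value", "valid"]
SUMMARY_COLUMNS = ["vector_id", "slope", "intercept", "r_squared", "n_valid_samples"]


def write_profiles_table(
    profiles: Iterable,
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write per-sample profile rows (and optionally a per-vector summary).

    One row per sample point: vector id, sample index, arc position (mm),
    interpolated value, and whether the sample belongs to the contiguous
    valid run used for the slope fit.
    """
    rows = []
    summaries = []
    for p in profiles:
        used = p.used_samples()
        for k, (arc, val) in enumerate(zip(p.arc_mm, p.values)):
            rows.append(
                {
                    "vector_id": int(p.vector_id),
                    "sample_index": k,
                    "arc_mm": float(arc),
                    "value": float(val) if np.isfinite(val) else np.nan,
                    "valid": bool(used[k]),
                }
            )
        summaries.append(
            {
                "vector_id": int(p.vector_id),
                "slope": p.slope,
                "intercept": p.intercept,
                "r_squared": p.r_squared,
                "n_valid_samples": int(np.sum(used)),
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)
    if summary_path is not None:
        pd.DataFrame(summaries, columns=SUMMARY_COLUMNS).to_csv(summary_path, index=False)


def read_profiles_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "mds", "os_days", "age_years", "event"]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-patient cohort table (MDS, overall survival, age).

    Requires no missing MDS or OS values, integer positive survival
    times, and ``event == 1`` for every row (the cohort design follows
    every patient to death, so there is no censoring).
    """
    missing = [c for c in ("mds", "os_days") if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    if table[["mds", "os_days"]].isna().any().any():
        raise ValueError("cohort table has missing mds or os_days values")
    os_days = table["os_days"].to_numpy()
    if np.any(os_days <= 0):
        raise ValueError("os_days must be positive")
    if "event" in table.columns and not np.all(table["event"].to_numpy() == 1):
        raise ValueError("all events must be observed (event == 1, no censoring)")
    out = table.copy()
    if "event" not in out.columns:
        out["event"] = 1
    return out


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
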