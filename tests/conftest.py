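import numpy as np
import pytest

from mdslope.io_core import ScalarVolume, SegmentationVolume, affine_from_spacing
from mdslope.profile_mds import MDSParams, Profile, apply_validity_filter, compute_mds, sample_profile
from mdslope.synthetic import SyntheticPatientSpec, make_synthetic_patient, make_synthetic_rodent


@pytest.fixture(scope="session")
def default_patient():
    return make_synthetic_patient(SyntheticPatientSpec())


@pytest.fixture(scope="session")
def default_patient_mds(default_patient):
    return compute_mds(default_patient.adc, default_patient.seg)


@pytest.fixture(scope="session")
def rodent():
    return make_synthetic_rodent(seed=3)


def make_slab_profile(abnormality_out_mm: float, spacing: float = 0.5):
    """Profile along +x across a slab boundary with a controlled run.

    The grid has ``spacing`` mm voxels so every sample position of the
    standard window (-2..+6 mm, 2/mm) coincides exactly with a voxel
    centre: a sample at arc ``a`` is in-abnormality iff ``a <=
    abnormality_out_mm``.  The enhancing slab ends at the base voxel
    (x = 10 mm); the abnormality shell extends ``abnormality_out_mm``
    beyond it, so the contiguous run spans exactly
    ``2 + abnormality_out_mm`` millimetres.
    """
    nx = int(round(20.0 / spacing)) + 1
    shape = (nx, 9, 9)
    affine = affine_from_spacing((spacing, spacing, spacing))
    x_mm = np.arange(nx) * spacing
    labels = np.zeros(shape, dtype=np.int16)
    labels[x_mm <= 10.0, :, :] = 1
    labels[(x_mm > 10.0) & (x_mm <= 10.0 + abnormality_out_mm), :, :] = 3
    seg = SegmentationVolume(labels, affine)
    adc = ScalarVolume(
        8e-4 + 1e-5 * x_mm[:, None, None] * np.ones(shape), affine, units="mm2_per_s"
    )
    base = np.array([10.0, 2.0, 2.0])
    direction = np.array([1.0, 0.0, 0.0])
    profile = sample_profile(adc, base, direction, window_mm=(-2.0, 6.0), rate_per_mm=2.0)
    apply_validity_filter(profile, seg, min_contiguous_mm=4.0)
    return profile, seg


def random_full_run_profile(rng: np.random.Generator, rate: float = 2.0) -> Profile:
    """A profile whose run covers the whole window, with random values."""
    n = int(round(8.0 * rate)) + 1
    arcs = -2.0 + np.arange(n) / rate
    p = Profile(
        vector_id=0,
        arc_mm=arcs,
        values=rng.normal(8e-4, 1e-4, size=n),
        missing=np.zeros(n, dtype=bool),
        world_points=np.zeros((n, 3)),
    )
    p.run = (0, n - 1)
    p.valid = True
    p.n_contiguous_mm = (n - 1) / rate
    return p
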