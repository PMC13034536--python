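import numpy as np
import pytest

from mdslope.io_core import affine_from_spacing
from mdslope.surface_vectors import (
    EmptyROIError,
    estimate_normals,
    extract_boundary,
    overlap_map,
    refine_roi,
)


def disc_mask(shape, radius, centre=None):
    centre = centre or tuple((s - 1) / 2 for s in shape)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return r2 <= radius**2


class TestRefineROI:
    def test_interior_hole_filled_exactly(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True  # cube: closing adds nothing
        mask[5, 5, 5] = False
        refined = refine_roi(mask)
        assert refined.sum() == mask.sum() + 1
        assert refined[5, 5, 5]

    def test_multifocal_components_both_retained(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:12, 2:12] = True
        mask[18:28, 18:28] = True
        refined = refine_roi(mask)
        _, comp = extract_boundary(refined)
        assert set(comp) == {1, 2}

    def test_isolated_voxel_removed_yields_empty_roi(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(EmptyROIError):
            refine_roi(mask, closing_radius_vox=0, min_component_vox=5)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyROIError, match="empty ROI"):
            refine_roi(np.zeros((5, 5), dtype=bool))


class TestExtractBoundary:
    def test_filled_square_perimeter_matches_brute_force(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True  # 5x5 square
        idx, _ = extract_boundary(mask)
        # oracle: enumerate voxels with a face-adjacent background neighbour
        expected = set()
        for i in range(2, 7):
            for j in range(2, 7):
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    if not mask[i + di, j + dj]:
                        expected.add((i, j))
                        break
        assert len(expected) == 16
        assert set(map(tuple, idx)) == expected

    def test_one_voxel_thick_shell_returned_entirely(self):
        shell = disc_mask((21, 21, 21), 7) & ~disc_mask((21, 21, 21), 5.8)
        idx, _ = extract_boundary(shell)
        assert len(idx) == shell.sum()

    def test_single_voxel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        idx, comp = extract_boundary(mask)
        assert idx.tolist() == [[2, 2]]
        assert comp.tolist() == [1]


class TestEstimateNormals:
    def test_disc_normals_are_radial(self):
        mask = disc_mask((48, 48), 20)
        field = estimate_normals(mask, affine_from_spacing((1.0, 1.0)))
        centre = np.array([23.5, 23.5])
        radial = field.base_points - centre
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.sum(field.directions * radial, axis=1)
        assert dots.mean() >= 0.98
        assert dots.min() >= 0.9

    def test_flat_slab_face_normal_is_axis(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2:18, 2:18, 2:8] = True
        field = estimate_normals(mask, affine_from_spacing((1, 1, 1)))
        # face voxel well away from slab edges
        i = np.flatnonzero(
            (np.abs(field.base_points[:, 0] - 10) < 2.5)
            & (np.abs(field.base_points[:, 1] - 10) < 2.5)
            & (field.base_points[:, 2] == 7)
        )
        assert len(i)
        np.testing.assert_allclose(
            field.directions[i], np.tile([0.0, 0.0, 1.0], (len(i), 1)), atol=1e-6
        )

    def test_sphere_mean_angular_error_below_5_degrees(self):
        mask = disc_mask((40, 40, 40), 14)
        field = estimate_normals(mask, affine_from_spacing((1, 1, 1)))
        radial = field.base_points - np.array([19.5] * 3)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.clip(np.sum(field.directions * radial, axis=1), -1, 1)
        assert np.degrees(np.arccos(dots)).mean() < 5.0

    def test_normal_orthogonal_to_tangential_eigenvectors(self):
        # recompute the local scatter at a few boundary voxels and check
        # the returned normal against its tangent space
        mask = disc_mask((40, 40), 15)
        idx, comp = extract_boundary(mask)
        field = estimate_normals(mask, affine_from_spacing((1, 1)), boundary=(idx, comp))
        bmask = np.zeros(mask.shape, dtype=bool)
        bmask[tuple(idx.T)] = True
        for k in range(0, len(field), 7):
            vox = field.base_points[k].astype(int)
            sl = tuple(slice(v - 2, v + 3) for v in vox)
            pts = np.argwhere(bmask[sl]) + [s.start for s in sl]
            centred = pts - pts.mean(axis=0)
            _, vecs = np.linalg.eigh(centred.T @ centred.astype(float))
            tangent = vecs[:, -1]
            assert abs(field.directions[k] @ tangent) <= 1e-9

    def test_rotation_equivariance_under_quarter_turn(self):
        mask = disc_mask((40, 40), 13, centre=(17.0, 21.0))
        aff = affine_from_spacing((1.0, 1.0))
        f0 = estimate_normals(mask, aff)
        f1 = estimate_normals(np.rot90(mask).copy(), aff)
        m = mask.shape[1]
        # np.rot90 maps old (r, c) -> new (m-1-c, r); directions rotate the same way
        lookup = {
            (int(b[0]), int(b[1])): d for b, d in zip(f1.base_points, f1.directions)
        }
        assert len(lookup) == len(f0)
        for b, d in zip(f0.base_points, f0.directions):
            rotated_pos = (m - 1 - int(b[1]), int(b[0]))
            expected_dir = np.array([-d[1], d[0]])
            np.testing.assert_allclose(lookup[rotated_pos], expected_dir, atol=1e-9)

    def test_vector_count_and_skip_fraction_on_convex_roi(self):
        mask = disc_mask((40, 40, 40), 12)
        idx, comp = extract_boundary(mask)
        field = estimate_normals(mask, affine_from_spacing((1, 1, 1)))
        assert len(field) + field.n_skipped == len(idx)
        assert field.n_skipped / len(idx) < 0.01

    def test_anisotropic_grid_normals_computed_in_world_mm(self):
        # slab boundary along z on a grid with 2 mm slices: normal must be
        # the world z axis regardless of index-space anisotropy
        mask = np.zeros((20, 20, 12), dtype=bool)
        mask[2:18, 2:18, 2:6] = True
        field = estimate_normals(mask, affine_from_spacing((1, 1, 2)))
        i = np.flatnonzero(
            (np.abs(field.base_points[:, 0] - 10) < 2.5)
            & (np.abs(field.base_points[:, 1] - 10) < 2.5)
            & (field.base_points[:, 2] == 10.0)
        )
        assert len(i)
        np.testing.assert_allclose(
            np.abs(field.directions[i] @ np.array([0, 0, 1.0])), 1.0, atol=1e-6
        )


class TestOverlapMap:
    def test_single_vector_samples_distinct_voxels(self):
        # 0.25 mm grid: consecutive 0.5 mm samples fall in distinct voxels
        mask = np.zeros((80, 40), dtype=bool)
        field_shape = mask.shape
        aff = affine_from_spacing((0.25, 0.25))
        from mdslope.surface_vectors import SurfaceVectorField

        field = SurfaceVectorField(
            base_points=np.array([[5.0, 5.0]]),
            directions=np.array([[1.0, 0.0]]),
            ids=np.array([0]),
            component_ids=np.array([1]),
            grid_shape=field_shape,
            affine=aff,
        )
        counts = overlap_map(field)
        assert counts.data.sum() == 17
        assert (counts.data[counts.data > 0] == 1).all()

    def test_two_nearby_parallel_vectors_double_count(self):
        from mdslope.surface_vectors import SurfaceVectorField

        aff = affine_from_spacing((2.0, 2.0))
        field = SurfaceVectorField(
            base_points=np.array([[10.0, 10.0], [10.0, 10.1]]),
            directions=np.array([[1.0, 0.0], [1.0, 0.0]]),
            ids=np.array([0, 1]),
            component_ids=np.array([1, 1]),
            grid_shape=(20, 20),
            affine=aff,
        )
        counts = overlap_map(field)
        assert counts.data.max() >= 2
        # the two sub-voxel-separated vectors always hit the same voxels
        assert np.all(counts.data % 2 == 0)

    def test_empty_field_gives_zero_volume(self):
        from mdslope.surface_vectors import SurfaceVectorField

        field = SurfaceVectorField(
            base_points=np.zeros((0, 2)),
            directions=np.zeros((0, 2)),
            ids=np.zeros(0, dtype=int),
            component_ids=np.zeros(0, dtype=int),
            grid_shape=(10, 10),
            affine=affine_from_spacing((1, 1)),
        )
        assert overlap_map(field).data.sum() == 0
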