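"""Boundary-shell construction and tumor shape metrics against brute-force oracles."""

import numpy as np
import pytest

from regioncontrast import (
    EmptyRegionError,
    NoBoundaryError,
    RegionMask,
    build_boundary_shell,
    max_extent_mm,
    shape_metrics,
    surface_area_mm2,
)

from conftest import brute_force_shell, random_tumor_mask


def _single_voxel_tumor(spacing=(1.0, 1.0, 1.0)):
    mask = np.zeros((9, 9, 9), dtype=bool)
    mask[4, 4, 4] = True
    return RegionMask(mask=mask, spacing=spacing)


class TestBoundaryShell:
    def test_single_voxel_tumor_matches_brute_force(self):
        tumor = _single_voxel_tumor()
        shell = build_boundary_shell(tumor)
        oracle_mask, oracle_t, _ = brute_force_shell(tumor)
        np.testing.assert_array_equal(shell.mask.mask, oracle_mask)
        assert shell.thickness_mm == pytest.approx(oracle_t)
        # 6 face neighbors at distance 1 do not reach volume 1? they do (6 >= 1)
        assert shell.mask.voxel_count == 6
        assert shell.thickness_mm == pytest.approx(1.0)

    def test_cube_tumor_matches_brute_force(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        tumor = RegionMask(mask=mask, spacing=(1.0, 1.0, 1.0))
        shell = build_boundary_shell(tumor)
        oracle_mask, oracle_t, _ = brute_force_shell(tumor)
        np.testing.assert_array_equal(shell.mask.mask, oracle_mask)
        assert shell.thickness_mm == pytest.approx(oracle_t)
        # face layer alone (600 voxels) is below the 1000-voxel tumor volume,
        # so the shell must extend past the first stratum
        assert shell.thickness_mm > 1.0
        assert shell.shell_volume_mm3 >= shell.tumor_volume_mm3

    @pytest.mark.parametrize("seed", range(8))
    def test_random_blobs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tumor = random_tumor_mask(rng)
        shell = build_boundary_shell(tumor)
        oracle_mask, oracle_t, oracle_deficit = brute_force_shell(tumor)
        np.testing.assert_array_equal(shell.mask.mask, oracle_mask)
        assert shell.thickness_mm == pytest.approx(oracle_t)
        assert shell.volume_deficit == oracle_deficit

    def test_anisotropic_spacing_prefers_in_plane_growth(self):
        # with 2 mm slices, the first stratum is purely in-plane (distance 1 mm)
        tumor = _single_voxel_tumor(spacing=(1.0, 1.0, 2.0))
        shell = build_boundary_shell(tumor)
        zs = np.argwhere(shell.mask.mask)[:, 2]
        assert shell.thickness_mm == pytest.approx(1.0)
        assert set(zs) == {4}

    def test_body_mask_restricts_shell(self):
        tumor = _single_voxel_tumor()
        body = np.zeros((9, 9, 9), dtype=bool)
        body[4, :, :] = True  # one-slab body
        shell = build_boundary_shell(tumor, body=RegionMask(mask=body, spacing=tumor.spacing))
        assert not shell.mask.mask[~body].any()

    def test_tumor_filling_grid_raises(self):
        tumor = RegionMask(mask=np.ones((4, 4, 4), dtype=bool), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(NoBoundaryError):
            build_boundary_shell(tumor)

    def test_empty_tumor_raises(self):
        tumor = RegionMask(mask=np.zeros((4, 4, 4), dtype=bool), spacing=(1.0, 1.0, 1.0))
        tumor.mask[:] = False
        with pytest.raises(EmptyRegionError):
            build_boundary_shell(tumor)

    def test_volume_deficit_flagged_when_body_too_small(self):
        tumor = _single_voxel_tumor()
        tiny_body = np.zeros((9, 9, 9), dtype=bool)
        tiny_body[4, 4, 4] = True  # body == tumor: no eligible voxels at all
        with pytest.raises(NoBoundaryError):
            build_boundary_shell(tumor, body=RegionMask(mask=tiny_body, spacing=tumor.spacing))
        tiny_body[4, 4, 5] = True  # a single eligible voxel: deficit for any multi-voxel tumor
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:5] = True
        big_tumor = RegionMask(mask=mask & ~tiny_body, spacing=tumor.spacing)
        shell = build_boundary_shell(big_tumor, body=RegionMask(mask=tiny_body, spacing=tumor.spacing))
        assert shell.volume_deficit
        assert shell.shell_volume_mm3 < shell.tumor_volume_mm3


class TestShapeMetrics:
    def test_unit_cube_closed_form(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        m = shape_metrics(RegionMask(mask=mask, spacing=(1.0, 1.0, 1.0)))
        assert m.volume_mm3 == pytest.approx(1.0)
        assert m.surface_area_mm2 == pytest.approx(6.0)
        assert m.max_extent_mm == pytest.approx(0.0)
        assert m.sphericity == pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6.0)

    def test_rod_face_count_and_extent(self):
        mask = np.zeros((3, 3, 12), dtype=bool)
        mask[1, 1, 1:11] = True
        m = shape_metrics(RegionMask(mask=mask, spacing=(1.0, 1.0, 1.0)))
        assert m.volume_mm3 == pytest.approx(10.0)
        assert m.surface_area_mm2 == pytest.approx(42.0)
        assert m.max_extent_mm == pytest.approx(9.0)
        assert m.sphericity == pytest.approx(np.pi ** (1 / 3) * 60 ** (2 / 3) / 42.0)

    def test_adjacent_pair_extent(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[2, 1, 1] = True
        assert max_extent_mm(RegionMask(mask=mask, spacing=(1.0, 1.0, 1.0))) == pytest.approx(1.0)

    def test_max_extent_matches_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tumor = random_tumor_mask(rng)
            coords = np.argwhere(tumor.mask) * np.asarray(tumor.spacing)
            diff = coords[:, None, :] - coords[None, :, :]
            expected = np.sqrt((diff**2).sum(axis=2)).max()
            assert max_extent_mm(tumor) == pytest.approx(expected)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        tumor = random_tumor_mask(rng, spacing=(1.0, 1.0, 1.0))
        doubled = RegionMask(mask=tumor.mask, spacing=(2.0, 2.0, 2.0))
        m1, m2 = shape_metrics(tumor), shape_metrics(doubled)
        assert m2.volume_mm3 == pytest.approx(8 * m1.volume_mm3)
        assert m2.max_extent_mm == pytest.approx(2 * m1.max_extent_mm)
        assert m2.surface_area_mm2 == pytest.approx(4 * m1.surface_area_mm2)
        assert m2.sphericity == pytest.approx(m1.sphericity)

    def test_digital_ball_sphericity_converges_to_face_count_limit(self):
        # exposed-face area of a digitized ball tends to 1.5x the smooth
        # sphere area, so sphericity converges to 2/3, not 1
        values = []
        for r in (6.0, 10.0, 14.0):
            n = int(2 * r + 5)
            c = n // 2
            ii, jj, kk = np.indices((n, n, n))
            ball = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= r**2
            values.append(shape_metrics(RegionMask(mask=ball, spacing=(1.0, 1.0, 1.0))).sphericity)
        assert values[-1] == pytest.approx(2.0 / 3.0, abs=0.03)
        assert abs(values[-1] - values[-2]) < abs(values[0] - 2.0 / 3.0) + 0.02

    def test_shell_volume_scale_equivariance(self):
        rng = np.random.default_rng(14)
        tumor = random_tumor_mask(rng, spacing=(1.0, 1.0, 1.0))
        doubled = RegionMask(mask=tumor.mask, spacing=(2.0, 2.0, 2.0))
        s1 = build_boundary_shell(tumor)
        s2 = build_boundary_shell(doubled)
        np.testing.assert_array_equal(s1.mask.mask, s2.mask.mask)
        assert s2.shell_volume_mm3 == pytest.approx(8 * s1.shell_volume_mm3)
        assert s2.thickness_mm == pytest.approx(2 * s1.thickness_mm)
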