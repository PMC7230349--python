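import numpy as np
import pytest

from eemauth import preprocess as pp
from eemauth.eem_io import AxisMismatchError, EEMCube, EEMError, EEMSample, WavelengthAxis

from conftest import small_random_cube


def axis(start, n, step=5.0):
    return WavelengthAxis(start + step * np.arange(n))


class TestSubtractBlank:
    def test_identical_blank_zeroes_sample(self):
        cube = small_random_cube(seed=1)
        blank = EEMSample("blank", cube.data[0], cube.ex, cube.em)
        out = pp.subtract_blank(cube, blank)
        assert np.all(out.data[0] == 0.0)

    def test_zero_blank_is_identity_and_clip_rule(self):
        cube = small_random_cube(seed=2)
        zero = EEMSample("blank", np.zeros(cube.shape[1:]), cube.ex, cube.em)
        assert np.array_equal(pp.subtract_blank(cube, zero).data, cube.data)
        big = np.zeros(cube.shape[1:])
        big[2, 3] = 1e9
        out = pp.subtract_blank(cube, EEMSample("b", big, cube.ex, cube.em))
        assert np.all(out.data[:, 2, 3] == 0.0)
        out2 = pp.subtract_blank(
            cube, EEMSample("b", big, cube.ex, cube.em), clip_negative=False
        )
        assert np.all(out2.data[:, 2, 3] < 0.0)

    def test_axis_mismatch_rejected(self):
        cube = small_random_cube(seed=3)
        blank = EEMSample(
            "b", np.zeros(cube.shape[1:]), axis(260.0, cube.shape[1]), cube.em
        )
        with pytest.raises(AxisMismatchError):
            pp.subtract_blank(cube, blank)


class TestRemoveExcitationBand:
    def test_grid_points_in_closed_interval_removed(self):
        cube = EEMCube(np.ones((1, 109, 4)), axis(210.0, 109), axis(400.0, 4))
        out = pp.remove_excitation_band(cube, 220.0, 240.0)
        assert len(out.ex) == 109 - 5  # 220, 225, 230, 235, 240
        assert not np.any((out.ex.values >= 220) & (out.ex.values <= 240))

    def test_band_outside_axis_is_noop(self):
        cube = small_random_cube(seed=4)
        out = pp.remove_excitation_band(cube, 700.0, 750.0)
        assert np.array_equal(out.data, cube.data)

    def test_emptying_axis_rejected(self):
        cube = small_random_cube(seed=5)
        with pytest.raises(EEMError):
            pp.remove_excitation_band(cube, 200.0, 800.0)


class TestZeroScatter:
    def test_em_le_ex_rule_on_two_point_axes(self):
        cube = EEMCube(
            np.ones((1, 2, 2)), axis(300.0, 2), axis(300.0, 2)
        )
        out, mask = pp.zero_scatter(cube, band_width=0.0)
        # zeroed: (300,300), (305,300), (305,305); kept: (300,305)
        assert out.data[0, 0, 0] == 0 and out.data[0, 1, 0] == 0
        assert out.data[0, 1, 1] == 0 and out.data[0, 0, 1] == 1.0
        assert mask.mask.sum() == 3

    def test_identical_axes_zero_count_is_triangular(self):
        cube = EEMCube(np.ones((2, 5, 5)), axis(300.0, 5), axis(300.0, 5))
        out, mask = pp.zero_scatter(cube, band_width=0.0)
        assert mask.mask.sum() == 15  # J(J+1)/2
        assert out.data[:, mask.mask].max() == 0.0

    def test_idempotent_and_band(self):
        cube = small_random_cube(seed=6, J=8, K=20)
        out1, m1 = pp.zero_scatter(cube, band_width=10.0)
        out2, m2 = pp.zero_scatter(out1, band_width=10.0)
        assert np.array_equal(out1.data, out2.data)
        exv, emv = cube.ex.values, cube.em.values
        inside_band = (emv[None, :] > exv[:, None]) & (
            emv[None, :] <= exv[:, None] + 10.0
        )
        assert np.all(m1.mask[inside_band])


class TestSelectRegion:
    def test_counts_on_instrument_grid(self):
        cube = EEMCube(np.ones((1, 109, 109)), axis(210.0, 109), axis(210.0, 109))
        out = pp.select_region(cube, (270.0, 510.0), (290.0, 575.0))
        assert out.shape == (1, 49, 58)

    def test_full_range_is_identity_and_nesting(self):
        cube = small_random_cube(seed=7)
        full = pp.select_region(cube, (200.0, 800.0), (200.0, 800.0))
        assert np.array_equal(full.data, cube.data)
        outer = pp.select_region(cube, (255.0, 275.0), (305.0, 325.0))
        nested = pp.select_region(outer, (260.0, 270.0), (310.0, 320.0))
        direct = pp.select_region(cube, (260.0, 270.0), (310.0, 320.0))
        assert np.array_equal(nested.data, direct.data)

    def test_empty_intersection_rejected(self):
        cube = small_random_cube(seed=8)
        with pytest.raises(EEMError):
            pp.select_region(cube, (600.0, 650.0), (300.0, 340.0))


class TestImputeAndCenter:
    def test_nan_replacement_count(self):
        cube = small_random_cube(seed=9)
        cube.data[0, 0, 0] = np.nan
        cube.data[1, 2, 3] = np.inf
        cube.data[2, 1, 1] = -np.inf
        out, count = pp.impute_missing_zero(cube)
        assert count == 3
        assert np.isfinite(out.data).all()
        out2, count2 = pp.impute_missing_zero(out)
        assert count2 == 0 and np.array_equal(out2.data, out.data)

    def test_centering_roundtrip_and_zero_means(self):
        cube = small_random_cube(seed=10)
        centered, state = pp.mean_center_mode1(cube)
        scale = np.abs(cube.data).max()
        assert np.abs(centered.data.mean(axis=0)).max() < 1e-9 * scale
        restored = pp.uncenter_mode1(centered, state)
        assert np.abs(restored.data - cube.data).max() < 1e-9 * scale

    def test_identical_samples_center_to_zero(self):
        one = small_random_cube(seed=11, I=1)
        cube = EEMCube(np.repeat(one.data, 2, axis=0), one.ex, one.em)
        centered, _ = pp.mean_center_mode1(cube)
        assert np.all(centered.data == 0.0)

    def test_single_sample_cannot_center(self):
        with pytest.raises(EEMError):
            pp.mean_center_mode1(small_random_cube(seed=12, I=1))
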