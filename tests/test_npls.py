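import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eemauth.eem_io import EEMCube, EEMError, WavelengthAxis
from eemauth.npls import (
    cross_validate,
    encode_response,
    fit_npls,
    predict,
    scan_latent_variables,
    venetian_blinds_folds,
    vip_scores,
)

from conftest import small_random_cube


def make_cube(X):
    I, J, K = X.shape
    return EEMCube(
        X,
        WavelengthAxis(270.0 + 5.0 * np.arange(J)),
        WavelengthAxis(300.0 + 5.0 * np.arange(K)),
    )


class TestEncodeResponse:
    def test_binary_origin_coding(self):
        assert np.array_equal(encode_response(["M", "M", "F"], positive="F"), [0, 0, 1])

    def test_swapped_mapping_is_complement(self):
        y1 = encode_response(["M", "F", "F"], positive="F")
        y2 = encode_response(["M", "F", "F"], positive="M")
        assert np.array_equal(y1 + y2, np.ones(3))

    def test_single_class_rejected(self):
        with pytest.raises(EEMError):
            encode_response(["M", "M"], positive="M")
        with pytest.raises(EEMError):
            encode_response(["A", "B", "C"], positive="A")


class TestFit:
    def test_recovers_constructed_triad(self):
        rng = np.random.default_rng(1)
        I, J, K = 20, 12, 14
        t0 = rng.standard_normal(I)
        wj0 = rng.standard_normal(J); wj0 /= np.linalg.norm(wj0)
        wk0 = rng.standard_normal(K); wk0 /= np.linalg.norm(wk0)
        X = np.einsum("i,j,k->ijk", t0, wj0, wk0)
        cube = make_cube(X)
        m = fit_npls(cube, t0, 1)
        assert m.yvar_pct[-1] >= 99.9
        assert abs(m.WJ[:, 0] @ wj0) >= 0.999
        assert abs(m.WK[:, 0] @ wk0) >= 0.999

    def test_weights_unit_norm_and_scores_orthogonal(self):
        cube = small_random_cube(seed=2, I=15, J=8, K=9)
        y = np.random.default_rng(3).uniform(0, 1, 15)
        m = fit_npls(cube, y, 5)
        assert np.allclose(np.linalg.norm(m.WJ, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(m.WK, axis=0), 1.0)
        G = m.T.T @ m.T
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_variance_fractions_monotone_and_bounded(self):
        cube = small_random_cube(seed=4, I=12)
        y = np.random.default_rng(5).uniform(0, 1, 12)
        m = fit_npls(cube, y, 6)
        for v in (m.xvar_pct, m.yvar_pct):
            assert np.all(np.diff(v) >= -1e-9)
            assert v[-1] <= 100.0 + 1e-9
        assert np.all(m.xvar_pct >= -1e-9)

    def test_preconditions(self):
        cube = small_random_cube(seed=6, I=5)
        with pytest.raises(EEMError):
            fit_npls(cube, np.zeros(5), 2)  # zero-variance response
        with pytest.raises(EEMError):
            fit_npls(cube, np.arange(5.0), 5)  # L > I-1


class TestPredict:
    def test_training_cube_reproduces_fit(self):
        cube = small_random_cube(seed=7, I=10)
        y = np.random.default_rng(8).uniform(0, 1, 10)
        m = fit_npls(cube, y, 3)
        y_hat, _ = predict(m, cube)
        assert np.abs(y_hat - m.fitted).max() < 1e-9

    def test_boundary_maps_to_class_one(self):
        cube = small_random_cube(seed=9, I=6)
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        m = fit_npls(cube, y, 1)
        y_hat, classes = predict(m, cube, threshold=float(m.fitted[0]))
        assert classes[0] == 1

    def test_axis_mismatch_rejected(self):
        cube = small_random_cube(seed=10, I=6)
        y = np.arange(6.0)
        m = fit_npls(cube, y, 1)
        other = EEMCube(
            cube.data,
            WavelengthAxis(cube.ex.values + 5.0),
            cube.em,
        )
        with pytest.raises(EEMError):
            predict(m, other)


class TestVenetianBlinds:
    def test_fold_pattern_i6_s3(self):
        folds = venetian_blinds_folds(6, 3)
        held = [sorted(np.flatnonzero(folds == f)) for f in range(3)]
        assert held == [[0, 3], [1, 4], [2, 5]]

    def test_i65_s5_balanced(self):
        folds = venetian_blinds_folds(65, 5)
        sizes = [int((folds == f).sum()) for f in range(5)]
        assert sizes == [13] * 5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(4, 80), st.integers(2, 10), st.integers(0, 9))
    def test_partition_property(self, I, s, offset):
        if s > I:
            return
        folds = venetian_blinds_folds(I, s, offset)
        assert folds.size == I
        assert set(folds.tolist()) == set(range(s))

    def test_s_out_of_range(self):
        with pytest.raises(EEMError):
            venetian_blinds_folds(4, 5)


class TestCrossValidate:
    def test_each_sample_predicted_once(self):
        cube = small_random_cube(seed=11, I=13)
        y = (np.arange(13) % 2).astype(float)
        res = cross_validate(cube, y, L=2, s=3)
        assert np.all(np.isfinite(res.y_pred_cv))
        assert res.rmsec >= 0 and res.rmsecv >= 0

    def test_perfect_fit_metrics(self):
        # response equal to a strong rank-one score: RMSEC ~ 0, accuracy 100
        rng = np.random.default_rng(12)
        t0 = np.concatenate([rng.uniform(0.8, 1.0, 6), rng.uniform(0.0, 0.2, 6)])
        wj = np.abs(rng.standard_normal(7)); wj /= np.linalg.norm(wj)
        wk = np.abs(rng.standard_normal(8)); wk /= np.linalg.norm(wk)
        X = np.einsum("i,j,k->ijk", t0, wj, wk)
        y = (t0 > 0.5).astype(float)
        res = cross_validate(make_cube(X), y, L=2, s=3)
        assert res.training_accuracy_pct == 100.0

    def test_scan_table_shape_and_monotonicity(self):
        cube = small_random_cube(seed=13, I=14)
        y = (np.arange(14) % 2).astype(float)
        tab = scan_latent_variables(cube, y, L_max=5, s=3, offsets=(0, 1, 2))
        assert list(tab["L"]) == [1, 2, 3, 4, 5]
        assert np.all(np.diff(tab["xvar_pct_mean"]) >= -1e-9)
        # RMSEC non-increasing: nested least squares on orthogonal scores
        assert np.all(np.diff(tab["rmsec_mean"]) <= 1e-9)


class TestVIP:
    def test_mean_square_is_one(self):
        cube = small_random_cube(seed=14, I=12)
        y = np.random.default_rng(15).uniform(0, 1, 12)
        m = fit_npls(cube, y, 4)
        vip = vip_scores(m, y)
        assert (vip.scores**2).mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(vip.scores >= 0)

    def test_single_lv_reduces_to_composite_weight(self):
        cube = small_random_cube(seed=16, I=10)
        y = np.random.default_rng(17).uniform(0, 1, 10)
        m = fit_npls(cube, y, 1)
        vip = vip_scores(m, y)
        w = np.abs(np.outer(m.WJ[:, 0], m.WK[:, 0]))
        ratio = vip.scores / np.maximum(w, 1e-300)
        assert ratio.std() / ratio.mean() < 1e-9


class TestBilinearConsistency:
    def test_k1_cube_equals_pls1(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(18)
        X = rng.uniform(0, 1, (20, 12, 1))
        y = rng.uniform(0, 1, 20)
        cube = make_cube(X)
        for L in (1, 2, 4):
            m = fit_npls(cube, y, L)
            sk = PLSRegression(n_components=L, scale=False).fit(X[:, :, 0], y)
            assert np.abs(m.fitted - sk.predict(X[:, :, 0]).ravel()).max() < 1e-8
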