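import numpy as np
import pytest

from eemauth.eem_io import EEMCube, EEMError, WavelengthAxis
from eemauth.parafac import (
    NONNEGATIVITY,
    UNIMODALITY,
    congruence,
    core_consistency,
    explained_variance,
    fit_parafac,
    identify_fluorophores,
    init_svd,
    match_components,
    scan_components,
    split_half,
)

from conftest import rank_f_cube, small_random_cube
from oracles import brute_force_als, corcondia_oracle


def match_to_truth(model, B_true, C_true):
    Bn = B_true / np.linalg.norm(B_true, axis=0)
    Cn = C_true / np.linalg.norm(C_true, axis=0)
    return match_components(model.B, model.C, Bn, Cn)


class TestInit:
    def test_rank1_cube_initialization_near_truth(self):
        cube, (A, B, C) = rank_f_cube(seed=1, F=1)
        A0, B0, C0 = init_svd(cube, 1)
        assert congruence(B0[:, 0], B[:, 0]) >= 0.99
        assert congruence(C0[:, 0], C[:, 0]) >= 0.99

    def test_replicates_differ_and_f0_rejected(self):
        cube = small_random_cube(seed=2)
        a1 = init_svd(cube, 2, seed=0, replicate=1)
        a2 = init_svd(cube, 2, seed=0, replicate=2)
        assert not np.allclose(a1[0], a2[0])
        with pytest.raises(EEMError):
            init_svd(cube, 0)

    def test_f_above_rank_falls_back_to_random_nonneg(self):
        cube, _ = rank_f_cube(seed=3, F=1, I=4, J=4, K=4)
        A0, B0, C0 = init_svd(cube, 3, seed=1)
        assert A0.shape == (4, 3) and np.all(A0 > 0)


class TestFit:
    def test_recovers_four_random_triads(self):
        cube, (A, B, C) = rank_f_cube(seed=4, F=4, I=12, J=10, K=11)
        model = fit_parafac(cube, 4, replicates=8, tol=1e-12, max_iter=3000, seed=0)
        assert model.explained_pct >= 99.9
        for _, _, s in match_to_truth(model, B, C):
            assert s >= 0.99 * 0.99  # product of two congruences

    def test_all_zero_cube_rejected(self):
        cube = small_random_cube(seed=5)
        with pytest.raises(EEMError):
            fit_parafac(cube.with_data(np.zeros(cube.shape)), 1)

    def test_f1_contract_and_scaling_convention(self):
        cube = small_random_cube(seed=6)
        model = fit_parafac(cube, 1, replicates=1, tol=1e-10)
        assert np.all(model.A >= 0) and np.all(model.B >= 0) and np.all(model.C >= 0)
        assert 0 < model.explained_pct <= 100
        assert np.allclose(np.linalg.norm(model.B, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(model.C, axis=0), 1.0)

    def test_loss_monotone_within_replicate(self):
        cube = small_random_cube(seed=7)
        model = fit_parafac(cube, 2, replicates=1, tol=1e-12, max_iter=300)
        d = np.diff(model.loss_history)
        assert np.all(d <= 1e-9 * np.maximum(model.loss_history[:-1], 1e-300))

    def test_component_order_by_descending_magnitude(self):
        cube, _ = rank_f_cube(seed=8, F=3)
        model = fit_parafac(cube, 3, replicates=2, tol=1e-12, seed=0)
        norms = np.linalg.norm(model.A, axis=0)
        assert np.all(np.diff(norms) <= 1e-12)

    def test_unimodality_constraint_shapes_spectral_loadings(self):
        cube, _ = rank_f_cube(seed=9, F=2)
        model = fit_parafac(
            cube, 2, constraints={NONNEGATIVITY, UNIMODALITY},
            replicates=1, tol=1e-10, max_iter=500,
        )
        for M in (model.B, model.C):
            for f in range(2):
                d = np.diff(M[:, f])
                falls = np.flatnonzero(d < -1e-10)
                if falls.size:
                    assert not np.any(d[falls[0]:] > 1e-10)

    def test_reconstruction_invariant_to_component_permutation(self):
        cube, _ = rank_f_cube(seed=10, F=3)
        model = fit_parafac(cube, 3, replicates=1, tol=1e-12)
        ref = model.reconstruct()
        perm = [2, 0, 1]
        model.A, model.B, model.C = model.A[:, perm], model.B[:, perm], model.C[:, perm]
        # identical up to summation-order rounding
        assert np.abs(model.reconstruct() - ref).max() <= 1e-12 * np.abs(ref).max()


class TestOracleEquivalence:
    """Unconstrained ALS against an explicit Kronecker least-squares fit."""

    @pytest.mark.parametrize("F", [1, 2])
    def test_tiny_cube_loss_matches_brute_force(self, F):
        rng = np.random.default_rng(20 + F)
        X = rng.uniform(0.0, 1.0, (6, 7, 8))
        cube = EEMCube(
            X,
            WavelengthAxis(300.0 + 5.0 * np.arange(7)),
            WavelengthAxis(400.0 + 5.0 * np.arange(8)),
        )
        model = fit_parafac(
            cube, F, constraints=(), replicates=5, tol=1e-14, max_iter=5000, seed=0
        )
        sse_ref = min(brute_force_als(X, F, n_iter=5000, seed=s)[3] for s in range(4))
        assert model.sse == pytest.approx(sse_ref, rel=1e-6)

    def test_core_consistency_matches_kronecker_oracle(self):
        cube, _ = rank_f_cube(seed=30, F=2, I=6, J=7, K=8)
        noisy = cube.with_data(
            cube.data + 0.01 * cube.data.max() * np.random.default_rng(3).standard_normal(cube.shape)
        )
        for F in (2, 4):
            model = fit_parafac(noisy, F, replicates=2, tol=1e-12, max_iter=2000, seed=0)
            mine = core_consistency(model, noisy)
            ref = corcondia_oracle(noisy.data, model.A, model.B, model.C)
            assert mine == pytest.approx(ref, abs=1e-6 * max(1.0, abs(ref)))
        # valid rank: near 100; overfitted: well below
        m2 = fit_parafac(noisy, 2, replicates=2, tol=1e-12, seed=0)
        assert core_consistency(m2, noisy) >= 99.0


class TestDiagnostics:
    def test_explained_variance_identities(self):
        cube, _ = rank_f_cube(seed=40, F=2)
        model = fit_parafac(cube, 2, replicates=2, tol=1e-13, seed=0)
        assert explained_variance(model, cube) == pytest.approx(100.0, abs=1e-6)
        zero = fit_parafac(cube, 1, replicates=1, max_iter=1)
        zero.A = np.zeros_like(zero.A)
        assert explained_variance(zero, cube) == pytest.approx(0.0)
        with pytest.raises(EEMError):
            explained_variance(model, cube.with_data(np.zeros(cube.shape)))

    def test_core_consistency_is_100_at_f1(self):
        cube = small_random_cube(seed=41)
        model = fit_parafac(cube, 1, replicates=1, tol=1e-12)
        assert core_consistency(model, cube) == pytest.approx(100.0, abs=1e-6)

    def test_split_half_duplicated_samples(self):
        cube, _ = rank_f_cube(seed=42, F=2, I=4)
        dup = EEMCube(
            np.concatenate([cube.data, cube.data]), cube.ex, cube.em
        )
        # alternating split on duplicated samples pairs identical cubes
        sim = split_half(dup, 2, replicates=2, tol=1e-12)
        assert sim >= 99.0

    def test_split_half_needs_four_samples(self):
        cube = small_random_cube(seed=43, I=3)
        with pytest.raises(EEMError):
            split_half(cube, 1)

    def test_scan_report_structure(self):
        cube, _ = rank_f_cube(seed=44, F=2, I=8, J=9, K=10)
        noisy = cube.with_data(
            cube.data + 0.02 * cube.data.max() * np.random.default_rng(4).standard_normal(cube.shape)
        )
        report = scan_components(noisy, 3, replicates=2, tol=1e-9, max_iter=500)
        expl = [r.explained_pct for r in report.rows]
        assert all(b >= a - 1e-6 for a, b in zip(expl, expl[1:]))
        scaled = [r.residual_scaled for r in report.rows]
        assert max(scaled) == pytest.approx(1.0)
        assert all(0.0 <= s <= 1.0 for s in scaled)
        assert report.rows[0].core_consistency_pct == pytest.approx(100.0, abs=1e-4)


class TestIdentify:
    def _model_with_peaks(self, pex, pem):
        ex = WavelengthAxis(250.0 + 5.0 * np.arange(91))
        em = WavelengthAxis(260.0 + 5.0 * np.arange(99))
        B = np.exp(-0.5 * ((ex.values - pex) / 10.0) ** 2)[:, None]
        C = np.exp(-0.5 * ((em.values - pem) / 10.0) ** 2)[:, None]
        cube = EEMCube(np.ones((2, 91, 99)), ex, em)
        model = fit_parafac(cube, 1, replicates=1, max_iter=1)
        model.B, model.C = B / np.linalg.norm(B), C / np.linalg.norm(C)
        model.ex_values, model.em_values = ex.values, em.values
        return model

    @pytest.mark.parametrize(
        "pex,pem,expected",
        [
            (410.0, 675.0, "chlorophyll"),
            (340.0, 525.0, "oxidation"),
            (295.0, 425.0, "tocopherol"),
            (280.0, 330.0, "phenolic"),
            (600.0, 640.0, "unassigned"),
        ],
    )
    def test_rule_windows(self, pex, pem, expected):
        model = self._model_with_peaks(pex, pem)
        (a,) = identify_fluorophores(model)
        assert a.name == expected
        assert a.peak_ex == pex and a.peak_em == pem
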