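import numpy as np
import pytest

from eemauth import preprocess as pp
from eemauth.eem_io import EEMCube, WavelengthAxis
from eemauth.synth import SyntheticSpec, generate_cube

FIXTURE_SEED = 7


def small_random_cube(seed: int = 0, I: int = 5, J: int = 6, K: int = 7) -> EEMCube:
    rng = np.random.default_rng(seed)
    return EEMCube(
        rng.uniform(0.0, 10.0, (I, J, K)),
        WavelengthAxis(250.0 + 5.0 * np.arange(J)),
        WavelengthAxis(300.0 + 5.0 * np.arange(K)),
    )


def rank_f_cube(seed: int, F: int, I: int = 8, J: int = 9, K: int = 10) -> tuple[EEMCube, tuple]:
    """Noiseless non-negative rank-F cube with known generating triads."""
    rng = np.random.default_rng(seed)
    # gamma-distributed factors: strictly positive but sparse enough that
    # the triads are well separated (dense uniform positives are nearly
    # collinear, a degenerate regime for any trilinear fit)
    A = rng.gamma(0.7, 1.0, (I, F)) + 0.05
    B = rng.gamma(0.7, 1.0, (J, F)) + 0.02
    C = rng.gamma(0.7, 1.0, (K, F)) + 0.02
    X = np.einsum("if,jf,kf->ijk", A, B, C)
    cube = EEMCube(
        X,
        WavelengthAxis(250.0 + 5.0 * np.arange(J)),
        WavelengthAxis(300.0 + 5.0 * np.arange(K)),
    )
    return cube, (A, B, C)


@pytest.fixture(scope="session")
def twoclass_cube():
    """30 'M' + 35 'F' noisy four-fluorophore cube (the standard cohort)."""
    cube, truth = generate_cube(SyntheticSpec(seed=FIXTURE_SEED))
    return cube, truth


@pytest.fixture(scope="session")
def noiseless_cube():
    cube, truth = generate_cube(
        SyntheticSpec(seed=FIXTURE_SEED, noise_sd=0.0, scatter=False)
    )
    return cube, truth


@pytest.fixture(scope="session")
def parafac_ready(twoclass_cube):
    """Two-class cube after the PARAFAC preprocessing path."""
    cube, truth = twoclass_cube
    pre, mask = pp.preprocess_parafac(cube)
    return pre, truth, mask


@pytest.fixture(scope="session")
def npls_ready(twoclass_cube):
    """Two-class cube after the tri-PLS preprocessing path (uncentered;
    centering happens inside the fits)."""
    cube, truth = twoclass_cube
    pre, _ = pp.preprocess_npls(cube, center=False)
    return pre, truth
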