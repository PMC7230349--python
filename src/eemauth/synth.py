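"""Synthetic EEM cubes with the four-fluorophore structure of virgin olive oil.

Each cube is an approximately trilinear sum of fluorophores — chlorophylls,
oxidation products, tocopherols and phenolics — whose excitation/emission
profiles are Gaussian-sum bands placed at the maxima reported for olive-oil
fluorescence, with unit-norm profiles so that mode-1 coefficients read as
relative concentrations.  Concentrations are drawn per class from
log-normal distributions (strictly positive, right-skewed, matching the
observed non-normality of phenolic and tocopherol levels); the class of
interest ("M", the authentic origin) has higher chlorophyll and markedly
lower phenolic and tocopherol medians than the reference class ("F").
Additive Gaussian noise and an optional Rayleigh-like scatter ridge along
the ex = em diagonal complete the emulation.  Ground truth (true loadings,
labels, and the exact noise field) is returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from eemauth.eem_io import EEMCube, EEMError, WavelengthAxis, write_cube, write_matrix_csv

__all__ = [
    "FluorophoreSpec",
    "SyntheticSpec",
    "GroundTruth",
    "DEFAULT_FLUOROPHORES",
    "build_profiles",
    "generate_cube",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class FluorophoreSpec:
    """Gaussian-sum spectral bands: (center nm, width nm, relative height)."""

    name: str
    ex_peaks: tuple[tuple[float, float, float], ...]
    em_peaks: tuple[tuple[float, float, float], ...]


#: Default four-fluorophore preset.  Peak centers sit at the characteristic
#: olive-oil maxima (chlorophyll em 675; oxidation em 525, ex 325/340;
#: tocopherol ex 295, em 425; phenolic ex 278, em 330); widths and the
#: relative height of chlorophyll's red excitation band (0.5, weaker than
#: the Soret-like blue band) are generator choices.
DEFAULT_FLUOROPHORES: tuple[FluorophoreSpec, ...] = (
    FluorophoreSpec("chlorophyll", ((410.0, 25.0, 1.0), (660.0, 15.0, 0.5)), ((675.0, 12.0, 1.0),)),
    FluorophoreSpec("oxidation", ((325.0, 12.0, 1.0), (340.0, 12.0, 1.0)), ((525.0, 40.0, 1.0),)),
    FluorophoreSpec("tocopherol", ((295.0, 8.0, 1.0),), ((425.0, 35.0, 1.0),)),
    FluorophoreSpec("phenolic", ((278.0, 8.0, 1.0),), ((330.0, 30.0, 1.0),)),
)

#: Per-class log-normal concentration medians (arbitrary units) for the
#: reference class "F"; geometric SD is shared.  The "M" class applies the
#: multipliers below: slightly more chlorophyll, unchanged oxidation, and
#: clearly less tocopherol and phenolic signal.
DEFAULT_MEDIANS_F: dict[str, float] = {
    "chlorophyll": 100.0,
    "oxidation": 40.0,
    "tocopherol": 60.0,
    "phenolic": 50.0,
}
DEFAULT_CLASS_M_MULTIPLIERS: dict[str, float] = {
    "chlorophyll": 1.2,
    "oxidation": 1.0,
    "tocopherol": 0.5,
    "phenolic": 0.4,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic cube; the seed determines it entirely."""

    ex_range: tuple[float, float] = (250.0, 700.0)
    ex_step: float = 5.0
    em_range: tuple[float, float] = (260.0, 750.0)
    em_step: float = 5.0
    fluorophores: tuple[FluorophoreSpec, ...] = DEFAULT_FLUOROPHORES
    medians_f: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEDIANS_F))
    class_m_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_M_MULTIPLIERS)
    )
    geometric_sd: float = 1.3
    noise_sd: float = 0.02          # fraction of the max clean signal
    scatter: bool = True
    scatter_band: float = 4.0       # nm, Gaussian sd of the diagonal ridge
    scatter_height: float = 0.5     # fraction of the max clean signal
    n_m: int = 30
    n_f: int = 35
    seed: int = 7

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything needed to verify recovery: truth + the exact noise field."""

    A: np.ndarray            # I x F true concentrations
    B: np.ndarray            # J x F true excitation profiles (unit norm)
    C: np.ndarray            # K x F true emission profiles (unit norm)
    labels: list[str]
    fluorophore_names: list[str]
    noise_field: np.ndarray  # emitted cube minus trilinear reconstruction


def _grid(rng: tuple[float, float], step: float) -> np.ndarray:
    n = int(round((rng[1] - rng[0]) / step)) + 1
    return rng[0] + step * np.arange(n)


def _gauss_sum(grid: np.ndarray, peaks) -> np.ndarray:
    y = np.zeros_like(grid)
    for center, width, height in peaks:
        if width <= 0 or height <= 0:
            raise EEMError("peak widths and heights must be positive")
        if not (grid[0] <= center <= grid[-1]):
            raise EEMError(f"peak center {center} nm lies off the grid")
        y += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return y / np.linalg.norm(y)


def build_profiles(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm excitation (J x F) and emission (K x F) profiles on the grid."""
    ex = _grid(spec.ex_range, spec.ex_step)
    em = _grid(spec.em_range, spec.em_step)
    B = np.column_stack([_gauss_sum(ex, fl.ex_peaks) for fl in spec.fluorophores])
    C = np.column_stack([_gauss_sum(em, fl.em_peaks) for fl in spec.fluorophores])
    return B, C


def generate_cube(spec: SyntheticSpec) -> tuple[EEMCube, GroundTruth]:
    """Draw one labelled two-class cube and its ground truth.

    X = sum_f a_f o b_f o c_f + scatter + noise, truncated at zero.  The
    first n_m samples carry label "M", the rest "F".  Concentrations are
    log-normal per class and fluorophore; the noise field stored in the
    ground truth is (emitted cube - trilinear reconstruction), absorbing
    scatter and the zero-truncation, so truth + noise reproduces the cube
    to floating-point rounding.
    """
    if spec.n_m < 1 or spec.n_f < 1:
        raise EEMError("need at least one sample per class")
    rng = np.random.default_rng(spec.seed)
    ex = _grid(spec.ex_range, spec.ex_step)
    em = _grid(spec.em_range, spec.em_step)
    B, C = build_profiles(spec)
    names = [fl.name for fl in spec.fluorophores]

    I = spec.n_m + spec.n_f
    labels = ["M"] * spec.n_m + ["F"] * spec.n_f
    sigma_ln = np.log(spec.geometric_sd)
    A = np.empty((I, len(names)))
    for f, name in enumerate(names):
        med_f = spec.medians_f[name]
        med_m = med_f * spec.class_m_multipliers.get(name, 1.0)
        med = np.where(np.array(labels) == "M", med_m, med_f)
        A[:, f] = np.exp(np.log(med) + sigma_ln * rng.standard_normal(I))

    clean = np.einsum("if,jf,kf->ijk", A, B, C)
    peak = float(clean.max())
    X = clean.copy()
    if spec.scatter:
        d = em[None, :] - ex[:, None]  # em minus ex, nm
        ridge = np.exp(-0.5 * (d / max(spec.scatter_band, 1e-9)) ** 2)
        X = X + spec.scatter_height * peak * ridge[None, :, :]
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * peak * rng.standard_normal(X.shape)
    np.maximum(X, 0.0, out=X)

    cube = EEMCube(
        X,
        WavelengthAxis(ex),
        WavelengthAxis(em),
        [f"{lab}{i:03d}" for i, lab in enumerate(labels)],
        list(labels),
    )
    truth = GroundTruth(
        A=A, B=B, C=C, labels=labels, fluorophore_names=names,
        noise_field=X - clean,
    )
    return cube, truth


def _write_truth(out: Path, stem: str, truth: GroundTruth, ex: np.ndarray, em: np.ndarray) -> None:
    write_matrix_csv(out / f"{stem}_true_A.csv", truth.A,
                     [f"s{i}" for i in range(truth.A.shape[0])], truth.fluorophore_names,
                     corner="sample")
    write_matrix_csv(out / f"{stem}_true_B.csv", truth.B, ex, truth.fluorophore_names,
                     corner="ex_nm")
    write_matrix_csv(out / f"{stem}_true_C.csv", truth.C, em, truth.fluorophore_names,
                     corner="em_nm")


def make_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write the standard synthetic test fixtures; returns manifest paths.

    * ``tiny``      — 6 x 7 x 8 low-rank cube for brute-force oracles;
    * ``noiseless`` — noise- and scatter-free rank-4 cube (recovery tests);
    * ``twoclass``  — 30 "M" + 35 "F" noisy cube with the class contrasts;
    * ``null``      — the two-class cube with seeded permuted labels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests: dict[str, Path] = {}

    rng = np.random.default_rng(seed)
    # tiny oracle cube: random non-negative rank-2 triads plus slight noise
    I, J, K = 6, 7, 8
    At = rng.uniform(0.5, 2.0, (I, 2))
    Bt = rng.uniform(0.1, 1.0, (J, 2))
    Ct = rng.uniform(0.1, 1.0, (K, 2))
    tiny = np.einsum("if,jf,kf->ijk", At, Bt, Ct)
    tiny += 0.01 * tiny.max() * rng.standard_normal(tiny.shape)
    np.maximum(tiny, 0.0, out=tiny)
    tiny_cube = EEMCube(
        tiny,
        WavelengthAxis(300.0 + 10.0 * np.arange(J)),
        WavelengthAxis(400.0 + 10.0 * np.arange(K)),
    )
    manifests["tiny"] = write_cube(tiny_cube, out_dir / "tiny")

    spec = SyntheticSpec(seed=seed)
    noiseless, truth = generate_cube(spec.with_(noise_sd=0.0, scatter=False))
    manifests["noiseless"] = write_cube(noiseless, out_dir / "noiseless")
    _write_truth(out_dir / "noiseless", "noiseless", truth,
                 noiseless.ex.values, noiseless.em.values)

    twoclass, truth2 = generate_cube(spec)
    manifests["twoclass"] = write_cube(twoclass, out_dir / "twoclass")
    _write_truth(out_dir / "twoclass", "twoclass", truth2,
                 twoclass.ex.values, twoclass.em.values)

    perm = np.random.default_rng(seed + 1).permutation(twoclass.n_samples)
    null_cube = EEMCube(
        twoclass.data,
        twoclass.ex,
        twoclass.em,
        list(twoclass.sample_ids),
        [twoclass.labels[i] for i in perm],
    )
    manifests["null"] = write_cube(null_cube, out_dir / "null")
    return manifests
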