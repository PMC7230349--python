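"""EEM preprocessing: blank subtraction, band removal, scatter zeroing,
region selection, missing-value handling and mode-1 mean centering.

The canonical order for the two analysis paths is::

    subtract_blank -> remove_excitation_band -> zero_scatter
        PARAFAC path: stop here
        tri-PLS path: -> select_region -> impute_missing_zero -> mean_center_mode1

Rayleigh scatter handling follows the physical rule that a fluorophore
cannot emit at higher energy than its excitation: every cell with
emission <= excitation wavelength, plus a band immediately above the
diagonal, is forced to zero.  All wavelength ranges are closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from eemauth.eem_io import AxisMismatchError, EEMCube, EEMError, EEMSample, WavelengthAxis

__all__ = [
    "ScatterMask",
    "CenteringState",
    "subtract_blank",
    "remove_excitation_band",
    "zero_scatter",
    "select_region",
    "impute_missing_zero",
    "mean_center_mode1",
    "uncenter_mode1",
    "preprocess_parafac",
    "preprocess_npls",
]

log = logging.getLogger(__name__)

DEFAULT_SCATTER_BAND_NM = 10.0
DEFAULT_EX_DROP = (220.0, 240.0)
DEFAULT_NPLS_EX_RANGE = (270.0, 510.0)
DEFAULT_NPLS_EM_RANGE = (290.0, 575.0)


@dataclass(frozen=True)
class ScatterMask:
    """Boolean J x K grid of cells forced to zero (True = zeroed)."""

    mask: np.ndarray
    band_width: float


@dataclass(frozen=True)
class CenteringState:
    """Per-variable means over samples, enough to undo mode-1 centering."""

    means: np.ndarray  # J x K


def subtract_blank(cube: EEMCube, blank: EEMSample, clip_negative: bool = True) -> EEMCube:
    """Subtract a blank (solvent) landscape from every sample.

    Negative differences are clipped to zero by default: negative
    fluorescence intensities are not physically meaningful.
    """
    if blank.ex_axis != cube.ex or blank.em_axis != cube.em:
        raise AxisMismatchError("blank axes do not match cube axes")
    out = cube.data - blank.matrix[None, :, :]
    if clip_negative:
        np.maximum(out, 0.0, out=out)
    return cube.with_data(out)


def remove_excitation_band(cube: EEMCube, lo: float, hi: float) -> EEMCube:
    """Delete all excitation rows with lo <= lambda_ex <= hi (inclusive)."""
    if lo > hi:
        raise EEMError(f"invalid excitation band: lo={lo} > hi={hi}")
    keep = ~((cube.ex.values >= lo) & (cube.ex.values <= hi))
    if not np.any(keep):
        raise EEMError("excitation-band removal would empty the excitation axis")
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("remove_excitation_band: dropped %d excitation rows in [%g, %g] nm", n_drop, lo, hi)
    return EEMCube(
        cube.data[:, keep, :],
        WavelengthAxis(cube.ex.values[keep]),
        cube.em,
        list(cube.sample_ids),
        list(cube.labels) if cube.labels is not None else None,
    )


def scatter_mask(ex: WavelengthAxis, em: WavelengthAxis, band_width: float) -> ScatterMask:
    """Mask of cells with em <= ex, plus the band ex < em <= ex + band_width."""
    if band_width < 0:
        raise EEMError("band_width must be >= 0")
    exv = ex.values[:, None]
    emv = em.values[None, :]
    mask = emv <= exv + band_width
    return ScatterMask(mask=mask, band_width=float(band_width))


def zero_scatter(
    cube: EEMCube, band_width: float = DEFAULT_SCATTER_BAND_NM
) -> tuple[EEMCube, ScatterMask]:
    """Zero the Rayleigh-scatter region (em <= ex and the near-diagonal band).

    Idempotent; returns the mask so downstream fits can optionally treat
    the zeroed cells as missing rather than as observed zeros.
    """
    m = scatter_mask(cube.ex, cube.em, band_width)
    out = cube.data.copy()
    out[:, m.mask] = 0.0
    n = int(m.mask.sum())
    log.info("zero_scatter: zeroed %d of %d cells per sample (band %.1f nm)",
             n, m.mask.size, band_width)
    return cube.with_data(out), m


def select_region(
    cube: EEMCube,
    ex_range: tuple[float, float],
    em_range: tuple[float, float],
) -> EEMCube:
    """Restrict the cube to closed wavelength ranges on both axes."""
    ex_keep = (cube.ex.values >= ex_range[0]) & (cube.ex.values <= ex_range[1])
    em_keep = (cube.em.values >= em_range[0]) & (cube.em.values <= em_range[1])
    if not np.any(ex_keep) or not np.any(em_keep):
        raise EEMError(
            f"selected region ex={ex_range}, em={em_range} does not intersect the axes"
        )
    return EEMCube(
        cube.data[:, ex_keep, :][:, :, em_keep],
        WavelengthAxis(cube.ex.values[ex_keep]),
        WavelengthAxis(cube.em.values[em_keep]),
        list(cube.sample_ids),
        list(cube.labels) if cube.labels is not None else None,
    )


def impute_missing_zero(cube: EEMCube) -> tuple[EEMCube, int]:
    """Replace all non-finite cells by 0; returns (cube, replacement count)."""
    bad = ~np.isfinite(cube.data)
    count = int(bad.sum())
    if count:
        sample_all_bad = bad.all(axis=(1, 2))
        for i in np.flatnonzero(sample_all_bad):
            log.warning("impute_missing_zero: sample %s is entirely missing", cube.sample_ids[i])
        log.info("impute_missing_zero: replaced %d missing cells with 0", count)
    out = cube.data.copy()
    out[bad] = 0.0
    return cube.with_data(out), count


def mean_center_mode1(cube: EEMCube) -> tuple[EEMCube, CenteringState]:
    """Center each (ex, em) variable to zero mean across samples (mode 1)."""
    if cube.n_samples < 2:
        raise EEMError("mode-1 centering requires at least 2 samples")
    means = cube.data.mean(axis=0)
    return cube.with_data(cube.data - means[None]), CenteringState(means=means)


def uncenter_mode1(cube: EEMCube, state: CenteringState) -> EEMCube:
    """Invert :func:`mean_center_mode1` using the stored means."""
    return cube.with_data(cube.data + state.means[None])


def preprocess_parafac(
    cube: EEMCube,
    blank: EEMSample | None = None,
    ex_drop: tuple[float, float] = DEFAULT_EX_DROP,
    scatter_band: float = DEFAULT_SCATTER_BAND_NM,
) -> tuple[EEMCube, ScatterMask]:
    """Composite preprocessing for the PARAFAC path (no centering)."""
    if blank is not None:
        cube = subtract_blank(cube, blank)
    cube = remove_excitation_band(cube, *ex_drop)
    return zero_scatter(cube, scatter_band)


def preprocess_npls(
    cube: EEMCube,
    blank: EEMSample | None = None,
    ex_drop: tuple[float, float] = DEFAULT_EX_DROP,
    scatter_band: float = DEFAULT_SCATTER_BAND_NM,
    ex_range: tuple[float, float] = DEFAULT_NPLS_EX_RANGE,
    em_range: tuple[float, float] = DEFAULT_NPLS_EM_RANGE,
    center: bool = True,
) -> tuple[EEMCube, CenteringState | None]:
    """Composite preprocessing for the tri-PLS path.

    Runs the PARAFAC steps, restricts to the discriminant wavelength window
    (defaults: ex 270-510 nm, em 290-575 nm), zero-imputes missing cells and
    optionally mean-centers in the sample mode.
    """
    cube, _ = preprocess_parafac(cube, blank, ex_drop, scatter_band)
    cube = select_region(cube, ex_range, em_range)
    cube, _ = impute_missing_zero(cube)
    if center:
        return mean_center_mode1(cube)
    return cube, None
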