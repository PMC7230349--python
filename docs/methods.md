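# Methods

`eemauth` implements a chemometric pipeline for authenticating the
geographic origin of extra virgin olive oil (EVOO) from excitation–emission
matrix (EEM) fluorescence: preprocessing, constrained PARAFAC with
model-selection diagnostics, discriminant tri-linear PLS with variable
importance analysis, and Fisher LDA on the reduced sample scores. This note
describes the models, their assumptions, the numerical choices, and what
the synthetic cohort does and does not establish.

## Data model

An EEM cube is a three-way array `X[i, j, k]` — sample × excitation
wavelength × emission wavelength — of fluorescence intensity in arbitrary
units. Axes are strictly increasing wavelength grids in nm; after removal
of an excitation band the mode-2 axis carries a gap, so uniform spacing is
reported but not required of the container. Class labels are binary
(authentic origin "M" vs reference "F").

## Preprocessing

The canonical order, applied by `preprocess_parafac` / `preprocess_npls`:

1. **Blank subtraction** (optional): entrywise subtraction of a solvent
   landscape; negative differences are clipped to zero, since negative
   fluorescence is not physically meaningful.
2. **Excitation band removal**: rows with 220 ≤ λ_ex ≤ 240 nm are deleted
   (instrumental artefact region). Closed intervals everywhere.
3. **Scatter zeroing**: every cell with λ_em ≤ λ_ex, plus a band
   λ_ex < λ_em ≤ λ_ex + `band_width`, is set to exactly zero — a
   fluorophore cannot emit at higher energy than its excitation, and the
   near-diagonal band carries Rayleigh scatter. `band_width` defaults to
   10 nm; the width of the contaminated band is an instrument property and
   the default is a documented choice. Zeroed cells are treated as
   ordinary observed zeros during fitting (matching how the data were
   modelled); the returned mask allows treating them as missing instead.
4. **Region selection** (tri-PLS path only): ex 270–510 nm, em 290–575 nm,
   the window carrying the discriminant signal.
5. **Zero imputation** of non-finite cells, then **mode-1 mean centering**
   (each (ex, em) variable centred over samples).

## PARAFAC

The trilinear model `X[i,j,k] ≈ Σ_f A[i,f] B[j,f] C[k,f]` is fitted by
alternating least squares minimizing the residual sum of squares. Under
the uniqueness conditions of trilinear decompositions, B and C estimate
the excitation and emission spectra of the underlying fluorophores and A
their relative concentrations.

* **Non-negativity** (default, all modes) is enforced by exact
  non-negative least squares per mode, never by clipping, so the loss is
  non-increasing at every iteration (asserted during fitting). The row
  problems share one F×F Gram matrix, so the exact active-set solution is
  obtained by enumerating passive sets with each subset's solve vectorized
  over rows (F ≤ 10; Lawson–Hanson fallback beyond).
* **Unimodality** (optional, spectral modes only) is enforced by unimodal
  non-negative regression (prefix/suffix pool-adjacent-violators with an
  exact peak-position scan) in column-wise ALS updates. Mode 1 is never
  constrained to unimodality: concentration profiles across samples have
  no single-peak structure.
* **Initialization**: leading singular vectors of each unfolding,
  sign-corrected and floored at small positive values. Replicates 2–3
  perturb that start multiplicatively; replicates ≥ 4 use seeded random
  starts, because perturbations of one start tend to fall back into its
  basin. The best-of-replicates (lowest SSE) model is kept; ten replicates
  by default, fewer in the desk-scale drivers.
* **Convergence**: relative SSE change < `tol` (default 1e-10) within a
  wall-clock budget (default 300 s, configurable) and an iteration cap.
* **Conventions**: B and C columns unit Euclidean norm with magnitude in
  A; components ordered by descending ‖A_f‖; degenerate pairs (triple
  congruence < −0.85) are logged.

### Model-selection diagnostics

* **Explained variance**: 100·(1 − SSE/SSX) with SSX over the uncentred cube.
* **Core consistency (CORCONDIA)**: the least-squares Tucker3 core G for
  the fitted loadings is compared with the superidentity T:
  100·(1 − Σ(G−T)²/Σ T²). The Kronecker-structured least-squares problem
  factorizes into mode-wise pseudo-inverses, which is how G is computed.
  For any one-component model at an ALS stationary point the core equals
  the scalar 1 identically, so F=1 reads 100.00 regardless of the data —
  the pipeline's built-in analytic check.
* **Split-half similarity**: samples are split into two disjoint halves
  (alternating index, stratified by class label), models fitted
  independently on each, components matched greedily by the product of
  Tucker congruences of B and C, and the similarity reported as 100× the
  mean matched congruence product. Valid trilinear models recover the
  same spectra in both halves (≈100); overfitted models collapse. The
  aggregation (mean of congruence products) is a documented choice; the
  greedy matching breaks ties by component index.
* `scan_components` tabulates all four diagnostics for F = 1..F_max, with
  the residual column scaled to its maximum across rows.

### Fluorophore identification

Components are assigned by their B/C argmax peaks to the first matching
rule window: chlorophylls (em 650–700 nm), oxidation products (ex 310–360,
em 500–560 nm), tocopherols (ex 285–300, em 380–470 nm), phenolics
(ex 265–285, em 295–380 nm); otherwise unassigned. Windows are closed
intervals; peaks necessarily lie on the model's wavelength grid.

## Discriminant tri-PLS (DN-PLSR)

The response is the 0/1 origin coding (1 = non-authentic class by
default). For each latent variable the weight pair (w^J, w^K) is the
leading singular pair of `Z = Σ_i r_i X_i` (r the current response
residual), which maximizes the covariance of the score
`t_i = Σ_jk X[i,j,k] w^J_j w^K_k` with r over unit-norm separable weights.
The inner regression of y on all scores so far is refreshed each round.

**Deflation.** X (only) is deflated by projecting out the score:
`X ← X − t tᵀX / tᵀt`. This choice keeps successive scores exactly
orthogonal — which makes the nested-model structure trivial (the L-LV
inner coefficients extend the (L−1)-LV ones) and makes the method reduce
exactly to single-response bilinear PLS1 when K = 1. Deflating by the
separable triad `t (w^K ⊗ w^J)ᵀ` instead projects onto the weight
complement and loses both properties; the loading vector p = Xᵀt/tᵀt kept
per LV is what new-sample prediction uses.

Mode-1 centering of X and centering of y happen inside the fit (and inside
every cross-validation training fold, so no information leaks from
held-out samples). Classification thresholds ŷ at 0.5, the boundary
mapping to class 1.

* **Venetian-blinds cross-validation**: fold(i) = (i + offset) mod s on
  the sample order; every sample held out exactly once. Default s = 3 for
  the tri-PLS scan; s = 5 for the LDA stage (each training fold is 80% of
  a 65-sample cohort). The multi-split summary averages over fold offsets
  0, 1, 2.
* **RMSEC** is the root mean squared residual of the full-data fit;
  **RMSECV** pools concatenated held-out predictions (not per-fold
  averages). One fit per fold at L_max serves every smaller L because the
  scores are orthogonal.
* **VIP**: VIP(j,k) = √(P · Σ_f SSY_f w_f(j,k)² / Σ_f SSY_f) with
  P = J·K, w_f the unit-norm outer product of the LV's weight vectors and
  SSY_f the response variance newly explained by LV f (sequential
  increments). Squared VIPs average to exactly 1; VIP < 0.8 marks
  unimportant variables. Because the per-LV weight map is a separable
  outer product, when two fluorophores co-differ between classes the
  important region is the product of their excitation and emission
  windows, including the cross terms — a structural property of
  tri-linear weights, not an artefact.

## Fisher LDA

Two-class Fisher LDA on the mode-1 scores (PARAFAC concentrations or
tri-PLS LV scores): the discriminant direction maximizes between- over
within-class scatter (`w ∝ S_w⁻¹(m₁ − m₀)`, ridge-regularized at
λ = 1e-8·tr(S_w)/D if singular); classification is by nearest projected
class mean with equal priors (the cohort's 30/35 split is close enough to
balanced that priors are a documented, not fitted, choice). Reports
include standardized coefficients (direction × pooled within-class SD) and
Pearson correlations of each variable with the discriminant scores.
Cross-validation uses the same venetian-blinds rule (s = 5 default).

## Synthetic cohort

The generator emulates the study material: 30 "M" + 35 "F" samples on a
5 nm grid (ex 250–700, em 260–750 nm; the instrument's 0.5 nm acquisition
grid is coarsened for desk-scale runtimes). Each sample is a sum of four
fluorophore triads with Gaussian-sum spectral bands at the characteristic
olive-oil maxima:

| fluorophore | excitation (centre, sd, height) | emission |
|---|---|---|
| chlorophyll | 410/25/1.0 + 660/15/0.5 | 675/12 |
| oxidation | 325/12/1.0 + 340/12/1.0 | 525/40 |
| tocopherol | 295/8 | 425/35 |
| phenolic | 278/8 | 330/30 |

Band widths are generator choices; the red chlorophyll excitation band is
set at half the Soret-like band's height, the usual ordering for
chlorophyll spectra. Concentrations are log-normal per class (strictly
positive, right-skewed — phenolic and tocopherol levels in oils are
reported as non-normal), geometric SD 1.3, class-F medians 100/40/60/50
(chl/ox/toco/phen, a.u.). Class M multiplies medians by 1.2 (chlorophyll),
1.0 (oxidation), 0.5 (tocopherol) and 0.4 (phenolic): the authentic class
has slightly more chlorophyll and clearly less tocopherol and phenolic
fluorescence. The magnitudes were calibrated so that the emulated cohort
matches the separability the method demonstrates on real oils —
cross-validated discrimination accuracy in the low-to-mid 90s — rather
than being trivially or barely separable.

Additive Gaussian noise defaults to 2% of the maximum clean signal. The
scatter ridge along λ_em ≈ λ_ex has Gaussian width 4 nm, inside the 10 nm
band the preprocessing zeroes: the zeroing step is designed to cover the
Rayleigh line, and a generator whose scatter leaked far beyond the zeroed
band would contradict the method it feeds (the leaked, deterministic
diagonal structure would masquerade as an extra stable component).
Intensities are truncated at zero. The stored ground truth (A, B, C,
labels, and the residual field absorbing noise, scatter and truncation)
reconstructs the emitted cube to floating-point rounding.

**What the synthetic cohort does not show.** It is exactly trilinear up
to noise and scatter; real EEMs carry inner-filter effects, concentration
quenching, Raman scatter and wavelength-dependent instrument response,
none of which are modelled. Passing recovery and discrimination tests on
this cohort validates the algorithms and their implementation, not the
field performance of the assay on real oils.

## Problem sizes and numerical defaults

The drivers and tests run at desk scale as the package's own choice:
65-sample cubes on the 5 nm grid, 2–3 ALS replicates, `tol` 1e-8–1e-10
with an 800–2000 iteration cap for scans, and F ≤ 6 in the component scan.
The library defaults (10 replicates, tol 1e-10, configurable time budget)
match standard practice for production fits. Ties in greedy component
matching break by index; SVD sign ambiguity is fixed by making each
weight/loading column's largest-magnitude element positive; degenerate
tri-PLS LVs (zero score variance on rank-deficient cubes) truncate the LV
sequence with a warning rather than erroring.

## Known limitations

* Two-class problems only (the multi-column response generalization is out
  of scope); one discriminant axis.
* Scatter cells are zeros, not missing, during fitting by default; the
  missing-data ALS option is exposed through the scatter mask but the
  default matches the modelling described above.
* The split-half similarity of a one-component model is near 100 by
  construction and carries little selection information on its own; the
  scan is meant to be read jointly across all four diagnostics.
* Unconstrained PARAFAC on random dense data can be degenerate (two-factor
  degeneracies are logged, not repaired).
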