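# eemauth

Chemometric authentication of extra virgin olive oil (EVOO) origin from
excitation–emission matrix (EEM) fluorescence.

A 3D fluorescence landscape — intensity over a grid of excitation and
emission wavelengths — fingerprints the fluorophores in an oil:
chlorophylls (em ≈ 675 nm), oxidation products (em ≈ 525 nm), tocopherols
(ex 290–297 nm) and phenolics (ex ≈ 270–280 nm). Because these bands
overlap heavily, single-spectrum methods cannot separate them; three-way
models can. `eemauth` implements the full pipeline for a two-class origin
question (authentic vs other):

* **Preprocessing** — blank subtraction, excitation-band removal
  (220–240 nm), Rayleigh-scatter zeroing (λ_em ≤ λ_ex plus a near-diagonal
  band), wavelength-region selection, mode-1 mean centering.
* **PARAFAC** — the trilinear decomposition
  `X[i,j,k] = Σ_f a_if b_jf c_kf + e_ijk`, fitted by multi-start
  alternating least squares with exact non-negativity (optionally
  unimodality) constraints; model order chosen by explained/residual
  variance, core consistency (CORCONDIA) and split-half validation;
  components auto-assigned to fluorophores from their ex/em maxima.
* **Discriminant tri-PLS (DN-PLSR)** — `X[i,j,k] = t_i w_j^J w_k^K + e_ijk`
  per latent variable, weights maximizing covariance with the 0/1 origin
  coding; venetian-blinds cross-validation (RMSEC/RMSECV, accuracy) and
  VIP maps locating the discriminating spectral regions.
* **Fisher LDA** — classification from the mode-1 scores of either model,
  with venetian-blinds validation (s = 5 → 80/20 folds).
* **Synthetic cohort** — a seeded generator emulating 30 + 35 oil EEMs
  with the four-fluorophore structure, class-dependent log-normal
  concentrations, noise and scatter, plus exact ground truth for
  recovery testing.

## Worked example

```python
from eemauth import preprocess as pp
from eemauth.parafac import fit_parafac, identify_fluorophores, scan_components
from eemauth.synth import SyntheticSpec, generate_cube

cube, truth = generate_cube(SyntheticSpec(seed=7))   # 65 samples, 91 x 99 grid
pre, mask = pp.preprocess_parafac(cube)

report = scan_components(pre, 6, replicates=2, tol=1e-8, max_iter=800, seed=0)
for r in report.rows:
    print(f"F={r.F}  core={r.core_consistency_pct:7.2f}  "
          f"explained={r.explained_pct:5.2f}  split-half={r.split_half_pct:5.2f}")
```

```
F=1  core= 100.00  explained=61.80  split-half=99.99
F=2  core= 100.00  explained=79.92  split-half=99.30
F=3  core=  99.74  explained=88.65  split-half=99.21
F=4  core=  99.83  explained=94.82  split-half=99.96
F=5  core=  79.86  explained=94.82  split-half=79.97
F=6  core=  77.43  explained=95.52  split-half=76.94
```

Explained variance rises smoothly, but core consistency and split-half
similarity collapse beyond four components: the scan recovers the true
four-fluorophore rank. Fitting that model and reading the spectral peaks:

```python
model = fit_parafac(pre, 4, replicates=3, tol=1e-9, seed=0)
for a in identify_fluorophores(model):
    print(a.component, a.name, a.peak_ex, a.peak_em)
```

```
0 chlorophyll 410.0 675.0
1 tocopherol 295.0 425.0
2 oxidation 330.0 525.0
3 phenolic 280.0 330.0
```

The mode-1 loadings of this model are relative fluorophore concentrations;
Fisher LDA on them classifies origin at 98.5% (training) / 96.9%
(cross-validated) on the synthetic cohort, with phenolics and tocopherols
carrying the discrimination. The tri-PLS route
(`analysis/04_npls_discrimination.py`) reaches 96.9% validated accuracy at
three latent variables and its VIP map concentrates the important
variables (VIP > 0.8) on the phenolic/tocopherol excitation–emission
windows.

## Analysis drivers

Numbered scripts under `analysis/` run the full study on the synthetic
cohort and write their tables under `results/` (large regenerable fixtures
go to `scratch/`):

1. `01_simulate_cohort.py` — generate the cohort and fixture suite.
2. `02_parafac_model_selection.py` — the component-count scan above.
3. `03_parafac_fit_and_lda.py` — four-component fit, fluorophore
   assignment, LDA on concentrations.
4. `04_npls_discrimination.py` — DN-PLSR latent-variable scan, VIP map,
   LDA on LV scores.
5. `05_null_control.py` — permuted-label control (both routes at chance).

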