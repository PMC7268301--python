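# Methods

This note documents the statistical machinery in `woodnir`, the design
choices that were genuinely open, and what the synthetic benchmark does
and does not establish.

## Data model

A `SpectraSet` couples a uniformly spaced wavenumber axis (stored
descending, 9000 → 4000 cm⁻¹ at 10 cm⁻¹ by default, 501 points — the
grid of fibre-optic FT-NIR probes), an `n × p` absorbance matrix, and
per-sample metadata: extractives content `ec` (% dry mass), grain angle
`angle` (0° = longitudinal face, 90° = cross section) and a `core_id`
grouping replicate scans. All downstream code is order-agnostic in the
axis; derivatives are taken with respect to physical wavenumber, so an
ascending axis gives identical results.

## Pre-treatments

**SNV** maps each spectrum to zero mean and unit spread using the
sample standard deviation (n−1 divisor; common chemometrics practice —
the divisor convention is otherwise arbitrary and is flagged here
because it changes nothing downstream except a constant row scale).
SNV removes per-spectrum additive offsets and multiplicative scatter
exactly, and is idempotent.

**Savitzky–Golay derivatives** fit an order-2 polynomial in a 15-point
moving window (both configurable) and differentiate the local fit,
scaled by the grid spacing so a first derivative is in absorbance per
cm⁻¹. Edge points whose window does not fit are *dropped* — the axis
shrinks by (window−1)/2 = 7 points per side — rather than padded or
mirrored: fabricated edge values would otherwise enter variable
selection. Combined variants apply SNV first, then the derivative.

A practical consequence worth knowing: in first-derivative space a
symmetric absorption band carries no signal at its own centre (the
derivative crosses zero there), so per-wavenumber selection methods
legitimately skip band centres.

## Sample partitioning

Kennard–Stone max–min selection on Euclidean distances, computed on the
pre-processed spectra that will feed the model (model-space geometry).
The first two picks are the maximally distant pair; each later pick
maximises the minimum distance to the already-selected set. Ties break
toward the lower row index, making the split fully deterministic. The
default benchmark splits at the *core* level (distances on core-averaged
spectra) so both faces of a core land in the same set and no reference
EC value is shared between calibration and validation.

## PLS1 and model size

NIPALS on column-centred X and centred y; columns are not
variance-scaled (for spectra, variance carries signal). Extraction
stops early, with a warning recorded on the model, if deflation
exhausts the covariance. The latent-variable count is the smallest k
whose leave-one-out RMSECV lies within 2% of the global minimum
(`PARSIMONY_REL`). The 2% band is this package's own rule: LOO curves
on spectral data are typically shallow past their elbow, and the
parsimony band prevents the CV noise floor from inflating the model.
Each LOO fold re-centres and refits from scratch; per-component
regression vectors are assembled as `b_k = W_k (P_kᵀW_k)⁻¹ q_k`, so one
NIPALS pass per fold serves every candidate k.

Grain angle is modelled as PLS1 regression on the numeric response
{0, 90}; R²/RMSE are reported for it exactly as for the trait, with a
45° threshold available where a class label is needed.

## sMC variable importance

For a fitted model with regression vector b, each sample's spectrum is
projected onto the b direction: `X̂ = ŷ bᵀ/(bᵀb)` with `ŷ = X_c b`, and
`E = X_c − X̂`. Per variable j,

    SSR_j = Σ_i X̂_ij²,   SSE_j = Σ_i E_ij²,
    F_j   = (SSR_j/1) / (SSE_j/(n−2)),

compared against `F(1, n−2)` at 1−α (α = 0.05 by default). Summed over
variables the decomposition is exact (ΣSSR + ΣSSE = ‖X_c‖²); per
variable the cross term between projection and residual does not
vanish, so SSE is computed from E explicitly.

Two properties of the statistic matter in practice. First, because
`SSR_j ∝ b_j²`, variables the model uses for *noise cancellation*
(suppressor variables, common in derivative-space PLS where adjacent
columns share windowed noise) can score as important without marginal
correlation with the response. Second, the F(1, n−2) reference is
slightly liberal in wide matrices: b is estimated from the same data,
so each null column's own noise is present in ŷ, and the null
flag rate sits somewhat above α (measured ≈ 0.06–0.08 at n = 100,
p = 500 against α = 0.05, growing with n/p). Selections should be read
as enriched-for-signal, not as exact-FDR sets.

## Deconfounding rule

Keep wavenumbers significant for the trait and *not* significant for
the confounder; an optional top-k (by trait F, ties to the lower index)
tightens the set. Profiles are computed on the calibration set only —
never on validation — to avoid selection leakage. An empty selection
raises an explicit error suggesting α adjustment rather than silently
returning nothing. The refit on the selected columns re-runs LOO-CV, so
the reduced model chooses its own (usually smaller) component count.

## Evaluation

The headline diagnostic is a one-way ANOVA of *validation* EC
predictions split by grain angle: the trait is independent of angle by
construction, so a significant angle effect in the predictions means
the calibration absorbed the confounder. ANOVA on calibration
predictions is available but validation-only is the default (the
held-out set is the honest surface). Significance stars: *** 0.001,
** 0.01, * 0.05. Score plots are exported as data tables (sample,
score1, score2, angle, set), not images, so they are testable;
plotting is left to the user.

With paired cores the two angle groups contain the same cores, which
makes the classical one-way ANOVA conservative (the between-group
difference in true EC is structurally zero while the within-group
variance still contains the full EC spread). A detectable effect
therefore requires a prediction shift comparable to the spread of
predicted EC itself. A rational CV-tuned linear calibration never
retains that much bias: whatever linear angle readout exists in the
spectra, the model re-uses it to cancel most of the artifact, and the
residual shift stays far below the ANOVA detection threshold at
n ≈ 36. The benchmark consequently demonstrates deconfounding through
the angle-R² collapse and the absence of any significant angle effect
in the reduced model — not through a significant-vs-nonsignificant
ANOVA contrast, which this design cannot produce robustly.

## Synthetic benchmark

The generator emulates diffuse-reflectance scans of increment cores:

* fixed quadratic baseline (removed by derivatives);
* trait-only Gaussian bands at 6000 and 5400 cm⁻¹ (C–H overtone region
  of extractives), amplitudes 0.0048/0.0038 absorbance per %EC;
* confounder-only *scattering shoulders* (sigmoid edges, ±0.037) at
  8100 and 7800 cm⁻¹ — shoulders rather than Gaussian bands so their
  first derivative carries angle information across the whole support,
  and opposite signs so their row-statistics contributions partially
  cancel under SNV;
* a shared band at 8500 cm⁻¹ driven by EC plus an additive angle gain
  of 1.5 %EC-equivalent (the overlap region that naive calibration
  picks up);
* inert water/background structure at 7070, 5100, 4300, 8800 cm⁻¹;
* per-spectrum lognormal multiplicative scatter (σ = 0.10), additive
  offset (σ = 0.02), white noise (σ = 0.013 absorbance), and a
  per-spectrum surface-condition factor (σ = 0.3) scaling how strongly
  the presented face expresses itself in the confounder shoulders.

EC is uniform on 1.23–16.49 % (the range observed in heartwood cores of
the target regime; the uniform mean 8.86 % coincides with the observed
mean but nothing relies on that). By default samples come in *paired
cores* — each core contributes one spectrum per face with identical
EC — matching how cores are actually scanned; `paired_cores=False`
gives independent Bernoulli angles. The default benchmark uses 118
cores (236 spectra) split 100/18 cores (200/36 spectra) by
Kennard–Stone.

Ground truth exports each band role's wavenumber support (within one
width of the centre), resolvable onto any truncated axis. Against this
truth, over 20 seeds, the dual-response rule recovers on average ~84%
of trait-only support points (the residual misses are derivative
zero-crossings at band centres and occasional seeds where the CV picks
a large component count and the regression vector roughens) and selects
zero confounder-only points.

**What passing does not show.** The generator is additive-linear in its
drivers apart from the surface jitter; real wood spectra add moisture
effects, anatomical gradients from pith to bark, instrument drift, and
nonlinear path-length effects. Band recovery against planted Gaussians
does not certify recovery of real, overlapping vibrational assignments;
the benchmark certifies the machinery (preprocessing identities,
selection logic, leakage-free evaluation), not field performance.

## Numerical choices and degenerate inputs

* Spacing uniformity is enforced to 1e-9 relative; non-finite
  absorbance fails loading with the offending sample and wavenumber.
* Zero-variance spectra fail SNV by name; zero-variance responses fail
  fitting and R².
* NIPALS stops on `‖Xᵀy‖` or `‖t‖²` below a scaled machine-epsilon
  threshold; `(PᵀW)` is solved, never inverted, except in the
  score-projection transform where the k × k inverse is benign.
* F statistics at zero-residual columns are +inf (significant); at
  zero-projection columns exactly 0 (not significant).
* All CLI outputs print floats at 12 significant digits; a rerun with
  identical config and seed is byte-identical.
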