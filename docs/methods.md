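# Methods

This note documents the statistical model behind `rfharmonize`, the choices
made where the design was open, and what the synthetic-data experiments do
and do not demonstrate.

## Response factors and the logRF scale

The calibration relation is `area = RF · c + intercept`; the response
factor RF is the slope, estimated by unweighted OLS with an intercept
(never forced through zero) on the detected calibration points (≥ 3
required — the minimum leaving a residual degree of freedom). All analysis
is on logRF = log₁₀(RF), since both compound ionization efficiencies and
instrument transmission vary by orders of magnitude. Concentrations are
held internally in mol/L, so typical areas of ~10⁶ counts at nanomolar
spikes give logRF ≈ 11–15 (units log₁₀(area·L/mol)).

Suspects have only two spike levels; their logRF is log₁₀ of the
*arithmetic mean* of the two area/concentration ratios (ratios averaged
before the log), from HPLC-water samples only. For ratios within 2× of
each other this differs from the mean-of-logs alternative by ≤ 0.15
log-units; the mean-ratio reading was chosen and is fixed here.

## QA rules

Evaluated per (dataset, compound, ion, matrix) cell, so a compound can pass
in HPLC water and fail in lake water (matrix effects are real and local):

* both suspect levels detected and area ratio ≤ 20 → kept; ratio > 20
  (strictly) → rejected (the theoretical ratio of a 10× spike is 10; a
  large excess signals a nonlinear response or level-dependent
  suppression);
* one level only → rejected (high-only or low-only); neither → not
  detected;
* calibrants: kept iff ≥ 3 of 6 points detected. No calibrant-level ratio
  rule exists; this point rule is the package's own convention.

Areas are first normalized to the internal standard of the *same sample
injection* (keyed by dataset × matrix × spike level); a per-injection
denominator was chosen over a per-dataset mean IS area because it also
removes injection-to-injection drift, and it makes normalization exactly
invariant to rescaling any single injection. Samples whose IS is missing
are excluded (flagged, never silently dropped). Per-dataset dilution
factors from the metadata divide the nominal concentrations at ingest.

## Anchor projection

Every dataset is mapped onto the anchoring dataset's logRF scale by
regressing the **anchor's** logRF (response) on the **dataset's** logRF
(predictor) over the compounds shared between the two, then evaluating the
fitted mapping on all of the dataset's logRFs. This direction keeps the
projection a plain evaluation (well defined for the spline model, no
inversion) and yields the attenuation property that motivates the range
diagnostics: the fitted slope shrinks toward zero as the overlap
correlation degrades, so `projected_range = |slope| · raw_range` and the
**range ratio** (raw/projected) grows above 1 exactly for poorly
correlated datasets. Two passes are run: a calibrants-only fit for the
LM-vs-GAM model comparison, and an all-compounds LM fit feeding the
consistency statistics. A minimum overlap of 6 shared calibrants (default,
configurable) is required; below it the dataset is flagged and skipped.

### Penalized cubic regression spline

The GAM mapping is a cubic regression spline in the values-at-knots
parameterization: k = 6 knots at the (0, 0.2, …, 1) quantiles of the
overlap predictor values; natural boundary conditions; linear extrapolation
beyond the end knots. The penalty is the integrated squared second
derivative, `S = Dᵀ B⁻¹ D` built from the knot spacings, whose null space
is the linear functions — hence λ → ∞ reproduces the OLS line exactly
(verified at λ = 10⁸ to < 10⁻³), and λ = 0 with n = k distinct points
interpolates. λ minimizes `GCV(λ) = n·RSS / (n − tr H)²` on a 61-point
log-spaced grid over [10⁻⁶, 10⁶], refined by bounded scalar minimization
around the grid optimum. A 10⁻¹⁰-scaled ridge keeps the λ = 0 square
system solvable; an ill-conditioned basis (e.g. too few distinct predictor
values) falls back to the LM with a warning.

### Model choice

Per dataset, suspect residuals (projected − anchor) from both mappings
enter a two-sided variance-ratio F-test, `F = RMSE_LM²/RMSE_GAM²`,
df (n−1, n−1). The simpler LM is preferred unless p < 0.05 *and* the
spline has the lower mean squared residual (`SS_res = Σr²/n`); with < 3
suspect residuals the test is skipped and LM used.

## Consistency statistics

With projected values v(l, c) and per-compound cross-dataset means m(c):
`SS_comp(c) = Σ_l (v − m(c))²/n_l` (the biased variance across the
datasets detecting c) and `SS_data(l) = Σ_c (v − m(c))²/n_c` over the
compounds dataset l detected. SS_data deliberately centers on the
*compound consensus*, not the dataset's own mean — it measures one
laboratory's departure from the consensus, which is the interpretable
quantity; both scopes share one definition of the mean. Dataset similarity
is the squared Pearson (or Spearman, mid-ranks) correlation on
pairwise-shared compounds (≥ 5, else missing), clustered with complete
linkage on 1 − R² (missing pairs imputed with the matrix minimum,
logged); dataset order is lexicographic so ties break deterministically.

## Error analysis

Prediction quality per record: ratio = predicted/true, fold error =
max(ratio, 1/ratio) ≥ 1, and *signed* log error = log₁₀(ratio) —
the sign distinguishes over- from under-prediction, which the additive-type
analysis needs. Two-level instrument parameters: Wilcoxon rank-sum per
(approach × spike level) stratum — exact enumeration when both groups
≤ 10 and tie-free, else normal approximation with tie and continuity
correction — effect size r = |Z|/√N, Bonferroni family = the strata tested
for that parameter. Three-or-more-level parameters: Friedman test blocked
by compound on the median fold error across the datasets at each level
(compounds missing a level are dropped; ≥ 3 complete blocks required),
with Nemenyi all-pairs p-values from the studentized-range distribution
when significant. Blocking by compound (rather than by dataset) was chosen
because the compound is the natural repeated-measures unit across
parameter levels.

The error model is a 100-tree random forest (unlimited depth, min split 2,
min leaf 1, fixed seed) on integer-encoded compound, approach, analyzer,
additive type, organic modifier, injection volume, spray voltage and
gradient length, using only HPLC-water high-spike records; the 80:20 split
is grouped by dataset so no laboratory leaks across it. Held-out R² is the
ordinary coefficient of determination (0 by convention for a constant test
target).

Feature attribution walks each tree's decision path and credits every
split's child-minus-parent node mean to the split feature, averaged over
trees; per-prediction attributions therefore sum *exactly* to prediction
minus baseline (the mean root value). Reported summaries are mean
|attribution| per feature and the mean signed attribution per categorical
level (direction). Permutation importance (scikit-learn, on the held-out
set) is available as an alternative summary; it estimates predictive
reliance, not additive contributions, and the two need not rank features
identically on small test sets.

## Synthetic interlaboratory studies

The generator produces the full study design: 37 datasets, 41 calibrants at
six log-spaced levels over two orders (0.5–50 nM), 45 suspects at two
levels 10× apart (low spikes log-uniform over 0.85–890 nM) in three
matrices, plus an internal standard in every injection. Its statistical
model:

* latent log ionization efficiency logIE ~ U[11, 15.3] per compound (the
  anchor-scale range);
* lab transform `logRF = a + b·logIE + ε`, a ~ N(0, 1.5), b lognormal
  (median 1, log-sd 0.2); the anchor has (a, b) = (0, 1), so the anchor
  scale *is* the latent scale and recovery metrics are well defined;
* compound–lab noise ε ~ N(0, σ_l·(1 + γ·max(0, 15 − logIE))) with σ_l ~
  U[0.1, 0.4] and γ = 0.2 per log-unit — the heteroscedasticity that makes
  poorly ionizing compounds less consistent across laboratories;
* areas `10^logRF · c` times lognormal measurement noise (sd 0.05 in
  log₁₀, truncated at 2 sd), so a QA-clean high/low pair keeps its area
  ratio inside [5, 20] by construction;
* per-measurement logistic detection in log₁₀(area), midpoint drawn per
  lab (base 4.0 ± 0.5 on the anchor scale, mapped through the lab's own
  affine transform so a lab's detection limit tracks its response scale)
  and 0.5 lower for MeOH-modifier labs — reproducing modifier-linked
  detection-frequency differences at realistic overall detection rates;
* planted QA violations among suspects: nonlinear responders
  (area ∝ c^p, p ~ U[1.55, 1.9], so the high/low ratio exceeds 20 even at
  the noise extremes) and matrix-suppressed compounds (attenuated in
  tap/lake water, more strongly at the low spike — suppression saturates
  with analyte level — so the violation is detectable by the ratio rule);
* optionally one nanospray outlier lab (b = 0.3 plus extra scatter);
* predicted concentrations per approach: `true · 10^δ`, δ ~ N(shift, τ_a)
  with per-approach τ (ionization-efficiency approaches tighter) and a
  −0.5 log-unit shift for buffer-additive labs (underprediction) as the
  planted metadata effect;
* internal standard: latent logIE 8.0 at 10⁻⁸ mol/L, measured with only
  injection noise — chosen so IS normalization shifts the anchor scale by
  exactly zero and the 11–15.3 logRF magnitude survives normalization.

What the generator does **not** emulate: retention-time structure (RTs are
drawn uniformly), adduct competition (all ions [M+H]⁺ by default),
correlated metadata beyond the modifier–additive linkage, drift over time,
and processing-software effects. Passing tests therefore demonstrate the
pipeline's statistical behaviour under the assumed affine-plus-noise model,
not robustness to every real-data pathology.

## Validation experiments and problem sizes

The experiments in `tests/test_acceptance.py` and `scripts/acceptance.py`:

* **Oracle equivalence** — OLS slopes, Σr²/n statistics in both scopes,
  Pearson/Spearman R², exact Wilcoxon p (full enumeration up to 8 per
  group) and the Friedman statistic agree with brute-force loop/enumeration
  implementations to 10⁻¹⁰ relative on ≥ 100 random small instances each.
* **Anchor-scale recovery** — a 37-lab affine study at σ = 0.15 (γ = 0,
  no outlier lab): projected logRFs recover the latent scale with RMSE
  ≤ 0.3 and fitted slope × true b within 10% of 1 for labs with ≥ 20
  overlaps; the noiseless limit recovers exactly.
* **Range compression** — 200 labs with σ ~ U[0.05, 0.8]: mean range
  ratio increases monotonically across noise quartiles, and labs with
  R² < 0.5 have mean range ratio > 1.
* **Heteroscedastic consistency** — 200 replicate studies (16 labs,
  50 compounds, γ = 0.2): the Spearman correlation of SS_comp with mean
  projected logRF is negative in ≥ 95% of replicates. The replicate size
  was set so the correlation's *sign* is estimated reliably; at much
  smaller studies the sign estimate itself becomes the bottleneck.
* **Type-I error** — under null simulations the exact Wilcoxon (n = 10
  per group, lognormal data) and the two-sided F-test (n = 20 residuals)
  reject at 3–7% at nominal α = 0.05 over 1000 replicates.
* **Spline limits** — λ = 10⁸ matches the LM to < 10⁻³; λ = 0 with
  n = k interpolates to RSS < 10⁻⁸.
* **Planted additive effect** — a balanced acid/buffer design (14 labs)
  with the −0.5 buffer shift: additive type ranks first by mean
  |attribution| with negative buffer direction. The balanced assignment is
  deliberate: under the natural skewed additive distribution a small study
  can draw almost no buffer labs, confounding the effect with laboratory
  identity and leaving the grouped split one-sided — a degenerate
  experiment rather than a hard one.

Numerical conventions throughout: base-10 logarithms; biased (1/n)
variances in the consistency statistics; mid-ranks for ties; stable
mergesort ordering wherever results could depend on row order; all
randomness through `numpy.random.default_rng` seeded from a single study
seed.

## Known limitations

* The projection assumes one affine (or smooth monotone) relation per
  dataset; compound-specific instrument effects end up in the residuals
  and are only visible through low R² and high SS values.
* SS_comp for compounds detected in very few datasets is unstable (the
  per-compound n is the divisor); downstream correlation analyses filter
  to n ≥ 3.
* The GCV-selected spline can still overfit small overlaps (the model
  comparison guards this per dataset, preferring the line).
* The error model's explainable variance is bounded by the planted
  effect's share of the total error variance; held-out R² on few test
  laboratories is noisy and can be negative even when the effect is
  recovered by the attributions.
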