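# Methods

## Scope and data model

The package operates downstream of vendor peak alignment: its input is a
feature table (samples × features, non-negative intensities, NaN = not
detected) with sample group labels, one of which (`qc`) marks pooled
quality-control injections. Raw spectra, peak picking and retention-time
alignment are out of scope.

## Synthetic data generator

The generator emulates a two-group botanical discrimination study:
52 + 34 biological batches and 8 pooled QC injections over 400 aligned
features, of which 10 are true markers.

* **Intensity model.** log2 intensity = feature baseline (uniform on
  [14, 20]) + group effect + Gaussian noise. The noise sd on the log scale is
  σ = √ln(1 + CV²) (converted to log2), so the natural-scale coefficient of
  variation is exactly the configured `biological_cv` (default 0.30, a
  typical batch-to-batch CV for plant extracts).
* **Markers.** Group effects are antisymmetric: +Δ/2 in group A, −Δ/2 in
  group B with Δ = `log2_fold_change` (default 2, i.e. a 4-fold change).
  All markers point the same way, so the mean realized log2 fold change
  estimates Δ directly.
* **QC injections** are multiplicative log-normal replicates (mean 1) of the
  empirical pooled mean profile with CV = `qc_cv` (default 0.08). A planted
  10% of features are "unstable": their QC CV is 0.40, far enough above the
  15% RSD filter threshold that the empirical RSD of 8 replicates exceeds it
  with probability ≳ 0.99.
* **Missingness.** Biological cells are blanked completely at random at rate
  0.05. A planted 5% of features (`frac_sparse`, a field added because the
  ground-truth contract requires sparse features but no count was otherwise
  determined) are additionally blanked in 30% of the samples of *both*
  groups, so they fail the 80% rule deterministically. Marker features are
  never planted as unstable or sparse.
* **Determinism.** All randomness flows through one
  `numpy.random.default_rng(seed)`; the same config yields byte-identical
  tables.

What the generator does **not** emulate: correlation between features. Real
LC-MS tables contain clusters of near-collinear features (adducts, isotopes,
in-source fragments of one compound, co-regulated metabolites); here every
feature's noise is independent. Consequences for interpreting test results
are discussed under "Known limitations".

## Filtering

Filters run in the study's order: QC-RSD first, then the 80% rule; the report
satisfies `n_input − n_removed_qc_rsd − n_removed_80pct = n_retained` and the
two removal lists are disjoint by construction.

* RSD uses the n−1 standard deviation (QC replicate counts are small); a QC
  mean of zero makes the RSD undefined and the feature is treated as
  unstable.
* "Present" for the 80% rule means non-missing **and** strictly positive,
  because vendor exports use 0 and blank interchangeably for undetected; the
  80% boundary is inclusive, and QC samples are excluded from the count.
* Missing cells elsewhere are imputed with half the feature's minimum
  observed value (the standard below-detection-limit convention) before any
  statistic that needs complete data.

The reference study reports 5528 → 366 retained features on its own data;
those counts depend on the unpublished raw data and are not reproducible —
here the filters are instead validated by exact recovery of the planted
unstable/sparse features.

## Univariate screen

Pooled-variance Student's t-test per feature (the study names Student, not
Welch; Welch is available via a flag), two-sided, on raw imputed abundances
(`log2=True` available), raw p < α = 0.05 with no multiple-testing correction
(BH-FDR available but off, matching the reference procedure). Features
identical in both groups get t = 0, p = 1 with a warning. The heat-map matrix
z-scores each significant feature across biological samples and clusters rows
and columns by average-linkage on Euclidean distance; orders are
deterministic leaf orders.

## PCA

Components come from the SVD of the column-centred scaled matrix; R²X per
component is its share of total sum of squares. Q² uses row-wise k-fold
cross-validation (default 7): folds are assigned round-robin over samples in
sorted-sample-id order (hence invariant to row permutation), each fold's rows
are held out, loadings are refit on the rest, and
Q² = 1 − PRESS/SS over held-out reconstructions. SIMCA's own PCA
cross-validation is element-wise (EM-style); the row-wise scheme implemented
here is a documented approximation, and the implementation is tested against
an independently coded brute-force fold loop to 1e-10.

## OPLS-DA

The Trygg–Wold O-PLS algorithm on the Pareto-scaled matrix and a centred ±1
class vector (alphabetically first label = +1):

1. w ∝ Xᵀy (unit norm); t = Xw; p = Xᵀt/tᵀt.
2. Orthogonal component: w_o ∝ p − (wᵀp)w (unit norm), t_o = Xw_o,
   p_o = Xᵀt_o/t_oᵀt_o; deflate X ← X − t_o p_oᵀ. Repeat k times.
3. Final single-component PLS on the filtered X gives t_pred, p_pred and the
   regression coefficient q; R²Y = 1 − ‖y − t_pred q‖²/‖y‖².

R²X(cum) counts predictive plus orthogonal captured variance; because each
deflation removes an orthogonal projection, total SS = captured + residual
exactly, and t_pred ⊥ every t_o.

* **Q²** comes from 7-fold CV of the full filter-then-predict composite,
  refit per training split, with the same deterministic fold assignment as
  PCA.
* **k selection.** `k_orth="auto"` adds orthogonal components while Q²
  improves by more than 0.01 (a SIMCA-like rule); any fixed k can be given.
* **VIP** is the all-components ("VIP total") form
  VIP_f = √(p · Σ_a SSY_a (w_af/‖w_a‖)² / Σ_a SSY_a), with SSY_a the y sum of
  squares explained by component a's score. Orthogonal components explain
  almost no y-variance, so their weight is near zero; mean VIP² = 1 holds
  exactly for any weighting. The exact SSY weighting inside SIMCA's VIP for
  OPLS models is not public; this implementation is defined above and
  oracle-tested against its own definition, with a predictive-only variant
  behind `vip_mode="pred"`.
* **Permutation test.** n (default 200) refits with shuffled labels and
  identical hyperparameters; records R²Y, Q², |corr(y_perm, y)|; R²/Q²
  intercepts come from the least-squares line through all points plus the
  unpermuted model at correlation 1 (the convention of SIMCA's validate
  plot). An empirical p-value for Q² uses the plus-one rule.

## Iterative random-forest selection

100 forests (500 trees, mtry = ⌊√p⌋) are fitted on the VIP > 1 features with
seeds base+i. The bagging loop is explicit (scikit-learn decision trees
underneath) so each tree's out-of-bag membership is available: importance is
out-of-bag permutation importance (mean decrease in accuracy — per tree, the
drop in OOB accuracy after shuffling one feature's OOB values, averaged over
trees; Gini impurity importance available behind a flag). Ranks are assigned
descending by importance with ties broken by ascending feature order, making
every iteration reproducible from its seed.

Aggregation: the cumulative matrix C[v, N] (iterations where v ranked ≤ N),
the stable set {v : C[v, N*] = 100} with N* either fixed or the smallest N
whose stable-set size is unchanged for 3 consecutive N, and the top-1
frequency (rank-1 counts, summing to the iteration count). Selection keeps
features with top-1 frequency ≥ 4; the threshold is inclusive because a
panel of 1 + 1 + 4 + 5 members at frequencies {9, 6, 5, 4} only totals 11
under ≥. Top-1 frequencies are computed over all VIP features by default,
with an option to restrict to the stable set. The final forest on the
selected markers reports its OOB error and the ROC AUC of its OOB class
votes (no held-out split is used anywhere in the reference procedure).

## Annotation arithmetic

Monoisotopic masses use C = 12 exactly, H 1.00782503, N 14.00307401,
O 15.99491462, S 31.97207117; deprotonation subtracts 1.00727646 (proton with
the electron mass folded in — invisible at 2-decimal reporting); the formate
adduct adds mass(CH₂O₂) computed from the same atomic masses. Formula parsing
accepts plain (C19H18O11) and underscore-subscript (C_19_H_18_O_11_) dialects,
including partially underscored variants present in the transcribed tables.
Neutral-loss explanation matches precursor−fragment differences against a
small library (H₂O, CH₂O, ketene, CO₂, C₃H₆O₃, anhydroglucose 162.0528,
anhydro-dihydroxybenzoyl, caffeoyl) as one or two losses within 0.02 Th,
keeping the smallest error. The packaged compound tables are transcribed
verbatim, including internally inconsistent printed values (e.g. the loganin
row's m/z and the syringaresinol formate adduct); `audit_fixture_mz` flags
rows whose printed m/z deviates from the exact arithmetic by more than
0.02 Th rather than correcting them; the audit of the marker table is
committed at `docs/table2_mz_audit.csv` (one flagged row: the syringaresinol
formate adduct, printed 491.14 vs computed 491.19).

## Problem sizes and numerical choices

* Default study design: 94 samples × 400 features; 100 × 500-tree forests on
  ≤ ~47 candidate features run in about a minute on one core, and the
  permutation test (200 refits with 7-fold CV) in well under a second.
* Degenerate inputs raise typed errors: < 2 QC samples, empty groups,
  single-class y, all-constant matrices, single-feature rankings, empty
  marker selections.
* Constant columns are dropped (with a warning) at scaling; zero pooled
  variance in a t-test yields p = 1 with a warning rather than NaN.
* Q² fold assignment is seeded from sorted sample ids, so every reported Q²
  is invariant to the row order of the input table.

## Known limitations

* **Top-1 selection under independent markers.** With planted markers of
  identical effect size and independent noise, one marker realizes the
  cleanest separation in any given dataset and wins the top-1 importance
  slot in essentially every forest iteration (the importance gap between the
  first two markers is several standard errors of a 500-tree mean). The
  top-1 frequency rule is then precise — everything selected is a true
  marker — but insensitive: typically 1–2 of 10 markers reach frequency 4.
  The flat frequency spread that makes this rule productive on real data
  reflects near-tied, strongly correlated features (multiple ions of the
  same compounds), which the generator deliberately does not simulate. The
  cumulative top-N view is the robust complement here: all planted markers
  occupy the top ranks and separate cleanly from noise.
* PCA Q² approximates SIMCA's element-wise cross-validation with a row-wise
  scheme; absolute Q² values are therefore not comparable to SIMCA output,
  though their qualitative use (model-dimension diagnostics) is unchanged.
* The univariate screen applies no multiple-testing correction by default,
  by fidelity to the reference procedure; the BH-FDR flag is recommended for
  new studies.
* Headline statistics of the reference study (feature counts 5528/366/283/
  47/11 and its R²/Q² values) depend on unpublished raw data and are not
  reproduction targets; the package validates the machinery on synthetic
  ground truth instead.
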