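# Methods

This note documents the models, defaults and numerical choices behind
`ctcmet`, and what the synthetic data do and do not establish.

## Data model and preprocessing

A cell's spectrum is a peak list of (m/z, intensity) pairs acquired in
full scan over 70–1050 Th. The internal standard (d5-phenylalanine,
protonated m/z 171.1279) is located as the nearest peak within a ppm
tolerance; all intensities are divided by its signal and the IS peak is
removed. This makes profiles dimensionless and scale-equivariant: a
cell-wide multiplicative change of all raw intensities (spray efficiency,
extraction volume) cancels exactly.

Reference alignment assigns each peak to its nearest panel entry when the
relative deviation |obs − ref|/ref · 10⁶ is within the tolerance
(default 5 ppm, Orbitrap-class accuracy; configurable). When two peaks
hit one reference the larger intensity is kept and the collision logged;
ties between two references at identical ppm break toward the lower
ref m/z — deterministic and logged. Unmatched references are missing,
encoded as NaN in memory and the empty field in TSV; zeros are measured
values.

Stable-feature selection is implemented as detection-fraction filtering:
a metabolite is kept when observed in ≥ 20% of cells overall or within at
least one group. This stage is an explicit stand-in — the criteria used
for the original data are not public — and is pluggable via its
threshold and grouping arguments.

Imputation uses the half-minimum rule (a missing entry receives half the
metabolite's smallest observed value), the usual proxy for
below-detection-limit censoring; then log₁₀; then per-metabolite
autoscaling (zero mean, unit variance) for multivariate modelling. The
normalization state machine (raw → is_normalized → log_scaled →
autoscaled) only moves forward, so double-scaling is a caught error.

## Differential screen

PLS-DA is fit by sequential NIPALS extraction with X and y deflation; for
a single binary response the component weight has the closed form
w = Xᵀy/‖Xᵀy‖. Cumulative R²X and R²Y are explained sums of squares; Q²
is 1 − PRESS/TSS with interleaved ("venetian blind") 7-fold
cross-validation stratified by class, each training split re-centred —
the conventional scheme in the chemometrics workflow this mirrors; the
fold count is configurable. Two components by default; more are extracted
on request and extraction truncates gracefully when no covariance
remains.

VIP_j = √( J · Σ_a SSY_a (w_{ja}/‖w_a‖)² / Σ_a SSY_a ), where SSY_a =
q_a² t_aᵀt_a is the y-variance captured by component a; the identity
mean(VIP²) = 1 is asserted in tests against an independently coded
evaluation of the formula.

The volcano filter keeps VIP ≥ 1 candidates with fold change ≥ 1.5 in
either direction (linear-scale group-mean ratio of imputed,
IS-normalized intensities — the most common convention; the scale is not
dictated by the workflow itself) and Mann-Whitney p ≤ 0.05. The
Mann-Whitney implementation is exact (full U-distribution) when both
samples have ≤ 8 observations without ties, otherwise the normal
approximation with tie and continuity corrections. No multiple-testing
correction is applied by default, matching the screen's per-comparison
convention across the 390 tests; Benjamini-Hochberg gating is available
(`correction="bh"`). Permutation tests refit the model on uniformly
permuted labels with identical settings; empirical p = (1 + #{permuted ≥
observed})/(n + 1).

## Enrichment

Hypergeometric upper tail P(X ≥ k) for k pathway members among n
selected out of N background metabolites with K pathway members in the
background; BH adjustment across pathways. The background defaults to the
full reference panel rather than the post-filter set (both are
selectable; the original analysis does not state its background). The
pathway map is user-supplied TSV; nothing is fetched from KEGG.

## Subgroup discovery

Clustering operates on 2-D embedding coordinates, not the full matrix,
matching the silhouette-on-embedding design of the source workflow (a
full-matrix mode exists for sensitivity analysis via
`pca_components=None` and passthrough embeddings). Defaults: t-SNE
perplexity 10 (appropriate for ≈ 120 cells), PCA reduction to 30
components before embedding (standard denoising for wide matrices), UMAP
n_neighbors 15 as the cross-check, embedding seed 42, Ward linkage with
Euclidean distance (the linkage is a declared choice; average and
complete are selectable). Mean silhouette width over k = 2..8 selects the
cluster number, ties broken toward smaller k; a singleton cluster
contributes s(i) = 0 and flags the candidate. Subgroups are relabelled by
descending size, so "subgroup 1" is always the largest; any clinical
meaning is attached downstream by association, never by label index.

## Risk model

AUC is the pair-counting (Mann-Whitney) estimator with ties counted 1/2;
the ROC curve uses thresholds at midpoints between adjacent distinct
scores plus ±∞ sentinels, which makes its trapezoidal area identical to
the pair-counting estimator (tested as an identity). Youden cutoffs scan
the same midpoints; on integer counts split between 1 and 2 this yields
the half-integer cutoff 1.5 deterministically. Ties in J break toward
higher specificity, then lower cutoff. The high-risk flag is strict
(count > cutoff, i.e. ≥ 2 at cutoff 1.5).

Endpoint assignment picks, per endpoint, the subgroup with maximal AUC,
leaving an endpoint unassigned when the best AUC is below a floor
(default 0.6) — the analogue of a subgroup with no metastatic
association. Logistic regression uses Newton-Raphson maximum likelihood
(via statsmodels) with Wald inference; complete separation is detected
and reported instead of diverging. The default multivariate covariate set
is subgroup count + total CTC count + the four serum biomarkers,
complete-case; follow-up outcomes are treated as binary one-year
endpoints, not time-to-event.

## Synthetic-data generator

The generator emulates the study design, not measured spectra:

- **Cell model.** log₁₀ intensity = per-metabolite baseline
  (uniform in [−1, 1], i.e. 0.1–10× the internal standard) + population
  shift (signature_log2fc · log₁₀2 on that population's signature set) +
  Normal(0, log_sd) cell noise; exponentiated to linear scale.
  Multiplicative noise matches MS intensity behaviour. Defaults: 390
  metabolites; three-population design 58/60/63 cells (signature
  discovery) or 3 × 40 (subgroup recovery) with 50 or 30 disjoint
  signature metabolites per population at log2fc 1.5; dropout 0.2.
- **Noise level.** log_sd = 0.1 (≈ 23% CV cell-to-cell). This is the one
  load-bearing free parameter: it was calibrated once so that the
  generated subgroups are as separable as the clusters observed in the
  motivating data (cleanly silhouette-selectable at k = 3); at markedly
  higher noise no unsupervised method recovers the designed structure and
  the generator would no longer emulate the study.
- **Dropout.** Missing-completely-at-random by default; an optional
  intensity-dependent mode (logistic in log-intensity, centred to match
  the overall rate) reflects low-abundance censoring typical of
  single-cell MS. The choice is config, since the original acquisition
  reports neither.
- **Peak lists.** Peaks sit at panel reference m/z perturbed by
  Normal(0, ppm_jitter_sd) ppm (default 2; 1 in round-trip settings so
  the default 5 ppm tolerance exceeds 3 SD); intensities are matrix
  entries times a lognormal per-cell IS intensity (mean 10⁵ counts, 0.15
  log₁₀ SD); the d5-Phe IS peak is appended. A jitter SD above half the
  minimal panel spacing triggers an ambiguity warning.
- **Cohorts.** Per-patient CTC counts follow the frequency distribution
  2: 10%, 3: 33.3%, 4: 30%, ≥5: 26.7%; the ≥5 category is drawn as 5 +
  truncated-geometric(0.5) capped at 11, giving an overall mean ≈ 4
  CTCs/patient within the observed 2–11 range. Counts below 2 do not
  occur (such patients are excluded by design). Subgroup mixtures by
  status default to brain (0.60, 0.15, 0.25), bone (0.10, 0.60, 0.30),
  none (0.25, 0.25, 0.50): subgroup 1 brain-enriched, subgroup 2
  bone-enriched, subgroup 3 background. Serum biomarkers are drawn
  lognormal, independent of status — the regime in which they carry no
  metastatic signal. All mixture and distribution values are config, not
  constants.
- **Seeding.** One global seed expands into per-stage child generators
  via `numpy.random.SeedSequence.spawn`; identical seeds give
  bit-identical tables.

What passing tests show: the implementation's statistics are correct
(oracle identities), calibrated (nominal type-I error, non-positive null
Q², uniform permutation p), and able to recover known structure under the
stated conditions. What they do not show: performance on real single-cell
spectra, whose noise is not lognormal-i.i.d., whose dropout is
structured, and which contain isotopes, adducts and chimeric peaks that
the generator (and the matcher's single-reference-per-metabolite model)
deliberately omit.

## Problem sizes in the default suites

Monte-Carlo checks use: 2000 replicates for Mann-Whitney type-I error
(n = 30/30); 200 null datasets for Q² calibration; 120 datasets × 59
permutations (n = 24, 15 features) for permutation-p uniformity; 50 seeds
for clustering recovery (k selection and ARI) at the default 3 × 40-cell
conditions; 100 cohorts for site-mapping recovery and the
subgroup-vs-total-count AUC comparison; 25 seeds for the screening
sensitivity/specificity envelope. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping the default
suite fast.

## Known limitations

- No centroiding, isotope/adduct deconvolution, or vendor raw parsing:
  input is already a peak list.
- Clustering on 2-D embeddings inherits t-SNE/UMAP distortions; the
  silhouette is computed in embedding space, not feature space.
- The ≥ 5 CTC tail distribution, biomarker distributions and all
  intensity parameters are stand-ins; conclusions about real cohorts
  require re-estimating them.
- AUC and cutoffs from 30-patient cohorts carry wide sampling error; the
  package reports them as computed without shrinkage or CIs on the ROC
  (CIs are available for logistic odds ratios only).
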