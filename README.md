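# ctcmet

Single-cell metabolomics of circulating tumor cells (CTCs) for
organ-specific metastasis-risk prediction in lung adenocarcinoma.

Liquid biopsy traditionally counts CTCs; this package implements the
qualitative step beyond counting: it profiles each CTC's metabolome from
its single-cell mass spectrum, discovers metabolic subgroups among the
CTCs of a patient cohort, and turns per-patient subgroup counts into
organ-specific (brain vs bone) metastasis-risk flags. It is aimed at
computational mass-spectrometry and translational-oncology groups working
with per-cell peak lists from nanoESI single-cell MS.

## The analysis

1. **Preprocessing** — each cell's peak list is normalized to the
   spiked internal standard (deuterated phenylalanine, d5-Phe; every
   intensity is divided by its signal, so a cell's profile is invariant
   to acquisition efficiency), then aligned to a reference metabolite
   panel by nearest m/z within a ppm tolerance (default 5 ppm,
   |m/z<sub>obs</sub> − m/z<sub>ref</sub>|/m/z<sub>ref</sub> · 10⁶ ≤ tol).
   Unstable features are dropped by detection fraction; remaining
   missingness is imputed (half-minimum), log₁₀-transformed and
   autoscaled.
2. **Differential screening** — pairwise PLS-DA (NIPALS) between cell
   populations with cumulative R²X/R²Y and cross-validated Q²
   (venetian-blind folds) plus label-permutation tests; candidates with
   VIP ≥ 1 are filtered by the volcano criterion FC ≥ 1.5 (either
   direction) and Mann-Whitney p ≤ 0.05. VIP follows
   VIP_j = √( J · Σ_a SSY_a (w_{ja}/‖w_a‖)² / Σ_a SSY_a ), so mean(VIP²) = 1.
3. **Pathway enrichment** — hypergeometric over-representation of the
   screened metabolites against a user-supplied pathway map, with
   Benjamini-Hochberg adjustment.
4. **Subgroup discovery** — t-SNE embedding of autoscaled profiles, mean
   silhouette width s(i) = (b−a)/max(a,b) of hierarchical (Ward)
   partitions selects the cluster number, and subgroups are labelled by
   descending size; UMAP cross-validates the partition (adjusted Rand
   index).
5. **Risk modelling** — per endpoint, the subgroup count with maximal
   pair-counting AUC is the predictor; the cutoff maximizes Youden's
   J = sensitivity + specificity − 1 over midpoints between observed
   counts (1.5 on integer counts split at 1 vs 2); logistic regression
   quantifies independence from total CTC count and serum biomarkers
   (NSE, CEA, CA-125, CYFRA21-1).

A synthetic-data generator (`ctcmet.simulate`) reproduces the study
design — three cell populations with signature metabolites, lognormal
intensities with dropout, ppm mass jitter, an internal-standard channel,
and patient cohorts with status-dependent subgroup mixtures — with ground
truth kept separate for calibration and recovery testing.

## Worked example

```python
from ctcmet import (three_subgroup_config, simulate_cell_matrix,
                    impute_and_scale, embed_cells, silhouette_select_k,
                    cluster_cells)

cfg = three_subgroup_config()                 # 3 x 40 cells, 390 metabolites
matrix, truth = simulate_cell_matrix(cfg, seed=7)
scaled = impute_and_scale(matrix, scale="autoscale")
emb = embed_cells(scaled, method="tsne", seed=42)
report = silhouette_select_k(emb, k_range=range(2, 9))
print(report.selected_k, cluster_cells(emb, report.selected_k).sizes.to_dict())
```

prints

```
3 {1: 43, 2: 39, 3: 38}
```

— the silhouette profile peaks at k = 3 (mean width 0.578 vs 0.456 at
k = 2) and the three recovered subgroups match the generating labels at
ARI = 0.876. The narrative scripts in `examples/` walk through each
capability (cohort simulation, differential screen, subgroup discovery,
risk prediction, full pipeline); `ctcmet run` executes the whole chain
from the shell and writes a reproducible artifact bundle with provenance.

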