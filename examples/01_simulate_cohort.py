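"""Generate a synthetic patient cohort with per-CTC peak lists.

Each patient gets a CTC count from the study's frequency distribution
(2: 10%, 3: 33.3%, 4: 30%, >=5: 26.7%), each CTC a latent metabolic
subgroup drawn from a metastasis-status-dependent mixture, and each
subgroup its own signature metabolites.
"""

from ctcmet import (SimCohortConfig, make_reference_panel,
                    simulate_patient_cohort, simulate_peak_lists,
                    three_subgroup_config)

cfg = three_subgroup_config()           # 390 metabolites, 30 signatures/subgroup
panel = make_reference_panel(cfg.n_metabolites, seed=0)
patients, matrix, truth = simulate_patient_cohort(SimCohortConfig(), cfg, seed=1)
peaks = simulate_peak_lists(matrix, panel, cfg, seed=2)

print(f"cohort: {len(patients)} patients, {matrix.shape[0]} CTCs total")
print(patients.groupby("status")["total_ctc"].agg(["count", "mean"]))
print(f"\nfirst CTC ({peaks[0].cell_id}): {len(peaks[0])} peaks, "
      f"m/z {peaks[0].mz.min():.3f}-{peaks[0].mz.max():.3f}")
print("true subgroup mixture by status:")
print(truth.cell_labels.groupby(truth.patient_status.loc[
    truth.cell_to_patient].to_numpy()).value_counts(normalize=True)
    .round(2).unstack())
# Brain-status patients are enriched in subgroup 1 and bone-status in
# subgroup 2 -- the association the downstream risk model must rediscover.
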