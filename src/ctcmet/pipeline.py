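"""End-to-end orchestration of the CTC metabolomics workflow.

A pipeline run chains: synthetic-input generation (optional) ->
preprocessing of per-cell peak lists -> differential screen on the
labelled cell-line matrix -> pathway enrichment -> patient-CTC subgroup
discovery -> per-patient metastasis-risk report. Every run writes the
fully resolved configuration, a provenance record (input hashes, package
version, parameters) and a run log next to its outputs, and re-running
with the same config and inputs reproduces identical tables.

All tables are UTF-8 TSV with a single header row; missing = empty field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .differential import screen_differential
from .enrichment import PathwayMap, enrich_pathways
from .preprocess import (IntensityMatrix, PeakList, ReferencePanel,
                         build_matrix, filter_features, impute_and_scale)
from .risk import risk_report
from .simulate import (SimCohortConfig, cell_line_config, make_reference_panel,
                       simulate_cell_matrix, simulate_patient_cohort,
                       simulate_peak_lists, three_subgroup_config)
from .subgroups import (cluster_cells, count_subgroups_per_patient,
                        embed_cells, silhouette_select_k)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_metabolites": 390,
        "n_patients_per_status": {"none": 10, "brain": 10, "bone": 10},
        "n_signature": 30,
        "dropout_rate": 0.2,
        "ppm_jitter_sd": 1.0,
    },
    "preprocess": {
        "ppm_tol": 5.0,
        "min_detection_fraction": 0.2,
    },
    "screen": {
        "n_components": 2,
        "cv_folds": 7,
        "vip_threshold": 1.0,
        "fc_threshold": 1.5,
        "p_threshold": 0.05,
        "correction": "none",
    },
    "enrich": {
        "correction": "bh",
    },
    "cluster": {
        "method": "tsne",
        "perplexity": 10.0,
        "k_range": [2, 8],
        "linkage": "ward",
        "distance": "euclidean",
        "embed_seed": 42,
    },
    "risk": {
        "endpoints": ["brain", "bone"],
        "auc_floor": 0.6,
    },
}


def resolve_config(config: dict[str, Any] | None) -> dict[str, Any]:
    """Merge a user config over the defaults, rejecting unknown keys."""
    resolved = {k: (dict(v) if isinstance(v, dict) else v)
                for k, v in DEFAULT_CONFIG.items()}
    for key, block in (config or {}).items():
        if key not in resolved:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(resolved[key], dict):
            for sub, val in block.items():
                if sub not in resolved[key]:
                    raise KeyError(f"unknown config key {key}.{sub}")
                resolved[key][sub] = val
        else:
            resolved[key] = block
    return resolved


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict[str, Any] | None = None,
                 outdir: str | Path = "ctcmet_run") -> dict[str, Path]:
    """Execute the full workflow and write the artifact bundle.

    With no external inputs configured, stage ``simulate`` generates the
    study's synthetic analogue: a labelled three-cell-line matrix for
    signature discovery and a 30-patient cohort of per-CTC peak lists for
    the clinical arm. Returns a mapping of artifact names to paths.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ctcmet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}
    provenance: dict[str, Any] = {"version": __version__, "config": cfg,
                                  "input_hashes": {}}

    def _write(name: str, path: Path) -> None:
        artifacts[name] = path
        provenance["input_hashes"][path.name] = _sha256(path)

    seed = int(cfg["seed"])
    try:
        stage = "simulate"
        sim = cfg["simulate"]
        panel = make_reference_panel(sim["n_metabolites"], seed=seed)
        panel.to_tsv(outdir / "reference_panel.tsv")
        _write("reference_panel", outdir / "reference_panel.tsv")

        cell_cfg = cell_line_config(n_metabolites=sim["n_metabolites"],
                                    dropout_rate=sim["dropout_rate"],
                                    ppm_jitter_sd=sim["ppm_jitter_sd"])
        line_matrix, line_truth = simulate_cell_matrix(cell_cfg, seed=seed + 1)
        line_truth.cell_labels.to_csv(outdir / "cell_line_labels.tsv", sep="\t")

        sub_cfg = three_subgroup_config(n_metabolites=sim["n_metabolites"],
                                        n_signature=sim["n_signature"],
                                        dropout_rate=sim["dropout_rate"],
                                        ppm_jitter_sd=sim["ppm_jitter_sd"])
        cohort_cfg = SimCohortConfig(
            n_patients_per_status=sim["n_patients_per_status"])
        patients, cohort_matrix, truth = simulate_patient_cohort(
            cohort_cfg, sub_cfg, seed=seed + 2)
        patients.to_csv(outdir / "patients.tsv", sep="\t", index=False)
        _write("patients", outdir / "patients.tsv")
        peak_dir = outdir / "peaks"
        peak_dir.mkdir(exist_ok=True)
        peak_lists = simulate_peak_lists(cohort_matrix, panel, sub_cfg,
                                         seed=seed + 3)
        for pl in peak_lists:
            pl.to_tsv(peak_dir / f"{pl.cell_id}.tsv")
        logger.info("simulate: %d patients, %d CTCs, %d cell-line cells",
                    len(patients), len(peak_lists), line_matrix.shape[0])

        stage = "preprocess"
        pp = cfg["preprocess"]
        loaded = [PeakList.from_tsv(p) for p in sorted(peak_dir.glob("*.tsv"))]
        matrix = build_matrix(loaded, panel, ppm_tol=pp["ppm_tol"])
        matrix = filter_features(matrix, pp["min_detection_fraction"])
        matrix.to_tsv(outdir / "intensity_matrix.tsv")
        _write("intensity_matrix", outdir / "intensity_matrix.tsv")

        stage = "screen"
        sc = cfg["screen"]
        diff_table, model = screen_differential(
            line_matrix, line_truth.cell_labels, group_a="Bom", group_b="Brm",
            n_components=sc["n_components"], cv_folds=sc["cv_folds"],
            vip_threshold=sc["vip_threshold"], fc_threshold=sc["fc_threshold"],
            p_threshold=sc["p_threshold"], correction=sc["correction"])
        diff_table.to_csv(outdir / "differential.tsv", sep="\t",
                          index_label="metabolite_id")
        _write("differential", outdir / "differential.tsv")
        logger.info("screen: R2X=%.3f R2Y=%.3f Q2=%.3f, %d survivors",
                    model.r2x, model.r2y, model.q2,
                    int(diff_table["passes_volcano"].sum()))

        stage = "enrich"
        pmap = PathwayMap.from_panel(panel)
        selected = set(diff_table.index[diff_table["passes_volcano"]])
        enr = enrich_pathways(selected, set(panel.metabolite_ids), pmap,
                              correction=cfg["enrich"]["correction"])
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        _write("enrichment", outdir / "enrichment.tsv")

        stage = "cluster"
        cl = cfg["cluster"]
        scaled = impute_and_scale(matrix, scale="autoscale")
        emb = embed_cells(scaled, method=cl["method"], seed=cl["embed_seed"],
                          perplexity=cl["perplexity"])
        lo, hi = cl["k_range"]
        report = silhouette_select_k(emb, range(lo, hi + 1),
                                     cl["linkage"], cl["distance"])
        assignment = cluster_cells(emb, report.selected_k,
                                   cl["linkage"], cl["distance"])
        counts = count_subgroups_per_patient(assignment, truth.cell_to_patient)
        out = pd.DataFrame({
            "cell_id": assignment.labels.index,
            "patient_id": truth.cell_to_patient.loc[assignment.labels.index],
            "subgroup": assignment.labels.to_numpy(),
        })
        out.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        _write("assignments", outdir / "assignments.tsv")
        emb.coords.to_csv(outdir / "embedding.tsv", sep="\t",
                          index_label="cell_id")
        counts.to_csv(outdir / "subgroup_counts.tsv", sep="\t",
                      index_label="patient_id")
        _write("subgroup_counts", outdir / "subgroup_counts.tsv")
        with open(outdir / "clustering_report.json", "w") as fh:
            json.dump({
                "selected_k": report.selected_k,
                "mean_silhouettes": {str(k): v for k, v in
                                     report.mean_silhouettes.items()},
                "linkage": report.linkage, "distance": report.distance,
                "subgroup_sizes": assignment.sizes.to_dict(),
            }, fh, indent=2)
        artifacts["clustering_report"] = outdir / "clustering_report.json"
        logger.info("cluster: selected k=%d, sizes=%s", report.selected_k,
                    assignment.sizes.to_dict())

        stage = "risk"
        statuses = truth.patient_status.loc[counts.index]
        results, flags = risk_report(counts, statuses,
                                     endpoints=cfg["risk"]["endpoints"],
                                     auc_floor=cfg["risk"]["auc_floor"])
        with open(outdir / "risk_report.json", "w") as fh:
            json.dump([asdict(r) for r in results], fh, indent=2)
        artifacts["risk_report"] = outdir / "risk_report.json"
        flags.to_csv(outdir / "risk_flags.tsv", sep="\t",
                     index_label="patient_id")
        _write("risk_flags", outdir / "risk_flags.tsv")
        for r in results:
            logger.info("risk %s: subgroup=%s cutoff=%s AUC=%.3f "
                        "(total-count AUC=%.3f)", r.endpoint, r.subgroup,
                        r.cutoff, r.auc, r.total_count_auc)
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, exc) from exc

    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    artifacts["resolved_config"] = outdir / "resolved_config.yaml"
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    artifacts["provenance"] = outdir / "provenance.json"
    root.removeHandler(handler)
    handler.close()
    return artifacts
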