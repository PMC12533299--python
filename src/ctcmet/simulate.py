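"""Synthetic single-cell metabolomics data with retained ground truth.

The generator emulates the statistical structure of a single-cell CTC
metabolomics study: populations of cells whose log-intensities carry
pathway-structured signature shifts, multiplicative (lognormal) detector
noise, missing-value dropout, an internal-standard channel (d5-Phe), and
ppm-level mass jitter; patient cohorts whose per-patient CTC counts follow
a given frequency distribution with metastasis-status-dependent subgroup
composition.

All intensity distributions are stand-ins: the generator reproduces the
study design (population sizes, count frequencies, effect directions),
not measured spectra. Ground truth is returned separately so pipeline
inputs never contain labels unless explicitly requested.

One global seed expands into per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import D5_PHE_MZ, IntensityMatrix, PeakList, ReferencePanel

LOG10_2 = float(np.log10(2.0))

#: CTC-count frequency distribution of the training cohort: mass on
#: 2, 3, 4 and ">=5" CTCs per 5 mL of blood.
DEFAULT_CTC_COUNT_DISTRIBUTION: dict[int | str, float] = {
    2: 0.10, 3: 0.333, 4: 0.30, "5+": 0.267,
}

#: status-dependent latent subgroup mixtures (subgroups 1, 2, 3):
#: subgroup 1 enriched in brain-metastatic, 2 in bone-metastatic patients,
#: 3 a background phenotype common in non-metastatic patients.
DEFAULT_SUBGROUP_MIXTURES: dict[str, tuple[float, float, float]] = {
    "none": (0.25, 0.25, 0.50),
    "brain": (0.60, 0.15, 0.25),
    "bone": (0.10, 0.60, 0.30),
}

STATUSES = ("none", "brain", "bone")


class SimulationError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class SimCellConfig:
    """Parameters of the per-cell intensity model.

    Log10-intensities are baseline + population shift + Normal noise;
    signature metabolites of a population are shifted up by
    ``signature_log2fc`` on the log2 scale. Intensities are relative to
    the internal standard (dimensionless); the IS channel itself has mean
    raw intensity ``is_intensity_mean`` in detector units.
    """

    n_cells_per_population: Mapping[str, int]
    signature_sets: Mapping[str, frozenset[int]]
    n_metabolites: int = 390
    signature_log2fc: float = 1.5
    baseline_log_mean_range: tuple[float, float] = (-1.0, 1.0)
    log_sd: float = 0.1
    dropout_rate: float = 0.2
    dropout_mode: str = "mcar"  # or "intensity" (logistic in log-intensity)
    is_intensity_mean: float = 1e5
    is_log_sd: float = 0.15
    ppm_jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_cells_per_population.values()):
            raise SimulationError("cell counts must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise SimulationError("dropout_rate must be in [0, 1]")
        if self.log_sd <= 0 or self.is_intensity_mean <= 0:
            raise SimulationError("log_sd and is_intensity_mean must be positive")
        if self.ppm_jitter_sd < 0:
            raise SimulationError("ppm_jitter_sd must be non-negative")
        if self.dropout_mode not in ("mcar", "intensity"):
            raise SimulationError(f"unknown dropout_mode {self.dropout_mode!r}")
        seen: set[int] = set()
        for pop, idx in self.signature_sets.items():
            overlap = seen & set(idx)
            if overlap:
                raise SimulationError(
                    f"signature sets must be disjoint across populations; "
                    f"population {pop!r} re-uses indices {sorted(overlap)[:5]}")
            seen |= set(idx)
        if seen and max(seen) >= self.n_metabolites:
            raise SimulationError("signature index exceeds n_metabolites - 1")

    @property
    def populations(self) -> list[str]:
        return list(self.n_cells_per_population)

    @property
    def n_cells(self) -> int:
        return sum(self.n_cells_per_population.values())


@dataclass(frozen=True)
class SimCohortConfig:
    """Parameters of the patient-cohort model."""

    n_patients_per_status: Mapping[str, int] = field(
        default_factory=lambda: {s: 10 for s in STATUSES})
    ctc_count_distribution: Mapping[int | str, float] = field(
        default_factory=lambda: dict(DEFAULT_CTC_COUNT_DISTRIBUTION))
    subgroup_mixtures: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_MIXTURES))

    def __post_init__(self) -> None:
        if not self.n_patients_per_status:
            raise SimulationError("cohort needs at least one status group")
        if any(n <= 0 for n in self.n_patients_per_status.values()):
            raise SimulationError("empty status group in cohort config")
        for cnt in self.ctc_count_distribution:
            if cnt != "5+" and int(cnt) < 2:
                raise SimulationError("CTC counts below 2 are excluded by design")
        total = sum(self.ctc_count_distribution.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise SimulationError(f"count distribution sums to {total}, not 1")
        for status, mix in self.subgroup_mixtures.items():
            if abs(sum(mix) - 1.0) > 1e-12:
                raise SimulationError(
                    f"subgroup mixture for {status!r} must sum to 1 within 1e-12")


@dataclass
class GroundTruth:
    """Generating labels kept aside for parameter-recovery tests."""

    cell_labels: pd.Series
    differential: pd.DataFrame  # metabolites x populations, True = signature
    patient_status: pd.Series | None = None
    cell_to_patient: pd.Series | None = None


# ---------------------------------------------------------------------------
# default study configurations


def make_reference_panel(n_metabolites: int = 390, seed: int = 0,
                         n_pathways: int = 12,
                         mz_range: tuple[float, float] = (70.0, 1050.0),
                         min_spacing: float = 0.05) -> ReferencePanel:
    """A synthetic reference metabolite panel.

    m/z values are drawn over the full-scan range with a minimum spacing
    (default 0.05 Th, i.e. > 45 ppm even at the top of the range) so that
    ppm matching at Orbitrap-class tolerances is unambiguous, and kept
    clear of the internal-standard channel. Pathway memberships are random
    but contiguous blocks dominate, so signature sets generated per
    population overlap coherent pathways.
    """
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    # keep 0.5 Th off each edge so ppm jitter never leaves the scan range
    lo_eff, hi_eff = lo + 0.5, hi - 0.5
    usable = (hi_eff - lo_eff) - n_metabolites * min_spacing
    if usable <= 0:
        raise SimulationError("mz range too narrow for requested panel")
    while True:
        gaps = rng.uniform(0, 1, n_metabolites)
        gaps = gaps / gaps.sum() * usable
        mz = lo_eff + np.cumsum(gaps + min_spacing)
        if np.all(np.abs(mz - D5_PHE_MZ) / D5_PHE_MZ * 1e6 > 50):
            break
    pathway_names = [
        "arginine and proline metabolism",
        "phenylalanine, tyrosine and tryptophan biosynthesis",
        "glycerophospholipid metabolism",
        "purine metabolism",
        "TCA cycle",
        "glutathione metabolism",
    ]
    pathway_ids = [f"PW{i + 1:02d}" for i in range(n_pathways)]
    names = (pathway_names + [f"pathway {i + 1}" for i in range(n_pathways)])[:n_pathways]
    # block-structured membership: consecutive metabolites share pathways
    membership: list[str] = []
    block = rng.integers(0, n_pathways)
    for j in range(n_metabolites):
        if rng.random() < 0.15:
            block = rng.integers(0, n_pathways)
        pws = {pathway_ids[block]}
        if rng.random() < 0.2:
            pws.add(pathway_ids[rng.integers(0, n_pathways)])
        membership.append(";".join(sorted(pws)))
    table = pd.DataFrame({
        "metabolite_id": [f"M{j + 1:04d}" for j in range(n_metabolites)],
        "name": [f"metabolite {j + 1}" for j in range(n_metabolites)],
        "ref_mz": np.round(mz, 5),
        "pathway_ids": membership,
    })
    table.attrs["pathway_names"] = dict(zip(pathway_ids, names))
    return ReferencePanel(table)


def _random_signatures(populations: Sequence[str], n_metabolites: int,
                       n_per_population: int, seed: int) -> dict[str, frozenset[int]]:
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_metabolites)
    out, start = {}, 0
    for pop in populations:
        out[pop] = frozenset(int(i) for i in idx[start:start + n_per_population])
        start += n_per_population
    return out


def two_population_config(n_per_group: int = 60, n_metabolites: int = 390,
                          n_signature: int = 50, signature_log2fc: float = 1.5,
                          dropout_rate: float = 0.2,
                          signature_seed: int = 7, **kwargs) -> SimCellConfig:
    """Two cell populations (e.g. bone- vs brain-tropic lines) for
    differential-screening studies: ``n_signature`` metabolites up in each."""
    pops = ("A", "B")
    return SimCellConfig(
        n_cells_per_population={p: n_per_group for p in pops},
        signature_sets=_random_signatures(pops, n_metabolites, n_signature,
                                          signature_seed),
        n_metabolites=n_metabolites, signature_log2fc=signature_log2fc,
        dropout_rate=dropout_rate, **kwargs)


def three_subgroup_config(n_per_group: int = 40, n_metabolites: int = 390,
                          n_signature: int = 30, signature_log2fc: float = 1.5,
                          dropout_rate: float = 0.2,
                          signature_seed: int = 7, **kwargs) -> SimCellConfig:
    """Three latent CTC subgroups with 30 signature metabolites each —
    the default conditions for clustering-recovery studies."""
    pops = ("1", "2", "3")
    return SimCellConfig(
        n_cells_per_population={p: n_per_group for p in pops},
        signature_sets=_random_signatures(pops, n_metabolites, n_signature,
                                          signature_seed),
        n_metabolites=n_metabolites, signature_log2fc=signature_log2fc,
        dropout_rate=dropout_rate, **kwargs)


def cell_line_config(n_metabolites: int = 390, n_signature: int = 50,
                     signature_seed: int = 7, **kwargs) -> SimCellConfig:
    """The three-cell-line design (58 primary-CTC, 60 bone-tropic, 63
    brain-tropic cells) used for signature discovery."""
    pops = ("PC9-CTC", "Bom", "Brm")
    return SimCellConfig(
        n_cells_per_population={"PC9-CTC": 58, "Bom": 60, "Brm": 63},
        signature_sets=_random_signatures(pops, n_metabolites, n_signature,
                                          signature_seed),
        n_metabolites=n_metabolites, **kwargs)


# ---------------------------------------------------------------------------
# generators


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _metabolite_ids(n: int) -> list[str]:
    return [f"M{j + 1:04d}" for j in range(n)]


def _generate_log_matrix(labels: Sequence[str], config: SimCellConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Log10-intensity matrix for cells with the given population labels."""
    n, m = len(labels), config.n_metabolites
    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, m)
    shift = np.zeros((n, m))
    delta = config.signature_log2fc * LOG10_2
    for pop, idx in config.signature_sets.items():
        if not idx:
            continue
        rows = np.asarray([lab == pop for lab in labels])
        cols = np.fromiter(idx, int)
        shift[np.ix_(rows, cols)] = delta
    return baseline + shift + rng.normal(0, config.log_sd, (n, m))


def _apply_dropout(logv: np.ndarray, config: SimCellConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if config.dropout_rate == 0:
        return np.zeros(logv.shape, bool)
    if config.dropout_mode == "mcar":
        return rng.random(logv.shape) < config.dropout_rate
    # intensity-dependent: logistic in log-intensity, centred so the
    # overall dropout fraction matches dropout_rate
    mid = np.quantile(logv, config.dropout_rate)
    p = expit((mid - logv) / 0.3)
    p *= config.dropout_rate / max(p.mean(), 1e-12)
    return rng.random(logv.shape) < np.clip(p, 0, 1)


def simulate_cell_matrix(config: SimCellConfig,
                         seed: int) -> tuple[IntensityMatrix, GroundTruth]:
    """Draw an IS-normalized cells x metabolites matrix with dropout.

    Identical seeds give bit-identical output.
    """
    rng_noise, rng_drop = _stage_rngs(seed, 2)
    labels = [pop for pop, n in config.n_cells_per_population.items()
              for _ in range(n)]
    cell_ids = [f"{pop}_c{i + 1:03d}" for pop, n in
                config.n_cells_per_population.items() for i in range(n)]
    logv = _generate_log_matrix(labels, config, rng_noise)
    drop = _apply_dropout(logv, config, rng_drop)
    values = np.power(10.0, logv)
    values[drop] = np.nan
    mids = _metabolite_ids(config.n_metabolites)
    data = pd.DataFrame(values, index=pd.Index(cell_ids, name="cell_id"),
                        columns=mids)
    diff = pd.DataFrame(False, index=mids, columns=config.populations)
    for pop, idx in config.signature_sets.items():
        diff.iloc[list(idx), diff.columns.get_loc(pop)] = True
    truth = GroundTruth(
        cell_labels=pd.Series(labels, index=data.index, name="population"),
        differential=diff)
    return IntensityMatrix(data, state="is_normalized"), truth


def simulate_peak_lists(matrix: IntensityMatrix, reference: ReferencePanel,
                        config: SimCellConfig, seed: int) -> list[PeakList]:
    """Invert preprocessing: emit raw-style peak lists from a matrix.

    Each cell's peaks sit at the panel's reference m/z perturbed by
    Normal(0, ppm_jitter_sd) ppm; intensities are the matrix entries times
    the cell's internal-standard intensity, and the d5-Phe IS peak itself
    is appended. Missing matrix entries produce no peak.
    """
    if matrix.shape[1] != len(reference):
        raise SimulationError(
            f"matrix has {matrix.shape[1]} metabolites but panel has "
            f"{len(reference)}")
    ref_mz = reference.ref_mz
    spacing_ppm = (np.min(np.diff(np.sort(ref_mz))) / np.max(ref_mz) * 1e6
                   if len(ref_mz) > 1 else np.inf)
    if config.ppm_jitter_sd > spacing_ppm / 2:
        import warnings
        warnings.warn(
            f"ppm jitter SD {config.ppm_jitter_sd} exceeds half the minimal "
            f"reference spacing ({spacing_ppm:.1f} ppm): matching ambiguity "
            "expected", stacklevel=2)
    rng_is, rng_jitter = _stage_rngs(seed, 2)
    out = []
    values = matrix.data.to_numpy(float)
    for i, cell_id in enumerate(matrix.cell_ids):
        row = values[i]
        observed = ~np.isnan(row)
        is_intensity = config.is_intensity_mean * np.power(
            10.0, rng_is.normal(0.0, config.is_log_sd))
        mz = ref_mz[observed]
        jitter = rng_jitter.normal(0.0, config.ppm_jitter_sd, mz.size + 1)
        mz = mz * (1 + jitter[:-1] * 1e-6)
        is_mz = D5_PHE_MZ * (1 + jitter[-1] * 1e-6)
        mzs = np.concatenate([mz, [is_mz]])
        intens = np.concatenate([row[observed] * is_intensity, [is_intensity]])
        order = np.argsort(mzs)
        out.append(PeakList(cell_id, mzs[order], intens[order]))
    return out


def _draw_ctc_count(rng: np.random.Generator,
                    dist: Mapping[int | str, float]) -> int:
    cats = list(dist)
    probs = np.array([dist[c] for c in cats], float)
    probs = probs / probs.sum()
    pick = cats[rng.choice(len(cats), p=probs)]
    if pick == "5+":
        # truncated geometric tail over 5..11 (observed cohort range 2-11)
        k = int(rng.geometric(0.5)) - 1
        return 5 + min(k, 6)
    return int(pick)


_BIOMARKERS = {  # serum tumour markers: (log10 median, log10 SD), assay units
    "NSE": (np.log10(12.0), 0.20),        # ng/mL
    "CEA": (np.log10(3.0), 0.35),         # ng/mL
    "CA125": (np.log10(15.0), 0.30),      # U/mL
    "CYFRA21_1": (np.log10(2.5), 0.25),   # ng/mL
}


def simulate_patient_cohort(
        config: SimCohortConfig, cell_config: SimCellConfig, seed: int,
) -> tuple[pd.DataFrame, IntensityMatrix, GroundTruth]:
    """Draw a patient cohort with status-dependent CTC subgroup composition.

    Each patient receives a CTC count from the configured frequency
    distribution; each CTC a latent subgroup from the patient's
    status-specific mixture; each CTC an intensity vector from that
    subgroup's signature model. Serum biomarkers are drawn independently
    of status (the setting where they carry no metastasis signal).
    Returns (patient table, IS-normalized cell matrix, ground truth).
    """
    subgroups = cell_config.populations
    for status, mix in config.subgroup_mixtures.items():
        if len(mix) != len(subgroups):
            raise SimulationError(
                f"mixture for {status!r} has {len(mix)} entries for "
                f"{len(subgroups)} subgroups")
    rng_counts, rng_labels, rng_cells, rng_biom = _stage_rngs(seed, 4)

    patients, cell_labels, cell_ids, cell_to_patient = [], [], [], []
    for status, n_pat in config.n_patients_per_status.items():
        mix = np.asarray(config.subgroup_mixtures[status], float)
        for p in range(n_pat):
            pid = f"{status}_p{p + 1:02d}"
            count = _draw_ctc_count(rng_counts, config.ctc_count_distribution)
            labs = [subgroups[i] for i in
                    rng_labels.choice(len(subgroups), size=count, p=mix)]
            for j, lab in enumerate(labs):
                cell_ids.append(f"{pid}_ctc{j + 1}")
                cell_labels.append(lab)
                cell_to_patient.append(pid)
            row = {"patient_id": pid, "status": status, "total_ctc": count}
            for name, (mu, sd) in _BIOMARKERS.items():
                row[name] = round(float(np.power(10.0, rng_biom.normal(mu, sd))), 2)
            patients.append(row)

    logv = _generate_log_matrix(cell_labels, cell_config, rng_cells)
    drop = _apply_dropout(logv, cell_config, rng_cells)
    values = np.power(10.0, logv)
    values[drop] = np.nan
    mids = _metabolite_ids(cell_config.n_metabolites)
    data = pd.DataFrame(values, index=pd.Index(cell_ids, name="cell_id"),
                        columns=mids)
    matrix = IntensityMatrix(data, state="is_normalized")

    patient_table = pd.DataFrame(patients)
    diff = pd.DataFrame(False, index=mids, columns=subgroups)
    for pop, idx in cell_config.signature_sets.items():
        diff.iloc[list(idx), diff.columns.get_loc(pop)] = True
    truth = GroundTruth(
        cell_labels=pd.Series(cell_labels, index=data.index, name="subgroup"),
        differential=diff,
        patient_status=patient_table.set_index("patient_id")["status"],
        cell_to_patient=pd.Series(cell_to_patient, index=data.index,
                                  name="patient_id"))
    return patient_table, matrix, truth
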