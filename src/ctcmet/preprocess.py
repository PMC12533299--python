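"""Raw per-cell peak lists -> normalized, reference-aligned intensity matrix.

The preprocessing chain mirrors how single-cell nanoESI mass spectra are
turned into a cells x metabolites table: locate the spiked internal
standard (deuterated phenylalanine, d5-Phe) and divide every peak by its
intensity, assign each peak to the nearest reference metabolite within a
ppm tolerance, drop unstable features by detection fraction, then impute
remaining missingness, log-transform and autoscale for multivariate
modelling.

Missing values are represented as NaN in memory and as empty fields in
TSV files; zeros are measured values, never missing codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: protonated d5-phenylalanine, the internal-standard channel
D5_PHE_MZ = 171.1279

#: monotone order of normalization states
_STATES = ("raw", "is_normalized", "log_scaled", "autoscaled")


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PeakList:
    """One cell's spectrum: (m/z, intensity) pairs plus acquisition metadata.

    m/z is in Thomson, intensities in arbitrary detector units (or
    dimensionless after internal-standard normalization).
    """

    cell_id: str
    mz: np.ndarray
    intensity: np.ndarray
    scan_range: tuple[float, float] = (70.0, 1050.0)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise PreprocessError(
                f"cell {self.cell_id!r}: mz and intensity must be 1-D and equal length"
            )
        lo, hi = self.scan_range
        if mz.size and (mz.min() < lo or mz.max() > hi):
            raise PreprocessError(
                f"cell {self.cell_id!r}: m/z outside scan range [{lo}, {hi}]"
            )
        if np.any(inten < 0):
            raise PreprocessError(f"cell {self.cell_id!r}: negative intensity")

    def __len__(self) -> int:
        return self.mz.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, cell_id: str | None = None,
                 scan_range: tuple[float, float] = (70.0, 1050.0)) -> "PeakList":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - message formatting
            raise PreprocessError(f"{path}: cannot parse peak list ({exc})") from exc
        for col in ("mz", "intensity"):
            if col not in df.columns:
                raise PreprocessError(f"{path}: missing column {col!r}")
        return cls(cell_id or path.stem, df["mz"].to_numpy(float),
                   df["intensity"].to_numpy(float), scan_range)


@dataclass(frozen=True)
class ReferencePanel:
    """Reference metabolite panel: id, name, reference m/z, pathway memberships."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"metabolite_id", "name", "ref_mz"}
        missing = required - set(self.table.columns)
        if missing:
            raise PreprocessError(f"reference panel missing columns {sorted(missing)}")
        if self.table["metabolite_id"].duplicated().any():
            raise PreprocessError("duplicate metabolite_id in reference panel")
        mz = self.table["ref_mz"].to_numpy(float)
        if np.unique(mz).size != mz.size:
            raise PreprocessError("reference m/z values must be unique")
        logger.info("loaded reference panel with %d metabolites", len(self.table))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def metabolite_ids(self) -> list[str]:
        return self.table["metabolite_id"].tolist()

    @property
    def ref_mz(self) -> np.ndarray:
        return self.table["ref_mz"].to_numpy(float)

    def pathway_map(self) -> dict[str, set[str]]:
        """pathway_id -> member metabolite ids, from the panel's annotations."""
        out: dict[str, set[str]] = {}
        if "pathway_ids" not in self.table.columns:
            return out
        for mid, raw in zip(self.table["metabolite_id"], self.table["pathway_ids"]):
            if not isinstance(raw, str) or not raw:
                continue
            for pid in raw.split(";"):
                out.setdefault(pid, set()).add(mid)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str, "name": str})
        if "pathway_ids" in df.columns:
            df["pathway_ids"] = df["pathway_ids"].fillna("")
        return cls(df)


@dataclass
class IntensityMatrix:
    """Cells x metabolites intensity table with a missingness mask.

    ``data`` has cell ids as the row index and metabolite ids as columns;
    NaN marks an unobserved entry. ``state`` advances monotonically
    raw -> is_normalized -> log_scaled -> autoscaled.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise PreprocessError(f"unknown normalization state {self.state!r}")
        if self.state in ("raw", "is_normalized"):
            if (self.data.to_numpy(float) < 0).any():
                raise PreprocessError("negative intensities before log transform")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def advance_state(self, new_state: str) -> None:
        if _STATES.index(new_state) < _STATES.index(self.state):
            raise PreprocessError(
                f"cannot move state backwards: {self.state} -> {new_state}"
            )
        self.state = new_state

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), self.state)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="cell_id", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, state: str = "raw") -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell_id")
        return cls(df, state)


# ---------------------------------------------------------------------------
# operations


def ppm_offset(observed: float | np.ndarray, reference: float | np.ndarray) -> np.ndarray:
    """Relative mass deviation |obs - ref| / ref in parts per million."""
    observed = np.asarray(observed, float)
    reference = np.asarray(reference, float)
    return np.abs(observed - reference) / reference * 1e6


def normalize_internal_standard(peaks: PeakList, is_mz: float = D5_PHE_MZ,
                                ppm_tol: float = 5.0) -> PeakList:
    """Divide all intensities by the internal-standard peak and remove it.

    The IS peak is the one nearest ``is_mz`` within ``ppm_tol``; if none is
    found the cell cannot be normalized and an error is raised so the caller
    can flag and exclude it.
    """
    if ppm_tol <= 0:
        raise PreprocessError("ppm_tol must be positive")
    offsets = ppm_offset(peaks.mz, is_mz)
    candidates = np.flatnonzero(offsets <= ppm_tol)
    if candidates.size == 0:
        raise PreprocessError(
            f"cell {peaks.cell_id!r}: no internal-standard peak within "
            f"{ppm_tol} ppm of m/z {is_mz}"
        )
    if candidates.size > 1:
        logger.warning("cell %r: %d candidate IS peaks, using nearest",
                       peaks.cell_id, candidates.size)
    idx = candidates[np.argmin(offsets[candidates])]
    is_intensity = peaks.intensity[idx]
    if is_intensity <= 0:
        raise PreprocessError(f"cell {peaks.cell_id!r}: non-positive IS intensity")
    keep = np.ones(len(peaks), bool)
    keep[idx] = False
    return PeakList(peaks.cell_id, peaks.mz[keep],
                    peaks.intensity[keep] / is_intensity, peaks.scan_range)


def match_to_reference(peaks: PeakList, panel: ReferencePanel,
                       ppm_tol: float = 5.0) -> pd.Series:
    """Assign each peak to its nearest reference m/z within ``ppm_tol``.

    Returns a per-metabolite intensity vector indexed like the panel;
    unmatched references are NaN. When several peaks map to one reference
    the maximum intensity is kept (the collision is logged). Ties between
    two references at identical ppm are broken toward the lower ref_mz.
    """
    if ppm_tol <= 0:
        raise PreprocessError("ppm_tol must be positive")
    if len(panel) == 0:
        raise PreprocessError("empty reference panel")
    order = np.argsort(panel.ref_mz, kind="stable")
    ref_sorted = panel.ref_mz[order]
    out = np.full(len(panel), np.nan)
    if len(peaks):
        pos = np.searchsorted(ref_sorted, peaks.mz)
        left = np.clip(pos - 1, 0, len(ref_sorted) - 1)
        right = np.clip(pos, 0, len(ref_sorted) - 1)
        ppm_left = ppm_offset(peaks.mz, ref_sorted[left])
        ppm_right = ppm_offset(peaks.mz, ref_sorted[right])
        # nearest in ppm; tie -> lower ref_mz (the left neighbour)
        take_left = ppm_left <= ppm_right
        nearest = np.where(take_left, left, right)
        best_ppm = np.where(take_left, ppm_left, ppm_right)
        for j, (ref_idx, off, inten) in enumerate(
                zip(nearest, best_ppm, peaks.intensity)):
            if off > ppm_tol:
                continue
            col = order[ref_idx]
            if np.isnan(out[col]):
                out[col] = inten
            else:
                logger.debug(
                    "cell %r: collision on %s, keeping max intensity",
                    peaks.cell_id, panel.metabolite_ids[col])
                out[col] = max(out[col], inten)
    return pd.Series(out, index=panel.metabolite_ids, name=peaks.cell_id)


def build_matrix(peak_lists: Iterable[PeakList], panel: ReferencePanel,
                 ppm_tol: float = 5.0, is_mz: float = D5_PHE_MZ,
                 is_ppm_tol: float | None = None) -> IntensityMatrix:
    """IS-normalize and reference-align a batch of peak lists.

    Cells whose internal standard cannot be located are excluded with a
    logged reason rather than aborting the batch.
    """
    rows, excluded = [], []
    for pl in peak_lists:
        try:
            norm = normalize_internal_standard(pl, is_mz, is_ppm_tol or ppm_tol)
        except PreprocessError as exc:
            logger.warning("excluding cell %r: %s", pl.cell_id, exc)
            excluded.append(pl.cell_id)
            continue
        rows.append(match_to_reference(norm, panel, ppm_tol))
    if not rows:
        raise PreprocessError("no cells survived internal-standard normalization")
    if excluded:
        logger.info("excluded %d/%d cells (no IS peak)", len(excluded),
                    len(excluded) + len(rows))
    data = pd.DataFrame(rows)
    data.index.name = "cell_id"
    return IntensityMatrix(data, state="is_normalized")


def filter_features(matrix: IntensityMatrix, min_detection_fraction: float = 0.2,
                    group_labels: Sequence | None = None) -> IntensityMatrix:
    """Keep metabolites detected in >= a fraction of cells.

    With ``group_labels``, a metabolite is retained when it meets the
    threshold within at least one group — a stable-feature criterion that
    keeps markers detected consistently in only one population.
    """
    if not 0 <= min_detection_fraction <= 1:
        raise PreprocessError("min_detection_fraction must be in [0, 1]")
    detected = matrix.data.notna()
    if group_labels is None:
        keep = detected.mean(axis=0) >= min_detection_fraction
    else:
        labels = pd.Series(list(group_labels), index=matrix.data.index)
        frac = detected.groupby(labels).mean()
        keep = (frac >= min_detection_fraction).any(axis=0)
    if not keep.any():
        raise PreprocessError(
            f"detection threshold {min_detection_fraction} removes every feature "
            f"({matrix.shape[1]} candidates)")
    logger.info("feature filter: kept %d/%d metabolites at fraction >= %s",
                int(keep.sum()), matrix.shape[1], min_detection_fraction)
    return IntensityMatrix(matrix.data.loc[:, keep].copy(), matrix.state)


def impute_and_scale(matrix: IntensityMatrix, impute: str = "half_min",
                     scale: str = "autoscale") -> IntensityMatrix:
    """Impute missing entries, log10-transform, and optionally autoscale.

    Default imputation is the half-minimum rule: a missing entry gets half
    the smallest observed value of its metabolite, the usual stand-in for
    below-detection-limit intensities. ``scale`` is ``"autoscale"``
    (per-metabolite zero mean / unit variance after log10), ``"log"``
    (log10 only) or ``"none"``.
    """
    if matrix.state != "is_normalized":
        raise PreprocessError(
            f"impute_and_scale expects an is_normalized matrix, got {matrix.state!r}")
    if impute not in ("half_min", "min", "none"):
        raise PreprocessError(f"unknown imputation policy {impute!r}")
    if scale not in ("autoscale", "log", "none"):
        raise PreprocessError(f"unknown scaling policy {scale!r}")
    data = matrix.data.copy()
    if impute != "none":
        all_missing = data.isna().all(axis=0)
        if all_missing.any():
            raise PreprocessError(
                "metabolites missing in every cell (filter first): "
                + ", ".join(data.columns[all_missing][:5]))
        col_min = data.min(axis=0, skipna=True)
        fill = col_min / 2.0 if impute == "half_min" else col_min
        data = data.fillna(fill)
    out = IntensityMatrix(data, matrix.state)
    if scale == "none":
        return out
    if (data.to_numpy() <= 0).any():
        raise PreprocessError("non-positive intensities cannot be log-transformed")
    logged = np.log10(data)
    if scale == "log":
        return IntensityMatrix(logged, "log_scaled")
    sd = logged.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        raise PreprocessError(
            "zero-variance metabolites cannot be autoscaled: "
            + ", ".join(logged.columns[zero_var][:5]))
    scaled = (logged - logged.mean(axis=0)) / sd
    return IntensityMatrix(scaled, "autoscaled")
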