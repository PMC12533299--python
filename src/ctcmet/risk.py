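"""Organ-specific metastasis-risk prediction from CTC subgroup counts.

ROC analysis with pair-counting AUC, Youden-index cutoffs over midpoint
thresholds (which yields the half-integer cutoffs characteristic of count
data, e.g. 1.5 between counts of 1 and 2), logistic-regression
confirmation, data-driven mapping of subgroups to metastatic sites, and
per-patient high-risk flags (count strictly above the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class RiskError(ValueError):
    pass


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise RiskError("labels must be binary 0/1")
    if y.min() == y.max():
        raise RiskError("both classes must be present")
    return y


def auc(scores, labels) -> float:
    """Pair-counting (Mann-Whitney) AUC estimator; ties contribute 1/2."""
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    ranks = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points at midpoints between adjacent distinct scores.

    A case is called positive when its score is strictly above the
    threshold. Thresholds run from +inf (fpr = tpr = 0) down through the
    midpoints to -inf (fpr = tpr = 1); the trapezoidal area under the
    resulting curve equals the pair-counting AUC exactly.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else np.array([])
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    n_pos, n_neg = y.sum(), (1 - y).sum()
    rows = []
    for t in thresholds:
        called = s > t
        rows.append({
            "fpr": float((called & (y == 0)).sum() / n_neg),
            "tpr": float((called & (y == 1)).sum() / n_pos),
            "threshold": float(t),
        })
    return pd.DataFrame(rows)


def trapezoid_auc(curve: pd.DataFrame) -> float:
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


@dataclass
class YoudenResult:
    cutoff: float
    j: float
    sensitivity: float
    specificity: float


def youden_cutoff(scores, labels) -> YoudenResult:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct observed
    scores; ties in J break toward higher specificity, then lower cutoff.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    distinct = np.unique(s)
    if distinct.size < 2:
        raise RiskError("scores are constant; no informative cutoff exists")
    mids = (distinct[:-1] + distinct[1:]) / 2
    best: YoudenResult | None = None
    for t in mids:
        called = s > t
        sens = float((called & (y == 1)).sum() / y.sum())
        spec = float((~called & (y == 0)).sum() / (1 - y).sum())
        j = sens + spec - 1
        cand = YoudenResult(float(t), j, sens, spec)
        if (best is None
                or j > best.j + 1e-12
                or (abs(j - best.j) <= 1e-12
                    and (spec > best.specificity + 1e-12
                         or (abs(spec - best.specificity) <= 1e-12
                             and t < best.cutoff)))):
            best = cand
    return best


def logistic_fit(design: pd.DataFrame, labels,
                 add_intercept: bool = True) -> pd.DataFrame:
    """Maximum-likelihood logistic regression with Wald inference.

    Returns per-coefficient estimate, standard error, z, Wald p, odds
    ratio with 95% CI. Complete separation is detected and reported
    rather than silently diverging.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    X = pd.DataFrame(design).astype(float)
    y = _check_binary(labels)
    if len(X) <= X.shape[1] + int(add_intercept):
        raise RiskError("more parameters than observations")
    const = X.nunique() <= 1
    if const.any():
        raise RiskError(f"constant predictor column: {list(X.columns[const])}")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", disp=False,
                                     tol=1e-10, maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise RiskError(f"complete separation: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise RiskError(f"singular design matrix: {exc}") from exc
    fitted = res.predict(X)
    if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)):
        raise RiskError("complete separation: fitted probabilities all 0/1")
    out = pd.DataFrame({
        "estimate": res.params, "std_error": res.bse,
        "z": res.tvalues, "p_value": res.pvalues,
        "odds_ratio": np.exp(res.params),
        "or_ci_low": np.exp(res.params - 1.959963984540054 * res.bse),
        "or_ci_high": np.exp(res.params + 1.959963984540054 * res.bse),
    })
    out.index.name = "term"
    return out


def map_subgroups_to_sites(counts: pd.DataFrame, statuses: pd.Series,
                           endpoints: Sequence[str] = ("brain", "bone"),
                           auc_floor: float = 0.6) -> dict[str, dict]:
    """Assign each metastatic endpoint the subgroup whose count best
    discriminates it (maximal AUC); endpoints whose best AUC falls below
    ``auc_floor`` stay unassigned (the no-association analogue).
    """
    statuses = statuses.loc[counts.index]
    mapping: dict[str, dict] = {}
    for endpoint in endpoints:
        y = (statuses == endpoint).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            raise RiskError(f"endpoint {endpoint!r}: one class absent")
        aucs = {sg: auc(counts[sg], y) for sg in counts.columns}
        best_sg = max(aucs, key=lambda sg: (aucs[sg], sg))
        entry = {"auc_per_subgroup": aucs}
        if aucs[best_sg] >= auc_floor:
            entry["subgroup"] = best_sg
            entry["auc"] = aucs[best_sg]
        else:
            entry["subgroup"] = None
            entry["auc"] = aucs[best_sg]
        mapping[endpoint] = entry
    return mapping


def predict_risk(counts: pd.DataFrame, cutoffs: Mapping[str, float],
                 mapping: Mapping[str, dict | str]) -> pd.DataFrame:
    """Per-patient high-risk flags: count strictly above the cutoff.

    ``mapping`` gives endpoint -> subgroup column (or the dict produced by
    :func:`map_subgroups_to_sites`); ``cutoffs`` gives endpoint -> cutoff.
    """
    flags = {}
    for endpoint, entry in mapping.items():
        sg = entry["subgroup"] if isinstance(entry, dict) else entry
        if sg is None:
            continue
        if sg not in counts.columns:
            raise RiskError(f"subgroup {sg!r} not in counts table")
        flags[f"{endpoint}_high_risk"] = counts[sg] > cutoffs[endpoint]
    return pd.DataFrame(flags, index=counts.index)


@dataclass
class EndpointRisk:
    endpoint: str
    subgroup: str | None
    cutoff: float | None
    j: float | None
    auc: float
    total_count_auc: float
    sensitivity: float | None
    specificity: float | None


def risk_report(counts: pd.DataFrame, statuses: pd.Series,
                endpoints: Sequence[str] = ("brain", "bone"),
                auc_floor: float = 0.6) -> tuple[list[EndpointRisk], pd.DataFrame]:
    """End-to-end risk analysis of a cohort.

    Maps subgroups to endpoints, derives Youden cutoffs, compares against
    the total-CTC-count baseline, and flags high-risk patients. Returns
    (per-endpoint results, per-patient flag table).
    """
    statuses = statuses.loc[counts.index]
    total = counts.sum(axis=1)
    mapping = map_subgroups_to_sites(counts, statuses, endpoints, auc_floor)
    results, cutoffs = [], {}
    for endpoint in endpoints:
        y = (statuses == endpoint).astype(int)
        entry = mapping[endpoint]
        total_auc = auc(total, y)
        if entry["subgroup"] is None:
            results.append(EndpointRisk(endpoint, None, None, None,
                                        entry["auc"], total_auc, None, None))
            continue
        yr = youden_cutoff(counts[entry["subgroup"]], y)
        cutoffs[endpoint] = yr.cutoff
        results.append(EndpointRisk(endpoint, entry["subgroup"], yr.cutoff,
                                    yr.j, entry["auc"], total_auc,
                                    yr.sensitivity, yr.specificity))
    flags = predict_risk(counts, cutoffs, mapping) if cutoffs else \
        pd.DataFrame(index=counts.index)
    return results, flags
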