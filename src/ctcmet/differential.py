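"""Differential-metabolite screening: PLS-DA -> VIP -> volcano cascade.

Two cell populations are compared with partial least squares discriminant
analysis (PLS-DA, NIPALS extraction with deflation). Variable importance
in projection (VIP >= 1) defines an initial candidate set, which is then
filtered by a volcano criterion: fold change >= 1.5 in either direction
and a Mann-Whitney U p-value <= 0.05. Permutation tests guard against
over-fitted discriminant models.

Model statistics follow chemometrics conventions: R2X/R2Y are cumulative
explained sums of squares of X and y, Q2 is the cross-validated
predictive ability 1 - PRESS/TSS with interleaved (venetian-blind) folds
stratified by class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import IntensityMatrix

__all__ = [
    "PLSModel", "PermutationReport", "fit_plsda", "vip_scores",
    "permutation_test", "mann_whitney_u", "fold_changes", "volcano_screen",
    "screen_differential",
]


class DifferentialError(ValueError):
    pass


@dataclass
class PLSModel:
    """A fitted PLS-DA model (single binary response)."""

    n_components: int
    weights: np.ndarray        # J x A, unit-norm per component
    x_loadings: np.ndarray     # J x A
    y_loadings: np.ndarray     # A
    scores: np.ndarray         # n x A
    ssy_per_component: np.ndarray   # y sum of squares explained per component
    r2x: float                 # cumulative
    r2y: float                 # cumulative
    q2: float                  # cumulative, cross-validated
    cv_scheme: str
    feature_names: list[str]
    classes: tuple
    x_mean: np.ndarray
    y_mean: float


def _as_arrays(X, y):
    if isinstance(X, IntensityMatrix):
        names = X.metabolite_ids
        X = X.data.to_numpy(float)
    elif isinstance(X, pd.DataFrame):
        names, X = list(X.columns), X.to_numpy(float)
    else:
        X = np.asarray(X, float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y)
    return X, y, names


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise DifferentialError(f"need exactly two classes, got {classes}")
    return np.asarray([1.0 if v == classes[1] else 0.0 for v in y]), classes


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Sequential NIPALS extraction with X and y deflation.

    Returns (W, P, q, T, ssy) where ssy[a] is the y sum of squares
    explained by component a. For a single response the weight vector has
    the closed form w = X'y / ||X'y||.
    """
    n, J = Xc.shape
    W = np.zeros((J, n_components))
    P = np.zeros((J, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    Xr, yr = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # no covariance left; truncate
            W, P, T, q, ssy = W[:, :a], P[:, :a], T[:, :a], q[:a], ssy[:a]
            break
        w /= norm
        t = Xr @ w
        tt = t @ t
        if tt < 1e-14:
            W, P, T, q, ssy = W[:, :a], P[:, :a], T[:, :a], q[:a], ssy[:a]
            break
        p = Xr.T @ t / tt
        qa = yr @ t / tt
        Xr = Xr - np.outer(t, p)
        yr = yr - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        ssy[a] = qa * qa * tt
    return W, P, q, T, ssy, Xr, yr


def _venetian_folds(y01: np.ndarray, n_folds: int) -> np.ndarray:
    """Interleaved fold assignment, stratified by class."""
    folds = np.empty(y01.size, int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y01 == cls)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def _predict(Xc, W, P, q):
    """Predicted (centered) response for already-centered X."""
    # regression coefficients b = W (P'W)^-1 q
    A = W.shape[1]
    if A == 0:
        return np.zeros(Xc.shape[0])
    b = W @ np.linalg.solve(P.T @ W, q)
    return Xc @ b


def fit_plsda(X, y, n_components: int = 2, cv_folds: int = 7) -> PLSModel:
    """Fit a two-class PLS-DA model and cross-validate Q2.

    ``X`` should be autoscaled (zero-mean, unit-variance columns); ``y``
    holds two class labels. Q2 uses interleaved ``cv_folds``-fold CV
    stratified by class; each training split is re-centred before fitting.
    """
    X, y, names = _as_arrays(X, y)
    if np.isnan(X).any():
        raise DifferentialError("X contains missing values; impute first")
    y01, classes = _encode_labels(y)
    counts = [int((y01 == c).sum()) for c in (0.0, 1.0)]
    if min(counts) < cv_folds:
        raise DifferentialError(
            f"each class needs >= cv_folds={cv_folds} members, got {counts}")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = names[int(np.argmax(sd == 0))]
        raise DifferentialError(f"zero-variance feature: {bad}")
    if np.all(y01 == y01[0]):
        raise DifferentialError("constant response")

    x_mean = X.mean(axis=0)
    y_mean = float(y01.mean())
    Xc, yc = X - x_mean, y01 - y_mean
    ss_x, ss_y = float((Xc ** 2).sum()), float((yc ** 2).sum())

    W, P, q, T, ssy, Xr, yr = _nipals(Xc, yc, n_components)
    r2x = 1.0 - float((Xr ** 2).sum()) / ss_x
    r2y = 1.0 - float((yr ** 2).sum()) / ss_y

    folds = _venetian_folds(y01, cv_folds)
    press = 0.0
    for f in range(cv_folds):
        train, test = folds != f, folds == f
        xm, ym = X[train].mean(axis=0), y01[train].mean()
        Wf, Pf, qf, *_ = _nipals(X[train] - xm, y01[train] - ym, n_components)
        yhat = _predict(X[test] - xm, Wf, Pf, qf) + ym
        press += float(((y01[test] - yhat) ** 2).sum())
    q2 = 1.0 - press / ss_y

    return PLSModel(
        n_components=W.shape[1], weights=W, x_loadings=P, y_loadings=q,
        scores=T, ssy_per_component=ssy, r2x=r2x, r2y=r2y, q2=q2,
        cv_scheme=f"venetian-blind {cv_folds}-fold, class-stratified",
        feature_names=names, classes=classes, x_mean=x_mean, y_mean=y_mean)


def vip_scores(model: PLSModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( J * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a );
    the mean of squared VIPs is exactly 1.
    """
    ssy = model.ssy_per_component
    total = ssy.sum()
    if total <= 0:
        raise DifferentialError("model explains no y variance (zero total SSY)")
    W = model.weights
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    J = W.shape[0]
    vip = np.sqrt(J * ((W ** 2) / wnorm2 * ssy).sum(axis=1) / total)
    return pd.Series(vip, index=model.feature_names, name="vip")


@dataclass
class PermutationReport:
    n_permutations: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_r2y: float
    p_q2: float


def permutation_test(X, y, n_components: int = 2, cv_folds: int = 7,
                     n_permutations: int = 200, seed: int = 0) -> PermutationReport:
    """Label-permutation null for R2Y and Q2.

    Labels are permuted uniformly and the model refit with identical
    settings; empirical p = (1 + #{permuted >= observed}) / (n + 1).
    """
    if n_permutations < 20:
        import warnings
        warnings.warn("fewer than 20 permutations: p-value resolution "
                      f"limited to {1 / (n_permutations + 1):.3f}", stacklevel=2)
    X, y, _ = _as_arrays(X, y)
    observed = fit_plsda(X, y, n_components, cv_folds)
    rng = np.random.default_rng(seed)
    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(y)
        while len(pd.unique(yp)) < 2:  # pragma: no cover - degenerate guard
            yp = rng.permutation(y)
        m = fit_plsda(X, yp, n_components, cv_folds)
        perm_r2y[i], perm_q2[i] = m.r2y, m.q2
    p_r2y = (1 + int((perm_r2y >= observed.r2y).sum())) / (n_permutations + 1)
    p_q2 = (1 + int((perm_q2 >= observed.q2).sum())) / (n_permutations + 1)
    return PermutationReport(n_permutations, observed.r2y, observed.q2,
                             perm_r2y, perm_q2, p_r2y, p_q2)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the U distribution when both samples have
    <= 8 observations and no ties occur; otherwise the normal
    approximation with tie and continuity corrections. U is reported for
    the first sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise DifferentialError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fold_changes(matrix, group_labels, group_a=None, group_b=None) -> pd.DataFrame:
    """Per-metabolite fold change between two groups.

    FC = mean linear-scale intensity in group A / mean in group B
    (imputation must precede: missing entries are not allowed in the
    denominator's support). Direction is "up" when FC > 1.
    """
    if isinstance(matrix, IntensityMatrix):
        if matrix.state not in ("raw", "is_normalized"):
            raise DifferentialError(
                "fold changes are computed on linear-scale intensities")
        data = matrix.data
    else:
        data = pd.DataFrame(matrix)
    labels = pd.Series(list(group_labels), index=data.index)
    groups = list(pd.unique(labels))
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise DifferentialError(f"specify group_a/group_b among {groups}")
        group_a, group_b = groups
    mean_a = data[labels == group_a].mean(axis=0)
    mean_b = data[labels == group_b].mean(axis=0)
    if (mean_b == 0).any() or mean_b.isna().any():
        raise DifferentialError("zero or undefined denominator mean; impute first")
    fc = mean_a / mean_b
    return pd.DataFrame({
        "fc": fc,
        "log2fc": np.log2(fc),
        "direction": np.where(fc > 1, "up", "down"),
    })


def volcano_screen(vip: pd.Series, fc_table: pd.DataFrame, p_values: pd.Series,
                   vip_threshold: float = 1.0, fc_threshold: float = 1.5,
                   p_threshold: float = 0.05,
                   correction: str = "none") -> pd.DataFrame:
    """Combine VIP, fold-change and significance filters into one table.

    A metabolite survives when VIP >= vip_threshold, FC >= fc_threshold
    or <= 1/fc_threshold, and p <= p_threshold. ``correction="bh"``
    applies Benjamini-Hochberg and gates on the adjusted p instead (off
    by default: the screen's convention is raw per-comparison p-values).
    """
    idx = vip.index
    if not (idx.equals(fc_table.index) and idx.equals(p_values.index)):
        raise DifferentialError("metabolite sets of vip/fc/p inputs differ")
    table = pd.DataFrame({
        "vip": vip, "fc": fc_table["fc"], "log2fc": fc_table["log2fc"],
        "p_value": p_values, "direction": fc_table["direction"],
    })
    table["neg_log10_p"] = -np.log10(table["p_value"].clip(lower=1e-300))
    gate_p = table["p_value"]
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        gate_p = table["p_adjusted"]
    elif correction != "none":
        raise DifferentialError(f"unknown correction {correction!r}")
    table["passes_vip"] = table["vip"] >= vip_threshold
    fc_crit = (table["fc"] >= fc_threshold) | (table["fc"] <= 1 / fc_threshold)
    table["passes_volcano"] = table["passes_vip"] & fc_crit & (gate_p <= p_threshold)
    return table


def screen_differential(matrix: IntensityMatrix, group_labels,
                        group_a=None, group_b=None, n_components: int = 2,
                        cv_folds: int = 7, vip_threshold: float = 1.0,
                        fc_threshold: float = 1.5, p_threshold: float = 0.05,
                        correction: str = "none") -> tuple[pd.DataFrame, PLSModel]:
    """Run the full screen on an IS-normalized matrix.

    Imputes (half-minimum) and autoscales for PLS-DA/VIP; fold changes
    and Mann-Whitney tests run on the imputed linear-scale intensities.
    Returns (DifferentialTable, fitted PLSModel).
    """
    from .preprocess import impute_and_scale
    labels = pd.Series(list(group_labels), index=matrix.data.index)
    groups = list(pd.unique(labels))
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise DifferentialError(f"specify group_a/group_b among {groups}")
        group_a, group_b = groups
    keep = labels.isin([group_a, group_b])
    sub = IntensityMatrix(matrix.data.loc[keep].copy(), matrix.state)
    labels = labels.loc[keep]

    imputed = impute_and_scale(sub, scale="none")
    scaled = impute_and_scale(sub, scale="autoscale")
    model = fit_plsda(scaled, labels.to_numpy(), n_components, cv_folds)
    vip = vip_scores(model)
    fc = fold_changes(imputed, labels, group_a, group_b)
    pvals = pd.Series({
        m: mann_whitney_u(imputed.data.loc[labels == group_a, m],
                          imputed.data.loc[labels == group_b, m])[1]
        for m in imputed.metabolite_ids}, name="p_value")
    table = volcano_screen(vip, fc, pvals, vip_threshold, fc_threshold,
                           p_threshold, correction)
    return table, model
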