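"""CTC subgroup discovery: embedding, silhouette-guided cluster number,
hierarchical partitioning, and cross-embedding concordance.

Cells are embedded in 2-D (t-SNE by default, UMAP as the cross-check),
candidate cluster numbers are scored by mean silhouette width of
hierarchical partitions of the embedding, and the winning k defines the
subgroups. Subgroup labels are ordered by descending size (subgroup 1 is
always the largest), so a label index never implies a clinical meaning —
mapping to metastatic sites happens downstream by association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .preprocess import IntensityMatrix


class SubgroupError(ValueError):
    pass


@dataclass
class Embedding:
    coords: pd.DataFrame          # cells x 2, centered
    method: str                   # "tsne" | "umap" | "passthrough"
    hyperparameters: dict
    seed: int


@dataclass
class ClusteringReport:
    k_candidates: list[int]
    mean_silhouettes: dict[int, float]
    selected_k: int
    silhouette_values: pd.Series  # per cell, at selected k
    linkage: str
    distance: str
    singleton_ks: list[int] = field(default_factory=list)


@dataclass
class SubgroupAssignment:
    labels: pd.Series             # per cell, int in 1..k, sizes non-increasing
    k: int

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _coords_matrix(matrix) -> tuple[np.ndarray, pd.Index]:
    if isinstance(matrix, IntensityMatrix):
        if matrix.data.isna().any().any():
            raise SubgroupError("matrix contains missing values; impute first")
        return matrix.data.to_numpy(float), matrix.data.index
    df = pd.DataFrame(matrix)
    return df.to_numpy(float), df.index


def embed_cells(matrix, method: str = "tsne", seed: int = 42,
                perplexity: float = 10.0, n_neighbors: int = 15,
                min_dist: float = 0.1,
                pca_components: int | None = 30) -> Embedding:
    """2-D embedding of an autoscaled cells x metabolites matrix.

    The matrix is first reduced to ``pca_components`` principal
    components (the usual denoising step before t-SNE/UMAP on wide
    matrices; ``None`` embeds the full matrix). Deterministic for a fixed
    seed (t-SNE uses PCA initialisation; UMAP pins its random state).
    Coordinates are centred.
    """
    X, index = _coords_matrix(matrix)
    n = X.shape[0]
    if method in ("tsne", "umap") and pca_components is not None \
            and 0 < pca_components < min(X.shape):
        from sklearn.decomposition import PCA
        X = PCA(n_components=pca_components, random_state=seed).fit_transform(X)
    if method == "tsne":
        if n < 3 * perplexity + 1:
            raise SubgroupError(
                f"t-SNE needs >= 3*perplexity + 1 = {int(3 * perplexity + 1)} "
                f"cells, got {n}")
        coords = TSNE(n_components=2, perplexity=perplexity, init="pca",
                      random_state=seed).fit_transform(X)
        params = {"perplexity": perplexity}
    elif method == "umap":
        if n <= n_neighbors:
            raise SubgroupError(
                f"UMAP needs more cells than n_neighbors={n_neighbors}, got {n}")
        import umap  # deferred: heavy import
        coords = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                           min_dist=min_dist,
                           random_state=seed).fit_transform(X)
        params = {"n_neighbors": n_neighbors, "min_dist": min_dist}
    elif method == "passthrough":
        if X.shape[1] != 2:
            raise SubgroupError("passthrough embedding needs 2 columns")
        coords, params = X.copy(), {}
    else:
        raise SubgroupError(f"unknown embedding method {method!r}")
    coords = np.asarray(coords, float)
    coords = coords - coords.mean(axis=0)
    if not np.isfinite(coords).all():
        raise SubgroupError("embedding produced non-finite coordinates")
    return Embedding(pd.DataFrame(coords, index=index, columns=["dim1", "dim2"]),
                     method, params, seed)


def _linkage_matrix(coords: np.ndarray, linkage: str, distance: str) -> np.ndarray:
    if linkage == "ward" and distance != "euclidean":
        raise SubgroupError("Ward linkage requires Euclidean distance")
    return hierarchy.linkage(pdist(coords, metric=distance), method=linkage)


def _cut(Z: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def silhouette_select_k(embedding: Embedding, k_range: Iterable[int] = range(2, 9),
                        linkage: str = "ward",
                        distance: str = "euclidean") -> ClusteringReport:
    """Score hierarchical partitions of the embedding by mean silhouette.

    The selected k maximises the mean silhouette width; ties break toward
    the smallest k (parsimony). A singleton cluster contributes s(i) = 0.
    """
    coords = embedding.coords.to_numpy(float)
    n = coords.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise SubgroupError(f"k_range must lie within [2, {n - 1}]")
    Z = _linkage_matrix(coords, linkage, distance)
    means: dict[int, float] = {}
    best_values: pd.Series | None = None
    singleton_ks = []
    selected = None
    for k in k_range:
        labels = _cut(Z, k)
        if np.unique(labels).size < 2:
            means[k] = float("nan")
            continue
        vals = silhouette_samples(coords, labels, metric=distance)
        sizes = np.bincount(labels)
        if (sizes[1:] == 1).any():
            singleton_ks.append(k)
            vals = vals.copy()
            for cl in np.flatnonzero(sizes == 1):
                vals[labels == cl] = 0.0
        means[k] = float(vals.mean())
        if selected is None or means[k] > means[selected]:
            selected = k
            best_values = pd.Series(vals, index=embedding.coords.index,
                                    name="silhouette")
    if selected is None:
        raise SubgroupError("no candidate k produced a valid partition")
    return ClusteringReport(k_range, means, selected, best_values,
                            linkage, distance, singleton_ks)


def cluster_cells(embedding: Embedding, k: int, linkage: str = "ward",
                  distance: str = "euclidean") -> SubgroupAssignment:
    """Agglomerative partition of the embedding into k subgroups,
    relabelled by descending size (ties by first occurrence)."""
    coords = embedding.coords.to_numpy(float)
    n = coords.shape[0]
    if k > n:
        raise SubgroupError(f"k={k} exceeds the number of cells ({n})")
    if k == 1:
        raw = np.ones(n, int)
    else:
        raw = _cut(_linkage_matrix(coords, linkage, distance), k)
    # relabel by descending size; tie-break on first occurrence for determinism
    sizes = pd.Series(raw).value_counts()
    first_seen = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([mapping[v] for v in raw],
                       index=embedding.coords.index, name="subgroup")
    return SubgroupAssignment(labels, k=len(order))


def cross_check_embeddings(matrix, k: int, methods: Sequence[str] = ("tsne", "umap"),
                           seeds: Sequence[int] = (42,), linkage: str = "ward",
                           distance: str = "euclidean") -> dict:
    """Concordance of subgroup assignments across embedding methods/seeds.

    Returns the pairwise adjusted Rand index matrix plus the headline
    minimum ARI between the first two methods.
    """
    runs: dict[str, pd.Series] = {}
    for method in methods:
        for seed in seeds:
            emb = embed_cells(matrix, method=method, seed=seed)
            runs[f"{method}:{seed}"] = cluster_cells(emb, k, linkage,
                                                     distance).labels
    names = list(runs)
    ari = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                val = adjusted_rand_score(runs[a], runs[b])
                ari.loc[a, b] = ari.loc[b, a] = val
    headline = None
    if len(methods) >= 2:
        pairs = [ari.loc[a, b] for a in names for b in names
                 if a.split(":")[0] == methods[0] and b.split(":")[0] == methods[1]]
        headline = float(min(pairs)) if pairs else None
    return {"ari_matrix": ari, "min_cross_method_ari": headline,
            "assignments": runs}


def count_subgroups_per_patient(assignment: SubgroupAssignment,
                                cell_to_patient: pd.Series) -> pd.DataFrame:
    """Per-patient integer count of cells in each subgroup.

    Row sums equal each patient's total CTC count.
    """
    unmapped = assignment.labels.index.difference(cell_to_patient.index)
    if len(unmapped):
        raise SubgroupError(f"cells not mapped to a patient: {list(unmapped[:5])}")
    df = pd.DataFrame({
        "patient_id": cell_to_patient.loc[assignment.labels.index],
        "subgroup": assignment.labels,
    })
    counts = (df.groupby(["patient_id", "subgroup"]).size()
                .unstack(fill_value=0)
                .reindex(columns=range(1, assignment.k + 1), fill_value=0))
    counts.columns = [f"CTC{c}" for c in counts.columns]
    return counts
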