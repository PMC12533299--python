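"""Pathway over-representation of screened metabolites.

Classic hypergeometric enrichment: given n selected metabolites out of a
background of N, a pathway with K members showing k selected members has
upper-tail p = P(X >= k), X ~ Hypergeom(N, K, n). Benjamini-Hochberg
adjustment across pathways by default. The pathway map is user-supplied
(e.g. KEGG-derived) as a TSV; no external service is queried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayMap:
    """pathway_id -> (name, member metabolite ids)."""

    members: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, m in self.members.items() if not m]
        if empty:
            raise EnrichmentError(f"empty pathways not allowed: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_panel(cls, panel) -> "PathwayMap":
        """Build from a ReferencePanel's pathway annotations."""
        members = {p: frozenset(m) for p, m in panel.pathway_map().items()}
        names = panel.table.attrs.get("pathway_names", {})
        return cls(members, {p: names.get(p, p) for p in members})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("pathway_id", "name", "members"):
            if col not in df.columns:
                raise EnrichmentError(f"{path}: missing column {col!r}")
        members = {r.pathway_id: frozenset(str(r.members).split(";"))
                   for r in df.itertuples()}
        return cls(members, dict(zip(df["pathway_id"], df["name"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "pathway_id": list(self.members),
            "name": [self.names.get(p, p) for p in self.members],
            "members": [";".join(sorted(m)) for m in self.members.values()],
        }).to_csv(path, sep="\t", index=False)


def enrich_pathways(selected: Iterable[str], background: Iterable[str],
                    pathway_map: PathwayMap,
                    correction: str = "bh") -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway.

    Returns one row per pathway with k (selected members), K (pathway size
    within background), n (selected), N (background), raw p and adjusted p,
    sorted by raw p.
    """
    selected = set(selected)
    background = set(background)
    offenders = selected - background
    if offenders:
        raise EnrichmentError(
            f"selected metabolites not in background: {sorted(offenders)[:5]}")
    N, n = len(background), len(selected)
    rows = []
    for pid, members in pathway_map.members.items():
        in_bg = members & background
        if not in_bg:
            continue
        K = len(in_bg)
        k = len(members & selected)
        # upper tail: P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"pathway_id": pid,
                     "name": pathway_map.names.get(pid, pid),
                     "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    if correction == "bh":
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
    elif correction == "none":
        result["p_adjusted"] = result["p_value"]
    else:
        raise EnrichmentError(f"unknown correction {correction!r}")
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)
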