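"""Lytic-lysogenic index (LLI) formulations and their group statistics.

The LLI compares virulent (obligately lytic) to temperate phage abundance.
Three formulations are used at different scopes:

* community: the plain ratio of total virulent to total temperate relative
  abundance per sample (optionally pseudocounted);
* per vOTU: ``|log2((v + 0.1)/(t + 0.1))|`` with the 0.1 pseudocount fixed,
  and a temporal change statistic ``log10(LLI_day10/LLI_day0 + 1)`` whose
  no-change baseline is log10(2), not 0 — kept verbatim, with a plain
  log10-ratio alternative behind a flag;
* per host genus: the median over that genus' phages of ``(v + 1)/(t + 1)``,
  with the day-10 vs day-0 shift reported as a signed log10 fold change
  (positive = shift toward lytic dominance).

Group comparisons use Kruskal-Wallis with tie correction, Dunn's pairwise
z tests, Benjamini-Hochberg adjustment within the pairwise family, and a
compact-letter display at adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import kruskal, norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "lli_community",
    "lli_votu",
    "lli_votu_change",
    "lli_host_genus",
    "lli_shift",
    "GroupComparison",
    "compare_groups",
    "dunn_test",
]

logger = logging.getLogger(__name__)

VOTU_PSEUDOCOUNT = 0.1  # fixed by the per-vOTU LLI definition
HOST_GENUS_PSEUDOCOUNT = 1.0


def lli_community(virulent_total: float, temperate_total: float, pseudocount: float = 0.0) -> float:
    """Ratio of virulent to temperate relative abundance (community scope)."""
    if virulent_total < 0 or temperate_total < 0:
        raise ValueError("abundance totals must be nonnegative")
    denom = temperate_total + pseudocount
    if denom == 0:
        raise ZeroDivisionError("temperate total is zero and no pseudocount was given")
    return (virulent_total + pseudocount) / denom


def lli_votu(v: float, t: float) -> float:
    """Per-vOTU LLI: |log2((v + 0.1) / (t + 0.1))|."""
    if v < 0 or t < 0:
        raise ValueError("abundances must be nonnegative")
    return abs(math.log2((v + VOTU_PSEUDOCOUNT) / (t + VOTU_PSEUDOCOUNT)))


def lli_votu_change(lli_d0: float, lli_d10: float, convention: str = "verbatim") -> float | None:
    """Temporal change of a vOTU's LLI between day 0 and day 10.

    ``verbatim``: log10(LLI_d10 / LLI_d0 + 1); equal nonzero values map to
    log10(2), not 0. ``log_ratio``: log10(LLI_d10 / LLI_d0), a conventional
    fold change with baseline 0 (requires lli_d10 > 0).

    A zero day-0 LLI makes the ratio undefined; the record is skipped
    (returns None) with a warning.
    """
    if lli_d0 < 0 or lli_d10 < 0:
        raise ValueError("LLI values must be nonnegative")
    if lli_d0 == 0:
        logger.warning("lli_votu_change skipped: day-0 LLI is zero")
        return None
    if convention == "verbatim":
        return math.log10(lli_d10 / lli_d0 + 1.0)
    if convention == "log_ratio":
        if lli_d10 == 0:
            logger.warning("lli_votu_change (log_ratio) skipped: day-10 LLI is zero")
            return None
        return math.log10(lli_d10 / lli_d0)
    raise ValueError(f"unknown convention {convention!r}")


def lli_host_genus(phage_pairs: Sequence[tuple[float, float]]) -> float:
    """Median over a host genus' phages of (v + 1) / (t + 1)."""
    if len(phage_pairs) == 0:
        raise ValueError("lli_host_genus needs at least one phage")
    ratios = [
        (v + HOST_GENUS_PSEUDOCOUNT) / (t + HOST_GENUS_PSEUDOCOUNT) for v, t in phage_pairs
    ]
    return float(np.median(ratios))


def lli_shift(genus_lli_d0: float, genus_lli_d10: float) -> float:
    """Signed log10 fold change of the per-genus LLI (day 10 vs day 0).

    Positive values indicate a shift toward lytic dominance, negative toward
    lysogenic dominance.
    """
    if genus_lli_d0 <= 0 or genus_lli_d10 <= 0:
        raise ValueError("lli_shift requires positive LLI values")
    return math.log10(genus_lli_d10 / genus_lli_d0)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + BH + compact letters
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    key: str
    group_medians: dict[str, float]
    group_n: dict[str, int]
    kruskal_p: float
    kruskal_stat: float
    pairwise: "list[dict]"  # group_a, group_b, z, p_raw, p_adj
    letters: dict[str, str]

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [(r["group_a"], r["group_b"]) for r in self.pairwise if r["p_adj"] < alpha]


def dunn_test(values_by_group: Mapping[str, Sequence[float]]) -> list[dict]:
    """Dunn's pairwise z tests on pooled ranks, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups. Two-sided raw p values;
    no multiplicity adjustment is applied here.
    """
    groups = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in groups])
    n_total = len(pooled)
    ranks = rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in groups:
        n_g = len(values_by_group[g])
        mean_ranks[g] = float(ranks[start : start + n_g].mean())
        sizes[g] = n_g
        start += n_g
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in combinations(groups, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * float(norm.sf(abs(z)))
        out.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    return out


def _compact_letters(groups: Sequence[str], sig_pairs: set[frozenset[str]], order_stat: Mapping[str, float]) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    for a, b in combinations(groups, 2):
        if frozenset((a, b)) not in sig_pairs:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    # deterministic letter assignment: order cliques by the best (highest) member statistic
    cliques.sort(key=lambda c: (-max(order_stat[m] for m in c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        for member in clique:
            letters[member].append(alphabet[i % len(alphabet)])
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    key: str = "",
    min_n: int = 5,
    alpha: float = 0.05,
) -> GroupComparison | None:
    """Kruskal-Wallis across groups, Dunn post-hoc, BH-adjusted, lettered.

    Returns None (with a logged reason) when fewer than two groups meet the
    ``min_n`` sample-size rule.
    """
    eligible = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items() if len(v) >= min_n}
    if len(eligible) < 2:
        logger.warning("compare_groups(%s) excluded: fewer than 2 groups with n >= %d", key, min_n)
        return None
    groups = list(eligible)
    arrays = [eligible[g] for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        kw_stat, kw_p = 0.0, 1.0  # all observations identical: no evidence of any difference
    else:
        kw_stat, kw_p = kruskal(*arrays)
    pairwise = dunn_test(eligible)
    p_adj = multipletests([r["p_raw"] for r in pairwise], method="fdr_bh")[1]
    for r, pa in zip(pairwise, p_adj):
        r["p_adj"] = float(pa)
    sig = {frozenset((r["group_a"], r["group_b"])) for r in pairwise if r["p_adj"] < alpha}
    medians = {g: float(np.median(eligible[g])) for g in groups}
    letters = _compact_letters(groups, sig, medians)
    return GroupComparison(
        key=key,
        group_medians=medians,
        group_n={g: len(eligible[g]) for g in groups},
        kruskal_p=float(kw_p),
        kruskal_stat=float(kw_stat),
        pairwise=pairwise,
        letters=letters,
    )
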