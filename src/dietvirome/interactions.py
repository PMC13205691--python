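"""Phage-bacterium correlation statistics and trend/concordance scoring.

Pairwise abundance association is measured by Spearman's rho with
Benjamini-Hochberg adjustment within each group stratum. Interaction-strength
change between control and intervention is classified by comparing median
|rho| sets with a Wilcoxon rank-sum gate. Per-project abundance-direction
votes summarize a phage's overall trend, and concordance scores how often a
phage and its host move in the same direction across projects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from ._stats import wilcoxon_rank_sum
from .data_io import AbundanceMatrix

__all__ = [
    "spearman",
    "bh_adjust",
    "PairCorrelation",
    "correlate_pairs",
    "InteractionChange",
    "classify_change",
    "TrendVote",
    "vote_trend",
    "ConcordanceScore",
    "concordance",
    "project_direction",
    "screen_differential",
]

logger = logging.getLogger(__name__)

EXACT_PERMUTATION_MAX_N = 9


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with average ranks; two-sided p value.

    The p value is an exact permutation p for n <= 9 and the t approximation
    otherwise. Constant vectors leave rho undefined and raise ValueError (the
    caller skips the pair with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("Spearman correlation requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant vectors")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(spearmanr(x, y).pvalue)
    return rho, p


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p: enumerate all orderings of the y ranks."""
    n = len(rx)
    rx_c = rx - rx.mean()
    sx = math.sqrt(float((rx_c**2).sum()))
    ry_c = ry - ry.mean()
    sy = math.sqrt(float((ry_c**2).sum()))
    count = 0
    total = 0
    threshold = abs(rho_obs) - 1e-12
    for perm in permutations(ry_c):
        r = float(np.dot(rx_c, perm)) / (sx * sy)
        if abs(r) >= threshold:
            count += 1
        total += 1
    return count / total


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairCorrelation:
    phage_id: str
    bacterium_id: str
    stratum: str
    n: int
    rho: float
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False


def correlate_pairs(
    phage_m: AbundanceMatrix,
    bact_m: AbundanceMatrix,
    pairs: Sequence[tuple[str, str]],
    strata: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    bh_scope: str = "stratum",
) -> list[PairCorrelation]:
    """Spearman correlation per phage-bacterium pair within each stratum.

    ``strata`` maps a stratum label (e.g. diet group) to its sample ids; BH
    adjustment is applied within each stratum's family by default
    (``bh_scope="global"`` pools all strata into one family). Strata with
    fewer than 4 samples and constant-vector pairs are skipped with warnings.
    """
    if bh_scope not in ("stratum", "global"):
        raise ValueError("bh_scope must be 'stratum' or 'global'")
    records: list[PairCorrelation] = []
    for stratum, sample_ids in strata.items():
        sample_ids = [s for s in sample_ids if s in phage_m.data.columns and s in bact_m.data.columns]
        if len(sample_ids) < 4:
            logger.warning("stratum %s skipped: fewer than 4 shared samples", stratum)
            continue
        pv = phage_m.data.loc[:, sample_ids]
        bv = bact_m.data.loc[:, sample_ids]
        stratum_records: list[PairCorrelation] = []
        for phage_id, bact_id in pairs:
            if phage_id not in pv.index or bact_id not in bv.index:
                continue
            try:
                rho, p = spearman(pv.loc[phage_id].to_numpy(), bv.loc[bact_id].to_numpy())
            except ValueError as exc:
                logger.warning("pair (%s, %s) in %s skipped: %s", phage_id, bact_id, stratum, exc)
                continue
            stratum_records.append(
                PairCorrelation(phage_id, bact_id, stratum, len(sample_ids), rho, p)
            )
        if bh_scope == "stratum" and stratum_records:
            adj = bh_adjust([r.p_raw for r in stratum_records])
            for r, pa in zip(stratum_records, adj):
                r.p_adj = float(pa)
                r.significant = r.p_adj < alpha
        records.extend(stratum_records)
    if bh_scope == "global" and records:
        adj = bh_adjust([r.p_raw for r in records])
        for r, pa in zip(records, adj):
            r.p_adj = float(pa)
            r.significant = r.p_adj < alpha
    return records


@dataclass
class InteractionChange:
    stratum: str
    median_abs_rho_control: float
    median_abs_rho_intervention: float
    p: float
    direction: str  # Increased | Decreased | non-significant


def classify_change(
    control_abs_rho: Sequence[float],
    intervention_abs_rho: Sequence[float],
    stratum: str = "",
    alpha: float = 0.05,
) -> InteractionChange:
    """Classify interaction-strength change between control and intervention.

    Wilcoxon rank-sum on the |rho| sets; "Increased" when the intervention
    median exceeds the control median with p < alpha, "Decreased" for the
    mirror case, "non-significant" otherwise (including equal medians even
    when p < alpha).
    """
    ctrl = np.abs(np.asarray(control_abs_rho, dtype=float))
    intv = np.abs(np.asarray(intervention_abs_rho, dtype=float))
    if len(ctrl) == 0 or len(intv) == 0:
        raise ValueError("both |rho| sets must be nonempty")
    med_c = float(np.median(ctrl))
    med_i = float(np.median(intv))
    if np.array_equal(np.sort(ctrl), np.sort(intv)):
        p = 1.0
    else:
        _, p = wilcoxon_rank_sum(intv, ctrl)
    if p < alpha and med_i > med_c:
        direction = "Increased"
    elif p < alpha and med_i < med_c:
        direction = "Decreased"
    else:
        direction = "non-significant"
    return InteractionChange(stratum, med_c, med_i, float(p), direction)


@dataclass
class TrendVote:
    phage_id: str
    n_increase: int
    n_decrease: int
    trend: str  # increasing | decreasing | indeterminate


def vote_trend(per_project_directions: Sequence[int], phage_id: str = "") -> TrendVote:
    """Majority vote over per-project direction signs (+1 / -1).

    Ties and empty vote lists yield "indeterminate".
    """
    for d in per_project_directions:
        if d not in (1, -1):
            raise ValueError(f"directions must be +1 or -1, got {d}")
    n_inc = sum(1 for d in per_project_directions if d == 1)
    n_dec = sum(1 for d in per_project_directions if d == -1)
    if n_inc > n_dec:
        trend = "increasing"
    elif n_dec > n_inc:
        trend = "decreasing"
    else:
        trend = "indeterminate"
    return TrendVote(phage_id, n_inc, n_dec, trend)


@dataclass
class ConcordanceScore:
    phage_id: str
    n_concordant: int
    n_discordant: int
    proportion_concordant: float | None  # None when no shared projects


def concordance(
    phage_direction_by_project: Mapping[str, int],
    host_direction_by_project: Mapping[str, int],
    phage_id: str = "",
) -> ConcordanceScore:
    """Count same-direction vs opposite-direction changes over shared projects."""
    shared = sorted(set(phage_direction_by_project) & set(host_direction_by_project))
    if not shared:
        logger.warning("concordance(%s): no shared projects, score undefined", phage_id)
        return ConcordanceScore(phage_id, 0, 0, None)
    n_con = sum(1 for p in shared if phage_direction_by_project[p] == host_direction_by_project[p])
    n_dis = len(shared) - n_con
    return ConcordanceScore(phage_id, n_con, n_dis, n_con / (n_con + n_dis))


def project_direction(control_values: Sequence[float], intervention_values: Sequence[float]) -> int | None:
    """Per-project direction of a taxon: sign of (median intervention - median control).

    Zero difference returns None (the project is excluded from voting).
    """
    diff = float(np.median(intervention_values)) - float(np.median(control_values))
    if diff > 0:
        return 1
    if diff < 0:
        return -1
    return None


def screen_differential(
    m: AbundanceMatrix,
    group_by_sample: Mapping[str, str],
    alpha: float = 0.05,
    effect_threshold: float = 0.5,
    pseudocount: float = 1e-6,
    supplied: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Surrogate differential-abundance screen for diet-associated taxa.

    Selects taxa with Kruskal-Wallis p < alpha across groups AND a maximum
    absolute log10 between-group mean difference (on pseudocounted means)
    above ``effect_threshold``. This is a transparent rank-test screen, not a
    replication of LDA-based methods; outputs are labeled "surrogate_screen"
    so externally supplied differential-taxon calls can be distinguished.
    A ``supplied`` table of external calls (column ``taxon_id``) bypasses the
    screen verbatim, labeled "provided".
    """
    if supplied is not None:
        out = supplied.copy()
        out["source"] = "provided"
        return out
    groups = sorted(set(group_by_sample.values()))
    if len(groups) < 2:
        raise ValueError("screen_differential needs at least 2 groups")
    cols_by_group = {
        g: [s for s in m.sample_ids if group_by_sample.get(s) == g] for g in groups
    }
    rows = []
    for taxon in m.taxon_ids:
        series = m.data.loc[taxon]
        per_group = [series[cols_by_group[g]].to_numpy(dtype=float) for g in groups]
        pooled = np.concatenate(per_group)
        if np.all(pooled == pooled[0]):
            continue  # identical distributions carry no signal
        _, p = kruskal(*per_group)
        log_means = [math.log10(float(v.mean()) + pseudocount) for v in per_group]
        effect = max(log_means) - min(log_means)
        if p < alpha and effect > effect_threshold:
            rows.append(
                {
                    "taxon_id": taxon,
                    "kruskal_p": float(p),
                    "log10_effect": effect,
                    "source": "surrogate_screen",
                }
            )
    return pd.DataFrame(rows, columns=["taxon_id", "kruskal_p", "log10_effect", "source"])
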