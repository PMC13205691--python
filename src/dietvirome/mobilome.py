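"""Phage-mediated HGT classification, mobility-gene trajectories and the AMG
reversal filter.

An HGT event (donor genome, recipient genome, transferred gene) is
"phage-mediated" when the transferred gene aligns to an assembled phage
contig with nucleotide identity strictly above 90% and E-value strictly
below 1e-5. Trajectories of HGT-associated enzymes (integrases,
recombinases, transposases) are summarized as per-(class, group, day)
medians with a strict-monotone "continuously increasing" flag. Auxiliary
metabolic gene (AMG) selection retains KEGG orthologs whose day-0 to day-10
abundance changes are significant in both the high-fat (HFD) and
fucoidan-supplemented (FUC) groups and that show the reversal pattern:
HFD up-regulated versus its own baseline while FUC sits below HFD at the
same time point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import wilcoxon_rank_sum
from .data_io import AlignmentHit

__all__ = [
    "classify_phage_mediated",
    "hgt_frequency_change",
    "donor_recipient_roles",
    "SignedLogChange",
    "signed_log10_change",
    "enzyme_trajectory",
    "AMGSelection",
    "amg_reversal_filter",
    "crosskingdom_homolog_filter",
]

logger = logging.getLogger(__name__)

HGT_ENZYME_CLASSES = ("integrase", "recombinase", "transposase")


def classify_phage_mediated(
    events: pd.DataFrame,
    hits: Sequence[AlignmentHit],
    min_identity: float = 90.0,
    max_evalue: float = 1e-5,
) -> pd.DataFrame:
    """Flag HGT events whose transferred gene has a qualifying phage hit.

    A hit qualifies when identity > ``min_identity`` (strict) and
    e_value < ``max_evalue`` (strict); the best qualifying hit (highest bit
    score) is recorded on the event. Returns a copy of ``events`` with
    ``phage_mediated``, ``phage_contig_id``, ``phage_nt_identity`` and
    ``phage_e_value`` columns rewritten from the screen.
    """
    best_by_gene: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.identity > min_identity and h.e_value < max_evalue:
            cur = best_by_gene.get(h.query_id)
            if cur is None or h.bit_score > cur.bit_score:
                best_by_gene[h.query_id] = h
    out = events.copy()
    flags, contigs, idents, evals = [], [], [], []
    for gene_id in out["gene_id"].astype(str):
        hit = best_by_gene.get(gene_id)
        if hit is None:
            flags.append(False)
            contigs.append(None)
            idents.append(np.nan)
            evals.append(np.nan)
        else:
            flags.append(True)
            contigs.append(hit.subject_id)
            idents.append(hit.identity)
            evals.append(hit.e_value)
    out["phage_mediated"] = flags
    out["phage_contig_id"] = contigs
    out["phage_nt_identity"] = idents
    out["phage_e_value"] = evals
    return out


def hgt_frequency_change(count_baseline: float, count_condition: float) -> tuple[float, float]:
    """(fold change, percent change) of HGT event frequency vs baseline."""
    if count_baseline <= 0:
        raise ValueError("baseline count must be positive; change vs an empty baseline is undefined")
    fold = count_condition / count_baseline
    percent = (count_condition - count_baseline) / count_baseline * 100.0
    return float(fold), float(percent)


def donor_recipient_roles(events: pd.DataFrame) -> pd.DataFrame:
    """Per-genus donor/recipient occurrence counts and strict-majority role bias.

    Expects ``donor_genus`` and ``recipient_genus`` columns (or falls back to
    ``donor_taxon``/``recipient_taxon``). Role is "donor-biased" when
    n_donor > n_recipient, "recipient-biased" for the mirror case, otherwise
    "balanced".
    """
    d_col = "donor_genus" if "donor_genus" in events.columns else "donor_taxon"
    r_col = "recipient_genus" if "recipient_genus" in events.columns else "recipient_taxon"
    donors = events[d_col].astype(str).value_counts()
    recipients = events[r_col].astype(str).value_counts()
    genera = sorted(set(donors.index) | set(recipients.index))
    rows = []
    for g in genera:
        n_d = int(donors.get(g, 0))
        n_r = int(recipients.get(g, 0))
        if n_d > n_r:
            role = "donor-biased"
        elif n_r > n_d:
            role = "recipient-biased"
        else:
            role = "balanced"
        rows.append({"genus": g, "n_donor": n_d, "n_recipient": n_r, "role": role})
    return pd.DataFrame(rows, columns=["genus", "n_donor", "n_recipient", "role"])


@dataclass(frozen=True)
class SignedLogChange:
    key: str
    value: float
    convention: str  # verbatim_difference | stabilized


def signed_log10_change(
    value_a: float, value_b: float, convention: str = "verbatim_difference", key: str = ""
) -> SignedLogChange:
    """Signed log10 summary of an abundance change from day a to day b.

    ``verbatim_difference``: +log10(b - a) when b > a, -log10(|b - a|) when
    b < a, 0 when equal. This convention is sign-unstable for |b - a| < 1
    (the log of a small positive difference is negative); the ``stabilized``
    convention sign(b - a) * log10(|b - a| + 1) keeps the sign faithful at
    all magnitudes.
    """
    if value_a < 0 or value_b < 0:
        raise ValueError("abundances must be nonnegative")
    diff = value_b - value_a
    if convention == "verbatim_difference":
        if diff == 0:
            val = 0.0
        elif diff > 0:
            val = math.log10(diff)
        else:
            val = -math.log10(abs(diff))
    elif convention == "stabilized":
        val = math.copysign(math.log10(abs(diff) + 1.0), diff) if diff != 0 else 0.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return SignedLogChange(key, val, convention)


def enzyme_trajectory(
    gene_table: pd.DataFrame,
    sample_info: pd.DataFrame,
    classes: Sequence[str] = HGT_ENZYME_CLASSES,
) -> pd.DataFrame:
    """Median abundance per (enzyme class, group, day) with a monotone flag.

    ``gene_table`` is long-format (gene_key, pathway, sample_id, value);
    ``sample_info`` supplies group and day per sample. The per-(class, group)
    flag ``continuously_increasing`` is True iff the medians strictly
    increase across the ordered days; a group missing any day leaves the
    flag undefined (None).
    """
    merged = gene_table.merge(sample_info[["sample_id", "group", "day"]], on="sample_id")
    merged = merged[merged["gene_key"].isin(classes)]
    med = (
        merged.groupby(["gene_key", "group", "day"])["value"]
        .median()
        .reset_index()
        .rename(columns={"value": "median_abundance"})
    )
    all_days = sorted(sample_info["day"].unique())
    if len(all_days) < 2:
        raise ValueError("enzyme_trajectory needs at least 2 time points")
    flags = []
    for (cls, group), sub in med.groupby(["gene_key", "group"]):
        by_day = dict(zip(sub["day"], sub["median_abundance"]))
        if any(d not in by_day for d in all_days):
            flag = None
        else:
            seq = [by_day[d] for d in all_days]
            flag = all(b > a for a, b in zip(seq, seq[1:]))
        flags.append({"gene_key": cls, "group": group, "continuously_increasing": flag})
    med = med.merge(pd.DataFrame(flags), on=["gene_key", "group"])
    return med.sort_values(["gene_key", "group", "day"]).reset_index(drop=True)


@dataclass
class AMGSelection:
    ko: str
    pathway: str
    eval_day: int
    medians: dict  # (group, day) -> median
    hfd_p: float
    fuc_p: float
    hfd_percent_change: float
    fuc_below_hfd: bool
    selected: bool


def amg_reversal_filter(
    ko_table: pd.DataFrame,
    sample_info: pd.DataFrame,
    groups: tuple[str, str] = ("HFD", "FUC"),
    days: Sequence[int] = (0, 10, 14, 18),
    alpha: float = 0.05,
) -> list[AMGSelection]:
    """Two-step reversal filter for KEGG-ortholog AMG abundances.

    Retention: the day-0 vs day-10 Wilcoxon rank-sum change must be
    significant (p < alpha) in both groups. Selection, evaluated
    independently at each post-baseline day d in ``days``: (1) the HFD
    median at day d exceeds its own day-0 baseline (positive percent
    change), and (2) the FUC median at day d is below the HFD median at
    day d. One record per (KO, evaluated day); output is ordered by pathway,
    then descending day-10 HFD percent change, then KO id. KOs missing a
    required group/day are excluded with a logged reason.
    """
    hfd, fuc = groups
    merged = ko_table.merge(sample_info[["sample_id", "group", "day"]], on="sample_id")
    eval_days = [d for d in sorted(days) if d != 0]
    day10 = eval_days[0]
    results: list[AMGSelection] = []
    for ko, sub in merged.groupby("gene_key"):
        pathway = str(sub["pathway"].iloc[0]) if sub["pathway"].notna().any() else ""
        cells = {
            (g, d): sub[(sub["group"] == g) & (sub["day"] == d)]["value"].to_numpy(dtype=float)
            for g in (hfd, fuc)
            for d in sorted(days)
        }
        required = [(hfd, 0), (hfd, day10), (fuc, 0), (fuc, day10)]
        if any(len(cells[k]) == 0 for k in required):
            logger.warning("KO %s excluded: missing group/day cell among %s", ko, required)
            continue
        try:
            _, hfd_p = wilcoxon_rank_sum(cells[(hfd, 0)], cells[(hfd, day10)])
            _, fuc_p = wilcoxon_rank_sum(cells[(fuc, 0)], cells[(fuc, day10)])
        except ValueError as exc:
            logger.warning("KO %s excluded: %s", ko, exc)
            continue
        retained = hfd_p < alpha and fuc_p < alpha
        medians = {
            (g, d): float(np.median(v)) for (g, d), v in cells.items() if len(v) > 0
        }
        hfd_base = medians[(hfd, 0)]
        for d in eval_days:
            if (hfd, d) not in medians or (fuc, d) not in medians:
                continue
            if hfd_base > 0:
                pct = (medians[(hfd, d)] - hfd_base) / hfd_base * 100.0
            else:
                pct = math.inf if medians[(hfd, d)] > 0 else 0.0
            below = medians[(fuc, d)] < medians[(hfd, d)]
            results.append(
                AMGSelection(
                    ko=str(ko),
                    pathway=pathway,
                    eval_day=int(d),
                    medians=medians,
                    hfd_p=float(hfd_p),
                    fuc_p=float(fuc_p),
                    hfd_percent_change=float(pct),
                    fuc_below_hfd=below,
                    selected=bool(retained and pct > 0 and below),
                )
            )
    day10_pct = {}
    for r in results:
        if r.eval_day == day10:
            day10_pct[r.ko] = r.hfd_percent_change
    results.sort(
        key=lambda r: (r.pathway, -day10_pct.get(r.ko, -math.inf), r.ko, r.eval_day)
    )
    return results


def crosskingdom_homolog_filter(
    hits: Sequence[AlignmentHit],
    max_evalue: float = 1e-5,
    min_bitscore: float = 90.0,
) -> list[AlignmentHit]:
    """Homolog screen then first-record deduplication per query id.

    Keeps hits with e_value < ``max_evalue`` and bit_score > ``min_bitscore``
    (both strict), then the first surviving record per query id in input
    order.
    """
    seen: set[str] = set()
    kept: list[AlignmentHit] = []
    for h in hits:
        if h.e_value < max_evalue and h.bit_score > min_bitscore and h.query_id not in seen:
            seen.add(h.query_id)
            kept.append(h)
    return kept
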