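"""Abundance normalization and the subsampled Bray-Curtis convergence test.

Coverage-style normalization divides mapped reads by target length and
sequencing depth and scales by 1e10; relative abundance divides each sample
column by its total. Community convergence between a pre- and a
post-intervention sample set is measured by repeatedly subsampling equal
numbers of samples per side and recording, per iteration, the median
inter-group Bray-Curtis distance and a two-sided Wilcoxon rank-sum p value
against the within-pre-group distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.stats import mannwhitneyu

from .data_io import AbundanceMatrix, UnitError

__all__ = [
    "normalize_abundance",
    "to_relative",
    "bray_curtis",
    "BCShiftResult",
    "subsampled_bc_shift",
]


def normalize_abundance(mapped_reads: float, target_length_bp: float, total_sample_reads: float) -> float:
    """mapped_reads / (L * N) * 1e10, the per-gene/per-contig depth normalization.

    L is the target length in bp and N the total read count of the sample;
    the 1e10 scale keeps typical gut-metagenome values in a readable range.
    """
    if target_length_bp <= 0 or total_sample_reads <= 0:
        raise ValueError("target length L and total reads N must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be nonnegative")
    return mapped_reads / (target_length_bp * total_sample_reads) * 1e10


def to_relative(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample column by its column sum (all-zero columns stay zero)."""
    if m.unit != "read_count":
        raise UnitError(f"to_relative expects read_count input, got {m.unit!r}")
    vals = m.values
    colsums = vals.sum(axis=0)
    safe = np.where(colsums > 0, colsums, 1.0)
    rel = vals / safe
    out = pd.DataFrame(rel, index=m.data.index, columns=m.data.columns)
    return AbundanceMatrix(out, "relative_fraction")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on nonnegative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined when both vectors are all-zero")
    return float(_scipy_braycurtis(x, y))


@dataclass
class BCShiftResult:
    """Per-iteration medians and p values from the subsampled Bray-Curtis shift."""

    median_bc: np.ndarray
    p_values: np.ndarray
    n_iterations: int
    per_iter_size: int
    seed: int

    def __post_init__(self) -> None:
        self.median_bc = np.asarray(self.median_bc, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.median_bc) != self.n_iterations or len(self.p_values) != self.n_iterations:
            raise ValueError("iteration count mismatch")
        if ((self.median_bc < 0) | (self.median_bc > 1)).any():
            raise ValueError("Bray-Curtis distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iterations + 1),
                "median_bc": self.median_bc,
                "p": self.p_values,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pairwise_bc(a: np.ndarray, b: np.ndarray) -> list[float]:
    return [bray_curtis(a[:, i], b[:, j]) for i in range(a.shape[1]) for j in range(b.shape[1])]


def _within_bc(a: np.ndarray) -> list[float]:
    return [bray_curtis(a[:, i], a[:, j]) for i, j in combinations(range(a.shape[1]), 2)]


def subsampled_bc_shift(
    pre: AbundanceMatrix,
    post: AbundanceMatrix,
    n_iter: int = 100,
    per_iter_size: int | None = None,
    seed: int = 0,
) -> BCShiftResult:
    """Balanced-subsampling Bray-Curtis shift between two sample sets.

    Each iteration draws ``per_iter_size`` samples per side without
    replacement, records the median of all inter-group pairwise Bray-Curtis
    distances, and a two-sided Wilcoxon rank-sum p comparing the inter-group
    distances against the within-pre-group distances of the same draw.
    Deterministic for a fixed seed.
    """
    n_pre, n_post = len(pre.sample_ids), len(post.sample_ids)
    if n_pre < 2 or n_post < 2:
        raise ValueError("need at least 2 samples per side")
    if per_iter_size is None:
        per_iter_size = min(n_pre, n_post)
    if per_iter_size > min(n_pre, n_post):
        raise ValueError("per_iter_size exceeds the smaller group size")
    if per_iter_size < 2:
        raise ValueError("per_iter_size must be >= 2")
    rng = np.random.default_rng(seed)
    pre_vals = pre.values
    post_vals = post.values
    medians = np.empty(n_iter)
    pvals = np.empty(n_iter)
    for it in range(n_iter):
        i_pre = rng.choice(n_pre, size=per_iter_size, replace=False)
        i_post = rng.choice(n_post, size=per_iter_size, replace=False)
        a = pre_vals[:, i_pre]
        b = post_vals[:, i_post]
        inter = _pairwise_bc(a, b)
        within = _within_bc(a)
        medians[it] = np.median(inter)
        if len(set(inter)) == 1 and len(set(within)) == 1 and inter[0] == within[0]:
            pvals[it] = 1.0
        else:
            pvals[it] = mannwhitneyu(inter, within, alternative="two-sided").pvalue
    return BCShiftResult(medians, pvals, n_iter, per_iter_size, seed)
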