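"""Pairwise single-cell co-expression: loop-defined and shared-enhancer gene
pairs against shuffled-pair nulls, correlation trajectories over treatment
time by trajectory class, and correlation-extreme composition by noise level.

Correlations are Spearman (average ranks for ties) over the cells of a single
timepoint; pairs are unordered and deduplicated. Shuffled controls re-pair
the second members of the observed pairs by a derangement-style permutation
that rejects self-pairs and re-creations of observed pairs, preserving each
gene's pair multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from intervaltree import IntervalTree

from .regions import GenomicRegion, Loop, RegulatoryMap


@dataclass
class GenePairSet:
    """Unordered, deduplicated gene pairs of one class."""

    pairs: list[tuple[str, str]]
    pair_class: str

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        cleaned: list[tuple[str, str]] = []
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                cleaned.append(key)
        self.pairs = cleaned

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)


def promoter_looped_pairs(
    promoters: Mapping[str, GenomicRegion], filtered_loops: Iterable[Loop]
) -> GenePairSet:
    """Pairs of genes whose promoters sit in the two anchors of one loop."""
    trees: dict[str, IntervalTree] = {}
    for gene_id, prom in promoters.items():
        trees.setdefault(prom.chrom, IntervalTree()).addi(
            prom.start, prom.end, gene_id
        )

    def genes_in(region: GenomicRegion) -> set[str]:
        tree = trees.get(region.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(region.start, region.end)}

    pairs: list[tuple[str, str]] = []
    for lp in filtered_loops:
        for a in genes_in(lp.anchor_a):
            for b in genes_in(lp.anchor_b):
                if a != b:
                    pairs.append((a, b))
    return GenePairSet(pairs, "PromoterLooped")


def shared_enhancer_pairs(reg_map: RegulatoryMap) -> GenePairSet:
    """Pairs of genes whose enhancer repertoires share a peak (by peak id)."""
    by_peak: dict[tuple, list[str]] = {}
    for gene_id, enhancers in reg_map.enhancers.items():
        for peak in enhancers:
            key = peak.id if peak.id is not None else (peak.chrom, peak.start, peak.end)
            by_peak.setdefault(key, []).append(gene_id)
    pairs: list[tuple[str, str]] = []
    for genes in by_peak.values():
        for a, b in combinations(sorted(set(genes)), 2):
            pairs.append((a, b))
    return GenePairSet(pairs, "SharedEnhancer")


def shuffled_pairs(
    pair_set: GenePairSet, seed: int = 0, max_tries: int = 1000
) -> GenePairSet:
    """Derangement-style null: permute second elements, rejecting self-pairs
    and re-creations of observed pairs. Same cardinality as the input."""
    if len(pair_set) < 2:
        raise ValueError("need >= 2 pairs to shuffle")
    rng = np.random.default_rng(seed)
    firsts = [a for a, _ in pair_set.pairs]
    seconds = [b for _, b in pair_set.pairs]
    original = pair_set.as_set()
    for _ in range(max_tries):
        perm = rng.permutation(len(seconds))
        candidate = [
            (a, seconds[j]) for a, j in zip(firsts, perm)
        ]
        keys = {(a, b) if a <= b else (b, a) for a, b in candidate}
        if any(a == b for a, b in candidate):
            continue
        if keys & original:
            continue
        if len(keys) < len(candidate):
            continue
        return GenePairSet(candidate, "ShuffledControl")
    raise ValueError(
        "could not find a valid shuffled pairing (degenerate pair set)"
    )


@dataclass
class CorrelationResult:
    """Per-pair Spearman rho plus the number of pairs dropped as degenerate."""

    rho: pd.Series
    n_dropped: int


def pairwise_spearman(
    matrix: pd.DataFrame, pair_set: GenePairSet, min_cells: int = 10
) -> CorrelationResult:
    """Spearman rho per pair over the cells (rows) of ``matrix``.

    Pairs with a zero-variance member are dropped and counted. Ranks use
    average ties; rho is the Pearson correlation of the rank vectors.
    """
    if len(matrix) < min_cells:
        raise ValueError(f"need >= {min_cells} cells, got {len(matrix)}")
    genes = sorted({g for pair in pair_set.pairs for g in pair})
    present = [g for g in genes if g in matrix.columns]
    ranks = pd.DataFrame(
        stats.rankdata(matrix[present].to_numpy(), axis=0),
        columns=present,
    )
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    rho: dict[tuple[str, str], float] = {}
    dropped = 0
    for a, b in pair_set.pairs:
        if a not in matrix.columns or b not in matrix.columns:
            dropped += 1
            continue
        if norms[a] == 0 or norms[b] == 0:
            dropped += 1
            continue
        rho[(a, b)] = float(
            (centered[a] * centered[b]).sum() / (norms[a] * norms[b])
        )
    return CorrelationResult(
        rho=pd.Series(rho, name="rho", dtype=float), n_dropped=dropped
    )


def compare_pair_groups(
    rho_a: Sequence[float], rho_b: Sequence[float], family_size: int = 1
) -> float:
    """Bonferroni-corrected two-sided Wilcoxon rank-sum p on rho sets."""
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both rho sets must be non-empty")
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(min(1.0, p * family_size))


def correlation_by_group_over_time(
    matrix: pd.DataFrame,
    timepoints: pd.Series,
    genes: Sequence[str],
    min_cells: int = 10,
) -> dict[float, pd.Series]:
    """All-pairs rho within a gene group, separately per timepoint.

    ``matrix`` is cells x genes (normalized); ``timepoints`` aligns with its
    rows. Only cells of each timepoint enter that timepoint's correlations.
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("group needs >= 2 genes")
    pair_set = GenePairSet(list(combinations(genes, 2)), "TrajectoryGroup")
    out: dict[float, pd.Series] = {}
    for t in sorted(timepoints.unique()):
        sub = matrix.loc[(timepoints == t).to_numpy()]
        out[float(t)] = pairwise_spearman(sub, pair_set, min_cells=min_cells).rho
    return out


def correlation_extremes_by_noise(
    rho_high: Sequence[float],
    rho_low: Sequence[float],
    n_quantiles: int = 10,
) -> pd.DataFrame:
    """Composition of pooled correlation quantiles by noise class.

    Pools both rho sets, cuts them into ``n_quantiles`` equal-frequency bins,
    and reports the proportion of high- and low-noise pairs per bin (each
    bin's proportions sum to 1).
    """
    hi = np.asarray(rho_high, dtype=float)
    lo = np.asarray(rho_low, dtype=float)
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both rho sets must be non-empty")
    pooled = np.concatenate([hi, lo])
    is_high = np.concatenate([np.ones(len(hi), bool), np.zeros(len(lo), bool)])
    order = np.argsort(pooled, kind="stable")
    bins = np.empty(len(pooled), dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(len(pooled)), n_quantiles)):
        bins[order[chunk]] = b
    rows = []
    for b in range(n_quantiles):
        mask = bins == b
        n = int(mask.sum())
        n_hi = int(is_high[mask].sum())
        rows.append(
            {
                "quantile": b,
                "n_pairs": n,
                "prop_high": n_hi / n if n else np.nan,
                "prop_low": (n - n_hi) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("quantile")
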