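"""Per-gene regulatory feature construction: Z-scored signal, enhancer scores.

The enhancer score aggregates signal over a gene's linked enhancers as
``sum_i log2(s_i + 1)`` where ``s_i`` is the Z-score of integrated assay
signal at enhancer ``i``. Z-scores below -1 would make the logarithm
undefined, so contributions are clamped at a configurable floor (-0.99 by
default, i.e. a floor contribution of log2(0.01) ~ -6.64); this preserves
monotonicity without discarding genes.

Standardization universes are role-specific: promoter regions are Z-scored
against all promoters and enhancer regions against all enhancers, per assay,
because the two classes of regions carry signal on different scales.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegulatoryMap

DEFAULT_CLAMP_FLOOR = -0.99

#: feature-table columns that are not assay signals
COUNT_FEATURES = ("n_enhancers", "n_erbs", "gene_length")


def read_signal(path) -> pd.DataFrame:
    """Read a region x assay integrated-signal TSV (region_id index)."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    if (sig.to_numpy() < 0).any():
        raise ValueError(f"{path}: integrated signal must be non-negative")
    return sig


def zscore(signal_table: pd.DataFrame, assay: str, ddof: int = 1) -> pd.Series:
    """Standardize one assay column to mean 0, unit (sample) sd."""
    if assay not in signal_table.columns:
        raise KeyError(f"assay {assay!r} not in signal table")
    x = signal_table[assay].astype(float)
    if len(x) < 2:
        raise ValueError(f"assay {assay!r}: need >= 2 regions to standardize")
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"assay {assay!r}: zero variance, cannot Z-score")
    return (x - x.mean()) / sd


def zscore_table(signal_table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score every assay column over the rows given (the universe)."""
    return pd.concat(
        {assay: zscore(signal_table, assay, ddof) for assay in signal_table.columns},
        axis=1,
    )


def enhancer_score(
    z_values: Sequence[float], floor: float = DEFAULT_CLAMP_FLOOR
) -> float:
    """``sum_i log2(clamp(s_i, floor) + 1)`` over a gene's enhancers; empty -> 0."""
    total = 0.0
    for s in z_values:
        total += math.log2(max(float(s), floor) + 1.0)
    return total


def build_feature_table(
    reg_map: RegulatoryMap,
    signal_table: pd.DataFrame,
    genes: pd.DataFrame,
    context_label: str,
    floor: float = DEFAULT_CLAMP_FLOOR,
) -> pd.DataFrame:
    """Assemble the gene x feature matrix used for importance ranking.

    Columns: ``promoter_<assay>`` (promoter Z-signal), ``enhancer_score_<assay>``,
    ``n_enhancers``, ``n_erbs``, ``gene_length``, plus a ``context`` label
    column so tables from several cell contexts can be concatenated.

    Promoter region ids in ``signal_table`` are the gene ids; enhancer rows
    are keyed by peak id.
    """
    gene_ids = reg_map.gene_ids
    missing = [g for g in gene_ids if g not in signal_table.index]
    if missing:
        raise ValueError(f"genes missing from signal table: {missing[:10]}")

    enhancer_ids = sorted(
        {e.id for enhancers in reg_map.enhancers.values() for e in enhancers if e.id}
    )
    missing_enh = [e for e in enhancer_ids if e not in signal_table.index]
    if missing_enh:
        raise ValueError(f"enhancers missing from signal table: {missing_enh[:10]}")

    prom_z = zscore_table(signal_table.loc[gene_ids])
    enh_z = (
        zscore_table(signal_table.loc[enhancer_ids])
        if len(enhancer_ids) >= 2
        else pd.DataFrame(columns=signal_table.columns, dtype=float)
    )

    rows = {}
    for gene_id in gene_ids:
        row: dict[str, float] = {}
        for assay in signal_table.columns:
            row[f"promoter_{assay}"] = float(prom_z.loc[gene_id, assay])
        enh_keys = [e.id for e in reg_map.enhancers.get(gene_id, [])]
        for assay in signal_table.columns:
            zvals = (
                enh_z.loc[enh_keys, assay].to_numpy() if enh_keys else np.array([])
            )
            row[f"enhancer_score_{assay}"] = enhancer_score(zvals, floor=floor)
        row["n_enhancers"] = reg_map.n_enhancers(gene_id)
        row["n_erbs"] = reg_map.n_erbs(gene_id)
        row["gene_length"] = float(genes.loc[gene_id, "length"])
        rows[gene_id] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    table["context"] = context_label
    if table.drop(columns="context").isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


def split_axis_features(
    confirmed_features: Iterable[str],
) -> tuple[list[str], list[str]]:
    """Split confirmed features into promoter / enhancer axes.

    Counts and gene length belong to neither axis (they are not Z-scored
    signals) and are dropped.
    """
    promoter = [
        f for f in confirmed_features
        if f.startswith("promoter_") and f not in COUNT_FEATURES
    ]
    enhancer = [
        f for f in confirmed_features
        if f.startswith("enhancer_score_") and f not in COUNT_FEATURES
    ]
    return promoter, enhancer


def aggregate_axes(
    feature_table: pd.DataFrame,
    confirmed_features: Iterable[str],
    labels: pd.Series,
) -> pd.DataFrame:
    """Per-class average promoter signal and enhancer score with 95% CI.

    For each gene, signal is first averaged across the confirmed promoter
    (resp. enhancer-score) features; class means and normal-approximation
    confidence intervals are then taken over genes. Enhancer/ERBS counts and
    gene length never enter either axis.
    """
    prom_feats, enh_feats = split_axis_features(confirmed_features)
    if not prom_feats or not enh_feats:
        raise ValueError("need >= 1 confirmed feature on each axis")

    labels = labels.reindex(feature_table.index).dropna()
    out = []
    for cls, idx in labels.groupby(labels).groups.items():
        sub = feature_table.loc[idx]
        if len(sub) < 2:
            raise ValueError(f"class {cls!r} has < 2 genes")
        record: dict[str, object] = {"label": cls, "n_genes": len(sub)}
        for axis, feats in (("promoter", prom_feats), ("enhancer", enh_feats)):
            per_gene = sub[feats].mean(axis=1)
            mean = per_gene.mean()
            half = stats.norm.ppf(0.975) * per_gene.std(ddof=1) / np.sqrt(len(per_gene))
            record[f"{axis}_mean"] = mean
            record[f"{axis}_ci_low"] = mean - half
            record[f"{axis}_ci_high"] = mean + half
        out.append(record)
    return pd.DataFrame(out).set_index("label")
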