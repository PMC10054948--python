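"""Single-cell time-course analysis: QC, normalization, trajectory classes,
stratified control selection, and the mean-corrected (GAM-adjusted CV) noise
metric.

Trajectory classification follows the hormone-response design: per-gene
two-sided Wilcoxon rank-sum tests of each treated timepoint against 0 h on
log-normalized values, no fold-change cutoff. Genes significant at the first
treated timepoint (2 h) are Early (Up/Down by sign); genes first significant
at 4 or 8 h are Late; the rest are Unlabeled. Multiple testing is corrected
per timepoint (Benjamini-Hochberg by default).

Noise is the residual of a generalized additive model of log2(CV + 1) on mean
expression at 0 h, back-transformed multiplicatively (2**residual - 1), then
labeled High/Mid/Low as the top/bottom 20% of adjusted CV within ten
equal-frequency mean bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionTimecourse:
    """Cell x gene counts with per-cell timepoint labels.

    ``counts`` is dense int (cells x genes); ``cell_meta`` carries at least a
    ``timepoint`` column (hours) indexed by cell id; ``normalized`` is the
    log-normalized layer, present only after :func:`normalize`.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_ids: pd.Index
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise ValueError("counts shape does not match cell_meta / gene_ids")
        if "timepoint" not in self.cell_meta.columns:
            raise ValueError("cell_meta must have a 'timepoint' column")

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.cell_meta["timepoint"].unique())

    def cells_at(self, timepoint: float) -> np.ndarray:
        return (self.cell_meta["timepoint"] == timepoint).to_numpy()

    def layer(self, which: str = "normalized") -> np.ndarray:
        if which == "counts":
            return self.counts
        if self.normalized is None:
            raise ValueError("normalized layer absent; call normalize() first")
        return self.normalized


def compute_qc(tc: ExpressionTimecourse, mito_prefix: str = "MT-") -> ExpressionTimecourse:
    """Attach total counts, detected genes, and % mitochondrial per cell."""
    meta = tc.cell_meta.copy()
    totals = tc.counts.sum(axis=1)
    meta["total_counts"] = totals
    meta["n_genes"] = (tc.counts > 0).sum(axis=1)
    mito = tc.gene_ids.str.startswith(mito_prefix)
    with np.errstate(invalid="ignore", divide="ignore"):
        meta["pct_mito"] = np.where(
            totals > 0, 100.0 * tc.counts[:, mito].sum(axis=1) / totals, 0.0
        )
    return replace(tc, cell_meta=meta)


def filter_cells(
    tc: ExpressionTimecourse,
    min_counts: float | None = None,
    max_counts: float | None = None,
    min_genes: float | None = None,
    max_genes: float | None = None,
    max_pct_mito: float | None = None,
) -> ExpressionTimecourse:
    """Keep cells satisfying all QC bounds (bounds inclusive, mito strict <).

    The study's Ishikawa defaults were 8500-35000 unique reads, 2700-6000
    unique genes, and < 7% mitochondrial reads; pass them explicitly.
    """
    meta = tc.cell_meta
    keep = np.ones(len(meta), dtype=bool)
    if min_counts is not None:
        keep &= meta["total_counts"].to_numpy() >= min_counts
    if max_counts is not None:
        keep &= meta["total_counts"].to_numpy() <= max_counts
    if min_genes is not None:
        keep &= meta["n_genes"].to_numpy() >= min_genes
    if max_genes is not None:
        keep &= meta["n_genes"].to_numpy() <= max_genes
    if max_pct_mito is not None:
        keep &= meta["pct_mito"].to_numpy() < max_pct_mito
    if not keep.any():
        raise ValueError("cell QC removed every cell")
    return replace(
        tc,
        counts=tc.counts[keep],
        cell_meta=meta.loc[keep].copy(),
        normalized=None if tc.normalized is None else tc.normalized[keep],
    )


def normalize(tc: ExpressionTimecourse, scale: float = 1e4) -> ExpressionTimecourse:
    """Log-normalize: ``ln(1 + scale * x / library_size)`` per cell."""
    totals = tc.counts.sum(axis=1, keepdims=True).astype(float)
    if (totals == 0).any():
        bad = int((totals == 0).sum())
        raise ValueError(f"{bad} cells have zero total counts; filter first")
    norm = np.log1p(scale * tc.counts / totals)
    return replace(tc, normalized=norm)


def filter_genes(
    tc: ExpressionTimecourse,
    min_mean: float = 0.01,
    layer: str = "normalized",
    per_timepoint: bool = True,
) -> ExpressionTimecourse:
    """Keep genes with mean > ``min_mean`` in every timepoint.

    ``per_timepoint=False`` instead applies the cutoff to the pooled mean.
    """
    x = tc.layer(layer)
    if per_timepoint:
        keep = np.ones(len(tc.gene_ids), dtype=bool)
        for t in tc.timepoints:
            keep &= x[tc.cells_at(t)].mean(axis=0) > min_mean
    else:
        keep = x.mean(axis=0) > min_mean
    return replace(
        tc,
        counts=tc.counts[:, keep],
        gene_ids=tc.gene_ids[keep],
        normalized=None if tc.normalized is None else tc.normalized[:, keep],
    )


# ---------------------------------------------------------------------------
# differential expression and trajectory classes
# ---------------------------------------------------------------------------

def call_differential(
    tc: ExpressionTimecourse, t: float, t_ref: float = 0.0
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene, timepoint ``t`` vs ``t_ref``.

    Returns a DataFrame (gene_id index) with columns ``p`` and ``direction``
    (sign of the mean difference). No fold-change cutoff is applied. Genes
    that are constant across both groups get p = 1, direction 0.
    """
    x = tc.layer("normalized")
    a = x[tc.cells_at(t)]
    b = x[tc.cells_at(t_ref)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both timepoints need >= 2 cells")
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # all-tie genes yield nan under the asymptotic normal approximation
    degenerate = (a.min(axis=0) == a.max(axis=0)) & (b.min(axis=0) == b.max(axis=0)) & (
        a.min(axis=0) == b.min(axis=0)
    )
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    direction = np.sign(a.mean(axis=0) - b.mean(axis=0))
    direction = np.where(degenerate, 0.0, direction)
    return pd.DataFrame({"p": p, "direction": direction}, index=tc.gene_ids)


def assign_trajectories(
    de_results: Mapping[float, pd.DataFrame],
    alpha: float = 0.05,
    correction: str = "BH",
) -> pd.DataFrame:
    """Classify genes as EarlyUp/EarlyDown/LateUp/LateDown/Unlabeled.

    ``de_results`` maps treated timepoints (hours) to the per-gene test
    output of :func:`call_differential`. The earliest treated timepoint
    defines Early; the first significant later timepoint defines Late with
    its direction. ``correction`` is 'BH', 'bonferroni', or 'none', applied
    per timepoint.
    """
    times = sorted(de_results)
    genes = de_results[times[0]].index
    adj: dict[float, np.ndarray] = {}
    for t in times:
        p = de_results[t]["p"].to_numpy()
        if correction == "BH":
            adj[t] = multipletests(p, method="fdr_bh")[1]
        elif correction.lower() == "bonferroni":
            adj[t] = multipletests(p, method="bonferroni")[1]
        elif correction == "none":
            adj[t] = p
        else:
            raise ValueError(f"unknown correction {correction!r}")

    labels = np.full(len(genes), "Unlabeled", dtype=object)
    early_t = times[0]
    sig_early = adj[early_t] < alpha
    dir_early = de_results[early_t]["direction"].to_numpy()
    labels[sig_early & (dir_early > 0)] = "EarlyUp"
    labels[sig_early & (dir_early < 0)] = "EarlyDown"

    undecided = ~sig_early
    for t in times[1:]:
        sig = (adj[t] < alpha) & undecided
        d = de_results[t]["direction"].to_numpy()
        labels[sig & (d > 0)] = "LateUp"
        labels[sig & (d < 0)] = "LateDown"
        undecided &= ~sig

    out = pd.DataFrame({"trajectory": labels}, index=genes)
    for t in times:
        out[f"p_{t:g}h"] = de_results[t]["p"].to_numpy()
        out[f"q_{t:g}h"] = adj[t]
        out[f"direction_{t:g}h"] = de_results[t]["direction"].to_numpy()
    return out


def _stable_order(values: pd.Series) -> np.ndarray:
    """Indices sorting by value with ties broken by gene id (stable)."""
    s = values.sort_index(kind="stable")
    order = np.argsort(s.to_numpy(), kind="stable")
    return s.index.to_numpy()[order]


def mean_bins(values: pd.Series, n_bins: int = 10) -> pd.Series:
    """Equal-frequency bin index (0..n_bins-1), stable tie-break by gene id."""
    ordered = _stable_order(values)
    chunks = np.array_split(np.arange(len(ordered)), n_bins)
    bin_of = {}
    for b, chunk in enumerate(chunks):
        for i in chunk:
            bin_of[ordered[i]] = b
    return pd.Series([bin_of[g] for g in values.index], index=values.index, name="mean_bin")


def select_controls(
    labels: pd.Series,
    means: pd.Series,
    n_bins: int = 10,
    seed: int = 0,
) -> list[str]:
    """Stratified sample of Unlabeled genes matching regulated genes' means.

    Genes are binned by mean into ``n_bins`` equal-frequency bins; within
    each bin, as many Unlabeled genes are drawn (without replacement) as
    there are regulated (non-Unlabeled) genes.
    """
    rng = np.random.default_rng(seed)
    bins = mean_bins(means, n_bins)
    regulated = labels.index[labels != "Unlabeled"]
    pool = labels.index[labels == "Unlabeled"]
    controls: list[str] = []
    for b in range(n_bins):
        need = int((bins.loc[regulated] == b).sum())
        if need == 0:
            continue
        avail = [g for g in pool if bins.loc[g] == b]
        if len(avail) < need:
            raise ValueError(
                f"mean bin {b}: need {need} control genes, only {len(avail)} unlabeled"
            )
        controls.extend(rng.choice(np.array(avail, dtype=object), size=need, replace=False))
    return [str(g) for g in controls]


def classify_mean_levels(means: pd.Series, q: float = 0.2) -> pd.Series:
    """Label genes Low (bottom 20%), Mid (middle 60%), High (top 20%) by mean."""
    if len(means) < 5:
        raise ValueError("need >= 5 genes to classify mean levels")
    if means.nunique() == 1:
        raise ValueError("all means identical; quantile cut degenerate")
    ordered = _stable_order(means)
    n = len(ordered)
    n_low = int(round(q * n))
    n_high = int(round(q * n))
    labels = pd.Series("Mid", index=means.index, name="mean_level", dtype=object)
    labels.loc[ordered[:n_low]] = "Low"
    labels.loc[ordered[n - n_high:]] = "High"
    return labels


# ---------------------------------------------------------------------------
# noise metric
# ---------------------------------------------------------------------------

def gene_mean_cv(
    tc: ExpressionTimecourse, timepoint: float = 0.0, layer: str = "normalized"
) -> pd.DataFrame:
    """Per-gene mean and CV over cells of one timepoint (default 0 h)."""
    x = tc.layer(layer)[tc.cells_at(timepoint)]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({"mean": mean, "cv": cv}, index=tc.gene_ids)


class CVNoiseModel:
    """Mean-corrected transcriptional noise via a GAM of log2(CV+1) on mean.

    A penalized cubic B-spline smooth (``df`` basis functions, penalty
    ``alpha``) is fitted to y = log2(CV + 1) against x = mean expression;
    the per-gene residual, back-transformed as ``2**r - 1``
    (``back_transform='multiplicative'``) or as CV minus fitted CV
    (``'additive'``), is the adjusted CV.

    Follows the scikit-learn fit/transform idiom; fitted attributes carry a
    trailing underscore.
    """

    def __init__(
        self,
        df: int = 10,
        degree: int = 3,
        alpha: float = 0.01,
        back_transform: str = "multiplicative",
    ):
        self.df = df
        self.degree = degree
        self.alpha = alpha
        self.back_transform = back_transform

    def get_params(self, deep: bool = True) -> dict:
        return {
            "df": self.df, "degree": self.degree, "alpha": self.alpha,
            "back_transform": self.back_transform,
        }

    def set_params(self, **params) -> "CVNoiseModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, means: np.ndarray, cvs: np.ndarray) -> "CVNoiseModel":
        means = np.asarray(means, dtype=float)
        cvs = np.asarray(cvs, dtype=float)
        if len(means) < 30:
            raise ValueError("need >= 30 genes to fit the CV-mean GAM")
        if not (np.isfinite(means).all() and np.isfinite(cvs).all()):
            raise ValueError("means/CVs must be finite; drop undetected genes first")
        y = np.log2(cvs + 1.0)
        smoother = BSplines(
            means[:, None], df=[self.df], degree=[self.degree],
            include_intercept=False,
        )
        # explicit unpenalized intercept so constant shifts in y move the
        # fit identically and leave residuals untouched
        model = GLMGam(
            y, exog=np.ones((len(means), 1)), smoother=smoother,
            alpha=[self.alpha],
        )
        try:
            self.result_ = model.fit()
        except Exception as exc:  # pragma: no cover - numerical failure path
            raise RuntimeError(f"GAM fit failed: {exc}") from exc
        self.smoother_ = smoother
        self.fitted_log2_ = np.asarray(self.result_.fittedvalues)
        self.train_means_ = means
        self.train_cvs_ = cvs
        return self

    def transform(self, means=None, cvs=None) -> np.ndarray:
        """Adjusted CV for the training genes (default) or new genes."""
        if means is None:
            yhat = self.fitted_log2_
            cvs = self.train_cvs_
        else:
            means = np.asarray(means, dtype=float)
            cvs = np.asarray(cvs, dtype=float)
            yhat = np.asarray(
                self.result_.predict(
                    exog=np.ones((len(means), 1)), exog_smooth=means[:, None]
                )
            )
        y = np.log2(np.asarray(cvs, dtype=float) + 1.0)
        resid = y - yhat
        if self.back_transform == "multiplicative":
            return 2.0 ** resid - 1.0
        if self.back_transform == "additive":
            return np.asarray(cvs, dtype=float) - (2.0 ** yhat - 1.0)
        raise ValueError(f"unknown back_transform {self.back_transform!r}")

    def fit_transform(self, means, cvs) -> np.ndarray:
        return self.fit(means, cvs).transform()


def adjusted_cv(
    means: pd.Series,
    cvs: pd.Series,
    df: int = 10,
    alpha: float = 0.01,
    back_transform: str = "multiplicative",
) -> pd.Series:
    """Convenience wrapper around :class:`CVNoiseModel` on aligned Series."""
    model = CVNoiseModel(df=df, alpha=alpha, back_transform=back_transform)
    adj = model.fit_transform(means.to_numpy(), cvs.reindex(means.index).to_numpy())
    return pd.Series(adj, index=means.index, name="adjusted_cv")


def assign_noise_levels(
    noise_table: pd.DataFrame, n_bins: int = 10, q: float = 0.2
) -> pd.DataFrame:
    """High/Mid/Low noise labels within equal-frequency mean bins.

    ``noise_table`` needs columns ``mean`` and ``adjusted_cv``. Within each
    of ``n_bins`` mean bins, the top ``q`` fraction of genes by adjusted CV
    is High and the bottom ``q`` fraction Low.
    """
    out = noise_table.copy()
    out["mean_bin"] = mean_bins(out["mean"], n_bins)
    out["noise_level"] = "Mid"
    for b in range(n_bins):
        idx = out.index[out["mean_bin"] == b]
        if len(idx) < 5:
            raise ValueError(f"mean bin {b} has {len(idx)} genes (< 5)")
        ordered = _stable_order(out.loc[idx, "adjusted_cv"])
        k = int(round(q * len(idx)))
        out.loc[ordered[:k], "noise_level"] = "Low"
        out.loc[ordered[len(idx) - k:], "noise_level"] = "High"
    return out


def compare_covariate(
    labels: pd.Series,
    covariate: pd.Series,
    group: str,
    control_group: str,
) -> tuple[float, float]:
    """Two-sample KS p-value and standardized shift of group vs control.

    shift = (mean(group) - mean(control)) / sd(control). Used e.g. to ask
    whether Early Down genes have shorter mRNA half-lives than controls.
    """
    vals = {}
    for name in (group, control_group):
        genes = labels.index[labels == name]
        if len(genes) < 5:
            raise ValueError(f"group {name!r} has < 5 genes")
        v = covariate.reindex(genes)
        if v.isna().mean() > 0.5:
            raise ValueError(f"group {name!r}: covariate missing for > 50% of genes")
        vals[name] = v.dropna().to_numpy()
    g, c = vals[group], vals[control_group]
    p = stats.ks_2samp(g, c).pvalue
    shift = (g.mean() - c.mean()) / c.std(ddof=1)
    return float(p), float(shift)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_counts_mtx(
    mtx_path: str | Path, cells_path: str | Path, genes_path: str | Path
) -> ExpressionTimecourse:
    """Read counts (MTX, genes x cells or cells x genes) + metadata TSVs."""
    mat = spio.mmread(str(mtx_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    counts = np.asarray(mat)
    if counts.shape == (len(genes), len(cells)) and counts.shape[0] != counts.shape[1]:
        counts = counts.T
    return ExpressionTimecourse(
        counts=counts.astype(np.int64),
        cell_meta=cells,
        gene_ids=pd.Index(genes.index.astype(str), name="gene_id"),
    )


def run_dynamics(
    tc: ExpressionTimecourse,
    alpha: float = 0.05,
    correction: str = "BH",
    min_mean: float = 0.01,
    n_bins: int = 10,
    gam_alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Full labeling pipeline: normalize, filter, classify, score noise.

    Returns one row per kept gene with trajectory, mean level, noise level,
    mean/CV/adjusted CV at 0 h, and per-timepoint p-values.
    """
    tc = normalize(tc)
    tc = filter_genes(tc, min_mean=min_mean)
    times = [t for t in tc.timepoints if t != 0.0]
    de = {t: call_differential(tc, t) for t in times}
    traj = assign_trajectories(de, alpha=alpha, correction=correction)

    mc = gene_mean_cv(tc, timepoint=0.0)
    mc = mc.dropna(subset=["cv"])
    noise = mc.copy()
    noise["adjusted_cv"] = adjusted_cv(mc["mean"], mc["cv"], alpha=gam_alpha)
    noise = assign_noise_levels(noise, n_bins=n_bins)

    out = traj.join(noise[["mean", "cv", "adjusted_cv", "mean_bin", "noise_level"]], how="left")
    kept = out.index[out["mean"].notna()]
    out = out.loc[kept]
    out["mean_level"] = classify_mean_levels(out["mean"])
    controls = select_controls(out["trajectory"], out["mean"], n_bins=n_bins, seed=seed)
    out.loc[out.index.isin(controls), "trajectory"] = "Control"
    out.index.name = "gene_id"
    return out
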