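"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates a 4-timepoint (0/2/4/8 h) hormone-induction scRNA-seq
experiment plus its regulatory architecture:

* negative-binomial counts with gene-level dispersion (the noise ground
  truth) and log-normal library-size variation;
* pulse-like Early trajectories (peak fold change at 2 h, half the
  log-fold-change decayed by 8 h) and monotone Late trajectories;
* a regulatory map — loops, H3K27ac/ER peaks, promoter and enhancer assay
  signal — statistically coupled to the planted classes with a tunable
  ``coupling_strength`` (0 = architecture independent of class);
* qPCR Ct tables whose ΔΔCt analysis recovers a specified relative
  expression curve.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dynamics import ExpressionTimecourse
from .regions import GenomicRegion, Loop, write_bed, write_loops

TRAJECTORY_CLASSES = ("EarlyUp", "EarlyDown", "LateUp", "LateDown", "Null")
NOISE_CLASSES = ("High", "Mid", "Low")

#: feature-table columns genuinely coupled to the planted classes
INFORMATIVE_FEATURES = (
    "promoter_SIN3A",
    "promoter_H3K27ac",
    "enhancer_score_ER",
    "n_erbs",
    "n_enhancers",
)

ASSAYS = ("H3K27ac", "ER", "SIN3A", "FOXA1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    n_genes: int = 2000
    n_cells_per_timepoint: int = 500
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    effect_size_early: float = 2.0
    effect_size_late: float = 2.0
    dispersion_low: float = 0.1
    dispersion_mid: float = 0.5
    dispersion_high: float = 2.5
    coupling_strength: float = 1.0
    library_size_sd: float = 0.3
    fraction_failing_loops: float = 0.2
    trajectory_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "EarlyUp": 0.05, "EarlyDown": 0.05, "LateUp": 0.05, "LateDown": 0.05,
            "Null": 0.8,
        }
    )
    noise_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"High": 0.2, "Mid": 0.6, "Low": 0.2}
    )

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if sorted(tps) != list(tps) or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be strictly increasing")
        if 0.0 not in tps:
            raise ValueError("timepoints must include 0")
        if len(tps) < 3:
            raise ValueError("need >= 3 timepoints")
        for name in ("dispersion_low", "dispersion_mid", "dispersion_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # 1.0 is the degenerate no-effect boundary used in null calibration
        if self.effect_size_early < 1 or self.effect_size_late < 1:
            raise ValueError("fold changes must be >= 1")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must be in [0, 1]")
        if not (0.0 <= self.fraction_failing_loops <= 1.0):
            raise ValueError("fraction_failing_loops must be in [0, 1]")
        self.timepoints = tps

    @property
    def dispersions(self) -> dict[str, float]:
        return {
            "Low": self.dispersion_low,
            "Mid": self.dispersion_mid,
            "High": self.dispersion_high,
        }


@dataclass
class GroundTruth:
    """Planted per-gene classes; the oracle for recovery tests."""

    table: pd.DataFrame  # index gene_id: true_trajectory, true_noise, ...
    informative_features: list[str] = field(
        default_factory=lambda: list(INFORMATIVE_FEATURES)
    )

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in ground truth")

    def genes_of(self, trajectory: str) -> pd.Index:
        return self.table.index[self.table["true_trajectory"] == trajectory]


@dataclass
class Architecture:
    """Synthetic regulatory architecture emitted alongside the truth."""

    loops: list[Loop]
    h3k27ac_peaks: list[GenomicRegion]
    er_peaks: list[GenomicRegion]
    signal: pd.DataFrame  # region_id x assay
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

MIN_TSS_SPACING = 10_000


def generate_annotation(
    n_genes: int, genome_size: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """One-TSS-per-gene annotation with >= 10 kb TSS spacing.

    Genes are laid out in equal slots on a single synthetic chromosome, so
    promoters (TSS +/- 250 bp) can never collide. Gene lengths are
    log-normal (median 20 kb).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if genome_size is None:
        genome_size = 100_000 * n_genes
    slot = genome_size // n_genes
    if slot < MIN_TSS_SPACING:
        raise ValueError(
            f"genome_size {genome_size} too small for {n_genes} genes with "
            f">= {MIN_TSS_SPACING} bp TSS spacing; need >= "
            f"{MIN_TSS_SPACING * n_genes}"
        )
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, slot - MIN_TSS_SPACING + 1, size=n_genes)
    tss = np.arange(n_genes) * slot + MIN_TSS_SPACING // 2 + offsets
    width = len(str(max(n_genes - 1, 1)))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(n_genes)],
            "chrom": "chrS",
            "tss": tss.astype(int),
            "strand": rng.choice(["+", "-"], size=n_genes),
            "length": np.round(
                rng.lognormal(mean=np.log(20_000), sigma=1.0, size=n_genes)
            ).astype(int) + 200,
        }
    )
    return genes.set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _exact_class_counts(n: int, fractions: Mapping[str, float]) -> list[str]:
    labels: list[str] = []
    names = list(fractions)
    for name in names[:-1]:
        labels.extend([name] * int(round(fractions[name] * n)))
    labels.extend([names[-1]] * (n - len(labels)))
    return labels


def assign_ground_truth(
    genes: pd.DataFrame, config: SimulationConfig, seed: int = 0
) -> GroundTruth:
    """Plant trajectory and noise classes plus baseline means per gene.

    Class counts are exact (rounded fractions of ``n_genes``); the
    assignment of classes to genes is a seeded permutation. Baseline mean
    expression is log-normal and independent of both classes.
    """
    rng = np.random.default_rng(seed)
    n = len(genes)
    traj = np.array(_exact_class_counts(n, config.trajectory_fractions), dtype=object)
    noise = np.array(_exact_class_counts(n, config.noise_fractions), dtype=object)
    rng.shuffle(traj)
    rng.shuffle(noise)
    table = pd.DataFrame(
        {
            "true_trajectory": traj,
            "true_noise": noise,
            "true_mean_level": rng.lognormal(np.log(0.5), 1.0, size=n),
        },
        index=genes.index,
    )
    return GroundTruth(table=table)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

ANCHOR_HALF = 2_500  # loop anchor half-width, bp
BASE_ENHANCER_RATE = 2.0
BASE_ER_PROB = 0.2


def generate_architecture(
    genes: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> Architecture:
    """Loops, peaks, and assay signal coupled to the planted classes.

    With coupling strength ``c``: EarlyUp genes get more enhancers (rate
    x(1+c)) and a higher ER-overlap probability per enhancer (0.2 + 0.6c);
    High-noise genes get more enhancers (x(1+0.5c)) and weaker promoter
    H3K27ac; LateUp genes get elevated promoter SIN3A signal; promoter
    H3K27ac also tracks baseline mean expression. A
    ``fraction_failing_loops`` share of loops is emitted with < 3 reads or
    FDR >= 0.05 and is expected to be filtered away downstream. Every
    enhancer peak lies inside a loop anchor whose partner anchor covers the
    gene's promoter; occasional enhancers are shared with the neighboring
    gene and occasional promoter-promoter loops are added so that
    co-expression pair sets are non-trivial.
    """
    if len(genes) == 0:
        raise ValueError("genes must be non-empty")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = assign_ground_truth(genes, config, seed=int(rng.integers(2**31)))
    c = config.coupling_strength
    tbl = truth.table

    loops: list[Loop] = []
    enh_peaks: list[GenomicRegion] = []
    er_peaks: list[GenomicRegion] = []
    enh_records: list[dict] = []  # per-peak bookkeeping for the signal table
    n_enh_true = pd.Series(0, index=genes.index, name="n_enhancers_true")

    gene_ids = list(genes.index)

    def loop_stats() -> tuple[int, float, bool]:
        failing = rng.random() < config.fraction_failing_loops
        if failing:
            if rng.random() < 0.5:
                return int(rng.integers(0, 3)), float(rng.uniform(0, 0.05)), False
            return int(3 + rng.poisson(10.0)), float(rng.uniform(0.05, 1.0)), False
        return int(3 + rng.poisson(10.0)), float(rng.uniform(0, 0.0499)), True

    for gi, gene_id in enumerate(gene_ids):
        row = genes.loc[gene_id]
        tss = int(row["tss"])
        traj = tbl.loc[gene_id, "true_trajectory"]
        noise = tbl.loc[gene_id, "true_noise"]

        rate = BASE_ENHANCER_RATE
        if traj == "EarlyUp":
            rate *= 1.0 + c
        if noise == "High":
            rate *= 1.0 + 0.5 * c
        n_enh = int(rng.poisson(rate))
        er_prob = BASE_ER_PROB + (0.6 * c if traj == "EarlyUp" else 0.0)

        prom_anchor = GenomicRegion(
            row["chrom"], max(0, tss - ANCHOR_HALF), tss + ANCHOR_HALF
        )
        for k in range(n_enh):
            offset = int(rng.integers(5_000, 80_000)) * int(rng.choice([-1, 1]))
            width = int(rng.integers(400, 1500))
            start = max(0, tss + offset - width // 2)
            peak = GenomicRegion(
                row["chrom"], start, start + width, id=f"enh_{gene_id}_{k}"
            )
            enh_peaks.append(peak)
            has_er = bool(rng.random() < er_prob)
            if has_er:
                quarter = max(1, width // 4)
                er_peaks.append(
                    GenomicRegion(
                        peak.chrom, peak.start + quarter, peak.end - quarter,
                        id=f"er_{gene_id}_{k}",
                    )
                )
            enh_records.append({"id": peak.id, "er": has_er})

            center = (peak.start + peak.end) // 2
            reads, fdr, passing = loop_stats()
            loops.append(
                Loop(
                    prom_anchor,
                    GenomicRegion(
                        peak.chrom, max(0, center - ANCHOR_HALF), center + ANCHOR_HALF
                    ),
                    reads=reads,
                    fdr=fdr,
                )
            )
            if passing:
                n_enh_true[gene_id] += 1

            # occasionally share this enhancer with the neighboring gene
            if gi + 1 < len(gene_ids) and rng.random() < 0.05:
                neighbor = genes.loc[gene_ids[gi + 1]]
                n_tss = int(neighbor["tss"])
                reads2, fdr2, _ = loop_stats()
                loops.append(
                    Loop(
                        GenomicRegion(
                            neighbor["chrom"], max(0, n_tss - ANCHOR_HALF),
                            n_tss + ANCHOR_HALF,
                        ),
                        GenomicRegion(
                            peak.chrom, max(0, center - ANCHOR_HALF),
                            center + ANCHOR_HALF,
                        ),
                        reads=reads2,
                        fdr=fdr2,
                    )
                )

        # occasional promoter-promoter loop with the next gene
        if gi + 1 < len(gene_ids) and rng.random() < 0.05:
            neighbor = genes.loc[gene_ids[gi + 1]]
            n_tss = int(neighbor["tss"])
            reads3, fdr3, _ = loop_stats()
            loops.append(
                Loop(
                    prom_anchor,
                    GenomicRegion(
                        neighbor["chrom"], max(0, n_tss - ANCHOR_HALF),
                        n_tss + ANCHOR_HALF,
                    ),
                    reads=reads3,
                    fdr=fdr3,
                )
            )

    # background H3K27ac peaks, unlooped
    genome_end = int(genes["tss"].max()) + 50_000
    bg_peaks: list[GenomicRegion] = []
    for i in range(len(genes) // 2):
        start = int(rng.integers(0, genome_end))
        bg_peaks.append(
            GenomicRegion("chrS", start, start + int(rng.integers(400, 1500)),
                          id=f"bg_{i}")
        )
    # background ER peaks away from enhancers
    for i in range(len(genes) // 4):
        start = int(rng.integers(0, genome_end))
        er_peaks.append(
            GenomicRegion("chrS", start, start + 300, id=f"erbg_{i}")
        )

    signal = _generate_signal(genes, tbl, enh_records, bg_peaks, c, rng)
    tbl = tbl.copy()
    tbl["n_enhancers_true"] = n_enh_true
    truth = GroundTruth(table=tbl, informative_features=truth.informative_features)
    return Architecture(
        loops=loops,
        h3k27ac_peaks=enh_peaks + bg_peaks,
        er_peaks=er_peaks,
        signal=signal,
        truth=truth,
    )


def _generate_signal(
    genes: pd.DataFrame,
    truth_table: pd.DataFrame,
    enh_records: list[dict],
    bg_peaks: list[GenomicRegion],
    c: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw integrated signal per region x assay (log-normal counts)."""
    n = len(genes)
    log_mean = np.log(truth_table["true_mean_level"].to_numpy())
    log_mean_z = (log_mean - log_mean.mean()) / (log_mean.std() + 1e-12)
    late_up = (truth_table["true_trajectory"] == "LateUp").to_numpy().astype(float)
    high_noise = (truth_table["true_noise"] == "High").to_numpy().astype(float)
    low_noise = (truth_table["true_noise"] == "Low").to_numpy().astype(float)

    prom = pd.DataFrame(index=genes.index, columns=list(ASSAYS), dtype=float)
    prom["H3K27ac"] = np.exp(
        rng.normal(3.0, 0.5, n)
        + c * (0.8 * log_mean_z - 0.5 * high_noise + 0.5 * low_noise)
    )
    prom["SIN3A"] = np.exp(rng.normal(2.0, 0.5, n) + 1.5 * c * late_up)
    prom["ER"] = np.exp(rng.normal(1.0, 0.5, n))
    prom["FOXA1"] = np.exp(rng.normal(1.5, 0.5, n))

    rows = {}
    for rec in enh_records:
        er_boost = 1.5 if rec["er"] else 0.0
        rows[rec["id"]] = {
            "H3K27ac": np.exp(rng.normal(3.0, 0.5)),
            "ER": np.exp(rng.normal(1.0, 0.5) + er_boost),
            "SIN3A": np.exp(rng.normal(0.5, 0.5)),
            "FOXA1": np.exp(rng.normal(1.5, 0.5)),
        }
    for peak in bg_peaks:
        rows[peak.id] = {
            "H3K27ac": np.exp(rng.normal(2.0, 0.5)),
            "ER": np.exp(rng.normal(1.0, 0.5)),
            "SIN3A": np.exp(rng.normal(0.5, 0.5)),
            "FOXA1": np.exp(rng.normal(1.5, 0.5)),
        }
    enh = pd.DataFrame.from_dict(rows, orient="index")[list(ASSAYS)]
    signal = pd.concat([prom, enh])
    signal.index.name = "region_id"
    return np.round(signal * 10.0).astype(int)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _log_fc_profile(
    trajectory: str, config: SimulationConfig
) -> np.ndarray:
    """Natural-log fold-change at each timepoint for one trajectory class.

    Early classes pulse: full effect at the first treated timepoint, half
    the log-fold-change decayed by the last. Late classes ramp from the
    second treated timepoint to the full effect at the end.
    """
    tps = config.timepoints
    k = len(tps)
    le = np.log(config.effect_size_early)
    ll = np.log(config.effect_size_late)
    prof = np.zeros(k)
    if trajectory in ("EarlyUp", "EarlyDown"):
        prof[1] = 1.0
        if k > 2:
            prof[2:] = np.linspace(1.0, 0.5, k - 1)[1:]
        prof = prof * le
        if trajectory == "EarlyDown":
            prof = -prof
    elif trajectory in ("LateUp", "LateDown"):
        if k > 2:
            prof[2:] = np.linspace(0.0, 1.0, k - 1)[1:]
        else:
            prof[-1] = 1.0
        prof = prof * ll
        if trajectory == "LateDown":
            prof = -prof
    return prof


def generate_expression(
    genes: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int = 0,
) -> ExpressionTimecourse:
    """NB counts per cell x gene over the timepoints, with planted classes.

    counts ~ NB(mean = lib_c * mu_g * FC_class(t), dispersion phi_g) with
    log-normal library factors (sd ``library_size_sd`` on the natural log).
    """
    missing = genes.index.difference(truth.table.index)
    if len(missing):
        raise ValueError(f"ground truth missing genes: {list(missing[:5])}")
    rng = np.random.default_rng(seed)
    tbl = truth.table.loc[genes.index]
    mu0 = tbl["true_mean_level"].to_numpy()
    phi = tbl["true_noise"].map(config.dispersions).to_numpy(dtype=float)
    profiles = {
        cls: np.exp(_log_fc_profile(cls, config)) for cls in TRAJECTORY_CLASSES
    }
    fc = np.stack([profiles[t] for t in tbl["true_trajectory"]])  # genes x tps

    blocks = []
    meta_rows = []
    n_cells = config.n_cells_per_timepoint
    r = 1.0 / phi  # NB size parameter per gene
    for ti, t in enumerate(config.timepoints):
        lib = rng.lognormal(0.0, config.library_size_sd, size=n_cells)
        mean = np.outer(lib, mu0 * fc[:, ti])
        p = r / (r + mean)
        counts = rng.negative_binomial(np.broadcast_to(r, mean.shape), p)
        blocks.append(counts)
        meta_rows.extend(
            {"cell_id": f"cell_{t:g}h_{i:05d}", "timepoint": float(t)}
            for i in range(n_cells)
        )
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    return ExpressionTimecourse(
        counts=np.vstack(blocks).astype(np.int64),
        cell_meta=meta,
        gene_ids=pd.Index(genes.index, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(
    curves: Mapping[str, Callable[[float], float]],
    timepoints: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0),
    n_reps: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    control_condition: str | None = None,
    reference_gene: str = "REF",
    target_gene: str = "TARGET",
    reference_ct: float = 20.0,
    baseline_dct: float = 5.0,
) -> pd.DataFrame:
    """Ct table whose ΔΔCt analysis recovers the given expression curves.

    ``curves`` maps condition name -> relative-expression function of time
    (relative to the control condition at 0 h, so the control curve should
    be 1 at t = 0). Gaussian Ct noise with sd ``noise_sd`` is added to every
    well independently.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if control_condition is None:
        control_condition = next(iter(curves))
    if control_condition not in curves:
        raise ValueError(f"control condition {control_condition!r} has no curve")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, curve in curves.items():
        for rep in range(1, n_reps + 1):
            for t in timepoints:
                y = float(curve(float(t)))
                if y <= 0:
                    raise ValueError(
                        f"curve for {condition!r} must be positive (t={t}: {y})"
                    )
                rows.append(
                    {
                        "condition": condition, "replicate": rep, "hours": float(t),
                        "gene": reference_gene,
                        "ct": reference_ct + rng.normal(0.0, noise_sd),
                    }
                )
                rows.append(
                    {
                        "condition": condition, "replicate": rep, "hours": float(t),
                        "gene": target_gene,
                        "ct": reference_ct + baseline_dct - np.log2(y)
                        + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dedicated generators for ranking / co-expression checks
# ---------------------------------------------------------------------------

def generate_feature_matrix(
    n_instances: int = 1000,
    n_informative: int = 5,
    n_noise: int = 20,
    n_classes: int = 3,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian features with a planted class shift on the informative ones.

    Informative feature j has mean ``effect * (k - (K-1)/2)`` in class k;
    noise features are standard normal. Classes are balanced.
    """
    rng = np.random.default_rng(seed)
    y = np.array(
        [f"C{i % n_classes}" for i in range(n_instances)], dtype=object
    )
    rng.shuffle(y)
    k_idx = np.array([int(label[1:]) for label in y], dtype=float)
    centered = k_idx - (n_classes - 1) / 2.0
    cols = {}
    for j in range(n_informative):
        cols[f"inf_{j}"] = effect * centered + rng.normal(0, 1, n_instances)
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.normal(0, 1, n_instances)
    X = pd.DataFrame(cols)
    return X, pd.Series(y, name="label")


def generate_coexpression_counts(
    n_pairs: int = 200,
    loading: float = 0.5,
    n_cells: int = 500,
    dispersion: float = 0.5,
    seed: int = 0,
):
    """Paired genes driven by a shared per-cell latent factor.

    Each of ``n_pairs`` pairs shares one standard-normal factor per cell;
    both members multiply their NB mean by ``exp(loading * factor)``. With
    ``loading=0`` the genes are independent (the null). Returns the
    log-normalized cells x genes matrix and the planted pair set.
    """
    from .coexpr import GenePairSet  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n_genes = 2 * n_pairs
    width = len(str(max(n_genes - 1, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    base = rng.lognormal(np.log(1.0), 0.5, size=n_genes)
    factors = rng.normal(0, 1, size=(n_cells, n_pairs))
    factor_per_gene = np.repeat(factors, 2, axis=1)  # pair k -> genes 2k, 2k+1
    mean = base[None, :] * np.exp(loading * factor_per_gene)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    norm = np.log1p(1e4 * counts / totals)
    matrix = pd.DataFrame(
        norm, columns=gene_ids,
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    pairs = GenePairSet(
        [(gene_ids[2 * k], gene_ids[2 * k + 1]) for k in range(n_pairs)],
        "SharedEnhancer",
    )
    return matrix, pairs


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------

def write_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_signal(signal: pd.DataFrame, path: str | Path) -> None:
    signal.to_csv(path, sep="\t")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    out = truth.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_counts(
    tc: ExpressionTimecourse, mtx_path: str | Path,
    cells_path: str | Path, genes_path: str | Path,
) -> None:
    """Write counts as MTX (genes x cells) with cell/gene metadata TSVs."""
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(tc.counts.T))
    meta = tc.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(cells_path, sep="\t")
    pd.DataFrame(index=pd.Index(tc.gene_ids, name="gene_id")).to_csv(
        genes_path, sep="\t"
    )


def write_all(outdir: str | Path, config: SimulationConfig, seed: int = 0) -> dict:
    """Generate one full synthetic study and write every input file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = generate_annotation(config.n_genes, seed=int(rng.integers(2**31)))
    truth = assign_ground_truth(genes, config, seed=int(rng.integers(2**31)))
    arch = generate_architecture(
        genes, config, seed=int(rng.integers(2**31)), truth=truth
    )
    tc = generate_expression(genes, arch.truth, config, seed=int(rng.integers(2**31)))
    write_annotation(genes, outdir / "annotation.tsv")
    write_loops(arch.loops, outdir / "loops.tsv")
    write_bed(arch.h3k27ac_peaks, outdir / "h3k27ac.bed")
    write_bed(arch.er_peaks, outdir / "er.bed")
    write_signal(arch.signal, outdir / "signal.tsv")
    write_truth(arch.truth, outdir / "truth.tsv")
    write_counts(
        tc, outdir / "counts.mtx", outdir / "cells.tsv", outdir / "genes.tsv"
    )
    return {
        "genes": genes, "architecture": arch, "timecourse": tc,
        "paths": sorted(str(p) for p in outdir.iterdir()),
    }
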