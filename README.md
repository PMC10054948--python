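# estro

Cis-regulatory architecture and the **level**, **timing**, and **noise** of
the estrogen transcriptional response.

When hormone-responsive cells (e.g. ER-positive endometrial or breast cancer
lines) are treated with 17β-estradiol (E2), hundreds of genes change
expression — some within 2 hours with a pulse-like response ("Early"
genes), others gradually over 8 hours ("Late" genes) — and genes differ
widely in cell-to-cell expression noise. `estro` implements a pipeline that
asks which features of a gene's cis-regulatory repertoire (promoter signal,
the number and strength of loop-connected enhancers, ER binding) predict
each of these three attributes, plus the downstream analyses that probe the
conclusions: qPCR-based perturbation timing and single-cell co-expression of
looped gene pairs.

It is aimed at computational biologists analyzing single-cell hormone
time-course experiments together with ChIP-seq/HiChIP regulatory maps. A
synthetic-data generator with planted ground truth makes the whole pipeline
testable without any external data.

## The statistics at the core

**Enhancer score.** For a gene with *n* linked enhancers (H3K27ac peaks
inside HiChIP loop anchors whose partner anchor touches the 500 bp
promoter; loops kept only with ≥ 3 reads and FDR < 0.05), each assay's
aggregate enhancer activity is

&nbsp;&nbsp;&nbsp;&nbsp;score = Σᵢ₌₁ⁿ log₂(sᵢ + 1)

where sᵢ is the Z-score of integrated assay signal at enhancer *i*
(standardized across all enhancers). Z-scores below −1 are clamped at −0.99
so the logarithm stays defined.

**Trajectory classes.** Per-gene two-sided Wilcoxon rank-sum tests of each
treated timepoint against 0 h on log-normalized counts
(ln(1 + 10⁴·x/library)), BH-corrected per timepoint, no fold-change cutoff.
Significant at 2 h → EarlyUp/EarlyDown; first significant at 4 or 8 h →
LateUp/LateDown. Mean-matched Control genes are drawn by stratified
sampling from the unlabeled genes.

**Adjusted CV (noise).** A GAM (cubic B-spline smooth) of log₂(CV + 1) on
mean expression at 0 h; the back-transformed residual 2^r − 1 is a
mean-corrected noise statistic. Genes are labeled High/Mid/Low as the
top/bottom 20% of adjusted CV within ten equal-frequency mean bins.

**Feature ranking.** A Boruta-style shadow-feature algorithm: each
iteration appends an independently shuffled copy of every surviving
feature, fits a random forest, scores a "hit" when a real feature's
held-out permutation importance beats the best shadow, and decides
Confirmed/Rejected by Bonferroni-corrected binomial tests of the hit counts
against Binomial(n, ½) (up to 100 iterations).

**Perturbation timing.** ΔΔCt relative expression
(2^−ΔΔCt, reference gene and control condition at 0 h as baseline), loess
(local quadratic, tricube weights, span 0.75) on a 0.1 h grid, and the time
to half-maximal response: the first grid time at which the fitted curve
reaches half of its maximum fitted value.

**Co-expression.** Pairwise Spearman correlation across the cells of one
timepoint for promoter-looped or shared-enhancer gene pairs, against a
derangement-style shuffled-pair null, compared with Bonferroni-corrected
Wilcoxon tests.

## Worked example

End-to-end on synthetic data (2,000 genes, 500 cells per timepoint at
0/2/4/8 h, full architecture–class coupling):

```python
from estro.simulate import (SimulationConfig, generate_annotation,
                            assign_ground_truth, generate_architecture,
                            generate_expression)
from estro.regions import define_promoters, filter_loops, assign_enhancers
from estro.features import build_feature_table
from estro.dynamics import run_dynamics
from estro.ranking import boruta_rank

cfg = SimulationConfig(n_genes=2000, n_cells_per_timepoint=500)
genes = generate_annotation(cfg.n_genes, seed=1)
truth = assign_ground_truth(genes, cfg, seed=2)
arch = generate_architecture(genes, cfg, seed=3, truth=truth)
tc = generate_expression(genes, arch.truth, cfg, seed=4)

loops = filter_loops(arch.loops)              # 5025 loops -> 3983 kept
reg = assign_enhancers(define_promoters(genes), loops,
                       arch.h3k27ac_peaks, er_peaks=arch.er_peaks)
features = build_feature_table(reg, arch.signal, genes, context_label="simA")
labels = run_dynamics(tc, seed=5)
lab = labels[labels.trajectory != "Unlabeled"]
res = boruta_rank(features.loc[lab.index.intersection(features.index)],
                  lab["trajectory"], analysis="trajectory", seed=6)
print(res.to_frame().sort_values("mean_importance", ascending=False).head(6))
```

prints (seeds as above):

```
                       decision  mean_importance  n_hits  n_iter
feature
promoter_SIN3A        Confirmed           0.1174      76      76
n_erbs                Confirmed           0.0560      76      76
enhancer_score_ER     Confirmed           0.0269      67      76
promoter_FOXA1         Rejected           0.0043      26      76
enhancer_score_FOXA1   Rejected           0.0007       1      76
gene_length            Rejected           0.0007       3      76
```

The three confirmed features are exactly the ones the generator coupled to
the trajectory classes: SIN3A promoter signal marks the planted LateUp
genes, while the number of ER-bound enhancers and the ER enhancer score
mark the planted EarlyUp genes. Trajectory labels themselves recover 95% of
the planted EarlyUp genes, and the class breakdown printed by
`run_dynamics` (98–111 genes per regulated class, 418 mean-matched
controls) reflects the planted 5%-per-class design.

The same stages are available from the shell, e.g.:

```sh
estro simulate --outdir sim --n-genes 2000 --n-cells 500 --seed 1
estro features build --annotation sim/annotation.tsv --loops sim/loops.tsv \
      --h3k27ac sim/h3k27ac.bed --er sim/er.bed --signal sim/signal.tsv \
      --out features.tsv
estro dynamics run --counts sim/counts.mtx --cells sim/cells.tsv \
      --genes sim/genes.tsv --out labels.tsv --seed 5
estro rank --features features.tsv --labels labels.tsv --target trajectory \
      --out importance.tsv --seed 6
```

## Layout

| module | contents |
| --- | --- |
| `estro.simulate` | synthetic annotation, architecture, counts, qPCR generators |
| `estro.regions` | intervals, loops, promoter windows, enhancer assignment |
| `estro.features` | Z-scoring, enhancer scores, gene×feature table |
| `estro.dynamics` | QC, normalization, trajectory calls, adjusted-CV noise |
| `estro.ranking` | `BorutaSelector`, group summaries, CART tree, profile PCA |
| `estro.timing` | ΔΔCt, loess fits, half-max times, slope aggregation |
| `estro.coexpr` | gene pairs, shuffled nulls, Spearman analyses |
| `estro.cli` | the `estro` command-line interface |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
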