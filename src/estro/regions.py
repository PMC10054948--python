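"""Genomic intervals, chromatin loops, and enhancer-promoter assignment.

All coordinates are 0-based, half-open ``[start, end)``. Overlap everywhere in
this package means >= 1 bp intersection. Enhancers are H3K27ac peaks that sit
inside a HiChIP loop anchor whose partner anchor touches the gene's promoter;
loops are pre-filtered on read support and FDR before assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Loop:
    """A chromatin loop between two anchors, with read support and FDR."""

    anchor_a: GenomicRegion
    anchor_b: GenomicRegion
    reads: int
    fdr: float

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValueError("loop read count must be non-negative")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("loop FDR must be in [0, 1]")


@dataclass
class RegulatoryMap:
    """Per-gene promoter plus the linked enhancer repertoire.

    ``enhancers[g]`` lists deduplicated enhancer peaks looped to gene ``g``'s
    promoter; ``er_overlap[g]`` is a parallel list of booleans marking which
    of them overlap an ER ChIP-seq peak (ERBS).
    """

    promoters: dict[str, GenomicRegion]
    enhancers: dict[str, list[GenomicRegion]] = field(default_factory=dict)
    er_overlap: dict[str, list[bool]] = field(default_factory=dict)

    def n_enhancers(self, gene_id: str) -> int:
        return len(self.enhancers.get(gene_id, []))

    def n_erbs(self, gene_id: str) -> int:
        return sum(self.er_overlap.get(gene_id, []))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.promoters)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read a BED3/BED4 file into regions (0-based half-open)."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else None
            try:
                regions.append(GenomicRegion(fields[0], start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


_LOOP_COLUMNS = ("chrom1", "start1", "end1", "chrom2", "start2", "end2", "reads", "fdr")


def read_loops(path: str | Path) -> list[Loop]:
    """Read a BEDPE-like loop table (chrom1..end2, reads, fdr; optional header)."""
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == _LOOP_COLUMNS[0]:  # header row
                continue
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 loop fields")
            try:
                loop = Loop(
                    GenomicRegion(fields[0], int(fields[1]), int(fields[2])),
                    GenomicRegion(fields[3], int(fields[4]), int(fields[5])),
                    reads=int(fields[6]),
                    fdr=float(fields[7]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            loops.append(loop)
    return loops


def write_loops(loops: Iterable[Loop], path: str | Path) -> None:
    rows = [
        (
            lp.anchor_a.chrom, lp.anchor_a.start, lp.anchor_a.end,
            lp.anchor_b.chrom, lp.anchor_b.start, lp.anchor_b.end,
            lp.reads, lp.fdr,
        )
        for lp in loops
    ]
    pd.DataFrame(rows, columns=list(_LOOP_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.id if r.id is not None else f"region_{i}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, tss, strand, length)."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand", "length"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    return ann.set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# loop filtering and enhancer assignment
# ---------------------------------------------------------------------------

def filter_loops(
    loops: Iterable[Loop], min_reads: int = 3, max_fdr: float = 0.05
) -> list[Loop]:
    """Keep loops with reads >= min_reads and fdr < max_fdr.

    Defaults follow the HiChIP processing rule that drops loops with fewer
    than 3 supporting reads or FDR >= 0.05.
    """
    return [lp for lp in loops if lp.reads >= min_reads and lp.fdr < max_fdr]


def define_promoters(
    genes: pd.DataFrame, width: int = 500
) -> dict[str, GenomicRegion]:
    """Promoter = ``width`` bp centered on the TSS, clipped at coordinate 0."""
    promoters: dict[str, GenomicRegion] = {}
    half = width // 2
    for gene_id, row in genes.iterrows():
        tss = int(row["tss"])
        start = max(0, tss - half)
        promoters[str(gene_id)] = GenomicRegion(
            str(row["chrom"]), start, tss + (width - half), id=str(gene_id)
        )
    return promoters


def _build_tree(regions: Iterable[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, (i, r))
    return trees


def _query(trees: Mapping[str, IntervalTree], region: GenomicRegion):
    tree = trees.get(region.chrom)
    if tree is None:
        return []
    return [iv.data for iv in tree.overlap(region.start, region.end)]


def assign_enhancers(
    promoters: Mapping[str, GenomicRegion],
    filtered_loops: Iterable[Loop],
    h3k27ac_peaks: Iterable[GenomicRegion],
    er_peaks: Iterable[GenomicRegion] | None = None,
) -> RegulatoryMap:
    """Link enhancers to genes through loop anchors.

    For every gene, loops with >= 1 bp anchor overlap with the promoter are
    collected; H3K27ac peaks overlapping the partner anchor become that gene's
    enhancers. Peaks reachable through several loops are counted once, and
    peaks overlapping the gene's own promoter are excluded. If ``er_peaks``
    is given, each enhancer is flagged for ER-peak overlap (ERBS).
    """
    loops = list(filtered_loops)
    peak_trees = _build_tree(h3k27ac_peaks)
    er_trees = _build_tree(er_peaks) if er_peaks is not None else {}

    anchor_tree: dict[str, IntervalTree] = {}
    for li, lp in enumerate(loops):
        for which, anchor in ((0, lp.anchor_a), (1, lp.anchor_b)):
            anchor_tree.setdefault(anchor.chrom, IntervalTree()).addi(
                anchor.start, anchor.end, (li, which)
            )

    reg = RegulatoryMap(promoters=dict(promoters))
    for gene_id, prom in promoters.items():
        seen: set[tuple[str, int, int]] = set()
        enhancers: list[GenomicRegion] = []
        for li, which in sorted(_query(anchor_tree, prom)):
            partner = loops[li].anchor_b if which == 0 else loops[li].anchor_a
            for _, peak in sorted(_query(peak_trees, partner)):
                key = (peak.chrom, peak.start, peak.end)
                if key in seen or peak.overlaps(prom):
                    continue
                seen.add(key)
                enhancers.append(peak)
        enhancers.sort(key=lambda r: (r.chrom, r.start, r.end))
        reg.enhancers[gene_id] = enhancers
        if er_peaks is not None:
            reg.er_overlap[gene_id] = [
                bool(_query(er_trees, e)) for e in enhancers
            ]
        else:
            reg.er_overlap[gene_id] = [False] * len(enhancers)
    return reg


def count_erbs(
    reg_map: RegulatoryMap, er_peaks: Iterable[GenomicRegion]
) -> dict[str, int]:
    """Number of linked enhancers overlapping an ER ChIP-seq peak, per gene."""
    er_trees = _build_tree(er_peaks)
    counts: dict[str, int] = {}
    for gene_id, enhancers in reg_map.enhancers.items():
        flags = [bool(_query(er_trees, e)) for e in enhancers]
        reg_map.er_overlap[gene_id] = flags
        counts[gene_id] = sum(flags)
    return counts
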