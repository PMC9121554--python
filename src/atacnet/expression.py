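"""Integration of condition-specific open chromatin with expression changes.

Links peaks to the genes whose transcript span they overlap and selects the
genes whose significant expression change is concordant with the supplied
condition-specific peak set (e.g. upregulated genes carrying a peak open
only in the same condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalSet, intersect

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene differential-expression summary (condition A versus B)."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"{self.gene_id}: padj must be in [0, 1]")


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    overlap: int
    link_type: str = "body"  # body | promoter | enhancer_assoc | super_enhancer

    def __post_init__(self) -> None:
        if self.link_type in ("body", "promoter") and self.overlap < 1:
            raise ValueError("body/promoter links require >=1 bp overlap")


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with header columns gene_id, log2fc, padj (case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("gene_id", "log2fc", "padj") if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    return [
        ExpressionRecord(str(r[cols["gene_id"]]), float(r[cols["log2fc"]]), float(r[cols["padj"]]))
        for _, r in df.iterrows()
    ]


def write_expression_table(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.padj:.6g}\n")


def link_peaks_to_gene_bodies(
    peaks: IntervalSet, genes: Sequence[GeneModel]
) -> list[PeakGeneLink]:
    """One link per (peak, gene) pair whose transcript spans share >=1 bp.

    A peak spanning several genes yields several links.  Peaks must carry
    unique names.
    """
    bodies = IntervalSet(
        [
            GenomicInterval(g.chrom, g.body.start, g.body.end, name=g.gene_id, strand=g.strand)
            for g in genes
        ],
        label="gene_bodies",
    )
    return [
        PeakGeneLink(p.name, b.name, ov, "body")
        for p, b, ov in intersect(peaks, bodies)
    ]


def select_concordant_genes(
    links: Iterable[PeakGeneLink],
    expression: Sequence[ExpressionRecord],
    direction: str = "up",
    alpha: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Genes with a significant expression change in ``direction`` and >=1 link.

    direction ``up`` requires ``log2fc > 0``; ``down`` requires
    ``log2fc < 0``; both require ``padj < alpha``.  Linked genes absent from
    the expression table are logged and excluded.

    Returns the selected gene set and a per-gene report with supporting peak
    ids (semicolon-joined), log2fc and padj.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not expression:
        raise ValueError("empty expression table")
    by_gene = {r.gene_id: r for r in expression}
    support: dict[str, list[str]] = {}
    missing: set[str] = set()
    for link in links:
        if link.gene_id not in by_gene:
            missing.add(link.gene_id)
            continue
        support.setdefault(link.gene_id, []).append(link.peak_id)
    if missing:
        logger.info("%d linked gene(s) absent from expression table; excluded", len(missing))
    rows = []
    for gene_id, peak_ids in sorted(support.items()):
        rec = by_gene[gene_id]
        concordant = rec.log2fc > 0 if direction == "up" else rec.log2fc < 0
        if concordant and rec.padj < alpha:
            rows.append(
                {
                    "gene_id": gene_id,
                    "log2fc": rec.log2fc,
                    "padj": rec.padj,
                    "n_peaks": len(set(peak_ids)),
                    "peak_ids": ";".join(sorted(set(peak_ids))),
                }
            )
    report = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "n_peaks", "peak_ids"])
    return set(report["gene_id"]), report
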