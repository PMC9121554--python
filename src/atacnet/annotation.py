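"""Peak annotation against gene models.

Classifies open-chromatin peaks into promoter / exon / intron / intergenic
and reports category proportions.  The promoter window defaults to 2 kb
upstream through 1 kb downstream of the TSS, applied strand-aware; the four
categories are assigned with promoter-first precedence so every peak gets
exactly one label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, intersect, merge, subtract

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """A single transcript model: body span, exon blocks, strand and TSS.

    The TSS is the body start on the ``+`` strand and the last covered base
    (``body.end - 1``) on the ``-`` strand.
    """

    gene_id: str
    chrom: str
    strand: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for ex in self.exons:
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside body")
        starts = sorted((ex.start, ex.end) for ex in self.exons)
        for (s1, e1), (s2, _) in zip(starts, starts[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


@dataclass(frozen=True)
class AnnotationConfig:
    """Promoter window sizes (bp) and category precedence."""

    promoter_upstream: int = 2000
    promoter_downstream: int = 1000
    precedence: tuple[str, ...] = ("promoter", "exon", "intron", "intergenic")

    def __post_init__(self) -> None:
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter windows must be >= 0")
        if sorted(self.precedence) != sorted(CATEGORIES):
            raise ValueError(f"precedence must be a permutation of {CATEGORIES}")


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file (one transcript per line).

    Duplicate gene ids are collapsed to the model with the longest body,
    with a log message, so downstream code sees one model per gene.
    """
    path = Path(path)
    models: dict[str, GeneModel] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            try:
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 line: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            body = GenomicInterval(chrom, start, end, name=name, strand=strand)
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + sz, name=name, strand=strand)
                for off, sz in zip(offsets, sizes)
            )
            model = GeneModel(name, chrom, strand, body, exons)
            if name in models:
                n_dup += 1
                if model.body.length <= models[name].body.length:
                    continue
            models[name] = model
    if n_dup:
        logger.info("%s: collapsed %d duplicate gene id(s) to longest body", path, n_dup)
    return sorted(models.values(), key=lambda g: (g.chrom, g.body.start, g.gene_id))


def write_gene_models_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id)):
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(e.length) for e in exons)
            offsets = ",".join(str(e.start - g.body.start) for e in exons)
            fh.write(
                f"{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.body.start}\t{g.body.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def promoter_window(gene: GeneModel, cfg: AnnotationConfig = AnnotationConfig()) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at the origin.

    ``+`` strand: ``[tss - upstream, tss + downstream)``; ``-`` strand
    mirrored: ``[tss - downstream, tss + upstream)``.
    """
    if gene.strand == "+":
        start = gene.tss - cfg.promoter_upstream
        end = gene.tss + cfg.promoter_downstream
    else:
        start = gene.tss - cfg.promoter_downstream
        end = gene.tss + cfg.promoter_upstream
    start = max(0, start)
    if end <= start:
        end = start + 1  # degenerate zero-size window clipped at origin
    return GenomicInterval(gene.chrom, start, end, name=gene.gene_id, strand=gene.strand)


def promoter_set(genes: list[GeneModel], cfg: AnnotationConfig = AnnotationConfig()) -> IntervalSet:
    """Un-merged promoter windows for all genes (one per gene, named)."""
    return IntervalSet([promoter_window(g, cfg) for g in genes], label="promoters")


def build_annotation_index(
    genes: list[GeneModel], cfg: AnnotationConfig = AnnotationConfig()
) -> dict[str, IntervalSet]:
    """Feature space per category.

    intron space is defined literally as gene bodies minus exons minus
    promoter windows, so the three genic spaces are consistent whatever the
    precedence order.
    """
    promoters = merge(promoter_set(genes, cfg)) if genes else IntervalSet(label="promoters")
    exons = IntervalSet(
        [ex for g in genes for ex in g.exons], label="exons"
    )
    bodies = IntervalSet([g.body for g in genes], label="bodies")
    introns = subtract(subtract(bodies, exons), promoters)
    introns = merge(introns)
    introns.label = "introns"
    return {"promoter": promoters, "exon": merge(exons) if len(exons) else exons, "intron": introns}


def classify_peaks(
    peaks: IntervalSet,
    genes: list[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    index: dict[str, IntervalSet] | None = None,
) -> pd.Series:
    """Category per peak: first category in precedence order overlapped >=1 bp.

    Returns a Series indexed by peak name (peaks must carry unique names;
    anonymous peaks are auto-named by position).
    """
    if index is None:
        index = build_annotation_index(genes, cfg)
    names = [iv.name for iv in peaks]
    if len(set(names)) != len(names) or "" in names:
        peaks = peaks.with_names("peak")
        names = [iv.name for iv in peaks]
    result = pd.Series("intergenic", index=pd.Index(names, name="peak_id"), dtype=object)
    remaining = set(names)
    for category in cfg.precedence:
        if category == "intergenic" or not remaining:
            continue
        space = index[category]
        if not len(space):
            continue
        hit = {p.name for p, _, _ in intersect(peaks, space)}
        for name in hit & remaining:
            result[name] = category
        remaining -= hit
    return result


def classify_peak(
    peak: GenomicInterval,
    genes: list[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
    index: dict[str, IntervalSet] | None = None,
) -> str:
    """Classify a single peak (convenience wrapper over :func:`classify_peaks`)."""
    named = GenomicInterval(peak.chrom, peak.start, peak.end, name="query")
    return classify_peaks(IntervalSet([named]), genes, cfg, index=index).iloc[0]


def category_proportions(
    peaks: IntervalSet,
    genes: list[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Counts and fractions of peaks per genomic category.

    Raises on an empty peak set; fractions sum to 1 by construction.
    """
    if not len(peaks):
        raise ValueError("no peaks to annotate")
    labels = classify_peaks(peaks, genes, cfg)
    counts = labels.value_counts().reindex(list(CATEGORIES), fill_value=0)
    out = pd.DataFrame(
        {"category": counts.index, "count": counts.values, "fraction": counts.values / len(peaks)}
    ).reset_index(drop=True)
    return out
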