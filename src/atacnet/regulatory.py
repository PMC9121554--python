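"""Enhancer definition and region-to-gene association.

Enhancers are H3K27ac-marked intervals with promoter windows subtracted.
Regions (enhancers, super-enhancers) are assigned to genes with a
basal-plus-extension regulatory-domain rule: each gene owns a strand-aware
basal domain around its TSS (default 5 kb upstream / 1 kb downstream),
extended in both directions up to a maximum (default 1 Mb) but never into a
neighboring gene's basal domain.  A region is associated with every gene
whose regulatory domain it overlaps.

Super-enhancers are treated as inputs (a published catalog); this module
reports which of them contain condition-unique ATAC peaks and which of
their associated genes are transcriptionally upregulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GeneModel
from .expression import ExpressionRecord
from .intervals import GenomicInterval, IntervalSet, intersect, subtract

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRule:
    """Basal-plus-extension parameters (bp)."""

    basal_upstream: int = 5000
    basal_downstream: int = 1000
    extension: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.basal_upstream, self.basal_downstream, self.extension) < 0:
            raise ValueError("association distances must be >= 0")


@dataclass
class SuperEnhancerHit:
    se: GenomicInterval
    atac_peaks: list[str]
    linked_genes: list[str]
    upregulated: dict[str, bool]


def define_enhancers(h3k27ac: IntervalSet, promoters: IntervalSet) -> IntervalSet:
    """H3K27ac intervals minus promoter windows; empty remnants are dropped.

    ``subtract`` never emits zero-length intervals, so the result is simply
    the subtraction, relabelled.
    """
    enhancers = subtract(h3k27ac, promoters)
    enhancers.label = "enhancers"
    return enhancers


def _basal_domain(gene: GeneModel, rule: AssociationRule) -> tuple[int, int]:
    if gene.strand == "+":
        start = gene.tss - rule.basal_upstream
        end = gene.tss + rule.basal_downstream
    else:
        start = gene.tss - rule.basal_downstream
        end = gene.tss + rule.basal_upstream
    return max(0, start), max(max(0, start) + 1, end)


def regulatory_domains(
    genes: Sequence[GeneModel], rule: AssociationRule = AssociationRule()
) -> IntervalSet:
    """Per-gene regulatory domains (named by gene id).

    Each basal domain is extended left and right by at most
    ``rule.extension`` bp, truncating at the nearest neighboring basal
    domain; basal domains themselves are always kept even when neighbors
    overlap.
    """
    domains: list[GenomicInterval] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in sorted(by_chrom.items()):
        basal = sorted(
            ((_basal_domain(g, rule), g) for g in gs), key=lambda t: (t[0][0], t[0][1])
        )
        starts = [b[0][0] for b in basal]
        ends = [b[0][1] for b in basal]
        n = len(basal)
        # running bounds from neighboring basal domains
        prev_end_max = [0] * n
        run = 0
        for i in range(1, n):
            run = max(run, ends[i - 1])
            prev_end_max[i] = run
        next_start_min = [None] * n
        run2: int | None = None
        for i in range(n - 2, -1, -1):
            run2 = starts[i + 1] if run2 is None else min(run2, starts[i + 1])
            next_start_min[i] = run2
        for i, ((bs, be), g) in enumerate(basal):
            left = max(bs - rule.extension, prev_end_max[i])
            left = min(left, bs)  # basal domain always kept
            right = be + rule.extension
            if next_start_min[i] is not None:
                right = min(right, max(next_start_min[i], be))
            domains.append(
                GenomicInterval(chrom, max(0, left), right, name=g.gene_id, strand=g.strand)
            )
    return IntervalSet(domains, label="regulatory_domains")


def associate_regions_to_genes(
    regions: IntervalSet,
    genes: Sequence[GeneModel],
    rule: AssociationRule = AssociationRule(),
) -> dict[str, list[str]]:
    """Map each region name to the gene ids whose regulatory domain it overlaps.

    Regions must carry unique names (anonymous regions are auto-named by
    coordinate).  Regions overlapping no domain map to an empty list.
    """
    names = [iv.name for iv in regions]
    if len(set(names)) != len(names) or "" in names:
        regions = IntervalSet(
            [
                GenomicInterval(iv.chrom, iv.start, iv.end, name=str(iv), strand=iv.strand)
                for iv in regions
            ],
            label=regions.label,
        )
    domains = regulatory_domains(genes, rule)
    out: dict[str, list[str]] = {iv.name: [] for iv in regions}
    for region, domain, _ in intersect(regions, domains):
        out[region.name].append(domain.name)
    return {k: sorted(set(v)) for k, v in out.items()}


def overlap_super_enhancers(
    atac_unique: IntervalSet,
    super_enhancers: IntervalSet,
    genes: Sequence[GeneModel],
    expression: Sequence[ExpressionRecord],
    rule: AssociationRule = AssociationRule(),
    alpha: float = 0.05,
    se_gene_override: Mapping[str, Sequence[str]] | None = None,
) -> list[SuperEnhancerHit]:
    """Super-enhancers containing >=1 condition-unique ATAC peak.

    Each hit lists the contained peak ids, the genes associated with the
    super-enhancer (by the basal-plus-extension rule, or taken from
    ``se_gene_override`` — a catalog's own SE-to-gene assignment — when
    provided), and an upregulated flag per gene (``padj < alpha`` and
    ``log2fc > 0``).
    """
    ses = super_enhancers
    if any(not iv.name for iv in ses) or len({iv.name for iv in ses}) != len(ses):
        ses = ses.with_names("se")
    by_se: dict[str, list[str]] = {}
    for se, peak, _ in intersect(ses, atac_unique):
        by_se.setdefault(se.name, []).append(peak.name)
    if not by_se:
        return []
    assoc = associate_regions_to_genes(
        IntervalSet([iv for iv in ses if iv.name in by_se], label="se_hits"), genes, rule
    )
    expr = {r.gene_id: r for r in expression}
    hits: list[SuperEnhancerHit] = []
    for se in ses:
        if se.name not in by_se:
            continue
        if se_gene_override is not None and se.name in se_gene_override:
            linked = sorted(set(se_gene_override[se.name]))
        else:
            linked = assoc.get(se.name, [])
        upreg = {
            g: (g in expr and expr[g].padj < alpha and expr[g].log2fc > 0) for g in linked
        }
        hits.append(
            SuperEnhancerHit(
                se=se,
                atac_peaks=sorted(set(by_se[se.name])),
                linked_genes=linked,
                upregulated=upreg,
            )
        )
    return hits


def super_enhancer_report(hits: Sequence[SuperEnhancerHit]) -> pd.DataFrame:
    """Flat table: one row per (SE, gene), plus gene-less SE hits."""
    rows = []
    for h in hits:
        if not h.linked_genes:
            rows.append(
                {
                    "se_id": h.se.name,
                    "chrom": h.se.chrom,
                    "start": h.se.start,
                    "end": h.se.end,
                    "peak_ids": ";".join(h.atac_peaks),
                    "gene_id": "",
                    "upregulated": False,
                }
            )
        for g in h.linked_genes:
            rows.append(
                {
                    "se_id": h.se.name,
                    "chrom": h.se.chrom,
                    "start": h.se.start,
                    "end": h.se.end,
                    "peak_ids": ";".join(h.atac_peaks),
                    "gene_id": g,
                    "upregulated": h.upregulated[g],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["se_id", "chrom", "start", "end", "peak_ids", "gene_id", "upregulated"],
    )
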