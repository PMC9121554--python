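"""End-to-end two-condition analysis: peaks to regulatory network.

Chains the package's stages in the canonical order for each condition:

1. occupancy-based condition-unique peak calling from replicate peak sets,
2. peak-to-gene-body links and concordant-gene selection against the
   expression table (condition A pairs with upregulated genes, condition B
   with downregulated ones, since log2FC is A versus B),
3. scrambled-background motif fold-enrichment over the condition-unique
   peak sequences,
4. FIMO-style scans of those sequences for the enriched motifs and assembly
   of the bipartite TF-to-gene network,
5. super-enhancer overlap with upregulation flags.

The pipeline operates on a :class:`~atacnet.simulate.SyntheticDataset` or
on equivalent components loaded from files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, GeneModel, category_proportions
from .differential import call_unique_peaks
from .expression import ExpressionRecord, PeakGeneLink, link_peaks_to_gene_bodies, select_concordant_genes
from .intervals import IntervalSet
from .motifs import (
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_N_SHUFFLES,
    DEFAULT_P_THRESHOLD,
    PWM,
    MotifEnrichment,
    MotifHit,
    extract_sequences,
    fold_enrichment,
    motif_target_genes,
    scan,
)
from .network import RegulatoryNetwork, build_network
from .regulatory import AssociationRule, SuperEnhancerHit, overlap_super_enhancers
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)


@dataclass
class ConditionResult:
    condition: str
    unique_peaks: IntervalSet
    links: list[PeakGeneLink]
    selected_genes: set[str]
    gene_report: pd.DataFrame
    enrichments: dict[str, MotifEnrichment]
    hits: list[MotifHit]
    network: RegulatoryNetwork
    se_hits: list[SuperEnhancerHit]


@dataclass
class PipelineResult:
    shared_peaks: IntervalSet
    conditions: dict[str, ConditionResult]
    annotation: pd.DataFrame | None = None


def _condition_direction(cond_index: int) -> str:
    return "up" if cond_index == 0 else "down"


def run_pipeline(
    dataset: SyntheticDataset,
    pwms: Mapping[str, PWM],
    scan_p_threshold: float = DEFAULT_P_THRESHOLD,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    alpha: float = 0.05,
    association_rule: AssociationRule = AssociationRule(),
    shuffle_seed: int = 0,
    annotate: bool = False,
) -> PipelineResult:
    """Run the full analysis on a synthetic dataset.

    ``shuffle_seed`` drives only the background scrambles and is
    independent of the dataset's generation seed.  TF network nodes use the
    PWM's TF name, so heterodimer motifs stay single nodes.
    """
    cfg = dataset.config
    conds = [cfg.condition_a, cfg.condition_b]
    by_cond = {
        c: [dataset.sample_peaks[s.sample_id] for s in dataset.samples if s.condition == c]
        for c in conds
    }
    unique_a, unique_b, shared = call_unique_peaks(by_cond, mode="occupancy")
    unique = {conds[0]: unique_a, conds[1]: unique_b}

    seed_root = np.random.SeedSequence(shuffle_seed)
    children = iter(seed_root.spawn(2 * len(pwms)))

    results: dict[str, ConditionResult] = {}
    for ci, cond in enumerate(conds):
        peaks = unique[cond]
        seqs = extract_sequences(dataset.genome, peaks)
        enrichments: dict[str, MotifEnrichment] = {}
        for motif_id in sorted(pwms):
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            enrichments[motif_id] = fold_enrichment(
                pwms[motif_id],
                seqs,
                n_shuffles=n_shuffles,
                p_threshold=scan_p_threshold,
                fold_threshold=fold_threshold,
                seed=child_seed,
            )
        enriched_ids = [m for m, e in sorted(enrichments.items()) if e.enriched]
        links = link_peaks_to_gene_bodies(peaks, dataset.genes)
        selected, report = select_concordant_genes(
            links, dataset.expression, direction=_condition_direction(ci), alpha=alpha
        )
        hits: list[MotifHit] = []
        for motif_id in enriched_ids:
            hits.extend(scan(pwms[motif_id], seqs, p_threshold=scan_p_threshold))
        # network nodes keyed by TF name (heterodimers remain one node)
        tf_of = {m: pwms[m].tf_name for m in pwms}
        hits_by_tf = [
            MotifHit(tf_of[h.motif_id], h.peak_id, h.offset, h.strand, h.score, h.pvalue)
            for h in hits
        ]
        tf_gene_sets = motif_target_genes(hits_by_tf, links, selected)
        net = build_network(
            tf_gene_sets,
            enriched_tfs=[tf_of[m] for m in enriched_ids],
            condition_label=cond,
        )
        se_hits = overlap_super_enhancers(
            peaks,
            dataset.super_enhancers,
            dataset.genes,
            dataset.expression,
            rule=association_rule,
            alpha=alpha,
        )
        results[cond] = ConditionResult(
            condition=cond,
            unique_peaks=peaks,
            links=links,
            selected_genes=selected,
            gene_report=report,
            enrichments=enrichments,
            hits=hits,
            network=net,
            se_hits=se_hits,
        )

    annotation = None
    if annotate and len(unique_a):
        annotation = category_proportions(unique_a, dataset.genes, AnnotationConfig())
    return PipelineResult(shared_peaks=shared, conditions=results, annotation=annotation)


# ---------------------------------------------------------------------------
# truth-recovery scoring (used by tests and the acceptance script)
# ---------------------------------------------------------------------------

def _interval_keys(peaks: IntervalSet) -> set[tuple[str, int, int]]:
    return {(iv.chrom, iv.start, iv.end) for iv in peaks}


def score_unique_peak_recovery(
    dataset: SyntheticDataset, unique: IntervalSet, condition: str
) -> dict[str, float]:
    """Recall/precision of called condition-unique peaks against truth.

    A truth peak counts as recovered when some called unique interval
    overlaps it by >=1 bp; a called interval is correct when it overlaps a
    truth peak of that condition.
    """
    from .intervals import intersect

    truth = dataset.true_peaks(condition)
    hit_truth = {t.name for _, t, _ in intersect(unique, truth)}
    hit_called = {u.name for u, _, _ in intersect(unique, truth)}
    recall = len(hit_truth) / len(truth) if len(truth) else float("nan")
    precision = len(hit_called) / len(unique) if len(unique) else float("nan")
    return {"recall": recall, "precision": precision}


def truth_edges(dataset: SyntheticDataset, pwms: Mapping[str, PWM]) -> set[tuple[str, str]]:
    """(TF name, gene) pairs implied by the generator's implant + coupling truth."""
    tf_of = {m: pwms[m].tf_name for m in pwms}
    edges = set()
    for row in dataset.truth_peaks.itertuples():
        if row.motif_id and row.linked_gene and row.linked_gene in dataset.flagged_genes:
            edges.add((tf_of.get(row.motif_id, row.motif_id), row.linked_gene))
    return edges


def score_network_recovery(
    dataset: SyntheticDataset,
    result: PipelineResult,
    pwms: Mapping[str, PWM],
) -> dict[str, float]:
    """Edge precision/recall of the condition-A network against truth edges."""
    cond_a = dataset.config.condition_a
    net = result.conditions[cond_a].network
    found = {(u, v) for u, v, _ in net.edges}
    truth = truth_edges(dataset, pwms)
    tp = len(found & truth)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {"precision": precision, "recall": recall, "n_truth": len(truth), "n_found": len(found)}


def score_concordant_genes(dataset: SyntheticDataset, result: PipelineResult) -> dict[str, float]:
    """Precision/recall of selected upregulated genes versus coupling truth."""
    cond_a = dataset.config.condition_a
    selected = result.conditions[cond_a].selected_genes
    truth = {
        row.linked_gene
        for row in dataset.truth_peaks.itertuples()
        if row.linked_gene and row.condition == cond_a
    }
    tp = len(selected & truth)
    precision = tp / len(selected) if selected else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {"precision": precision, "recall": recall}
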