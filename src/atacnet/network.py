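"""Bipartite TF-to-target regulatory network from motif hits.

Nodes are enriched TF motifs and the upregulated genes whose
condition-specific peaks contain those motifs; each edge pools its
peak-level evidence (peak id, hit offset, strand).  Heterodimer motif ids
(e.g. ``FOSL1::JUN``) are single TF nodes.  Hubs are reported as an
out-degree ranking — a descriptive summary, not a statistical test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

Evidence = tuple[str, int, str]  # (peak id, hit offset, strand)


@dataclass
class RegulatoryNetwork:
    """Bipartite TF -> gene graph with peak-level evidence per edge."""

    graph: nx.DiGraph
    condition_label: str = ""

    @property
    def tf_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tf")

    @property
    def gene_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene")

    @property
    def edges(self) -> list[tuple[str, str, list[Evidence]]]:
        return sorted(
            (u, v, d["evidence"]) for u, v, d in self.graph.edges(data=True)
        )

    def targets(self, tf: str) -> set[str]:
        return set(self.graph.successors(tf))

    def __len__(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    tf_gene_sets: Mapping[str, Mapping[str, Sequence[Evidence]]],
    enriched_tfs: Sequence[str],
    condition_label: str = "",
) -> RegulatoryNetwork:
    """Assemble the network from per-TF target maps, keeping enriched TFs only.

    ``tf_gene_sets`` maps motif/TF id -> gene id -> evidence records.  TFs
    absent from ``enriched_tfs`` are dropped entirely; isolated nodes never
    appear because edges are the only way in.  An empty result logs a
    warning rather than raising.
    """
    g = nx.DiGraph()
    enriched = set(enriched_tfs)
    for tf in sorted(tf_gene_sets):
        if tf not in enriched:
            continue
        for gene in sorted(tf_gene_sets[tf]):
            evidence = sorted(tf_gene_sets[tf][gene])
            if not evidence:
                continue
            g.add_node(tf, kind="tf")
            g.add_node(gene, kind="gene")
            g.add_edge(tf, gene, evidence=list(evidence), n_peaks=len({e[0] for e in evidence}))
    if g.number_of_edges() == 0:
        logger.warning("network %s is empty", condition_label or "(unlabelled)")
    return RegulatoryNetwork(graph=g, condition_label=condition_label)


def tf_overlap(network: RegulatoryNetwork) -> pd.DataFrame:
    """Pairwise shared-target counts and Jaccard indices, descending Jaccard.

    Empty for networks with fewer than two TFs.
    """
    tfs = network.tf_nodes
    rows = []
    for i, t1 in enumerate(tfs):
        for t2 in tfs[i + 1 :]:
            s1, s2 = network.targets(t1), network.targets(t2)
            union = s1 | s2
            shared = len(s1 & s2)
            rows.append(
                {
                    "tf1": t1,
                    "tf2": t2,
                    "shared": shared,
                    "jaccard": shared / len(union) if union else 0.0,
                }
            )
    df = pd.DataFrame(rows, columns=["tf1", "tf2", "shared", "jaccard"])
    return df.sort_values(["jaccard", "tf1", "tf2"], ascending=[False, True, True]).reset_index(
        drop=True
    )


def hub_ranking(network: RegulatoryNetwork) -> pd.DataFrame:
    """TFs ranked by out-degree (number of target genes)."""
    rows = [
        {"tf": tf, "out_degree": network.graph.out_degree(tf)} for tf in network.tf_nodes
    ]
    df = pd.DataFrame(rows, columns=["tf", "out_degree"])
    return df.sort_values(["out_degree", "tf"], ascending=[False, True]).reset_index(drop=True)


FORMATS = ("graphml", "sif", "tsv")


def export_network(
    network: RegulatoryNetwork,
    outdir: str | Path,
    formats: Sequence[str] = FORMATS,
    basename: str = "network",
) -> list[Path]:
    """Write the network as GraphML, SIF and/or node+edge TSV files.

    Evidence records are serialized on GraphML edges as a semicolon-joined
    string (GraphML attributes cannot hold lists); re-reading the GraphML
    reproduces the same edge set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "graphml":
            g = nx.DiGraph()
            for n, d in network.graph.nodes(data=True):
                g.add_node(n, kind=d.get("kind", ""))
            for u, v, d in network.graph.edges(data=True):
                g.add_edge(
                    u,
                    v,
                    n_peaks=d.get("n_peaks", 0),
                    evidence=";".join(f"{p}:{o}:{s}" for p, o, s in d.get("evidence", [])),
                )
            path = outdir / f"{basename}.graphml"
            nx.write_graphml(g, path)
            written.append(path)
        elif fmt == "sif":
            path = outdir / f"{basename}.sif"
            with open(path, "w") as fh:
                for u, v, _ in network.edges:
                    fh.write(f"{u}\tregulates\t{v}\n")
            written.append(path)
        elif fmt == "tsv":
            nodes = pd.DataFrame(
                [
                    {"id": n, "type": d.get("kind", ""), "degree": network.graph.degree(n)}
                    for n, d in sorted(network.graph.nodes(data=True))
                ],
                columns=["id", "type", "degree"],
            )
            edges = pd.DataFrame(
                [
                    {"tf": u, "gene": v, "n_peaks": d.get("n_peaks", 0)}
                    for u, v, d in sorted(network.graph.edges(data=True))
                ],
                columns=["tf", "gene", "n_peaks"],
            )
            npath = outdir / f"{basename}.nodes.tsv"
            epath = outdir / f"{basename}.edges.tsv"
            nodes.to_csv(npath, sep="\t", index=False)
            edges.to_csv(epath, sep="\t", index=False)
            written.extend([npath, epath])
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written


def read_graphml(path: str | Path, condition_label: str = "") -> RegulatoryNetwork:
    """Read a network written by :func:`export_network` back from GraphML."""
    g = nx.read_graphml(path)
    out = nx.DiGraph()
    for n, d in g.nodes(data=True):
        out.add_node(n, kind=d.get("kind", ""))
    for u, v, d in g.edges(data=True):
        evidence = []
        for token in str(d.get("evidence", "")).split(";"):
            if token:
                peak, off, strand = token.rsplit(":", 2)
                evidence.append((peak, int(off), strand))
        out.add_edge(u, v, evidence=evidence, n_peaks=int(d.get("n_peaks", 0)))
    return RegulatoryNetwork(graph=out, condition_label=condition_label)
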