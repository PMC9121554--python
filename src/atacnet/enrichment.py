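"""Gene-set over-representation with hypergeometric tests and BH-FDR.

Implements the standard GO-style analysis: for a query gene list against a
universe, each term's overlap is scored with the upper-tail hypergeometric
probability and adjusted per category (BP / CC / MF / KEGG / other) with
the Benjamini-Hochberg step-up procedure, matching how per-category panels
are usually reported.  An EASE-style offset (scoring k - 1 overlapping
genes instead of k) is available for compatibility with DAVID-like tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CATEGORY_TAGS = ("BP", "CC", "MF", "KEGG", "other")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]


class GeneSetCollection:
    """Term id -> (name, category, gene ids); gene ids uppercased on load."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            if not s.genes:
                raise ValueError(f"term {s.term_id} has no genes")
            cat = s.category if s.category in CATEGORY_TAGS else "other"
            self.sets[s.term_id] = GeneSet(
                s.term_id, s.name, cat, frozenset(g.upper() for g in s.genes)
            )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Read a GMT file (term, description, genes...).

        A category tag may be embedded in the description as a ``CAT:BP``
        style prefix; otherwise terms land in ``other``.
        """
        sets: list[GeneSet] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs term, description, genes")
                term, desc = f[0], f[1]
                category = "other"
                if desc.startswith("CAT:"):
                    tag = desc[4:].split(maxsplit=1)
                    category = tag[0]
                    desc = tag[1] if len(tag) > 1 else ""
                sets.append(GeneSet(term, desc, category, frozenset(g for g in f[2:] if g)))
        return cls(sets)


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = query-term overlap, K = term size in universe, n = query size,
    N = universe size.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    q_threshold: float = 0.05,
    ease: bool = False,
    per_category: bool = True,
) -> pd.DataFrame:
    """Rank all terms by over-representation of ``query`` within ``universe``.

    Query genes outside the universe are logged and dropped.  Terms with no
    gene in the universe are skipped.  BH correction runs separately per
    category unless ``per_category=False``.  ``ease`` applies the DAVID-style
    conservative offset (tests k - 1 instead of k).

    Returns a DataFrame (term_id, name, category, k, K, n, N, pvalue,
    qvalue, significant) sorted by (qvalue, pvalue, term_id).
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    query_set = {g.upper() for g in query}
    outside = query_set - universe_set
    if outside:
        logger.info("%d query gene(s) outside universe dropped", len(outside))
        query_set &= universe_set
    N = len(universe_set)
    n = len(query_set)
    rows = []
    if n == 0:
        return pd.DataFrame(
            columns=[
                "term_id", "name", "category", "k", "K", "n", "N",
                "pvalue", "qvalue", "significant",
            ]
        )
    for term in sorted(collection, key=lambda t: t.term_id):
        term_genes = term.genes & universe_set
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query_set)
        k_eff = max(0, k - 1) if ease else k
        p = hypergeometric_test(k_eff, K, n, N)
        rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "category": term.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "category", "k", "K", "n", "N", "pvalue"]
    )
    if df.empty:
        df["qvalue"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["qvalue"] = np.nan
    if per_category:
        for cat in df["category"].unique():
            mask = df["category"] == cat
            df.loc[mask, "qvalue"] = bh_adjust(df.loc[mask, "pvalue"].to_numpy())
    else:
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < q_threshold
    return df.sort_values(["qvalue", "pvalue", "term_id"]).reset_index(drop=True)
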