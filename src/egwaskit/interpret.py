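"""Downstream characterisation of a candidate list.

Term enrichment is the plain hypergeometric upper tail: for a term annotating
K of N universe genes, the p-value of seeing k of them among an n-gene hit
list is P(X >= k) with X ~ Hypergeometric(N, K, n), multiplicity-adjusted by
Benjamini-Hochberg (default) or Bonferroni. Network hub identification is
degree centrality on the interaction subgraph induced by the candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """term -> gene-id set, with a namespace label (biological process,
    cellular component, molecular function or pathway)."""

    terms: dict[str, set[str]]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.terms.items() if not genes]
        if empty:
            raise ValueError(f"empty terms rejected: {empty[:5]}")
        for genes in self.terms.values():
            if not all(isinstance(g, str) for g in genes):
                raise ValueError("annotated gene ids must be strings")


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    annotation: AnnotationSet,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``hits`` within ``universe``.

    Returns one row per term — k (hits in term), K (term size within the
    universe), n (list size), N (universe size), p and adjusted p — sorted by
    ascending p. Terms with no gene in the universe are skipped.
    """
    hits, universe = set(hits), set(universe)
    offenders = hits - universe
    if offenders:
        raise ValueError(f"hits outside the universe: {sorted(offenders)[:10]}")
    N, n = len(universe), len(hits)
    rows = []
    for term in sorted(annotation.terms):
        term_genes = annotation.terms[term] & universe
        K = len(term_genes)
        if K == 0:
            log.debug("term %s has no genes in the universe; skipped", term)
            continue
        k = len(term_genes & hits)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, k, K, n, N, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if out.empty:
        raise ValueError("annotation shares no genes with the universe")
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(adjust)
    if method is None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["p_adjusted"] = multipletests(out["p"], method=method)[1]
    out["namespace"] = annotation.namespace
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def hub_rank(
    candidates: Iterable[str],
    edges: pd.DataFrame,
    include_neighbors: bool = False,
) -> pd.DataFrame:
    """Degree-centrality ranking of candidates in an interaction network.

    Parallel edges are deduplicated and self-loops dropped; degree is taken
    in the subgraph induced on the candidates (plus their first neighbors
    with ``include_neighbors``). Rows are sorted by descending degree with
    lexicographic tie-break, and ties for the top are flagged rather than
    silently broken.
    """
    candidates = set(candidates)
    graph = nx.Graph()
    for _, row in edges.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        if a == b:
            continue
        graph.add_edge(a, b)
    keep = set(graph.nodes) & candidates
    if include_neighbors:
        for node in list(keep):
            keep |= set(graph.neighbors(node))
    sub = graph.subgraph(keep)
    degree = {g: 0 for g in candidates} | {g: d for g, d in sub.degree()}
    out = pd.DataFrame(
        sorted(degree.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "degree"],
    )
    out["rank"] = out["degree"].rank(method="min", ascending=False).astype(int)
    top = out["degree"].iloc[0] if len(out) else 0
    out["tied_for_top"] = (out["degree"] == top) & (
        (out["degree"] == top).sum() > 1
    )
    return out
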