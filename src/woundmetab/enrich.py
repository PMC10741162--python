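"""Pathway over-representation and topology impact analysis.

Annotated compounds (KEGG ids) are tested against pathway membership
with the upper-tail hypergeometric test, and each pathway's topological
impact is the summed relative betweenness centrality of the hit
compounds as a fraction of the pathway total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datamodel import PathwayGraph, ValidationError
from .stats import bh_adjust


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    n_universe: int
    n_pathway: int
    n_hits_total: int
    n_overlap: int
    p_value: float
    impact: float
    hit_ids: list[str] = field(default_factory=list)
    q_value: float = float("nan")


def map_compounds(
    names_or_ids: Iterable[str],
    name_to_kegg: Mapping[str, str],
) -> tuple[list[str], list[str]]:
    """Exact (case-insensitive) name or direct KEGG-id mapping.

    Returns ``(mapped kegg ids, unmapped inputs verbatim)``; no fuzzy
    matching is attempted.
    """
    lookup = {name.lower(): kegg for name, kegg in name_to_kegg.items()}
    known_ids = set(name_to_kegg.values())
    mapped: list[str] = []
    unmapped: list[str] = []
    for item in names_or_ids:
        if item in known_ids:
            mapped.append(item)
        elif item.lower() in lookup:
            mapped.append(lookup[item.lower()])
        else:
            unmapped.append(item)
    return mapped, unmapped


def hypergeom_ora(n_universe: int, n_pathway: int, n_hits: int, n_overlap: int) -> float:
    """Upper-tail P(X >= n_overlap) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= n_overlap <= min(n_pathway, n_hits)):
        raise ValidationError(
            f"inconsistent counts: overlap {n_overlap}, pathway {n_pathway}, hits {n_hits}"
        )
    if not (n_pathway <= n_universe and n_hits <= n_universe):
        raise ValidationError("pathway and hit counts must not exceed the universe")
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_pathway, n_hits))


def relative_betweenness(pathway: PathwayGraph) -> dict[str, float]:
    """Pair-normalized betweenness centrality rescaled so the maximum
    node scores 1 (all-zero graphs stay all-zero).  Disconnected
    components contribute shortest paths within components only."""
    g = pathway.to_networkx()
    if g.number_of_nodes() <= 2:
        return {n: 0.0 for n in g.nodes}
    bc = nx.betweenness_centrality(g, normalized=True)
    top = max(bc.values())
    if top == 0:
        return {n: 0.0 for n in bc}
    return {n: v / top for n, v in bc.items()}


def pathway_impact(pathway: PathwayGraph, hits: Iterable[str]) -> float:
    """Summed relative betweenness of hit nodes over the pathway total."""
    bc = relative_betweenness(pathway)
    denom = sum(bc.values())
    if denom == 0:
        return 0.0
    return sum(v for n, v in bc.items() if n in set(hits)) / denom


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    pathways: Sequence[PathwayGraph],
) -> list[EnrichmentResult]:
    """Per-pathway over-representation p-value and topology impact.

    Counts are restricted to universe members; results are sorted by
    ascending p-value with BH-adjusted q-values appended.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty compound universe")
    hit_set = set(hits)
    if not hit_set <= universe_set:
        raise ValidationError("hits must be a subset of the universe")

    results: list[EnrichmentResult] = []
    for pw in pathways:
        members = pw.nodes & universe_set
        overlap = sorted(members & hit_set)
        p = hypergeom_ora(len(universe_set), len(members), len(hit_set), len(overlap))
        results.append(EnrichmentResult(
            pathway_id=pw.pathway_id,
            name=pw.name,
            n_universe=len(universe_set),
            n_pathway=len(members),
            n_hits_total=len(hit_set),
            n_overlap=len(overlap),
            p_value=p,
            impact=pathway_impact(pw, overlap),
            hit_ids=overlap,
        ))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "pathway_id": r.pathway_id,
            "name": r.name,
            "n_pathway": r.n_pathway,
            "n_overlap": r.n_overlap,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "neg_log10_p": -np.log10(r.p_value) if r.p_value > 0 else np.inf,
            "impact": r.impact,
            "hits": ";".join(r.hit_ids),
        })
    return pd.DataFrame(rows)
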