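"""Metabolite-set pathway analysis.

Two complementary scores per pathway, following the MetaboAnalyst
convention: an exact hypergeometric over-representation p-value, and a
topology "impact" — the summed relative betweenness centrality of the hit
compounds within the pathway graph.
"""

from __future__ import annotations

import logging
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import PathwayDef, TriomixError, load_pathway_library

log = logging.getLogger(__name__)


def load_bundled_library() -> list[PathwayDef]:
    """Load the miniature pathway library shipped with the package."""
    data = resources.files("triomix") / "data"
    return load_pathway_library(str(data / "minikegg.gmt"), str(data / "minikegg_edges.tsv"))


def ora_hypergeometric(hits: set[str], pathway: PathwayDef, universe: set[str]) -> float:
    """Exact over-representation p-value, P(X >= x).

    X ~ Hypergeometric(N=|universe|, K=|members∩universe|, n=|hits|) where
    x is the observed overlap. Hits must lie within the universe; pathway
    members are intersected with the universe before testing.
    """
    if not universe:
        raise TriomixError("empty universe")
    if not set(hits) <= set(universe):
        raise TriomixError("hits must be a subset of the universe")
    N = len(universe)
    members = set(pathway.members) & set(universe)
    K = len(members)
    n = len(hits)
    x = len(set(hits) & members)
    if x == 0:
        return 1.0
    # survival function at x-1 gives P(X >= x); scipy's pmf is exact to float
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def pathway_impact(hits: set[str], pathway: PathwayDef) -> float:
    """Topology impact: summed relative betweenness centrality of hit nodes.

    Centralities are computed on the undirected, unweighted pathway graph
    (members without edges are isolated nodes with centrality 0) and
    normalized to sum to 1. A pathway whose graph has no interior nodes at
    all (all-zero centrality) gets impact 0.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(pathway.members))
    g.add_edges_from(pathway.edges)
    bc = nx.betweenness_centrality(g, normalized=False)
    total = sum(bc.values())
    if total == 0:
        log.warning("pathway %s has all-zero centrality; impact set to 0", pathway.pathway_id)
        return 0.0
    return float(sum(bc[node] for node in set(hits) & pathway.members) / total)


def bh_adjust_pathways(p: np.ndarray) -> np.ndarray:
    # local import avoids a cycle (diffexpr imports nothing from here)
    from .diffexpr import bh_adjust

    return bh_adjust(p)


def analyze_pathways(
    selected_metabolites: set[str],
    library: list[PathwayDef],
    universe: set[str],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Score every pathway against a selected-metabolite list.

    Returns a DataFrame sorted by ORA p ascending, ties by impact
    descending then pathway id; the ``potential`` flag marks pathways with
    BH q <= 0.05 or impact >= ``cfg.impact_min``.
    """
    cfg = cfg or RunConfig()
    hits = set(selected_metabolites) & set(universe)
    dropped = set(selected_metabolites) - hits
    if dropped:
        log.info("%d selected metabolites outside the universe ignored", len(dropped))
    rows = []
    for pw in library:
        members = set(pw.members) & set(universe)
        x = len(hits & members)
        p = ora_hypergeometric(hits, pw, universe)
        expected = len(hits) * len(members) / len(universe)
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "name": pw.name,
                "n_members": len(members),
                "n_hits": x,
                "expected_hits": expected,
                "p": p,
                "impact": pathway_impact(hits, pw),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust_pathways(df["p"].to_numpy()) if len(df) else []
    df["potential"] = (df["q"] <= 0.05) | (df["impact"] >= cfg.impact_min)
    df = df.sort_values(
        ["p", "impact", "pathway_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df[
        ["pathway_id", "name", "n_members", "n_hits", "expected_hits", "p", "q", "impact", "potential"]
    ]
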