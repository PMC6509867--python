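"""Pathway enrichment and the stage-evolution pathway network.

Each stage module's gene set is tested for over-representation in every
pathway with an upper-tail hypergeometric test (the standard model behind
gene-set over-representation tools), Benjamini–Hochberg adjusted within the
stage. Significant pathways across stages become nodes of a pathway network
whose nodes carry the set of stages they are significant in, and whose
edges link any two pathways sharing annotated genes, weighted by the
overlap score

    W = k^2 / (p * q)

with k the shared-gene count and p, q the pathways' annotated-set sizes.
Connected components of this network are reported as pathway groups whose
stage composition traces the disease's stage evolution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "enrich",
    "overlap_score",
    "build_pathway_network",
    "group_components",
    "enrichment_table",
]


@dataclass
class EnrichmentResult:
    """One pathway's over-representation test for one stage's module genes."""

    pathway_id: str
    stage: str
    k_overlap: int
    pathway_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float = 1.0


def enrich(
    module_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    stage: str = "",
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``module_genes`` per pathway.

    Pathway gene sets are intersected with the universe; pathways with no
    overlap with the query are excluded. P-values are upper-tail
    hypergeometric (probability of >= k overlaps by chance) and q-values
    are Benjamini–Hochberg within this batch. Results are sorted by p-value.
    """
    if not universe:
        raise ValueError("empty universe")
    query = module_genes & universe
    if not module_genes or not query:
        raise ValueError("empty query gene set")
    N, n = len(universe), len(query)

    results: list[EnrichmentResult] = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        k = len(members & query)
        if k == 0 or not members:
            continue
        K = len(members)
        # P[overlap >= k] under sampling n genes from N with K marked
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                pathway_id=name,
                stage=stage,
                k_overlap=k,
                pathway_size=K,
                query_size=n,
                universe_size=N,
                p_value=min(p, 1.0),
            )
        )
    if results:
        _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def overlap_score(set_i: set[str], set_j: set[str]) -> float:
    """Overlap score W = k²/(p·q) between two pathway gene sets.

    Symmetric, in [0, 1]; 1 exactly when the sets are identical and 0 when
    disjoint. Raises on an empty set.
    """
    p, q = len(set_i), len(set_j)
    if p == 0 or q == 0:
        raise ValueError("overlap_score undefined for an empty gene set")
    k = len(set_i & set_j)
    return k * k / (p * q)


def build_pathway_network(
    results_by_stage: dict[str, list[EnrichmentResult]],
    gene_sets: dict[str, set[str]],
    fdr: float = 0.05,
    min_w: float = 0.0,
) -> nx.Graph:
    """Assemble the stage-evolution pathway network.

    Nodes are pathways significant (q <= fdr) in at least one stage; a
    pathway significant in several stages is a single node carrying the
    stage set. Edges connect every pathway pair sharing at least one
    annotated gene with overlap score >= ``min_w``; edge attributes are the
    shared-gene count ``k`` and the score ``w``.
    """
    stages_of: dict[str, set[str]] = {}
    for stage, results in results_by_stage.items():
        for r in results:
            if r.q_value <= fdr:
                stages_of.setdefault(r.pathway_id, set()).add(stage)
    g = nx.Graph()
    for pw, stages in sorted(stages_of.items()):
        g.add_node(pw, stages=",".join(sorted(stages)), size=len(gene_sets[pw]))
    for a, b in itertools.combinations(sorted(stages_of), 2):
        k = len(gene_sets[a] & gene_sets[b])
        if k == 0:
            continue
        w = overlap_score(gene_sets[a], gene_sets[b])
        if w >= min_w:
            g.add_edge(a, b, k=k, w=w)
    if g.number_of_nodes() == 0:
        logger.warning("pathway network is empty: no pathway passed fdr=%g", fdr)
    return g


def group_components(network: nx.Graph) -> dict[str, dict]:
    """Connected components of the pathway network as ordered groups.

    Groups are ordered by size descending, ties by lexicographically
    smallest member list, and named g1, g2, ... Each group records its
    pathways and the union of stages present, the raw material for reading
    an evolution history off the network.
    """
    comps = sorted(
        (sorted(c) for c in nx.connected_components(network)),
        key=lambda c: (-len(c), c),
    )
    groups: dict[str, dict] = {}
    for i, members in enumerate(comps, 1):
        stages: set[str] = set()
        for pw in members:
            attr = network.nodes[pw].get("stages", "")
            stages.update(s for s in attr.split(",") if s)
        groups[f"g{i}"] = {"pathways": members, "stages": sorted(stages)}
    return groups


def enrichment_table(results: list[EnrichmentResult], fdr: float = 0.05) -> pd.DataFrame:
    """TSV-ready per-stage enrichment table."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway_id,
                "stage": r.stage,
                "k_overlap": r.k_overlap,
                "pathway_size": r.pathway_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.q_value <= fdr,
            }
            for r in results
        ]
    )
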