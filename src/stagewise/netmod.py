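"""Stage-specific module detection on the PPI network.

Selected seed genes are expanded with their direct (one-hop) neighbors in
the background PPI graph, the subgraph induced by seeds plus neighbors is
extracted, and only its giant connected component is kept as the stage
module. Nodes carry a role — ``detected`` (a selected seed) or ``neighbor``
— and, after all stage modules exist, cross-stage overlap tags such as
``"2-3N"`` (stage-2 detected genes that are stage-3 neighbors) or
``"2N-4N"`` (neighbor genes shared by stages 2 and 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StageModule",
    "expand_with_neighbors",
    "giant_component",
    "build_stage_module",
    "annotate_cross_stage",
    "write_module",
]


@dataclass
class StageModule:
    """Giant-component subgraph for one stage, with node roles and tags."""

    stage: str
    graph: nx.Graph
    role: dict[str, str]  # gene -> "detected" | "neighbor"
    cross_tags: dict[str, set[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def detected(self) -> set[str]:
        return {g for g, r in self.role.items() if r == "detected"}

    @property
    def neighbors(self) -> set[str]:
        return {g for g, r in self.role.items() if r == "neighbor"}


def expand_with_neighbors(seeds: set[str], ppi: nx.Graph) -> nx.Graph:
    """Induce the subgraph on seeds plus their direct PPI neighbors.

    Seeds absent from the PPI graph are logged and dropped; the returned
    graph carries all background edges among the retained node set.
    """
    present = {s for s in seeds if s in ppi}
    absent = seeds - present
    if absent:
        logger.info("%d seed genes absent from the PPI network", len(absent))
    nodes = set(present)
    for s in present:
        nodes.update(ppi.neighbors(s))
    return ppi.subgraph(nodes).copy()


def giant_component(graph: nx.Graph, seeds: set[str] | None = None) -> nx.Graph:
    """Return the largest connected component of ``graph``.

    Ties on size are broken by most seed genes contained, then by the
    lexicographically smallest sorted node list. An empty graph returns an
    empty graph with a warning.
    """
    if graph.number_of_nodes() == 0:
        logger.warning("giant_component: empty subnetwork")
        return nx.Graph()
    seeds = seeds or set()
    components = [set(c) for c in nx.connected_components(graph)]
    max_size = max(len(c) for c in components)
    cands = [c for c in components if len(c) == max_size]
    max_seed = max(len(c & seeds) for c in cands)
    cands = [c for c in cands if len(c & seeds) == max_seed]
    best = min(cands, key=lambda c: sorted(c))
    return graph.subgraph(best).copy()


def build_stage_module(stage: str, seeds: set[str], ppi: nx.Graph) -> StageModule:
    """Expand seeds, take the giant component, and assign node roles."""
    sub = expand_with_neighbors(seeds, ppi)
    core = giant_component(sub, seeds=seeds)
    role = {n: ("detected" if n in seeds else "neighbor") for n in core.nodes}
    return StageModule(stage=stage, graph=core, role=role, cross_tags={n: set() for n in core.nodes})


def _stage_num(stage: str) -> str:
    return stage.lstrip("tT") or stage


def annotate_cross_stage(modules: dict[str, StageModule]) -> dict[str, StageModule]:
    """Tag genes shared between stage modules, encoding both roles.

    For stages s < t a shared gene is tagged ``"s-t"`` (detected in both),
    ``"s-tN"`` (detected in s, neighbor in t), ``"sN-t"`` or ``"sN-tN"``;
    the lower stage always comes first. Tags are added to the gene's entry
    in both modules.
    """
    stages = sorted(modules)
    for i, s in enumerate(stages):
        for t in stages[i + 1 :]:
            ms, mt = modules[s], modules[t]
            for gene in ms.nodes & mt.nodes:
                left = _stage_num(s) + ("" if ms.role[gene] == "detected" else "N")
                right = _stage_num(t) + ("" if mt.role[gene] == "detected" else "N")
                tag = f"{left}-{right}"
                ms.cross_tags.setdefault(gene, set()).add(tag)
                mt.cross_tags.setdefault(gene, set()).add(tag)
    return modules


def module_tables(module: StageModule) -> tuple[pd.DataFrame, pd.DataFrame]:
    """nodes.tsv / edges.tsv content for one stage module."""
    nodes = pd.DataFrame(
        [
            {
                "gene": n,
                "role": module.role[n],
                "cross_tags": ",".join(sorted(module.cross_tags.get(n, ()))),
                "stage": module.stage,
            }
            for n in sorted(module.graph.nodes)
        ]
    )
    edges = pd.DataFrame(
        [{"source": u, "target": v} for u, v in sorted(tuple(sorted(e)) for e in module.graph.edges)]
    )
    return nodes, edges


def write_module(module: StageModule, outdir: str | Path) -> None:
    """Write GraphML (Cytoscape-importable) plus nodes/edges TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = nx.Graph()
    for n in sorted(module.graph.nodes):
        g.add_node(
            n,
            role=module.role[n],
            cross_tags=",".join(sorted(module.cross_tags.get(n, ()))),
            stage=module.stage,
        )
    for u, v in sorted(tuple(sorted(e)) for e in module.graph.edges):
        g.add_edge(u, v, source_network="ppi")
    nx.write_graphml(g, outdir / f"module_{module.stage}.graphml")
    nodes, edges = module_tables(module)
    nodes.to_csv(outdir / f"module_{module.stage}_nodes.tsv", sep="\t", index=False)
    edges.to_csv(outdir / f"module_{module.stage}_edges.tsv", sep="\t", index=False)
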