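"""Gene–pathway bipartite network, functional modules and hub genes.

Significantly enriched pathways and the prioritized genes they contain
form an undirected bipartite graph.  Pathways are grouped into curated
functional modules (immune, metabolic, endocrine, signal transduction /
cellular regulation) via a user-supplied category map — module themes
come from curation, never from the data — and genes inherit the union
of their neighboring pathways' modules, so module overlap is expected.
Within each module, hub genes are those connected to the most
same-module pathways (degree centrality restricted to module-internal
edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .enrichment import EnrichmentResult, GeneSet
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

MODULE_LABELS = (
    "immune",
    "metabolic",
    "endocrine",
    "signal_transduction_cellular_regulation",
)
UNASSIGNED = "unassigned"


@dataclass
class BipartiteNetwork:
    gene_nodes: set[str] = field(default_factory=set)
    pathway_nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)  # (gene_id, set_id)
    gene_degree: dict[str, int] = field(default_factory=dict)
    pathway_degree: dict[str, int] = field(default_factory=dict)
    #: set_id -> display name, for exports
    pathway_names: dict[str, str] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.gene_nodes), node_type="gene")
        g.add_nodes_from(sorted(self.pathway_nodes), node_type="pathway")
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass
class ModuleAssignment:
    pathway_module: dict[str, str] = field(default_factory=dict)
    gene_modules: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class HubReport:
    """Per-module ranking of genes by module-internal pathway degree."""

    per_module: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def build_network(
    significant: Sequence[EnrichmentResult],
    sets: Sequence[GeneSet],
    prioritized: Iterable[str],
    universe: Iterable[str] | None = None,
) -> BipartiteNetwork:
    """Edges connect prioritized genes to the significant pathways
    containing them (membership intersected with the universe when
    given).  Genes with zero edges are excluded from the node set; an
    empty significant list yields an empty network with a warning.
    """
    net = BipartiteNetwork()
    if not significant:
        logger.warning("no significant pathways: returning an empty network")
        return net
    by_id = {s.set_id: s for s in sets}
    missing = [r.set_id for r in significant if r.set_id not in by_id]
    if missing:
        raise ConfigurationError(f"significant results reference unknown sets: {missing}")
    prioritized = set(prioritized)
    uni = set(universe) if universe is not None else None

    for r in significant:
        net.pathway_nodes.add(r.set_id)
        net.pathway_names[r.set_id] = r.name
        members = by_id[r.set_id].genes & prioritized
        if uni is not None:
            members &= uni
        for g in members:
            net.edges.add((g, r.set_id))
            net.gene_nodes.add(g)

    for g, s in net.edges:
        net.gene_degree[g] = net.gene_degree.get(g, 0) + 1
        net.pathway_degree[s] = net.pathway_degree.get(s, 0) + 1
    for s in net.pathway_nodes:
        net.pathway_degree.setdefault(s, 0)
    return net


def load_category_map(path: str | Path) -> dict[str, str]:
    """Load a pathway -> module label map from YAML.

    Keys are exact set ids or case-insensitive substrings of pathway
    names; values must be one of the canonical module labels.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"category map {path} must be a mapping")
    bad = {k: v for k, v in raw.items() if v not in MODULE_LABELS}
    if bad:
        raise ConfigurationError(
            f"category map {path} uses unknown module labels: {bad}; "
            f"allowed: {MODULE_LABELS}"
        )
    return dict(raw)


def assign_modules(
    network: BipartiteNetwork,
    category_map: Mapping[str, str],
) -> ModuleAssignment:
    """Assign each pathway a module and derive gene modules by union.

    A pathway matches by exact set id first, then by case-insensitive
    substring of its display name; unmatched pathways become
    ``unassigned`` with a logged count.  A gene's modules are the union
    over its adjacent pathways — overlap across modules is allowed.
    """
    assignment = ModuleAssignment()
    patterns = {k.lower(): v for k, v in category_map.items()}
    n_unassigned = 0
    for set_id in sorted(network.pathway_nodes):
        label = category_map.get(set_id)
        if label is None:
            name = network.pathway_names.get(set_id, "").lower()
            for pattern, candidate in sorted(patterns.items()):
                if pattern and pattern in name:
                    label = candidate
                    break
        if label is None:
            label = UNASSIGNED
            n_unassigned += 1
        assignment.pathway_module[set_id] = label
    if n_unassigned:
        logger.info("%d pathways not covered by the category map", n_unassigned)

    for gene, set_id in network.edges:
        assignment.gene_modules.setdefault(gene, set()).add(
            assignment.pathway_module[set_id]
        )
    return assignment


def find_hubs(
    network: BipartiteNetwork,
    modules: ModuleAssignment,
    top_n: int = 5,
) -> HubReport:
    """Rank genes within each module by module-internal degree.

    A gene's within-module degree counts adjacent pathways carrying
    that module label; ranking ties break by overall degree then gene
    id.  The top ``top_n`` genes per module are reported.
    """
    if top_n < 1:
        raise ConfigurationError(f"top_n must be >= 1, got {top_n}")
    within: dict[str, dict[str, int]] = {}
    for gene, set_id in network.edges:
        label = modules.pathway_module[set_id]
        within.setdefault(label, {}).setdefault(gene, 0)
        within[label][gene] += 1

    report = HubReport()
    for label in sorted(within):
        ranked = sorted(
            within[label].items(),
            key=lambda item: (-item[1], -network.gene_degree[item[0]], item[0]),
        )
        report.per_module[label] = ranked[:top_n]
    return report


def export_layout(
    network: BipartiteNetwork,
    modules: ModuleAssignment,
    seed: int,
) -> pd.DataFrame:
    """Seeded force-directed (Fruchterman–Reingold) 2-D coordinates.

    Returns a plain table (node, type, modules, degree, x, y); the same
    network and seed always give identical coordinates.  An empty
    network yields an empty table.
    """
    columns = ["node", "node_type", "modules", "degree", "x", "y"]
    if network.is_empty:
        return pd.DataFrame(columns=columns)
    graph = network.to_networkx()
    pos = nx.spring_layout(graph, seed=seed)
    rows = []
    for node in sorted(graph.nodes):
        is_gene = graph.nodes[node]["node_type"] == "gene"
        if is_gene:
            mods = ";".join(sorted(modules.gene_modules.get(node, set())))
            degree = network.gene_degree.get(node, 0)
        else:
            mods = modules.pathway_module.get(node, UNASSIGNED)
            degree = network.pathway_degree.get(node, 0)
        x, y = pos[node]
        rows.append((node, "gene" if is_gene else "pathway", mods, degree, float(x), float(y)))
    return pd.DataFrame(rows, columns=columns)


def write_edge_list_tsv(network: BipartiteNetwork, path: str | Path) -> None:
    pd.DataFrame(
        sorted(network.edges), columns=["gene_id", "set_id"]
    ).to_csv(path, sep="\t", index=False)


def write_node_attributes_tsv(
    network: BipartiteNetwork, modules: ModuleAssignment, path: str | Path
) -> None:
    rows = []
    for g in sorted(network.gene_nodes):
        rows.append(
            (g, "gene", ";".join(sorted(modules.gene_modules.get(g, set()))),
             network.gene_degree.get(g, 0))
        )
    for s in sorted(network.pathway_nodes):
        rows.append(
            (s, "pathway", modules.pathway_module.get(s, UNASSIGNED),
             network.pathway_degree.get(s, 0))
        )
    pd.DataFrame(rows, columns=["node", "node_type", "modules", "degree"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(
    network: BipartiteNetwork, modules: ModuleAssignment, path: str | Path
) -> None:
    graph = network.to_networkx()
    for node in graph.nodes:
        if graph.nodes[node]["node_type"] == "gene":
            graph.nodes[node]["modules"] = ";".join(sorted(modules.gene_modules.get(node, set())))
            graph.nodes[node]["degree"] = network.gene_degree.get(node, 0)
        else:
            graph.nodes[node]["modules"] = modules.pathway_module.get(node, UNASSIGNED)
            graph.nodes[node]["degree"] = network.pathway_degree.get(node, 0)
    nx.write_graphml(graph, path)


def write_hubs_tsv(report: HubReport, path: str | Path) -> None:
    rows = []
    for label in sorted(report.per_module):
        for rank, (gene, degree) in enumerate(report.per_module[label], start=1):
            rows.append((label, rank, gene, degree))
    pd.DataFrame(rows, columns=["module", "rank", "gene_id", "within_module_degree"]).to_csv(
        path, sep="\t", index=False
    )
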