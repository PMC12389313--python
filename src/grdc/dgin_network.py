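"""Drug–gene interaction network (DGIN) construction and export.

The DGIN is a bipartite, undirected networkx graph.  Drug nodes are keyed
``"<name>_<RiskLevel>"`` so the same drug observed under different
combination risk labels appears as distinct nodes; gene nodes are keyed by
gene symbol and shared across all drug variants.  Drug nodes carry their
risk label and a fixed color code (High = red, Moderate = orange,
Low = gold, Unknown = gray, None = white); gene nodes are uniformly green.
A drug with many targets forms a star; drugs sharing targets form clusters.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple, Sequence

import networkx as nx

from .freq_mining import DrugCombination
from .io_model import DrugGeneMap, RiskLevel

__all__ = [
    "RISK_COLORS",
    "GENE_COLOR",
    "NetworkStats",
    "build_network",
    "network_stats",
    "export_network",
    "import_network",
]

RISK_COLORS: dict[RiskLevel, str] = {
    RiskLevel.HIGH: "red",
    RiskLevel.MODERATE: "orange",
    RiskLevel.LOW: "gold",
    RiskLevel.UNKNOWN: "gray",
    RiskLevel.NONE: "white",
}
GENE_COLOR = "green"


class NetworkStats(NamedTuple):
    drug_nodes: int
    gene_nodes: int
    edges: int
    distinct_drugs: int  # drug nodes collapsed over risk variants


def build_network(
    labeled: Sequence[tuple[DrugCombination, RiskLevel]],
    genes: DrugGeneMap,
) -> nx.Graph:
    """Assemble the bipartite drug–gene graph from risk-labeled combinations.

    Every (drug, risk) pair observed in the labeled combinations becomes
    one drug node, connected to each of the drug's target genes; drugs
    without mapped targets remain as isolated drug nodes.
    """
    g = nx.Graph()
    for combo, level in labeled:
        for drug in combo.drugs:
            node = f"{drug}_{level.value}"
            if node not in g:
                g.add_node(
                    node,
                    kind="drug",
                    drug=drug,
                    risk=level.value,
                    color=RISK_COLORS[level],
                )
            for gene in genes.genes(drug):
                if gene not in g:
                    g.add_node(gene, kind="gene", color=GENE_COLOR)
                g.add_edge(node, gene, risk=level.value)
    return g


def network_stats(g: nx.Graph) -> NetworkStats:
    """Node/edge counts by kind, plus the count of distinct underlying drugs."""
    drug_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "drug"]
    gene_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "gene"]
    distinct = {g.nodes[n]["drug"] for n in drug_nodes}
    return NetworkStats(
        drug_nodes=len(drug_nodes),
        gene_nodes=len(gene_nodes),
        edges=g.number_of_edges(),
        distinct_drugs=len(distinct),
    )


def export_network(g: nx.Graph, path: str | Path) -> None:
    """Write the graph as GraphML (default) or GEXF by file extension."""
    path = Path(path)
    if path.suffix == ".gexf":
        nx.write_gexf(g, path)
    else:
        nx.write_graphml(g, path)


def import_network(path: str | Path) -> nx.Graph:
    path = Path(path)
    if path.suffix == ".gexf":
        return nx.read_gexf(path)
    return nx.read_graphml(path)
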