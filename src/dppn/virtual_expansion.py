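"""Virtual locative proteins: multi-label to single-label conversion.

A protein annotated with κ subcellular locations is split into κ virtual
locative proteins, one per location.  Virtual copies inherit every interaction
of the parent (each real edge {u, v} becomes all κ_u × κ_v cross pairs) and
the parent's expression profile, but siblings — copies of the same real
protein — never interact with each other, since they stand for the protein in
different compartments.  Unannotated proteins pass through unchanged as single
unlabeled nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .network_io import AnnotationMap, PPINetwork, edge_key
from .vocabulary import LOCATION_TOKENS, sort_locations

logger = logging.getLogger(__name__)

SEPARATOR = "::"


@dataclass
class VirtualNetwork:
    """A PPI network over virtual locative proteins.

    ``parent`` maps every virtual ID to its real protein; ``label`` maps each
    annotated virtual node to its single location (unannotated nodes are
    absent from ``label``).
    """

    nodes: list[str]
    edges: set[tuple[str, str]]
    parent: dict[str, str]
    label: dict[str, str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def siblings(self) -> dict[str, list[str]]:
        """Group virtual nodes by real parent, preserving node order."""
        groups: dict[str, list[str]] = {}
        for node in self.nodes:
            groups.setdefault(self.parent[node], []).append(node)
        return groups


def virtual_id(protein: str, location: str) -> str:
    return f"{protein}{SEPARATOR}{LOCATION_TOKENS[location]}"


def expand(network: PPINetwork, annotations: AnnotationMap) -> VirtualNetwork:
    """Split annotated proteins into virtual locative copies.

    Annotations for proteins absent from the network are ignored (logged).
    Node order is lexicographic for matrix reproducibility.
    """
    node_set = set(network.nodes)
    orphans = [p for p in annotations if p not in node_set]
    if orphans:
        logger.info("%d annotated proteins are absent from the network", len(orphans))

    copies: dict[str, list[str]] = {}
    parent: dict[str, str] = {}
    label: dict[str, str] = {}
    for protein in network.nodes:
        locs = annotations.get(protein)
        if locs:
            ids = []
            for loc in sort_locations(locs):
                vid = virtual_id(protein, loc)
                ids.append(vid)
                parent[vid] = protein
                label[vid] = loc
            copies[protein] = ids
        else:
            copies[protein] = [protein]
            parent[protein] = protein

    edges: set[tuple[str, str]] = set()
    for u, v in network.edges:
        for cu in copies[u]:
            for cv in copies[v]:
                edges.add(edge_key(cu, cv))
    nodes = sorted(parent)
    return VirtualNetwork(nodes=nodes, edges=edges, parent=parent, label=label)


def contract(vnet: VirtualNetwork) -> PPINetwork:
    """Collapse virtual copies back to real proteins (inverse of :func:`expand`)."""
    edges = {
        edge_key(vnet.parent[u], vnet.parent[v])
        for u, v in vnet.edges
        if vnet.parent[u] != vnet.parent[v]
    }
    nodes = sorted(set(vnet.parent.values()))
    return PPINetwork(nodes=nodes, edges=edges)


@dataclass(frozen=True)
class MultiplicitySummary:
    """Distribution of annotation multiplicities κ = |locations(u)|."""

    counts: dict[int, int]  # κ -> number of proteins
    n_proteins: int
    n_locative: int  # Σ κ·n_κ, the virtual locative protein count
    mean_multiplicity: float

    def __str__(self) -> str:
        per_k = ", ".join(f"κ={k}: {n}" for k, n in sorted(self.counts.items()))
        return (
            f"{self.n_proteins} annotated proteins ({per_k}); "
            f"{self.n_locative} locative proteins; "
            f"mean multiplicity {self.mean_multiplicity:.2f}"
        )


def multiplicity_summary(annotations: AnnotationMap) -> MultiplicitySummary:
    """Summarize the per-protein location-count distribution."""
    if not annotations:
        raise ValueError("annotation map is empty")
    counts: dict[int, int] = {}
    for locs in annotations.values():
        k = len(locs)
        counts[k] = counts.get(k, 0) + 1
    n_proteins = sum(counts.values())
    n_locative = sum(k * n for k, n in counts.items())
    return MultiplicitySummary(
        counts=counts,
        n_proteins=n_proteins,
        n_locative=n_locative,
        mean_multiplicity=n_locative / n_proteins,
    )


def write_virtual_network(vnet: VirtualNetwork, edges_path, parent_path, label_path) -> None:
    """Persist a virtual network as three TSV files (edges, parent map, labels)."""
    with open(edges_path, "w") as fh:
        for u, v in sorted(vnet.edges):
            fh.write(f"{u}\t{v}\n")
    with open(parent_path, "w") as fh:
        for node in vnet.nodes:
            fh.write(f"{node}\t{vnet.parent[node]}\n")
    with open(label_path, "w") as fh:
        for node in vnet.nodes:
            if node in vnet.label:
                fh.write(f"{node}\t{vnet.label[node]}\n")
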