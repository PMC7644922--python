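"""Reading, screening and validating PPI edge lists and location annotations.

Raw interaction records are screened with four criteria before any modeling:

1. both interactors belong to the target organism (default human, taxon 9606);
2. self-interactions are discarded;
3. duplicate records (in either endpoint order) are reduced to unique edges;
4. only physical interaction types are kept (PSI-MI ``MI:0915`` physical
   association and ``MI:0407`` direct interaction by default).

Location annotations are GO cellular-component terms restricted to a fixed
12-compartment vocabulary and to experimental evidence codes (IDA / HDA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .vocabulary import GO_TO_LOCATION, LOCATIONS, sort_locations

logger = logging.getLogger(__name__)

DEFAULT_TAXON = 9606
DEFAULT_INTERACTION_TYPES = frozenset({"MI:0915", "MI:0407"})
DEFAULT_EVIDENCE_CODES = frozenset({"IDA", "HDA"})


@dataclass(frozen=True)
class InteractionRecord:
    """One raw pairwise interaction record."""

    interactor_a: str
    interactor_b: str
    organism_a: int
    organism_b: int
    interaction_type: str

    def __post_init__(self):
        if not self.interactor_a or not self.interactor_b:
            raise ValueError("interactor IDs must be non-empty")
        if self.organism_a <= 0 or self.organism_b <= 0:
            raise ValueError("taxon IDs must be positive integers")


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class PPINetwork:
    """An undirected simple graph over real protein IDs.

    ``provenance`` carries per-criterion removal counts from filtering so the
    screening step is auditable.
    """

    nodes: list[str]
    edges: set[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-edge {u!r}")
            if u > v:
                raise ValueError(f"edge {(u, v)} not in canonical order")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {(u, v)} references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return edge_key(u, v) in self.edges

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj


# AnnotationMap: protein ID -> non-empty set of locations from the vocabulary.
AnnotationMap = dict[str, set[str]]


def filter_interactions(
    records: Iterable[InteractionRecord],
    taxon: int = DEFAULT_TAXON,
    allowed_types: frozenset[str] | set[str] = DEFAULT_INTERACTION_TYPES,
) -> PPINetwork:
    """Apply the four screening criteria and return the unique-edge network.

    Criteria are applied in a fixed order (taxon, self-loop, interaction type,
    duplicate collapse) so the per-criterion removal counts in
    ``network.provenance`` are reproducible; the resulting edge set does not
    depend on the order.
    """
    allowed_types = frozenset(allowed_types)
    counts = {
        "input_records": 0,
        "removed_taxon": 0,
        "removed_self": 0,
        "removed_type": 0,
        "removed_duplicate": 0,
    }
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    for rec in records:
        counts["input_records"] += 1
        if rec.organism_a != taxon or rec.organism_b != taxon:
            counts["removed_taxon"] += 1
            continue
        if rec.interactor_a == rec.interactor_b:
            counts["removed_self"] += 1
            continue
        if rec.interaction_type not in allowed_types:
            counts["removed_type"] += 1
            continue
        key = edge_key(rec.interactor_a, rec.interactor_b)
        if key in edges:
            counts["removed_duplicate"] += 1
            continue
        edges.add(key)
        nodes.update(key)
    counts["kept_edges"] = len(edges)
    if not edges:
        logger.warning("filtering produced an empty network")
    return PPINetwork(nodes=sorted(nodes), edges=edges, provenance=counts)


def load_annotations(
    rows: Iterable[tuple[str, str, str]],
    evidence_whitelist: frozenset[str] | set[str] = DEFAULT_EVIDENCE_CODES,
) -> AnnotationMap:
    """Build the protein -> location-set map from (protein, GO CC, evidence) rows.

    Rows with non-whitelisted evidence codes or GO terms outside the
    12-compartment vocabulary are dropped (counted and logged).  Proteins that
    retain no location are absent from the result.
    """
    evidence_whitelist = frozenset(evidence_whitelist)
    annotations: AnnotationMap = {}
    dropped_evidence = dropped_term = 0
    for protein, go_term, evidence in rows:
        if evidence not in evidence_whitelist:
            dropped_evidence += 1
            continue
        location = GO_TO_LOCATION.get(go_term)
        if location is None:
            dropped_term += 1
            continue
        annotations.setdefault(protein, set()).add(location)
    if dropped_evidence or dropped_term:
        logger.info(
            "dropped %d rows by evidence code, %d rows outside the vocabulary",
            dropped_evidence,
            dropped_term,
        )
    return annotations


def apply_id_mapping(
    network: PPINetwork, mapping: Mapping[str, str]
) -> PPINetwork:
    """Rename network nodes through a source->target ID mapping.

    Only one-to-one mapped IDs are kept: nodes without a mapping, and nodes
    whose targets collide (many-to-one), are removed along with their edges.
    """
    target_counts: dict[str, int] = {}
    for node in network.nodes:
        tgt = mapping.get(node)
        if tgt is not None:
            target_counts[tgt] = target_counts.get(tgt, 0) + 1
    usable = {
        n: mapping[n]
        for n in network.nodes
        if n in mapping and target_counts[mapping[n]] == 1
    }
    dropped = len(network.nodes) - len(usable)
    if dropped:
        logger.info("dropped %d nodes without a unique ID mapping", dropped)
    edges = {
        edge_key(usable[u], usable[v])
        for u, v in network.edges
        if u in usable and v in usable
    }
    nodes = sorted({n for e in edges for n in e} | set(usable.values()))
    return PPINetwork(
        nodes=nodes,
        edges=edges,
        provenance={**network.provenance, "unmapped_nodes_dropped": dropped},
    )


# ---------------------------------------------------------------------------
# File I/O

_BIOGRID_COLUMNS = {
    "interactor_a": ("interactor_a", "BioGRID ID Interactor A", "#BioGRID Interaction ID"),
    "interactor_b": ("interactor_b", "BioGRID ID Interactor B"),
    "organism_a": ("organism_a", "Organism ID Interactor A", "Organism Interactor A"),
    "organism_b": ("organism_b", "Organism ID Interactor B", "Organism Interactor B"),
    "interaction_type": ("interaction_type", "Interaction Type"),
}


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read interaction records from a TSV file.

    Accepts either a minimal five-column file (interactor_a, interactor_b,
    organism_a, organism_b, interaction_type — with or without a header) or a
    BioGRID TAB-style export containing equivalently named columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.strip(): c for c in df.columns}
    resolved = {}
    for field_name, candidates in _BIOGRID_COLUMNS.items():
        for cand in candidates:
            if cand in cols:
                resolved[field_name] = cols[cand]
                break
    if len(resolved) < 5:
        # headerless minimal layout: positional 5 columns
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] < 5:
            raise ValueError(
                f"{path}: expected 5 interaction columns, found {df.shape[1]}"
            )
        df = df.iloc[:, :5]
        df.columns = list(_BIOGRID_COLUMNS)
        resolved = {k: k for k in _BIOGRID_COLUMNS}
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        try:
            records.append(
                InteractionRecord(
                    interactor_a=str(r[resolved["interactor_a"]]).strip(),
                    interactor_b=str(r[resolved["interactor_b"]]).strip(),
                    organism_a=int(r[resolved["organism_a"]]),
                    organism_b=int(r[resolved["organism_b"]]),
                    interaction_type=str(r[resolved["interaction_type"]]).strip(),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed record at data line {i}: {exc}") from exc
    return records


def read_annotation_rows(path: str | Path) -> list[tuple[str, str, str]]:
    """Read (protein, GO CC term, evidence code) rows from a TSV file."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 annotation columns")
    return [tuple(map(str.strip, map(str, row[:3]))) for row in df.itertuples(index=False)]


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column source->target ID mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    return dict(zip(df[0].str.strip(), df[1].str.strip()))


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    """Write the canonical two-column sorted edge list."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path, extra_nodes: Sequence[str] = ()) -> PPINetwork:
    """Read a two-column edge list back into a network."""
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split("\t")[:2]
            edges.add(edge_key(u, v))
    nodes = sorted({n for e in edges for n in e} | set(extra_nodes))
    return PPINetwork(nodes=nodes, edges=edges)


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    """Write the filtered annotation map as protein<TAB>location rows."""
    with open(path, "w") as fh:
        for protein in sorted(annotations):
            for loc in sort_locations(annotations[protein]):
                fh.write(f"{protein}\t{loc}\n")


def read_annotation_map(path: str | Path) -> AnnotationMap:
    """Read a protein<TAB>location file written by :func:`write_annotations`."""
    annotations: AnnotationMap = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            protein, loc = line.split("\t")[:2]
            if loc not in LOCATIONS:
                raise ValueError(f"unknown location {loc!r}")
            annotations.setdefault(protein, set()).add(loc)
    return annotations
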