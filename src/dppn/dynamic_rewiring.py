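"""Condition-specific rewiring of the PPI network from differential co-expression.

For every unordered pair of proteins measured in both conditions the PCC
difference h_{u,v} = rho_{u,v}(theta1) - rho_{u,v}(theta0) is computed, and
thresholds t_plus / t_minus are set three standard deviations above / below
the mean of all h values.  An existing interaction is removed when its pair's
h falls strictly below t_minus (the partners decouple in disease); a missing
interaction is created when h rises strictly above t_plus.  Pairs without
expression in both conditions are never edited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_io import PPINetwork, edge_key


@dataclass
class DeltaPCC:
    """Pairwise PCC differences between conditions with +/- 3 sigma thresholds.

    The mean and (population) standard deviation are taken over all unordered
    pairs u < v of the ``proteins`` list, excluding the diagonal.  By default
    every measured pair enters the statistics, matching the convention that
    co-expression is computed regardless of interaction status; the
    ``edges_only`` population restricts them to current edges.
    """

    proteins: list[str]
    h: np.ndarray
    h_bar: float
    sigma: float
    n_sigma: float = 3.0

    @property
    def t_plus(self) -> float:
        return self.h_bar + self.n_sigma * self.sigma

    @property
    def t_minus(self) -> float:
        return self.h_bar - self.n_sigma * self.sigma

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}


def delta_pcc(
    rho0: np.ndarray,
    rho1: np.ndarray,
    proteins: list[str],
    n_sigma: float = 3.0,
    stat_population: str = "all_pairs",
    network: PPINetwork | None = None,
) -> DeltaPCC:
    """Compute h = rho(theta1) - rho(theta0) and its threshold statistics."""
    rho0 = np.asarray(rho0, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if rho0.shape != rho1.shape or rho0.shape[0] != len(proteins):
        raise ValueError("correlation matrices must share shape and protein order")
    h = rho1 - rho0
    if stat_population == "all_pairs":
        iu = np.triu_indices(len(proteins), k=1)
        values = h[iu]
    elif stat_population == "edges_only":
        if network is None:
            raise ValueError("edges_only population requires the network")
        idx = {p: i for i, p in enumerate(proteins)}
        pairs = [
            (idx[u], idx[v])
            for u, v in network.edges
            if u in idx and v in idx
        ]
        values = np.array([h[i, j] for i, j in pairs])
    else:
        raise ValueError(f"unknown stat population {stat_population!r}")
    return DeltaPCC(
        proteins=list(proteins),
        h=h,
        h_bar=float(values.mean()),
        sigma=float(values.std()),  # population standard deviation
        n_sigma=n_sigma,
    )


@dataclass
class RewireResult:
    """The disease-condition network plus an exact edit log."""

    network: PPINetwork
    added: set[tuple[str, str]] = field(default_factory=set)
    removed: set[tuple[str, str]] = field(default_factory=set)

    def edit_log(self) -> list[tuple[str, str, str]]:
        rows = [(u, v, "added") for u, v in sorted(self.added)]
        rows += [(u, v, "removed") for u, v in sorted(self.removed)]
        return rows


def rewire(network0: PPINetwork, delta: DeltaPCC) -> RewireResult:
    """Edit the control network into the disease-condition topology.

    Strict inequalities are used on both sides, so a degenerate sigma = 0
    (identical correlation structure) produces no edits.  The node set is
    never changed; only edges are.
    """
    idx = delta.index
    t_plus, t_minus = delta.t_plus, delta.t_minus
    removed: set[tuple[str, str]] = set()
    for u, v in network0.edges:
        iu, iv = idx.get(u), idx.get(v)
        if iu is None or iv is None:
            continue
        if delta.h[iu, iv] < t_minus:
            removed.add(edge_key(u, v))

    node_set = set(network0.nodes)
    added: set[tuple[str, str]] = set()
    n = len(delta.proteins)
    hi, hj = np.nonzero(np.triu(delta.h > t_plus, k=1))
    for i, j in zip(hi, hj):
        u, v = delta.proteins[i], delta.proteins[j]
        if u in node_set and v in node_set:
            key = edge_key(u, v)
            if key not in network0.edges:
                added.add(key)

    edges = (network0.edges - removed) | added
    network1 = PPINetwork(
        nodes=list(network0.nodes),
        edges=edges,
        provenance={
            "rewired_from": "theta0",
            "edges_added": len(added),
            "edges_removed": len(removed),
            "t_plus": t_plus,
            "t_minus": t_minus,
        },
    )
    return RewireResult(network=network1, added=added, removed=removed)


def write_edit_log(result: RewireResult, delta: DeltaPCC, path) -> None:
    """Write the pairwise edit log (pair, h value, action) as TSV."""
    idx = delta.index
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\th\taction\n")
        for u, v, action in result.edit_log():
            h = delta.h[idx[u], idx[v]]
            fh.write(f"{u}\t{v}\t{h:.6g}\t{action}\n")
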