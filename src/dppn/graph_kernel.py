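"""Edge clustering coefficients, weighted adjacency and the diffusion kernel.

The edge clustering coefficient (ECC) of an edge {u, v} is

    eta_{u,v} = z_{u,v} / min(d_u - 1, d_v - 1),

where z is the number of triangles through the edge and d the endpoint
degrees; eta = 0 when the denominator degrades to zero (an endpoint of
degree 1).  A high ECC indicates a densely interconnected neighborhood, which
for PPI networks is a signal that the two interactors share a compartment.

The network is weighted by the product of co-expression and ECC,
a_{u,v} = rho_{u,v} * eta_{u,v} on edges and 0 elsewhere, and similarity
between all node pairs is obtained from the diffusion kernel

    K(tau) = exp(-tau * L),    L = D - A,

with D the diagonal matrix of (weighted) row sums of A.  Because L
annihilates the constant vector, each row of K sums to one, and K is
symmetric positive definite for any symmetric A — including signed weights
from negative correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.linalg import eigh

from .network_io import PPINetwork, edge_key
from .virtual_expansion import VirtualNetwork

Graph = PPINetwork | VirtualNetwork


def edge_clustering_coefficient(network: Graph, u: str, v: str) -> float:
    """ECC of the single edge {u, v}; raises if {u, v} is not an edge."""
    if edge_key(u, v) not in network.edges:
        raise ValueError(f"{{{u}, {v}}} is not an edge")
    adj = network.adjacency()
    return _ecc(adj[u], adj[v])


def _ecc(neigh_u: set, neigh_v: set) -> float:
    denom = min(len(neigh_u) - 1, len(neigh_v) - 1)
    if denom <= 0:
        return 0.0
    return len(neigh_u & neigh_v) / denom


def ecc_all(network: Graph) -> dict[tuple[str, str], float]:
    """ECC for every edge of the (unweighted) network topology."""
    adj = network.adjacency()
    return {(u, v): _ecc(adj[u], adj[v]) for u, v in network.edges}


@dataclass
class WeightedAdjacency:
    """Symmetric zero-diagonal weighted adjacency over an ordered node list."""

    node_order: list[str]
    A: np.ndarray

    def __post_init__(self):
        n = len(self.node_order)
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape does not match node order")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diagonal(self.A) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_order)}


def weighted_adjacency(
    network: Graph,
    pcc: Mapping[tuple[str, str], float] | Callable[[str, str], float] | None,
    ecc: Mapping[tuple[str, str], float] | None = None,
    clamp_negative_weights: bool = False,
) -> WeightedAdjacency:
    """Build a_{u,v} = rho_{u,v} * eta_{u,v} on edges, 0 elsewhere.

    ``pcc`` maps a canonical edge pair (or, as a callable, two node names) to
    the co-expression coefficient; a missing value defaults to a neutral 1 so
    that edges of unmeasured proteins keep their topological ECC weight.
    ``ecc`` defaults to the ECC of the network itself.  With
    ``clamp_negative_weights`` negative products are set to 0.
    """
    if ecc is None:
        ecc = ecc_all(network)
    nodes = list(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in network.edges:
        key = edge_key(u, v)
        if pcc is None:
            rho = 1.0
        elif callable(pcc):
            rho = pcc(u, v)
        else:
            rho = pcc.get(key, 1.0)
        w = rho * ecc[key]
        if clamp_negative_weights and w < 0:
            w = 0.0
        i, j = index[u], index[v]
        A[i, j] = A[j, i] = w
    return WeightedAdjacency(node_order=nodes, A=A)


@dataclass
class KernelBundle:
    """Adjacency, Laplacian and diffusion kernel over a fixed node order."""

    node_order: list[str]
    A: np.ndarray
    degrees: np.ndarray  # weighted degrees, the diagonal of D
    L: np.ndarray
    K: np.ndarray
    tau: float

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_order)}

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        idx = self.index
        ri = [idx[r] for r in rows]
        ci = [idx[c] for c in cols]
        return self.K[np.ix_(ri, ci)]


def diffusion_kernel(adjacency: WeightedAdjacency, tau: float) -> KernelBundle:
    """Compute K(tau) = exp(-tau L) by symmetric eigendecomposition.

    The weighted degree d_i = sum_v a_{i,v} is used for D, which makes L
    annihilate the constant vector and hence K row-stochastic.  Cost is
    O(n^3); intended for networks up to a few thousand nodes.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    A = adjacency.A
    degrees = A.sum(axis=1)
    L = np.diag(degrees) - A
    eigvals, U = eigh(L)
    K = (U * np.exp(-tau * eigvals)) @ U.T
    K = (K + K.T) / 2.0  # enforce exact symmetry against roundoff
    return KernelBundle(
        node_order=list(adjacency.node_order),
        A=A,
        degrees=degrees,
        L=L,
        K=K,
        tau=float(tau),
    )


def save_kernel(bundle: KernelBundle, matrix_path, nodes_path) -> None:
    """Persist the kernel matrix with a sidecar node-order list."""
    np.savetxt(matrix_path, bundle.K, delimiter="\t")
    with open(nodes_path, "w") as fh:
        fh.write("\n".join(bundle.node_order) + "\n")
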