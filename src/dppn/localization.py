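"""Diffusion-kernel SVM localization scores.

The classifier is transductive: the diffusion kernel is computed once over
the whole virtual network, and training / scoring only ever split the label
set, never the graph (a diffusion kernel cannot be evaluated for a node
outside the graph).  A multi-class SVM with the precomputed kernel and
pairwise-coupled probability estimates produces, for every scored node, a
probability vector p_u over the m locations that sums to one.

Because location class sizes are imbalanced, raw probabilities are rescaled
per location (column-wise min-max over the scored cohort) into p-hat, and
each protein's p-hat row is renormalized into the adjusted score vector q_u.
The called location set S_u contains every location whose q is within an
alpha fraction of the protein's q range below its maximum:

    q_{u,k} >= max_k q_u - alpha * (max_k q_u - min_k q_u).

alpha = 0 calls only the argmax; alpha = 1 calls every location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .graph_kernel import KernelBundle
from .vocabulary import LOCATIONS


@dataclass
class LocalizationScores:
    """Per-node localization probabilities over an ordered location list."""

    node_order: list[str]
    locations: list[str]
    P: np.ndarray  # raw probabilities, rows on the simplex
    condition: str = "theta0"

    def __post_init__(self):
        if self.P.shape != (len(self.node_order), len(self.locations)):
            raise ValueError("P shape does not match node/location lists")


def fit_predict_proba(
    kernel: KernelBundle,
    labels: dict[str, str],
    train_nodes: Sequence[str] | None = None,
    score_nodes: Sequence[str] | None = None,
    locations: Sequence[str] | None = None,
    C: float = 1.0,
    random_state: int = 0,
    condition: str = "theta0",
    check_psd: bool = True,
) -> LocalizationScores:
    """Train the precomputed-kernel SVM on labeled nodes and score nodes.

    ``train_nodes`` defaults to all labeled nodes and ``score_nodes`` to all
    kernel nodes.  ``locations`` fixes the column order of the result (classes
    absent from training get probability 0); it defaults to the sorted set of
    training labels, or the full 12-location vocabulary if requested.
    """
    if train_nodes is None:
        train_nodes = [n for n in kernel.node_order if n in labels]
    else:
        train_nodes = list(train_nodes)
    if score_nodes is None:
        score_nodes = list(kernel.node_order)
    else:
        score_nodes = list(score_nodes)

    y = [labels[n] for n in train_nodes]
    class_counts: dict[str, int] = {}
    for lab in y:
        class_counts[lab] = class_counts.get(lab, 0) + 1
    small = sorted(k for k, c in class_counts.items() if c < 2)
    if small:
        raise ValueError(f"classes with fewer than 2 training nodes: {small}")
    if len(class_counts) < 2:
        raise ValueError("need at least 2 classes in training labels")

    K_train = kernel.submatrix(train_nodes, train_nodes)
    if check_psd:
        min_eig = float(np.linalg.eigvalsh(K_train).min())
        if min_eig < -1e-8:
            raise ValueError(f"kernel is not positive definite (min eigenvalue {min_eig:.3g})")

    clf = SVC(kernel="precomputed", C=C, probability=True, random_state=random_state)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates probability=True; the pairwise-coupled
        # Platt estimates are exactly the probability machinery we model.
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(K_train, y)
    proba = clf.predict_proba(kernel.submatrix(score_nodes, train_nodes))

    if locations is None:
        locations = sorted(class_counts, key=lambda loc: LOCATIONS.index(loc))
    locations = list(locations)
    P = np.zeros((len(score_nodes), len(locations)))
    col = {loc: j for j, loc in enumerate(locations)}
    for ci, cls in enumerate(clf.classes_):
        if cls not in col:
            raise ValueError(f"training class {cls!r} missing from location list")
        P[:, col[cls]] = proba[:, ci]
    return LocalizationScores(
        node_order=score_nodes, locations=locations, P=P, condition=condition
    )


def adjust_scores(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise min-max rescaling and per-row renormalization.

    Returns (P_hat, Q).  The min and max are taken over the proteins being
    scored in this call, so Q is cohort-dependent by construction.  A
    degenerate column (max == min) carries no ranking information and is set
    to 0; a row that ends up all-zero becomes the uniform distribution.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least 2 protein rows")
    lo = P.min(axis=0)
    hi = P.max(axis=0)
    span = hi - lo
    ok = span > 0
    P_hat = np.zeros_like(P)
    P_hat[:, ok] = (P[:, ok] - lo[ok]) / span[ok]
    row_sum = P_hat.sum(axis=1)
    zero_rows = row_sum == 0
    Q = np.empty_like(P_hat)
    Q[~zero_rows] = P_hat[~zero_rows] / row_sum[~zero_rows, None]
    Q[zero_rows] = 1.0 / P.shape[1]
    return P_hat, Q


def call_locations(q_row: np.ndarray, alpha: float) -> set[int]:
    """Indices of locations called for one protein at tolerance alpha."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    q_row = np.asarray(q_row, dtype=float)
    q_max = q_row.max()
    threshold = q_max - alpha * (q_max - q_row.min())
    # tiny slack so the boundary cases (alpha = 1 must include the minimum)
    # are not lost to floating-point roundoff in the threshold
    tol = 1e-12 * max(1.0, abs(q_max))
    return {int(i) for i in np.nonzero(q_row >= threshold - tol)[0]}


def call_all(Q: np.ndarray, locations: Sequence[str], alpha: float) -> list[set[str]]:
    """Called location-name sets for every row of Q."""
    return [{locations[i] for i in call_locations(row, alpha)} for row in Q]


def reduce_siblings(
    scores: LocalizationScores,
    parent: dict[str, str],
    how: str = "mean",
) -> LocalizationScores:
    """Collapse virtual-copy rows to one row per real protein.

    Sibling rows are combined by ``mean`` (default) or ``max``; mean keeps the
    row on the probability simplex.  Real proteins are ordered
    lexicographically.
    """
    groups: dict[str, list[int]] = {}
    for i, node in enumerate(scores.node_order):
        groups.setdefault(parent.get(node, node), []).append(i)
    proteins = sorted(groups)
    P = np.empty((len(proteins), len(scores.locations)))
    for r, protein in enumerate(proteins):
        rows = scores.P[groups[protein]]
        if how == "mean":
            P[r] = rows.mean(axis=0)
        elif how == "max":
            P[r] = rows.max(axis=0)
        else:
            raise ValueError(f"unknown sibling reduction {how!r}")
    return LocalizationScores(
        node_order=proteins,
        locations=list(scores.locations),
        P=P,
        condition=scores.condition,
    )
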