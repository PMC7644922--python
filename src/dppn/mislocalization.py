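"""Mis-localization scores and candidate ranking between conditions.

For a protein u and location k with adjusted localization scores q0 (control)
and q1 (disease), the mis-localization score is the relative change

    phi_{u,k} = (q1 - q0) / q0,

which is +Inf when a location unreachable in control (q0 = 0) gains score in
disease, and 0 when both conditions give it zero.  Per protein, the largest
phi over locations (sup) measures the strongest gained compartment and the
smallest (inf) the strongest lost one.  Proteins are ranked by sup descending
("moves to" list) and by inf ascending ("moves from" list); the top fixed
fraction of each list (0.1% by default) is flagged as candidate mis-localized
proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def mislocalization_score(q0: float, q1: float) -> float:
    """Relative score change (q1 - q0) / q0 with the 0/0 -> 0 convention."""
    if q0 < 0 or q1 < 0:
        raise ValueError("adjusted scores must be non-negative")
    if q0 == 0:
        return math.inf if q1 > 0 else 0.0
    return (q1 - q0) / q0


def phi_matrix(Q0: np.ndarray, Q1: np.ndarray) -> np.ndarray:
    """Element-wise mis-localization scores for matched score matrices."""
    Q0 = np.asarray(Q0, dtype=float)
    Q1 = np.asarray(Q1, dtype=float)
    if Q0.shape != Q1.shape:
        raise ValueError("score matrices must have the same shape")
    if (Q0 < 0).any() or (Q1 < 0).any():
        raise ValueError("adjusted scores must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (Q1 - Q0) / Q0
    phi[(Q0 == 0) & (Q1 > 0)] = np.inf
    phi[(Q0 == 0) & (Q1 == 0)] = 0.0
    return phi


@dataclass
class RankedProtein:
    protein: str
    location: str  # the extreme location driving the rank
    q0: float
    q1: float
    phi: float
    rank: int  # 1-based position in its list
    flagged: bool


@dataclass
class MislocalizationReport:
    """phi matrix plus the two ranked candidate lists."""

    proteins: list[str]
    locations: list[str]
    phi: np.ndarray
    sup: np.ndarray  # max over locations per protein
    inf: np.ndarray  # min over locations per protein
    moves_to: list[RankedProtein]  # sup descending
    moves_from: list[RankedProtein]  # inf ascending
    fraction: float
    n_flagged: int

    def flagged_to(self) -> list[str]:
        return [r.protein for r in self.moves_to if r.flagged]

    def flagged_from(self) -> list[str]:
        return [r.protein for r in self.moves_from if r.flagged]


def rank_candidates(
    Q0: np.ndarray,
    Q1: np.ndarray,
    proteins: list[str],
    locations: list[str],
    fraction: float = 0.001,
) -> MislocalizationReport:
    """Rank proteins by sup/inf mis-localization scores.

    Ties (notably multiple +Inf sup scores) are broken by the disease-side
    score q1 at the extreme location, descending, then by protein ID.  The top
    ceil(fraction * N) of each list is flagged.
    """
    Q0 = np.asarray(Q0, dtype=float)
    Q1 = np.asarray(Q1, dtype=float)
    if Q0.shape != Q1.shape or Q0.shape[0] != len(proteins):
        raise ValueError("score matrices and protein list are inconsistent")
    phi = phi_matrix(Q0, Q1)
    sup = phi.max(axis=1)
    inf = phi.min(axis=1)
    k_sup = phi.argmax(axis=1)
    k_inf = phi.argmin(axis=1)
    n = len(proteins)
    n_flagged = math.ceil(fraction * n)

    def build(order: list[int], extremes: np.ndarray, ks: np.ndarray) -> list[RankedProtein]:
        out = []
        for pos, i in enumerate(order, start=1):
            k = ks[i]
            out.append(
                RankedProtein(
                    protein=proteins[i],
                    location=locations[k],
                    q0=float(Q0[i, k]),
                    q1=float(Q1[i, k]),
                    phi=float(extremes[i]),
                    rank=pos,
                    flagged=pos <= n_flagged,
                )
            )
        return out

    to_order = sorted(
        range(n),
        key=lambda i: (-sup[i], -Q1[i, k_sup[i]], proteins[i]),
    )
    from_order = sorted(
        range(n),
        key=lambda i: (inf[i], Q1[i, k_inf[i]], proteins[i]),
    )
    return MislocalizationReport(
        proteins=list(proteins),
        locations=list(locations),
        phi=phi,
        sup=sup,
        inf=inf,
        moves_to=build(to_order, sup, k_sup),
        moves_from=build(from_order, inf, k_inf),
        fraction=fraction,
        n_flagged=n_flagged,
    )


def write_report(report: MislocalizationReport, path) -> None:
    """Write both ranked lists as TSV, scores expressed in percent."""
    with open(path, "w") as fh:
        fh.write("protein\tlocation\tq0\tq1\tphi_percent\tlist\trank\tflagged\n")
        for tag, rows in (("to", report.moves_to), ("from", report.moves_from)):
            for r in rows:
                pct = "+Inf" if math.isinf(r.phi) else f"{100 * r.phi:.2f}"
                fh.write(
                    f"{r.protein}\t{r.location}\t{r.q0:.6g}\t{r.q1:.6g}\t"
                    f"{pct}\t{tag}\t{r.rank}\t{r.flagged}\n"
                )
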