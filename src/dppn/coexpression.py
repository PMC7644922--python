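"""Per-condition expression matrices and all-pairs Pearson correlation.

Expression arrives as a probe-level matrix (rows = probes, columns =
samples); probes mapping many-to-one onto a protein are aggregated by the
arithmetic mean.  Within one sample group (control theta0 or case theta1)
the co-expression of two proteins is the Pearson correlation of their
sample-wise centered expression vectors.  Correlations are computed for every
pair of measured proteins, whether or not they physically interact, because
both edge weighting (interacting pairs) and network rewiring (all pairs) need
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

THETA0 = "theta0"  # control / non-disease group
THETA1 = "theta1"  # case / disease group


@dataclass
class ExpressionCondition:
    """Protein-by-sample expression for one sample group."""

    proteins: list[str]
    X: np.ndarray
    group: str = THETA0

    def __post_init__(self):
        if self.X.shape[0] != len(self.proteins):
            raise ValueError("matrix rows do not match protein list")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein IDs")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples per condition")
        if np.isnan(self.X).any():
            raise ValueError("missing values in expression matrix")

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}


def aggregate_probes(
    probe_matrix: pd.DataFrame,
    probe_to_protein: Mapping[str, str],
    group: str = THETA0,
) -> ExpressionCondition:
    """Collapse probe rows to protein rows by the arithmetic mean.

    Probes absent from the map are dropped (counted and logged).
    """
    mapped = probe_matrix.index.to_series().map(dict(probe_to_protein))
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info("dropped %d probes without a protein mapping", n_dropped)
    kept = probe_matrix.loc[mapped.notna()]
    collapsed = kept.groupby(mapped.dropna(), sort=True).mean()
    return ExpressionCondition(
        proteins=list(collapsed.index),
        X=collapsed.to_numpy(dtype=float),
        group=group,
    )


def center(condition: ExpressionCondition) -> np.ndarray:
    """Sample-wise centered expression vectors (each row sums to zero)."""
    return condition.X - condition.X.mean(axis=1, keepdims=True)


def pcc(xu: np.ndarray, xv: np.ndarray) -> float:
    """Pearson correlation of two centered vectors; 0 when either has zero norm."""
    xu = np.asarray(xu, dtype=float)
    xv = np.asarray(xv, dtype=float)
    if xu.shape != xv.shape:
        raise ValueError("vectors have different lengths")
    denom = np.sqrt((xu @ xu) * (xv @ xv))
    if denom == 0:
        return 0.0
    return float(np.clip((xu @ xv) / denom, -1.0, 1.0))


def all_pairs_pcc(condition: ExpressionCondition) -> np.ndarray:
    """Full symmetric correlation matrix over the condition's proteins.

    Zero-variance rows are uninformative; their correlations (including the
    diagonal entry) are set to 0 by convention.
    """
    Xc = center(condition)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    Z = Xc / safe[:, None]
    R = Z @ Z.T
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    R[~ok, :] = 0.0
    R[:, ~ok] = 0.0
    return R


def pcc_lookup(condition: ExpressionCondition, rho: np.ndarray | None = None):
    """Return a callable (u, v) -> rho for real-protein IDs.

    Virtual locative IDs are resolved through their parent automatically by
    the caller; pairs with an unmeasured protein get a neutral 1.0 so that
    edge weights fall back to ECC alone.
    """
    if rho is None:
        rho = all_pairs_pcc(condition)
    index = condition.index

    def lookup(u: str, v: str) -> float:
        iu = index.get(u)
        iv = index.get(v)
        if iu is None or iv is None:
            return 1.0
        return float(rho[iu, iv])

    return lookup


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV (first column = row ID, header = sample IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_groups(path) -> dict[str, str]:
    """Read the sample-group TSV (sample ID, theta0|theta1)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    groups = dict(zip(df[0].str.strip(), df[1].str.strip()))
    bad = {g for g in groups.values() if g not in (THETA0, THETA1)}
    if bad:
        raise ValueError(f"unknown sample groups: {sorted(bad)}")
    return groups


def split_conditions(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[ExpressionCondition, ExpressionCondition]:
    """Split a protein-level matrix into (theta0, theta1) conditions."""
    out = []
    for tag in (THETA0, THETA1):
        cols = [s for s in matrix.columns if groups.get(s) == tag]
        out.append(
            ExpressionCondition(
                proteins=list(matrix.index),
                X=matrix[cols].to_numpy(dtype=float),
                group=tag,
            )
        )
    return out[0], out[1]


def write_expression(condition: ExpressionCondition, path) -> None:
    pd.DataFrame(
        condition.X,
        index=condition.proteins,
        columns=[f"{condition.group}_s{i}" for i in range(condition.n_samples)],
    ).to_csv(path, sep="\t")
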