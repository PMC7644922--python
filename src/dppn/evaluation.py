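"""Multi-label and single-label performance metrics, cross-validation and
parameter calibration.

Multi-label metrics compare the predicted location set S_u(theta0) of each
protein with its annotated set S_u:

    AIM   — mean |pred ∩ true| / |pred|   (precision-like "aiming")
    CVR   — mean |pred ∩ true| / |true|   (recall-like "coverage")
    mlACC — mean Jaccard |pred ∩ true| / |pred ∪ true|
    ATR   — mean exact-match indicator    ("absolute true rate")

Single-label metrics (Sen, Spe, PPV, vlAcc, MCC) are computed from a pooled
one-vs-rest confusion over (protein, location) cells — each annotated
(protein, location) pair is one virtual locative positive — aggregated
micro-style across the 10 cross-validation folds.

Cross-validation is transductive and grouped: the kernel is fixed, labels are
split, and all virtual copies of one real protein share a fold so sibling
rows can never leak between training and test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .graph_kernel import KernelBundle
from .localization import adjust_scores, call_all, fit_predict_proba, reduce_siblings
from .vocabulary import LOCATION_INDEX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultiLabelMetrics:
    AIM: float
    CVR: float
    mlACC: float
    ATR: float
    b: int  # number of proteins evaluated


def multilabel_metrics(pred: Sequence[set], truth: Sequence[set]) -> MultiLabelMetrics:
    """Set-overlap metrics averaged over proteins.

    An empty predicted set contributes 0 to AIM (and the other statistics);
    the thresholding rule cannot produce one, so this only covers externally
    supplied predictions.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    if any(not t for t in truth):
        raise ValueError("truth sets must be non-empty")
    b = len(pred)
    if b == 0:
        raise ValueError("no proteins to evaluate")
    aim = cvr = jac = atr = 0.0
    n_empty = 0
    for p, t in zip(pred, truth):
        inter = len(p & t)
        if p:
            aim += inter / len(p)
        else:
            n_empty += 1
        cvr += inter / len(t)
        jac += inter / len(p | t) if (p | t) else 0.0
        atr += 1.0 if p == t else 0.0
    if n_empty:
        logger.warning("%d empty predicted sets counted as 0 aiming", n_empty)
    return MultiLabelMetrics(AIM=aim / b, CVR=cvr / b, mlACC=jac / b, ATR=atr / b, b=b)


@dataclass(frozen=True)
class BinaryMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    Sen: float
    Spe: float
    PPV: float
    vlAcc: float
    MCC: float


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> BinaryMetrics:
    """Sensitivity, specificity, PPV, accuracy and MCC from a confusion table.

    A zero marginal makes the MCC denominator vanish; MCC is 0 by convention
    in that case.  Ratio statistics with a zero denominator are also 0.
    """
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num, den):
        return num / den if den else 0.0

    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return BinaryMetrics(
        TP=tp, TN=tn, FP=fp, FN=fn,
        Sen=ratio(tp, tp + fn),
        Spe=ratio(tn, tn + fp),
        PPV=ratio(tp, tp + fp),
        vlAcc=(tp + tn) / total,
        MCC=mcc,
    )


def confusion_from_sets(
    pred: Sequence[set], truth: Sequence[set], locations: Sequence[str]
) -> tuple[int, int, int, int]:
    """Micro one-vs-rest confusion over every (protein, location) cell."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth):
        for loc in locations:
            in_p, in_t = loc in p, loc in t
            if in_p and in_t:
                tp += 1
            elif in_p:
                fp += 1
            elif in_t:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------
# Cross-validation


def truth_sets(labels: dict[str, str], parent: dict[str, str]) -> dict[str, set[str]]:
    """Annotated location set per real protein from virtual-node labels."""
    truth: dict[str, set[str]] = {}
    for node, loc in labels.items():
        truth.setdefault(parent.get(node, node), set()).add(loc)
    return truth


def assign_folds(
    proteins: Sequence[str],
    first_location: dict[str, str],
    folds: int,
    seed: int,
) -> dict[str, int]:
    """Deterministic grouped, location-stratified fold assignment.

    Proteins are shuffled within strata of their first (canonical-order)
    location and dealt round-robin, so fold sizes differ by at most one.
    """
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for p in sorted(proteins):
        strata.setdefault(first_location[p], []).append(p)
    ordered: list[str] = []
    for loc in sorted(strata, key=LOCATION_INDEX.__getitem__):
        block = strata[loc]
        rng.shuffle(block)
        ordered.extend(block)
    return {p: i % folds for i, p in enumerate(ordered)}


@dataclass
class FoldScores:
    """Held-out adjusted scores for the proteins of one fold."""

    proteins: list[str]
    Q: np.ndarray
    locations: list[str]


def _cv_fold_scores(
    kernel: KernelBundle,
    labels: dict[str, str],
    parent: dict[str, str],
    folds: int,
    seed: int,
    C: float,
    sibling_reduce: str = "mean",
) -> list[FoldScores]:
    """Run the label-split CV and return per-fold adjusted score matrices."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    truth = truth_sets(labels, parent)
    first_loc = {
        p: sorted(locs, key=LOCATION_INDEX.__getitem__)[0] for p, locs in truth.items()
    }
    fold_of = assign_folds(list(truth), first_loc, folds, seed)
    locations = sorted({loc for loc in labels.values()}, key=LOCATION_INDEX.__getitem__)

    copies: dict[str, list[str]] = {}
    for node in kernel.node_order:
        if node in labels:
            copies.setdefault(parent.get(node, node), []).append(node)

    out: list[FoldScores] = []
    for f in range(folds):
        test_proteins = sorted(p for p, fd in fold_of.items() if fd == f)
        train_nodes = [
            n for n in kernel.node_order
            if n in labels and fold_of[parent.get(n, n)] != f
        ]
        class_counts: dict[str, int] = {}
        for n in train_nodes:
            class_counts[labels[n]] = class_counts.get(labels[n], 0) + 1
        skipped = {c for c, k in class_counts.items() if k < 2}
        if skipped:
            logger.warning("fold %d: classes %s absent/rare in training, skipped", f, sorted(skipped))
            train_nodes = [n for n in train_nodes if labels[n] not in skipped]
        score_nodes = [n for p in test_proteins for n in copies[p]]
        scores = fit_predict_proba(
            kernel,
            labels,
            train_nodes=train_nodes,
            score_nodes=score_nodes,
            locations=locations,
            C=C,
            random_state=seed + f,
            check_psd=False,
        )
        reduced = reduce_siblings(scores, parent, how=sibling_reduce)
        _, Q = adjust_scores(reduced.P)
        out.append(FoldScores(proteins=reduced.node_order, Q=Q, locations=locations))
    return out


@dataclass
class CVResult:
    multilabel: MultiLabelMetrics
    binary: BinaryMetrics
    folds: int
    alpha: float
    seed: int


def _metrics_at_alpha(
    fold_scores: list[FoldScores],
    truth: dict[str, set[str]],
    alpha: float,
) -> tuple[MultiLabelMetrics, BinaryMetrics]:
    pred_sets: list[set] = []
    truth_list: list[set] = []
    locations = fold_scores[0].locations
    for fs in fold_scores:
        calls = call_all(fs.Q, fs.locations, alpha)
        pred_sets.extend(calls)
        truth_list.extend(truth[p] for p in fs.proteins)
    ml = multilabel_metrics(pred_sets, truth_list)
    tp, tn, fp, fn = confusion_from_sets(pred_sets, truth_list, locations)
    return ml, binary_metrics(tp, tn, fp, fn)


def cross_validate(
    kernel: KernelBundle,
    labels: dict[str, str],
    parent: dict[str, str],
    folds: int = 10,
    alpha: float = 0.3,
    seed: int = 0,
    C: float = 1.0,
    sibling_reduce: str = "mean",
) -> CVResult:
    """Grouped 10-fold CV of the localization step; deterministic per seed."""
    fold_scores = _cv_fold_scores(kernel, labels, parent, folds, seed, C, sibling_reduce)
    truth = truth_sets(labels, parent)
    ml, bm = _metrics_at_alpha(fold_scores, truth, alpha)
    return CVResult(multilabel=ml, binary=bm, folds=folds, alpha=alpha, seed=seed)


# ---------------------------------------------------------------------------
# Grid-search calibration

DEFAULT_TAU_GRID = tuple(round(0.1 * i, 1) for i in range(1, 21))  # 0.1 .. 2.0
DEFAULT_ALPHA_GRID = (0.1, 0.2, 0.3)


@dataclass
class CalibrationResult:
    """Global MCC per (tau, alpha) grid cell and the argmax cell."""

    grid: dict[tuple[float, float], float]
    best: tuple[float, float]

    @property
    def best_mcc(self) -> float:
        return self.grid[self.best]


def grid_search(
    kernel_builder: Callable[[float], KernelBundle],
    labels: dict[str, str],
    parent: dict[str, str],
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> CalibrationResult:
    """Cross-validated global MCC over the (tau, alpha) grid.

    The SVM scores depend only on tau, so each kernel's CV is run once and
    re-thresholded per alpha.  Ties at the maximum resolve to the smallest
    (tau, alpha) in grid order.
    """
    if not tau_grid or not alpha_grid:
        raise ValueError("grids must be non-empty")
    truth = truth_sets(labels, parent)
    grid: dict[tuple[float, float], float] = {}
    for tau in tau_grid:
        kernel = kernel_builder(tau)
        fold_scores = _cv_fold_scores(kernel, labels, parent, folds, seed, C)
        for alpha in alpha_grid:
            _, bm = _metrics_at_alpha(fold_scores, truth, alpha)
            grid[(tau, alpha)] = bm.MCC
    best = max(grid, key=lambda cell: (grid[cell], (-cell[0], -cell[1])))
    return CalibrationResult(grid=grid, best=best)


def write_calibration(result: CalibrationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("tau\talpha\tMCC\n")
        for (tau, alpha), mcc in sorted(result.grid.items()):
            fh.write(f"{tau}\t{alpha}\t{mcc:.6f}\n")
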