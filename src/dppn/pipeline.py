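"""End-to-end orchestration: control branch, disease branch, comparison.

The flow is

    filter -> annotate
    -> PCC(theta0) -> expand -> ECC -> weight -> kernel -> scores (theta0)
    -> PCC(theta1) -> rewire -> expand -> ECC -> weight -> kernel -> scores (theta1)
    -> mis-localization scores -> ranked candidate lists.

Rewiring operates on the real-protein network; virtual expansion happens
afterwards, per condition, from the same annotation map, so each condition's
kernel reflects its own topology while co-expression stays defined per real
gene.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .coexpression import ExpressionCondition, all_pairs_pcc
from .dynamic_rewiring import DeltaPCC, RewireResult, delta_pcc, rewire
from .graph_kernel import KernelBundle, diffusion_kernel, ecc_all, weighted_adjacency
from .localization import (
    LocalizationScores,
    adjust_scores,
    call_all,
    fit_predict_proba,
    reduce_siblings,
)
from .mislocalization import MislocalizationReport, rank_candidates
from .network_io import AnnotationMap, PPINetwork
from .virtual_expansion import VirtualNetwork, expand
from .vocabulary import LOCATION_INDEX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of one pipeline run (defaults are the calibrated values)."""

    tau: float = 1.1
    alpha: float = 0.3
    fraction: float = 0.001
    svm_C: float = 1.0
    seed: int = 0
    rewire_n_sigma: float = 3.0
    rewire_stat_population: str = "all_pairs"
    sibling_reduce: str = "mean"
    clamp_negative_weights: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


@dataclass
class ConditionResult:
    """Everything computed for one condition branch."""

    network: PPINetwork
    virtual: VirtualNetwork
    kernel: KernelBundle
    scores: LocalizationScores  # per real protein, sibling-reduced
    Q: np.ndarray
    called: list[set[str]]


@dataclass
class PipelineResult:
    config: RunConfig
    control: ConditionResult
    disease: ConditionResult
    delta: DeltaPCC
    rewiring: RewireResult
    report: MislocalizationReport
    manifest: dict = field(default_factory=dict)


def _condition_branch(
    network: PPINetwork,
    annotations: AnnotationMap,
    rho: np.ndarray,
    expr: ExpressionCondition,
    config: RunConfig,
    condition: str,
    locations: list[str],
) -> ConditionResult:
    vnet = expand(network, annotations)
    ecc = ecc_all(vnet)
    expr_idx = expr.index

    def pcc_of(u: str, v: str) -> float:
        pu = vnet.parent.get(u, u)
        pv = vnet.parent.get(v, v)
        iu, iv = expr_idx.get(pu), expr_idx.get(pv)
        if iu is None or iv is None:
            return 1.0  # unmeasured pair: fall back to ECC-only weight
        return float(rho[iu, iv])

    W = weighted_adjacency(
        vnet, pcc_of, ecc, clamp_negative_weights=config.clamp_negative_weights
    )
    kernel = diffusion_kernel(W, config.tau)
    raw = fit_predict_proba(
        kernel,
        vnet.label,
        locations=locations,
        C=config.svm_C,
        random_state=config.seed,
        condition=condition,
        check_psd=False,  # exp(-tau L) is positive definite by construction
    )
    reduced = reduce_siblings(raw, vnet.parent, how=config.sibling_reduce)
    _, Q = adjust_scores(reduced.P)
    called = call_all(Q, locations, config.alpha)
    logger.info(
        "%s: %d nodes, %d edges, %d virtual nodes, %d proteins scored",
        condition, network.n_nodes, network.n_edges, vnet.n_nodes, len(reduced.node_order),
    )
    return ConditionResult(
        network=network, virtual=vnet, kernel=kernel,
        scores=reduced, Q=Q, called=called,
    )


def run_pipeline(
    network: PPINetwork,
    annotations: AnnotationMap,
    expression0: ExpressionCondition,
    expression1: ExpressionCondition,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full control/disease comparison on in-memory inputs."""
    if expression0.proteins != expression1.proteins:
        raise ValueError("expression conditions must share the same protein order")
    locations = sorted(
        {loc for locs in annotations.values() for loc in locs},
        key=LOCATION_INDEX.__getitem__,
    )

    rho0 = all_pairs_pcc(expression0)
    control = _condition_branch(
        network, annotations, rho0, expression0, config, "theta0", locations
    )

    rho1 = all_pairs_pcc(expression1)
    delta = delta_pcc(
        rho0, rho1, list(expression0.proteins),
        n_sigma=config.rewire_n_sigma,
        stat_population=config.rewire_stat_population,
        network=network,
    )
    rewiring = rewire(network, delta)
    logger.info(
        "rewiring: %d edges added, %d removed (t+=%.4f, t-=%.4f)",
        len(rewiring.added), len(rewiring.removed), delta.t_plus, delta.t_minus,
    )
    disease = _condition_branch(
        rewiring.network, annotations, rho1, expression1, config, "theta1", locations
    )

    if control.scores.node_order != disease.scores.node_order:
        raise AssertionError("condition branches scored different protein sets")
    report = rank_candidates(
        control.Q, disease.Q, control.scores.node_order, locations,
        fraction=config.fraction,
    )

    manifest = {
        "dppn_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_proteins": network.n_nodes,
        "n_edges_theta0": network.n_edges,
        "n_edges_theta1": rewiring.network.n_edges,
        "edges_added": len(rewiring.added),
        "edges_removed": len(rewiring.removed),
        "n_virtual_theta0": control.virtual.n_nodes,
        "n_virtual_theta1": disease.virtual.n_nodes,
        "locations": locations,
    }
    return PipelineResult(
        config=config, control=control, disease=disease,
        delta=delta, rewiring=rewiring, report=report, manifest=manifest,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Persist every pipeline artifact (scores, edit log, report, manifest)."""
    from .dynamic_rewiring import write_edit_log
    from .mislocalization import write_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for branch, tag in ((result.control, "theta0"), (result.disease, "theta1")):
        _write_scores(branch, outdir / f"scores_{tag}.tsv")
    write_edit_log(result.rewiring, result.delta, outdir / "rewire_edits.tsv")
    write_report(result.report, outdir / "mislocalization.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def _write_scores(branch: ConditionResult, path: Path) -> None:
    locs = branch.scores.locations
    with open(path, "w") as fh:
        header = ["protein"] + [f"p:{l}" for l in locs] + [f"q:{l}" for l in locs] + ["called"]
        fh.write("\t".join(header) + "\n")
        for i, protein in enumerate(branch.scores.node_order):
            p_vals = "\t".join(f"{x:.6g}" for x in branch.scores.P[i])
            q_vals = "\t".join(f"{x:.6g}" for x in branch.Q[i])
            called = ";".join(sorted(branch.called[i]))
            fh.write(f"{protein}\t{p_vals}\t{q_vals}\t{called}\n")
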