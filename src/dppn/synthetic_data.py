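"""Self-contained benchmark instances with known ground truth.

The generator emulates the statistical structure the pipeline exploits:

* a PPI network with location-correlated community structure — proteins
  sharing a subcellular location interact with probability ``p_in``, others
  with ``p_out`` (a stochastic block model keyed on location, with
  multi-location proteins bridging blocks);
* per-condition expression with controlled pairwise correlation — each
  location contributes a latent per-sample factor, protein u's profile is the
  mean of its locations' factors plus Gaussian noise, so interacting
  same-location pairs show elevated Pearson correlation;
* a planted subset of proteins whose co-expression partners change between
  conditions — in the case condition their profiles follow a *target*
  location's factor instead, raising the PCC difference h toward new partners
  and lowering it toward old ones.

Everything is a deterministic function of the seed.  The defaults (300
proteins, 4 locations, multiplicity distribution shaped like typical human
annotation data, co-expression strength 0.8, 40 samples per condition, 10
planted proteins) are a desk-scale instance strong enough for the planted
signal to dominate sampling noise in the correlation estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import THETA0, THETA1, ExpressionCondition
from .mislocalization import MislocalizationReport
from .network_io import AnnotationMap, PPINetwork, edge_key
from .vocabulary import LOCATIONS


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 300
    m_locations: int = 4
    #: probability that a protein has 1, 2, ... locations (truncated at m)
    multiplicity_probs: tuple[float, ...] = (0.64, 0.27, 0.08, 0.01)
    p_in: float = 0.15
    p_out: float = 0.01
    n_samples_control: int = 40
    n_samples_case: int = 40
    #: target Pearson correlation between same-location interacting pairs
    coexpression_strength: float = 0.8
    n_planted: int = 10
    seed: int = 7

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need p_in > p_out >= 0")
        if self.n_samples_control < 3 or self.n_samples_case < 3:
            raise ValueError("need at least 3 samples per condition")
        if not 0 < self.coexpression_strength < 1:
            raise ValueError("coexpression strength must be in (0, 1)")
        if self.n_planted >= self.n_proteins:
            raise ValueError("cannot plant more proteins than exist")
        if self.m_locations > len(LOCATIONS):
            raise ValueError("at most 12 locations available")

    @property
    def locations(self) -> tuple[str, ...]:
        return LOCATIONS[: self.m_locations]

    @property
    def noise_sd(self) -> float:
        # corr(f + s*eps, f + s*eps') = 1 / (1 + s^2) = strength
        return float(np.sqrt(1.0 / self.coexpression_strength - 1.0))


@dataclass(frozen=True)
class PlantedMislocalization:
    protein: str
    source_locations: frozenset[str]
    target_location: str


@dataclass
class SyntheticInstance:
    config: SyntheticConfig
    network: PPINetwork
    annotations: AnnotationMap
    expression0: ExpressionCondition
    expression1: ExpressionCondition
    planted: list[PlantedMislocalization] = field(default_factory=list)


def generate(config: SyntheticConfig) -> SyntheticInstance:
    """Generate one benchmark instance, fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    locations = config.locations
    m = config.m_locations
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]

    # annotations: multiplicity from the configured distribution, locations
    # sampled without replacement
    probs = np.asarray(config.multiplicity_probs, dtype=float)
    probs = probs[: m] / probs[: m].sum()
    kappas = rng.choice(np.arange(1, len(probs) + 1), size=config.n_proteins, p=probs)
    annotations: AnnotationMap = {}
    for protein, kappa in zip(proteins, kappas):
        chosen = rng.choice(m, size=kappa, replace=False)
        annotations[protein] = {locations[i] for i in chosen}

    # network: share-a-location stochastic block structure
    edges: set[tuple[str, str]] = set()
    loc_sets = [annotations[p] for p in proteins]
    for i in range(config.n_proteins):
        for j in range(i + 1, config.n_proteins):
            p = config.p_in if loc_sets[i] & loc_sets[j] else config.p_out
            if rng.random() < p:
                edges.add(edge_key(proteins[i], proteins[j]))
    network = PPINetwork(nodes=list(proteins), edges=edges,
                         provenance={"generator": "synthetic", "seed": config.seed})

    # planted mis-localizations: single-location proteins moving to a
    # location they are not annotated with
    singles = [p for p in proteins if len(annotations[p]) == 1]
    rng.shuffle(singles)
    planted: list[PlantedMislocalization] = []
    for protein in singles[: config.n_planted]:
        source = annotations[protein]
        candidates = [loc for loc in locations if loc not in source]
        target = candidates[rng.integers(len(candidates))]
        planted.append(
            PlantedMislocalization(
                protein=protein,
                source_locations=frozenset(source),
                target_location=target,
            )
        )
    planted_target = {p.protein: p.target_location for p in planted}

    loc_index = {loc: k for k, loc in enumerate(locations)}
    sd = config.noise_sd

    def expression(n_samples: int, condition: str) -> ExpressionCondition:
        factors = rng.standard_normal((m, n_samples))
        X = np.empty((config.n_proteins, n_samples))
        for i, protein in enumerate(proteins):
            if condition == THETA1 and protein in planted_target:
                signal = factors[loc_index[planted_target[protein]]]
            else:
                rows = [loc_index[loc] for loc in annotations[protein]]
                signal = factors[rows].sum(axis=0) / np.sqrt(len(rows))
            X[i] = signal + sd * rng.standard_normal(n_samples)
        return ExpressionCondition(proteins=list(proteins), X=X, group=condition)

    expression0 = expression(config.n_samples_control, THETA0)
    expression1 = expression(config.n_samples_case, THETA1)
    return SyntheticInstance(
        config=config,
        network=network,
        annotations=annotations,
        expression0=expression0,
        expression1=expression1,
        planted=planted,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the ranked candidate lists recover the planted proteins."""

    recovered: frozenset[str]
    recall: float
    precision: float
    k: int


def ground_truth_recovery(
    report: MislocalizationReport,
    planted: list[PlantedMislocalization],
    k: int | None = None,
) -> RecoveryMetrics:
    """Recall/precision of planted proteins in the top-k sup and inf lists.

    A planted protein counts as recovered if it appears in the top k of
    either ranked list (it gains its target compartment and loses its source
    one, so both lists are informative).  ``k`` defaults to the planted count.
    """
    truth = {p.protein for p in planted}
    if not truth:
        return RecoveryMetrics(recovered=frozenset(), recall=0.0, precision=0.0, k=0)
    if k is None:
        k = len(truth)
    top = {r.protein for r in report.moves_to[:k]} | {
        r.protein for r in report.moves_from[:k]
    }
    recovered = frozenset(truth & top)
    return RecoveryMetrics(
        recovered=recovered,
        recall=len(recovered) / len(truth),
        precision=len(recovered) / len(top) if top else 0.0,
        k=k,
    )


def permute_conditions(
    instance: SyntheticInstance, seed: int, stratified: bool = True
) -> tuple[ExpressionCondition, ExpressionCondition]:
    """Null model: shuffle the condition labels across the pooled samples.

    With ``stratified`` (the default) each permuted group draws the same
    number of samples from each original condition, the standard balanced
    permutation null: it removes the condition signal without confounding the
    two permuted groups with their original-condition composition.  An
    unstratified shuffle leaves a residual composition signal for exactly the
    condition-heterogeneous (planted) proteins.  Planted recovery on the
    permuted data should drop to the chance level.
    """
    rng = np.random.default_rng(seed)
    X0_, X1_ = instance.expression0.X, instance.expression1.X
    n0 = instance.expression0.n_samples
    if stratified:
        half0 = rng.permutation(n0)
        half1 = rng.permutation(X1_.shape[1])
        a0, b0 = np.array_split(half0, 2)
        a1, b1 = np.array_split(half1, 2)
        X0 = np.hstack([X0_[:, a0], X1_[:, a1]])
        X1 = np.hstack([X0_[:, b0], X1_[:, b1]])
    else:
        pooled = np.hstack([X0_, X1_])
        order = rng.permutation(pooled.shape[1])
        X0 = pooled[:, order[:n0]]
        X1 = pooled[:, order[n0:]]
    proteins = list(instance.expression0.proteins)
    return (
        ExpressionCondition(proteins=proteins, X=X0, group=THETA0),
        ExpressionCondition(proteins=list(proteins), X=X1, group=THETA1),
    )


def write_instance(instance: SyntheticInstance, outdir: str | Path) -> None:
    """Write the instance in the pipeline's TSV formats plus a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "edges.tsv", "w") as fh:
        for u, v in sorted(instance.network.edges):
            fh.write(f"{u}\t{v}\n")
    with open(outdir / "annotations.tsv", "w") as fh:
        for protein in sorted(instance.annotations):
            for loc in sorted(instance.annotations[protein]):
                fh.write(f"{protein}\t{loc}\n")
    for cond, name in ((instance.expression0, "expression_theta0.tsv"),
                       (instance.expression1, "expression_theta1.tsv")):
        pd.DataFrame(
            cond.X,
            index=cond.proteins,
            columns=[f"{cond.group}_s{i}" for i in range(cond.n_samples)],
        ).to_csv(outdir / name, sep="\t")
    with open(outdir / "planted_truth.tsv", "w") as fh:
        fh.write("protein\tsource_locations\ttarget_location\n")
        for p in instance.planted:
            srcs = ";".join(sorted(p.source_locations))
            fh.write(f"{p.protein}\t{srcs}\t{p.target_location}\n")
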