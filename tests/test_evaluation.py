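import math

import numpy as np
import pytest

from dppn.evaluation import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_TAU_GRID,
    assign_folds,
    binary_metrics,
    confusion_from_sets,
    cross_validate,
    grid_search,
    multilabel_metrics,
    truth_sets,
)
from dppn.graph_kernel import diffusion_kernel, ecc_all, weighted_adjacency


def brute_force_multilabel(pred, truth):
    """Independent indicator-vector oracle for the set-overlap metrics."""
    labels = sorted(set().union(*pred, *truth))
    idx = {l: i for i, l in enumerate(labels)}

    def vec(s):
        v = np.zeros(len(labels))
        for l in s:
            v[idx[l]] = 1
        return v

    P = np.array([vec(s) for s in pred])
    T = np.array([vec(s) for s in truth])
    inter = (P * T).sum(axis=1)
    union = np.clip(P + T, 0, 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        aim = np.where(P.sum(axis=1) > 0, inter / P.sum(axis=1), 0.0)
    cvr = inter / T.sum(axis=1)
    jac = np.where(union > 0, inter / union, 0.0)
    atr = (P == T).all(axis=1).astype(float)
    return aim.mean(), cvr.mean(), jac.mean(), atr.mean()


class TestMultilabelMetrics:
    def test_perfect_prediction(self):
        sets = [{"Nucleus"}, {"Cytosol", "Nucleus"}]
        m = multilabel_metrics(sets, sets)
        assert (m.AIM, m.CVR, m.mlACC, m.ATR) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_example(self):
        pred = [{"N"}, {"N", "C"}, {"M"}]
        truth = [{"N"}, {"C"}, {"N"}]
        m = multilabel_metrics(pred, truth)
        assert m.AIM == pytest.approx(0.5)
        assert m.CVR == pytest.approx(2 / 3)
        assert m.mlACC == pytest.approx(0.5)
        assert m.ATR == pytest.approx(1 / 3)

    def test_disjoint_everywhere_is_zero(self):
        m = multilabel_metrics([{"A"}, {"B"}], [{"B"}, {"A"}])
        assert (m.AIM, m.CVR, m.mlACC, m.ATR) == (0.0, 0.0, 0.0, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(18)
        labels = list("ABCDEF")
        for _ in range(100):
            n = int(rng.integers(1, 15))
            pred = [set(rng.choice(labels, size=rng.integers(0, 4), replace=False))
                    for _ in range(n)]
            truth = [set(rng.choice(labels, size=rng.integers(1, 4), replace=False))
                     for _ in range(n)]
            m = multilabel_metrics(pred, truth)
            aim, cvr, jac, atr = brute_force_multilabel(pred, truth)
            assert m.AIM == pytest.approx(aim)
            assert m.CVR == pytest.approx(cvr)
            assert m.mlACC == pytest.approx(jac)
            assert m.ATR == pytest.approx(atr)
            assert m.ATR <= m.mlACC + 1e-12  # exact match implies Jaccard 1

    def test_truth_must_be_non_empty(self):
        with pytest.raises(ValueError):
            multilabel_metrics([{"A"}], [set()])


class TestBinaryMetrics:
    def test_hand_example(self):
        m = binary_metrics(4, 3, 1, 2)
        assert m.Sen == pytest.approx(4 / 6)
        assert m.Spe == pytest.approx(0.75)
        assert m.PPV == pytest.approx(0.8)
        assert m.vlAcc == pytest.approx(0.7)
        assert m.MCC == pytest.approx(10 / math.sqrt(600))

    def test_perfect_classifier(self):
        m = binary_metrics(5, 5, 0, 0)
        assert (m.Sen, m.Spe, m.PPV, m.vlAcc, m.MCC) == (1, 1, 1, 1, 1)

    def test_zero_marginal_mcc_convention(self):
        assert binary_metrics(0, 5, 0, 5).MCC == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(0, 0, 0, 0)

    def test_random_predictions_mcc_near_zero(self):
        rng = np.random.default_rng(19)
        truth = rng.integers(0, 2, size=20_000)
        pred = rng.integers(0, 2, size=20_000)
        tp = int(np.sum((truth == 1) & (pred == 1)))
        tn = int(np.sum((truth == 0) & (pred == 0)))
        fp = int(np.sum((truth == 0) & (pred == 1)))
        fn = int(np.sum((truth == 1) & (pred == 0)))
        assert abs(binary_metrics(tp, tn, fp, fn).MCC) < 0.03

    def test_confusion_from_sets_conserves_cells(self):
        pred = [{"A"}, {"B", "C"}]
        truth = [{"A", "B"}, {"C"}]
        tp, tn, fp, fn = confusion_from_sets(pred, truth, ["A", "B", "C"])
        assert tp + tn + fp + fn == 6  # 2 proteins x 3 locations
        assert (tp, fp, fn) == (2, 1, 1)


class TestCrossValidation:
    def test_deterministic_for_seed(self, community_kernel, two_communities):
        _, labels = two_communities
        parent = {n: n for n in labels}
        r1 = cross_validate(community_kernel, labels, parent, folds=4, seed=5)
        r2 = cross_validate(community_kernel, labels, parent, folds=4, seed=5)
        assert r1 == r2

    def test_fold_sizes_differ_by_at_most_one(self):
        proteins = [f"P{i}" for i in range(23)]
        first = {p: "Nucleus" if i % 2 else "Cytosol" for i, p in enumerate(proteins)}
        fold_of = assign_folds(proteins, first, folds=5, seed=0)
        sizes = [list(fold_of.values()).count(f) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_siblings_share_folds(self, synthetic_instance):
        from dppn.virtual_expansion import expand

        vnet = expand(synthetic_instance.network, synthetic_instance.annotations)
        truth = truth_sets(vnet.label, vnet.parent)
        first = {p: sorted(locs)[0] for p, locs in truth.items()}
        fold_of = assign_folds(list(truth), first, folds=10, seed=1)
        # fold assignment is at the real-protein level by construction;
        # check every labeled virtual node resolves through its parent
        for node in vnet.label:
            assert vnet.parent[node] in fold_of

    def test_separable_fixture_high_sensitivity(self, community_kernel, two_communities):
        _, labels = two_communities
        parent = {n: n for n in labels}
        cv = cross_validate(community_kernel, labels, parent, folds=4, alpha=0.0, seed=0)
        assert cv.binary.Sen > 0.9
        assert cv.multilabel.ATR > 0.9


class TestGridSearch:
    def test_default_grid_dimensions(self):
        assert len(DEFAULT_TAU_GRID) * len(DEFAULT_ALPHA_GRID) == 60

    def _builder(self, two_communities):
        network, _ = two_communities
        W = weighted_adjacency(network, pcc=None, ecc=ecc_all(network))
        return lambda tau: diffusion_kernel(W, tau)

    def test_single_cell_grid(self, two_communities):
        _, labels = two_communities
        parent = {n: n for n in labels}
        result = grid_search(self._builder(two_communities), labels, parent,
                             tau_grid=[1.1], alpha_grid=[0.3], folds=4, seed=0)
        assert result.best == (1.1, 0.3)
        assert list(result.grid) == [(1.1, 0.3)]

    def test_best_attains_grid_maximum(self, two_communities):
        _, labels = two_communities
        parent = {n: n for n in labels}
        result = grid_search(self._builder(two_communities), labels, parent,
                             tau_grid=[0.5, 1.1], alpha_grid=[0.1, 0.3],
                             folds=4, seed=0)
        assert result.best_mcc == pytest.approx(max(result.grid.values()))
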