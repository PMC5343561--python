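import itertools

import numpy as np
import pytest

from egonet import module_search
from egonet.data_io import InteractionNetwork
from egonet.errors import ValidationError
from egonet.module_search import (
    CandidateModule,
    _loocv_decision_values,
    _rank_auc,
    expand_ego,
    filter_modules,
    module_auc,
)
from egonet.network_construction import DifferentialNetwork
from tests.conftest import make_expression


def brute_force_auc(scores, y):
    """Pair-counting oracle: fraction of (case, control) pairs ranked correctly."""
    wins = 0.0
    pairs = 0
    for i, j in itertools.product(np.where(y)[0], np.where(~y)[0]):
        pairs += 1
        if scores[i] > scores[j]:
            wins += 1.0
        elif scores[i] == scores[j]:
            wins += 0.5
    return wins / pairs


def den_from_edges(edges):
    return DifferentialNetwork(
        network=InteractionNetwork.from_edges(edges), pcc_threshold=0.8, p_threshold=0.05
    )


class TestRankAuc:
    def test_toy_decision_values_by_pair_counting(self):
        scores = np.array([0.9, 0.8, 0.4, 0.6, 0.3, 0.1])
        y = np.array([True, True, True, False, False, False])
        assert _rank_auc(scores, y) == pytest.approx(8 / 9)
        assert brute_force_auc(scores, y) == pytest.approx(8 / 9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_values(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = rng.permutation(np.arange(n) < 5)
        assert _rank_auc(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)


class TestModuleAuc:
    def test_perfectly_separating_gene_scores_one(self):
        values = np.r_[np.full(6, 5.0), np.full(6, -5.0)][None, :]
        values = values + np.linspace(0, 0.1, 12)  # break exact ties within groups
        expr = make_expression(values, n_cases=6)
        assert module_auc(["g0"], expr) == 1.0

    def test_label_symmetry_of_rank_auc(self):
        # swapping class labels on fixed decision values maps auc -> 1 - auc
        rng = np.random.default_rng(4)
        scores = rng.normal(size=14)
        y = rng.permutation(np.arange(14) < 8)
        assert _rank_auc(scores, ~y) == pytest.approx(1.0 - _rank_auc(scores, y), abs=1e-12)

    def test_retrained_classifier_is_label_flip_invariant(self):
        # the linear SVM is symmetric in the two classes, so retraining on
        # flipped labels flips the decision values and leaves the AUC unchanged
        rng = np.random.default_rng(4)
        expr = make_expression(rng.normal(size=(3, 14)), n_cases=8)
        y = expr.case_mask
        auc = module_auc(["g0", "g1", "g2"], expr)
        flipped = module_auc(["g0", "g1", "g2"], expr, labels=~y)
        assert flipped == pytest.approx(auc, abs=1e-12)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(1, 8)), n_cases=4)
        with pytest.raises(ValidationError, match="one class"):
            module_auc(["g0"], expr, labels=np.ones(8, dtype=bool))

    def test_empty_module_rejected(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(1, 8)), n_cases=4)
        with pytest.raises(ValidationError, match="at least one gene"):
            module_auc([], expr)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        expr = make_expression(rng.normal(size=(4, 16)), n_cases=9)
        genes = ["g0", "g1", "g2", "g3"]
        assert module_auc(genes, expr) == module_auc(genes, expr)

    def test_held_out_decision_auc_equals_pair_count_oracle(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.normal(size=(3, 12)), n_cases=6)
        y = expr.case_mask
        scores = _loocv_decision_values(expr.submatrix(["g0", "g1", "g2"]), y.astype(int))
        assert _rank_auc(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)


class StubAuc:
    """Deterministic AUC lookup keyed by frozen gene sets, for search-logic tests."""

    def __init__(self, table, default=0.5):
        self.table = {frozenset(k): v for k, v in table.items()}
        self.default = default

    def __call__(self, genes, expr, labels=None):
        return self.table.get(frozenset(genes), self.default)


@pytest.fixture
def stub_expr():
    # 19/6 design so one ranking inversion is 1/114
    rng = np.random.default_rng(0)
    return make_expression(rng.normal(size=(6, 25)), n_cases=19)


class TestExpandEgo:
    def test_ego_not_in_den_rejected(self, stub_expr):
        with pytest.raises(ValidationError, match="not a DEN node"):
            expand_ego("gX", den_from_edges([("g0", "g1", 0.9)]), stub_expr)

    def test_stays_at_ego_when_all_additions_drop(self, stub_expr, monkeypatch):
        den = den_from_edges([("g0", "g1", 0.9), ("g0", "g2", 0.9)])
        stub = StubAuc({("g0",): 0.95, ("g0", "g1"): 0.90, ("g0", "g2"): 0.85})
        monkeypatch.setattr(module_search, "module_auc", stub)
        m = expand_ego("g0", den, stub_expr)
        assert m.genes == ["g0"]
        assert m.auc == 0.95
        assert m.trace == [("g0", 0.95)]

    def test_zero_gain_neighbour_is_absorbed(self, stub_expr, monkeypatch):
        den = den_from_edges([("g0", "g1", 0.9)])
        stub = StubAuc({("g0",): 0.9, ("g0", "g1"): 0.9})
        monkeypatch.setattr(module_search, "module_auc", stub)
        m = expand_ego("g0", den, stub_expr)
        assert m.genes == ["g0", "g1"]

    def test_drop_within_one_inversion_tolerated_but_larger_stops(self, stub_expr, monkeypatch):
        den = den_from_edges([("g0", "g1", 0.9), ("g1", "g2", 0.9)])
        one_inv = 1 / 114
        stub = StubAuc(
            {("g0",): 0.95, ("g0", "g1"): 0.95 - one_inv, ("g0", "g1", "g2"): 0.95 - 3 * one_inv}
        )
        monkeypatch.setattr(module_search, "module_auc", stub)
        m = expand_ego("g0", den, stub_expr)
        assert m.genes == ["g0", "g1"]  # one-inversion drop absorbed, two-inversion drop stops
        strict = expand_ego("g0", den, stub_expr, drop_tol_pairs=0)
        assert strict.genes == ["g0"]

    def test_tie_broken_by_higher_z(self, stub_expr, monkeypatch):
        den = den_from_edges([("g0", "g1", 0.9), ("g0", "g2", 0.9)])
        stub = StubAuc({("g0",): 0.7, ("g0", "g1"): 0.8, ("g0", "g2"): 0.8})
        monkeypatch.setattr(module_search, "module_auc", stub)
        m = expand_ego("g0", den, stub_expr, z_scores={"g1": 0.2, "g2": 1.5})
        assert m.genes[1] == "g2"

    def test_frontier_grows_with_module(self, stub_expr, monkeypatch):
        # g2 only reachable through g1
        den = den_from_edges([("g0", "g1", 0.9), ("g1", "g2", 0.9)])
        stub = StubAuc(
            {("g0",): 0.6, ("g0", "g1"): 0.7, ("g0", "g1", "g2"): 0.8}
        )
        monkeypatch.setattr(module_search, "module_auc", stub)
        m = expand_ego("g0", den, stub_expr)
        assert m.genes == ["g0", "g1", "g2"]
        assert [a for _, a in m.trace] == [0.6, 0.7, 0.8]

    def test_size_cap_respected(self, stub_expr, monkeypatch):
        den = den_from_edges([(f"g{i}", f"g{i+1}", 0.9) for i in range(5)])
        monkeypatch.setattr(module_search, "module_auc", StubAuc({}, default=0.9))
        m = expand_ego("g0", den, stub_expr, size_cap=3)
        assert m.size == 3

    def test_trace_never_drops_more_than_tolerance(self, default_synthetic):
        expr, net, _, truth = default_synthetic
        from egonet.network_construction import build_background_ppin, edge_statistics, extract_den

        den = extract_den(edge_statistics(expr, build_background_ppin(expr, net)))
        m = expand_ego(truth.planted_hub, den, expr)
        aucs = [a for _, a in m.trace]
        tol = 1 / (19 * 6) + 1e-9
        assert all(b >= a - tol for a, b in zip(aucs, aucs[1:]))
        assert m.auc == aucs[-1]


class TestFilterModules:
    @staticmethod
    def _cand(auc, size):
        return CandidateModule(
            module_id=f"m-{auc}-{size}",
            ego_gene="e",
            genes=["e"] + [f"g{i}" for i in range(size - 1)],
            auc=auc,
        )

    def test_reported_candidate_set_reduces_seven_to_five(self):
        candidates = [
            self._cand(0.75, 2),
            self._cand(1.00, 4),
            self._cand(1.00, 5),
            self._cand(1.00, 6),
            self._cand(1.00, 4),
            self._cand(1.00, 5),
            self._cand(0.94, 3),
        ]
        kept = filter_modules(candidates)
        assert len(kept) == 5
        assert all(c.auc >= 0.8 and c.size >= 4 for c in kept)

    def test_boundary_values_retained(self):
        kept = filter_modules([self._cand(0.8, 4)])
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_modules([]) == []

    def test_order_preserved(self):
        candidates = [self._cand(0.9, 5), self._cand(0.2, 5), self._cand(0.85, 6)]
        kept = filter_modules(candidates)
        assert [c.module_id for c in kept] == [candidates[0].module_id, candidates[2].module_id]
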