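import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollinet import metrics as M
from pollinet import synth
from pollinet.networks import BipartiteNetwork


def make_network(weights, floral=None):
    weights = np.asarray(weights, dtype=int)
    plants = [f"p{i}" for i in range(weights.shape[0])]
    polls = [f"a{j}" for j in range(weights.shape[1])]
    floral = floral or {p: 1.0 for p in plants}
    return BipartiteNetwork("s", "edge", weights, plants, polls, floral)


# ---------------------------------------------------------------------------
# relative connectance
# ---------------------------------------------------------------------------

class TestRelativeConnectance:
    def test_self_reference_is_one(self):
        net = make_network([[1, 0], [2, 3]])
        assert M.relative_connectance(net, net.links()) == 1.0

    def test_simple_ratio(self):
        # 10 local links out of 40 global links among the same species
        w = np.zeros((10, 4), dtype=int)
        w[np.arange(10), np.arange(10) % 4] = 1
        net = make_network(w)
        global_links = {(f"p{i}", f"a{j}") for i in range(10) for j in range(4)}
        assert M.relative_connectance(net, global_links) == pytest.approx(0.25)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            w = (rng.random((6, 7)) < 0.4).astype(int)
            if w.sum() == 0 or (w.sum(1) == 0).any() or (w.sum(0) == 0).any():
                continue
            net = make_network(w)
            extra = {(f"p{i}", f"a{j}") for i in range(6) for j in range(7)
                     if rng.random() < 0.5}
            global_links = net.links() | extra
            # brute force: count global links with both endpoints present
            s_obs = 0
            for (p, a) in global_links:
                if p in net.plant_names and a in net.pollinator_names:
                    s_obs += 1
            expected = len(net.links()) / s_obs
            assert M.relative_connectance(net, global_links) == pytest.approx(expected)

    def test_dict_index_agrees_with_set(self, rng):
        w = (rng.random((5, 6)) < 0.5).astype(int) + 1
        net = make_network(w)
        links = net.links() | {("p0", "a_extra"), ("p_extra", "a0")}
        index = {}
        for p, a in links:
            index.setdefault(p, set()).add(a)
        assert M.relative_connectance(net, links) == \
            M.relative_connectance(net, index)

    def test_no_links_errors(self):
        net = make_network(np.zeros((2, 2), dtype=int))
        with pytest.raises(M.UndefinedMetricError):
            M.relative_connectance(net, {("p0", "a0")})


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def nodf_oracle(mat):
    """Direct, loop-based paired-overlap NODF."""
    mat = (np.asarray(mat) > 0).astype(int)

    def pair_scores(m):
        scores = []
        for i, j in itertools.combinations(range(m.shape[0]), 2):
            fi, fj = m[i].sum(), m[j].sum()
            if fi == fj or min(fi, fj) == 0:
                scores.append(0.0)
            else:
                poor, rich = (m[i], m[j]) if fi < fj else (m[j], m[i])
                scores.append((poor & rich).sum() / poor.sum())
        return scores

    scores = pair_scores(mat) + pair_scores(mat.T)
    return 100 * np.mean(scores) if scores else 0.0


class TestNodf:
    def test_perfectly_nested_triangle(self):
        m = synth.generate_structured_matrix("nested", 5, 5, 1.0, 0)
        assert M.nodf(m) == pytest.approx(100.0)

    def test_identical_rows_score_zero(self):
        assert M.nodf(np.ones((4, 4))) == 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            m = (rng.random((6, 6)) < rng.uniform(0.2, 0.8)).astype(int)
            if m.sum() == 0:
                continue
            assert M.nodf(m) == pytest.approx(nodf_oracle(m), abs=1e-10)

    @given(st.integers(0, 2**30))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_permutation(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((5, 7)) < 0.5).astype(int)
        if m.sum() == 0:
            return
        perm = m[rng.permutation(5)][:, rng.permutation(7)]
        assert M.nodf(perm) == pytest.approx(M.nodf(m), abs=1e-10)

    def test_all_zero_errors(self):
        with pytest.raises(M.UndefinedMetricError):
            M.nodf(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def all_partitions(n):
    """Restricted-growth-string enumeration of set partitions of n items."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    yield from rec([], -1)


def exhaustive_best_q(weights):
    m, n = weights.shape
    best = 0.0
    for part in all_partitions(m + n):
        q = M.barber_modularity(weights, np.array(part[:m]), np.array(part[m:]))
        best = max(best, q)
    return best


class TestBarberModularity:
    def test_all_ones_single_module_is_zero(self):
        q = M.barber_modularity(np.ones((3, 3)), np.zeros(3, int), np.zeros(3, int))
        assert q == pytest.approx(0.0)

    def test_two_equal_blocks_give_half(self):
        w = synth.generate_structured_matrix("modular", 4, 4, 1.0, 0)
        q = M.barber_modularity(w, np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1]))
        assert q == pytest.approx(0.5)

    def test_matches_hand_expanded_double_sum(self, rng):
        w = rng.integers(0, 5, size=(5, 4)).astype(float)
        pl = rng.integers(0, 3, 5)
        al = rng.integers(0, 3, 4)
        f = w.sum()
        k, d = w.sum(1), w.sum(0)
        expected = sum((w[i, j] - k[i] * d[j] / f) / f
                       for i in range(5) for j in range(4) if pl[i] == al[j])
        assert M.barber_modularity(w, pl, al) == pytest.approx(expected)

    def test_module_relabelling_invariance(self, rng):
        w = rng.integers(0, 4, size=(4, 5)).astype(float) + 1
        pl = rng.integers(0, 3, 4)
        al = rng.integers(0, 3, 5)
        assert M.barber_modularity(w, pl, al) == \
            pytest.approx(M.barber_modularity(w, pl + 10, al + 10))


class TestOptimizeModules:
    def test_recovers_planted_blocks(self):
        w = synth.generate_structured_matrix("modular", 6, 6, 1.0, 0)
        part = M.optimize_modules(w, n_restarts=20, seed=0)
        assert part.q == pytest.approx(0.5)
        assert len(set(part.plant_labels)) == 2

    def test_structureless_matrix_stays_near_zero(self):
        part = M.optimize_modules(np.ones((3, 3)), n_restarts=20, seed=0)
        assert part.q <= 1e-9

    def test_never_below_single_module(self, rng):
        for _ in range(10):
            w = (rng.random((5, 5)) < 0.5).astype(int)
            if w.sum() == 0:
                continue
            assert M.optimize_modules(w, n_restarts=5, seed=1).q >= 0.0

    def test_partition_q_is_consistent(self):
        w = synth.generate_structured_matrix("modular", 4, 6, 1.0, 3)
        part = M.optimize_modules(w, n_restarts=10, seed=2)
        assert part.q == pytest.approx(
            M.barber_modularity(w, part.plant_labels, part.pollinator_labels))

    def test_matches_exhaustive_search_on_small_matrices(self, rng):
        checked = 0
        while checked < 20:
            m, n = rng.integers(2, 5, 2)
            w = (rng.random((m, n)) < 0.5).astype(int)
            if w.sum() == 0 or (w.sum(1) > 3).any():
                continue
            assert M.optimize_modules(w, n_restarts=20, seed=4).q == \
                pytest.approx(exhaustive_best_q(w), abs=1e-9)
            checked += 1

    def test_deterministic_given_seed(self):
        w = synth.generate_structured_matrix("random", 8, 8, 0.4, 9)
        a = M.optimize_modules(w, n_restarts=10, seed=5)
        b = M.optimize_modules(w, n_restarts=10, seed=5)
        assert a.q == b.q
        assert np.array_equal(a.plant_labels, b.plant_labels)


# ---------------------------------------------------------------------------
# extinction robustness
# ---------------------------------------------------------------------------

def robustness_oracle(weights, order, plants, polls):
    """Step-by-step removal simulation."""
    weights = np.asarray(weights) > 0
    alive_plants = set(plants)
    survivors = [1.0]
    for name in order:
        alive_plants.remove(name)
        rows = [plants.index(p) for p in alive_plants]
        alive = 0
        for j in range(len(polls)):
            if rows and weights[rows, j].any():
                alive += 1
        survivors.append(alive / len(polls))
    survivors[-1] = 0.0
    xs = np.linspace(0, 1, len(order) + 1)
    return np.trapezoid(survivors, xs)


class TestRobustness:
    def test_minimal_network(self):
        net = make_network([[1]])
        assert M.robustness(net, ["p0"]) == pytest.approx(0.5)

    def test_fully_connected_closed_form(self):
        net = make_network(np.ones((5, 9), dtype=int))
        assert M.robustness(net, [f"p{i}" for i in range(5)]) == pytest.approx(0.9)

    def test_matches_simulation_oracle(self, rng):
        for _ in range(10):
            w = (rng.random((8, 8)) < 0.35).astype(int)
            keep = (w.sum(1) > 0)
            w = w[keep][:, w[keep].sum(0) > 0]
            if w.size == 0:
                continue
            net = make_network(w)
            order = list(rng.permutation(net.plant_names))
            expected = robustness_oracle(w, order, net.plant_names,
                                         net.pollinator_names)
            assert M.robustness(net, order) == pytest.approx(expected)

    def test_adding_a_link_never_decreases_robustness(self, rng):
        for _ in range(15):
            w = (rng.random((6, 6)) < 0.4).astype(int)
            if w.sum() == 0 or (w.sum(1) == 0).any() or (w.sum(0) == 0).any():
                continue
            net = make_network(w)
            order = sorted(net.plant_names)
            zero = np.argwhere(w == 0)
            if not len(zero):
                continue
            i, j = zero[rng.integers(len(zero))]
            w2 = w.copy()
            w2[i, j] = 1
            assert M.robustness(make_network(w2), order) >= \
                M.robustness(net, order) - 1e-12

    def test_bad_order_rejected(self):
        net = make_network([[1, 1], [1, 0]])
        with pytest.raises(ValueError):
            M.robustness(net, ["p0"])


class TestExtinctionOrder:
    def test_rarest_first(self):
        net = make_network([[1], [1], [1]], floral={"p0": 5.0, "p1": 1.0, "p2": 3.0})
        assert M.extinction_order_by_rarity(net) == ["p1", "p2", "p0"]

    def test_ties_break_lexicographically(self):
        net = make_network([[1], [1], [1]], floral={"p0": 2.0, "p1": 2.0, "p2": 2.0})
        assert M.extinction_order_by_rarity(net) == ["p0", "p1", "p2"]

    def test_matches_independent_sort(self, rng):
        areas = {f"p{i}": float(rng.random()) for i in range(6)}
        net = make_network(np.ones((6, 2), dtype=int), floral=areas)
        assert M.extinction_order_by_rarity(net) == \
            sorted(areas, key=lambda p: (areas[p], p))


# ---------------------------------------------------------------------------
# sample coverage
# ---------------------------------------------------------------------------

class TestSampleCoverage:
    def test_no_singletons_is_complete(self):
        assert M.sample_coverage([5, 3, 2]) == 1.0

    def test_all_singletons_is_zero(self):
        assert M.sample_coverage([1] * 8) == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        # n=10, f1=2, f2=1 -> 1 - 0.2 * 18/20 = 0.82
        assert M.sample_coverage([1, 1, 2, 3, 3]) == pytest.approx(0.82)

    def test_empty_sample_errors(self):
        with pytest.raises(M.UndefinedMetricError):
            M.sample_coverage([0, 0])
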