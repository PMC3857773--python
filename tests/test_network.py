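import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmra.core import ValidationError
from netmra.network import (
    Edge,
    RegulatoryNetwork,
    apply_dpi,
    compute_mi,
    default_bins,
    extract_regulons,
    infer_network,
    permutation_threshold,
)
from netmra.simulate import SimulationConfig, simulate_chain_expression, simulate_network_expression


def brute_force_mi(x, y, bins):
    """Independent oracle: equal-frequency rank binning, then MI from an
    explicitly counted contingency table via H(X) + H(Y) - H(X,Y)."""
    def labels(v):
        order = np.argsort(v, kind="stable")
        rank = np.empty(len(v), dtype=int)
        rank[order] = np.arange(len(v))
        return [(r * bins) // len(v) for r in rank]

    lx, ly = labels(x), labels(y)
    n = len(x)

    def entropy(counts):
        return -sum((c / n) * math.log2(c / n) for c in counts.values())

    hx = entropy(Counter(lx))
    hy = entropy(Counter(ly))
    hxy = entropy(Counter(zip(lx, ly)))
    return hx + hy - hxy


class TestComputeMI:
    def test_constant_vector_gives_zero(self):
        assert compute_mi(np.ones(20), np.arange(20.0), 2) == 0.0

    def test_identical_distinct_vectors_four_bins_exactly_two_bits(self):
        x = np.random.default_rng(0).permutation(100).astype(float)
        assert compute_mi(x, x, 4) == pytest.approx(2.0, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_mi(np.arange(10.0), np.arange(12.0), 2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        assert compute_mi(x, y, 2) == pytest.approx(brute_force_mi(x, y, 2), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        mi = compute_mi(x, y, 4)
        assert mi == compute_mi(y, x, 4)
        assert 0.0 <= mi <= 2.0 + 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        assert compute_mi(x, y, 4) == compute_mi(np.exp(x), y, 4)
        assert compute_mi(x, y, 4) == compute_mi(x, np.arctan(y) * 7 + 2, 4)

    def test_independent_vectors_rarely_exceed_own_permutation_null(self):
        """MI of independent uniforms stays below the 95th percentile of its
        permutation null in >=93% of seeds."""
        below = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x, y = rng.random(200), rng.random(200)
            obs = compute_mi(x, y, 4)
            null = [compute_mi(x, rng.permutation(y), 4) for _ in range(100)]
            # conservative empirical quantile (ties count as extreme)
            if obs < np.quantile(null, 0.95, method="higher"):
                below += 1
        assert below >= 93

    def test_quadratic_dependence_detected(self):
        """MI finds non-monotone (quadratic) dependence that Spearman misses."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        x = rng.standard_normal(400)
        y = x**2 + rng.normal(0, 0.25, 400)
        assert abs(spearmanr(x, y).statistic) < 0.2
        assert compute_mi(x, y, 8) > 0.5


class TestPermutationThreshold:
    def test_empirical_p_floor(self):
        """An observed MI above every null value gets p = 1/(n_null+1)."""
        cfg = SimulationConfig(n_tfs=2, n_targets=10, n_background_genes=5,
                               regulon_size_range=(5, 5), n_samples=100,
                               noise_sd=0.05, seed=3)
        expr, truth = simulate_network_expression(cfg)
        pairs, mi, p, _ = permutation_threshold(expr, truth.tf_ids, n_perm=200, seed=1)
        assert p.min() == pytest.approx(1.0 / 201)

    def test_nperm_too_small_for_alpha(self):
        cfg = SimulationConfig(n_tfs=1, n_targets=5, n_background_genes=0,
                               regulon_size_range=(5, 5), n_samples=50, seed=1)
        expr, truth = simulate_network_expression(cfg)
        with pytest.raises(ValidationError, match="n_perm"):
            permutation_threshold(expr, truth.tf_ids, n_perm=100, alpha=0.001)

    def test_false_edge_rate_controlled_on_pure_noise(self):
        """On an all-noise matrix the number of BH-significant edges stays
        near the nominal level."""
        total_edges, total_pairs = 0, 0
        for seed in range(20):
            cfg = SimulationConfig(n_tfs=5, n_targets=50, n_background_genes=0,
                                   regulon_size_range=(10, 10), n_samples=100,
                                   nonlinearity="none", seed=seed)
            expr, truth = simulate_network_expression(cfg)
            _, _, _, p_adj = permutation_threshold(expr, truth.tf_ids, n_perm=400,
                                                   seed=seed + 500)
            total_edges += int((p_adj < 0.05).sum())
            total_pairs += p_adj.size
        assert total_edges <= 0.05 * total_pairs * 1.5


class TestDPI:
    def _net(self, edges):
        return RegulatoryNetwork(["A", "B"], [Edge(*e) for e in edges])

    def test_triangle_free_unchanged(self):
        net = self._net([("A", "x", 1.0, 0.01, 0.01, 1), ("B", "y", 0.8, 0.01, 0.01, 1)])
        assert apply_dpi(net, 0.0).edges == net.edges

    def test_epsilon_one_removes_nothing(self):
        net = self._net([
            ("A", "B", 1.0, 0.01, 0.01, 1),
            ("B", "c", 0.9, 0.01, 0.01, 1),
            ("A", "c", 0.1, 0.01, 0.01, 1),
        ])
        assert len(apply_dpi(net, 1.0).edges) == 3

    def test_weakest_triangle_edge_removed(self):
        net = self._net([
            ("A", "B", 1.0, 0.01, 0.01, 1),
            ("B", "c", 0.9, 0.01, 0.01, 1),
            ("A", "c", 0.1, 0.01, 0.01, 1),
        ])
        pruned = apply_dpi(net, 0.0)
        assert {(e.tf, e.target) for e in pruned.edges} == {("A", "B"), ("B", "c")}

    def test_tie_kept_on_strict_inequality_rule(self):
        net = self._net([
            ("A", "B", 0.5, 0.01, 0.01, 1),
            ("B", "c", 0.5, 0.01, 0.01, 1),
            ("A", "c", 0.5, 0.01, 0.01, 1),
        ])
        assert len(apply_dpi(net, 0.0).edges) == 3

    def test_pruning_never_increases_edges(self):
        cfg = SimulationConfig(n_tfs=5, n_targets=50, n_background_genes=10,
                               regulon_size_range=(10, 10), n_samples=100, seed=2)
        expr, truth = simulate_network_expression(cfg)
        pairs, mi, p, p_adj = permutation_threshold(expr, truth.tf_ids, n_perm=200, seed=3)
        edges = [Edge(tf, tgt, m, pv, pa, 1)
                 for (tf, tgt), m, pv, pa in zip(pairs, mi, p, p_adj) if pa < 0.05]
        net = RegulatoryNetwork(truth.tf_ids, edges)
        assert len(apply_dpi(net, 0.0).edges) <= len(net.edges)

    def test_chains_pruned_to_direct_edges(self):
        """Indirect A-C edges of planted A->B->C chains are removed while
        the direct edges survive."""
        ind_removed = dir_kept = n_ind = n_dir = 0
        for seed in range(20):
            expr, chains = simulate_chain_expression(8, 200, 0.25, 1.0, seed)
            tfs = [c[0] for c in chains] + [c[1] for c in chains]
            net = infer_network(expr, tfs, n_perm=300, seed=seed + 99)
            pairs = net.edge_pairs()
            undirected = {frozenset(p) for p in pairs}
            for a, b, c in chains:
                n_ind += 1
                n_dir += 2
                if frozenset((a, c)) not in undirected:
                    ind_removed += 1
                dir_kept += (frozenset((a, b)) in undirected) + (frozenset((b, c)) in undirected)
        assert ind_removed / n_ind >= 0.90
        assert dir_kept / n_dir >= 0.95


class TestInferNetwork:
    def test_empty_tf_list_gives_empty_network(self, small_expr):
        net = infer_network(small_expr, [])
        assert net.edges == []

    def test_recovery_on_small_benchmark(self):
        cfg = SimulationConfig(n_tfs=5, n_targets=100, n_background_genes=30,
                               regulon_size_range=(20, 20), n_samples=200, seed=11)
        expr, truth = simulate_network_expression(cfg)
        net = infer_network(expr, truth.tf_ids, seed=12)
        pred, true = net.edge_pairs(), truth.edge_set()
        tp = len(pred & true)
        assert tp / len(pred) >= 0.9 and tp / len(true) >= 0.8

    def test_negative_slope_edges_get_negative_sign(self):
        cfg = SimulationConfig(n_tfs=5, n_targets=100, n_background_genes=0,
                               regulon_size_range=(20, 20), n_samples=200, seed=21)
        expr, truth = simulate_network_expression(cfg)
        net = infer_network(expr, truth.tf_ids, seed=22)
        truth_sign = {(tf, tgt): s for tf, tgt, s, _ in truth.edges}
        checked = [e for e in net.edges if truth_sign.get((e.tf, e.target)) == -1]
        assert checked, "no negative-slope edges recovered"
        agree = sum(e.sign == -1 for e in checked)
        assert agree / len(checked) >= 0.95

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_tfs=3, n_targets=30, n_background_genes=10,
                               regulon_size_range=(10, 10), n_samples=80, seed=5)
        expr, truth = simulate_network_expression(cfg)
        n1 = infer_network(expr, truth.tf_ids, seed=42)
        n2 = infer_network(expr, truth.tf_ids, seed=42)
        assert n1.edges == n2.edges


class TestExtractRegulons:
    def test_tf_without_edges_emits_no_regulon(self):
        net = RegulatoryNetwork(["A", "B"], [Edge("A", "x", 1.0, 0.01, 0.01, 1)])
        regs = extract_regulons(net, min_size=1)
        assert [r.name for r in regs] == ["A"]

    def test_min_size_filter(self):
        net = RegulatoryNetwork(
            ["A", "B"],
            [Edge("A", "x", 1, 0.01, 0.01, 1), Edge("A", "y", 1, 0.01, 0.01, 1),
             Edge("B", "z", 1, 0.01, 0.01, 1)],
        )
        assert [r.name for r in extract_regulons(net, min_size=2)] == ["A"]

    def test_planted_regulons_recovered(self):
        cfg = SimulationConfig(n_tfs=5, n_targets=100, n_background_genes=20,
                               regulon_size_range=(20, 20), n_samples=200, seed=31)
        expr, truth = simulate_network_expression(cfg)
        net = infer_network(expr, truth.tf_ids, seed=32)
        from netmra.mra import jaccard

        regs = {r.name: r.as_set() for r in extract_regulons(net)}
        sims = [jaccard(regs.get(tf, set()), members)
                for tf, members in truth.regulons.items()]
        assert min(sims) >= 0.7
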