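"""MI estimation, CLR z-scoring, network selection, power-law fitting."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from metaphenet import (
    ClrConfig,
    CoexpressionScores,
    SyntheticConfig,
    clr_zscores,
    compute_scores,
    generate_expression,
    generate_master_network,
    largest_component,
    mutual_information_matrix,
    powerlaw_fit,
    threshold_network,
    top_k_network,
    zscore_to_pvalue,
)

HARD = ClrConfig(mi_estimator="equal_width_bins", rank_transform=False)


def expr_frame(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"1.1.1.{i+1}" for i in range(rows.shape[0])]
    cols = [f"c_A_r{i+1}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=cols)


class TestMutualInformation:
    def test_self_copy_equals_marginal_entropy(self, rng):
        x = rng.normal(size=200)
        expr = expr_frame([x, x])
        scores = mutual_information_matrix(expr, HARD)
        # I(X;X) = H(X) for the plug-in estimator with hard bins
        w = np.histogram(x, bins=10)[0] / x.size
        h = -(w[w > 0] * np.log2(w[w > 0])).sum()
        assert scores.mi[0, 1] == pytest.approx(h, abs=1e-12)

    def test_independent_profiles_near_zero(self):
        mis = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            expr = expr_frame([r.uniform(size=500), r.uniform(size=500)])
            mis.append(mutual_information_matrix(expr, HARD).mi[0, 1])
        # plug-in bias bound for B bins and N samples: (B-1)^2 / (2 N ln 2)
        bound = (10 - 1) ** 2 / (2 * 500 * math.log(2))
        assert np.mean(mis) < 1.5 * bound

    def test_discrete_joint_one_bit(self):
        x = np.tile([0.0, 1.0], 30)
        expr = expr_frame([x, x])
        config = ClrConfig(mi_estimator="equal_width_bins", n_bins=2,
                           spline_order=1, rank_transform=False)
        assert mutual_information_matrix(expr, config).mi[0, 1] == pytest.approx(1.0)

    def test_discrete_joint_hand_computed(self):
        # joint p(0,0)=0.4, p(0,1)=0.1, p(1,0)=0.2, p(1,1)=0.3 over 10 samples
        x = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 0, 0, 1, 1, 1], dtype=float)
        expr = expr_frame([x, y])
        config = ClrConfig(mi_estimator="equal_width_bins", n_bins=2,
                           spline_order=1, rank_transform=False)
        joint = {(0, 0): 0.4, (0, 1): 0.1, (1, 0): 0.2, (1, 1): 0.3}
        px = {0: 0.5, 1: 0.5}
        py = {0: 0.6, 1: 0.4}
        expected = sum(
            p * math.log2(p / (px[a] * py[b])) for (a, b), p in joint.items()
        )
        assert mutual_information_matrix(expr, config).mi[0, 1] == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_gene_excluded(self, rng):
        expr = expr_frame([np.full(50, 3.0), rng.normal(size=50)])
        scores = mutual_information_matrix(expr, HARD)
        assert scores.excluded == ["1.1.1.1"]
        assert scores.genes == ["1.1.1.2"]
        assert np.isfinite(scores.mi).all()

    def test_bspline_close_to_hard_on_two_level_data(self):
        x = np.tile([0.0, 1.0], 30)
        expr = expr_frame([x, x])
        config = ClrConfig(mi_estimator="bspline", rank_transform=False)
        assert mutual_information_matrix(expr, config).mi[0, 1] == pytest.approx(1.0)

    def test_symmetric_nonnegative(self, rng):
        expr = expr_frame(rng.normal(size=(6, 40)))
        mi = mutual_information_matrix(expr, ClrConfig()).mi
        assert (mi >= 0).all()
        np.testing.assert_allclose(mi, mi.T, atol=1e-12)


class TestClrZscores:
    def toy_scores(self):
        mi = np.array([[0.0, 0.5, 0.2], [0.5, 0.0, 0.1], [0.2, 0.1, 0.0]])
        return CoexpressionScores(genes=["a", "b", "c"], mi=mi)

    def test_per_gene_hand_computation(self):
        scores = self.toy_scores()
        z = clr_zscores(scores, ClrConfig(background_mode="per_gene"))
        # row backgrounds: a:(0.5,0.2) mean .35 sd .15; b:(0.5,0.1) mean .3
        # sd .2; c:(0.2,0.1) mean .15 sd .05 -> rectified z of 1 or 0 each
        assert z[0, 1] == pytest.approx(math.sqrt(2.0), abs=1e-12)
        assert z[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert z[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_global_hand_computation(self):
        scores = self.toy_scores()
        z = clr_zscores(scores, ClrConfig(background_mode="global"))
        off = np.array([0.5, 0.2, 0.5, 0.1, 0.2, 0.1])
        expected = (0.5 - off.mean()) / off.std()
        assert z[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_flat_background_all_zero(self):
        mi = np.full((4, 4), 0.3)
        np.fill_diagonal(mi, 0.0)
        scores = CoexpressionScores(genes=list("abcd"), mi=mi)
        for mode in ("per_gene", "global"):
            z = clr_zscores(scores, ClrConfig(background_mode=mode))
            off = z[~np.eye(4, dtype=bool)]
            assert np.allclose(off, 0.0) or (off <= 0).all()

    def test_global_monotonicity_single_pair(self):
        scores = self.toy_scores()
        base = clr_zscores(scores, ClrConfig(background_mode="global")).copy()
        bumped_mi = scores.mi.copy()
        bumped_mi[0, 1] = bumped_mi[1, 0] = 0.9
        bumped = clr_zscores(
            CoexpressionScores(genes=list("abc"), mi=bumped_mi),
            ClrConfig(background_mode="global"),
        )
        # raw score of the bumped pair increases relative to every other pair
        assert (bumped[0, 1] - base[0, 1]) > (bumped[0, 2] - base[0, 2])
        assert bumped_mi[0, 1] - scores.mi[0, 1] > 0

    def test_permutation_equivariance(self, rng):
        expr = expr_frame(rng.normal(size=(8, 30)))
        scores = compute_scores(expr, ClrConfig())
        perm = rng.permutation(8)
        scores_p = compute_scores(expr.iloc[perm], ClrConfig())
        np.testing.assert_allclose(scores_p.z, scores.z[np.ix_(perm, perm)], atol=1e-9)


class TestNetworkSelection:
    def scores_from(self, z, genes):
        n = len(genes)
        return CoexpressionScores(genes=genes, mi=np.zeros((n, n)), z=np.asarray(z, float))

    def test_threshold_empty_below(self):
        z = np.array([[0, 1.0], [1.0, 0]])
        net = threshold_network(self.scores_from(z, ["a", "b"]), 4.2)
        assert net.number_of_edges() == 0

    def test_threshold_inclusive_at_cutoff(self):
        z = np.array([[0, 4.20], [4.20, 0]])
        net = threshold_network(self.scores_from(z, ["a", "b"]), 4.20)
        assert net.has_edge("a", "b")

    def test_threshold_matches_brute_force_count(self, rng):
        n = 20
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        genes = [f"g{i:02d}" for i in range(n)]
        net = threshold_network(self.scores_from(z, genes), 0.8)
        brute = sum(
            1 for i in range(n) for j in range(i + 1, n) if z[i, j] >= 0.8
        )
        assert net.number_of_edges() == brute

    def test_top_k_one_and_all(self, rng):
        n = 6
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        genes = [f"g{i}" for i in range(n)]
        scores = self.scores_from(z, genes)
        top1 = top_k_network(scores, 1)
        ii, jj = np.triu_indices(n, k=1)
        best = np.argmax(z[ii, jj])
        assert set(top1.edges) == {(genes[ii[best]], genes[jj[best]])} or set(
            (tuple(sorted(e)) for e in top1.edges)
        ) == {tuple(sorted((genes[ii[best]], genes[jj[best]])))}
        full = top_k_network(scores, n * (n - 1) // 2)
        assert full.number_of_edges() == n * (n - 1) // 2

    def test_top_k_matches_independent_sort(self, rng):
        n = 15
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        genes = [f"g{i:02d}" for i in range(n)]
        k = 30
        net = top_k_network(self.scores_from(z, genes), k)
        pairs = sorted(
            ((z[i, j], genes[i], genes[j]) for i in range(n) for j in range(i + 1, n)),
            key=lambda t: (-t[0], t[1], t[2]),
        )[:k]
        expected = {(a, b) for _, a, b in pairs}
        assert {tuple(sorted(e)) for e in net.edges} == expected

    def test_top_k_input_errors(self, rng):
        z = np.zeros((3, 3))
        scores = self.scores_from(z, ["a", "b", "c"])
        with pytest.raises(ValueError):
            top_k_network(scores, 0)
        with pytest.raises(ValueError):
            top_k_network(scores, 4)

    def test_threshold_subset_of_top_k(self, rng):
        n = 12
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        genes = [f"g{i:02d}" for i in range(n)]
        scores = self.scores_from(z, genes)
        t = 0.5
        thresh = threshold_network(scores, t)
        k = thresh.number_of_edges()
        if k:
            topk = top_k_network(scores, k)
            assert {tuple(sorted(e)) for e in thresh.edges} == {
                tuple(sorted(e)) for e in topk.edges
            }


class TestLargestComponent:
    def test_connected_identity(self):
        g = nx.path_graph(["a", "b", "c"])
        assert set(largest_component(g).nodes) == {"a", "b", "c"}

    def test_picks_bigger_component(self):
        g = nx.Graph()
        nx.add_path(g, ["a", "b", "c", "d", "e"])
        nx.add_path(g, ["x", "y", "z"])
        assert set(largest_component(g).nodes) == {"a", "b", "c", "d", "e"}

    def test_matches_bfs_labeling(self, rng):
        def bfs_components(g):
            remaining = set(g.nodes)
            comps = []
            while remaining:
                start = min(remaining)
                seen = {start}
                frontier = [start]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in g.neighbors(u):
                            if v not in seen:
                                seen.add(v)
                                nxt.append(v)
                    frontier = nxt
                comps.append(seen)
                remaining -= seen
            return comps

        for _ in range(100):
            g = nx.gnp_random_graph(12, 0.15, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            comps = bfs_components(g)
            expected = min(comps, key=lambda c: (-len(c), min(c)))
            assert set(largest_component(g).nodes) == expected


class TestZscoreToPvalue:
    def test_half_at_zero(self):
        assert zscore_to_pvalue(0.0) == pytest.approx(0.5)

    def test_cutoff_tail_below_bound_and_matches_quadrature(self):
        p = zscore_to_pvalue(4.20)
        assert p < 5e-5
        quad, _ = integrate.quad(
            lambda t: math.exp(-t * t / 2) / math.sqrt(2 * math.pi), 4.20, np.inf
        )
        assert p == pytest.approx(quad, rel=1e-9)
        assert p == pytest.approx(1.33e-5, rel=0.01)

    def test_limits(self):
        assert zscore_to_pvalue(float("-inf")) == 1.0
        assert zscore_to_pvalue(float("inf")) == 0.0


class _DegreeStub:
    def __init__(self, pairs):
        self._pairs = pairs

    def degree(self):
        return self._pairs


class TestPowerlawFit:
    def test_exact_inverse_square_line(self):
        pairs = []
        node = 0
        for d, count in [(1, 64), (2, 16), (4, 4), (8, 1)]:
            for _ in range(count):
                pairs.append((f"n{node}", d))
                node += 1
        exponent, r2 = powerlaw_fit(_DegreeStub(pairs))
        assert exponent == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_regular_graph_undefined(self):
        g = nx.cycle_graph(6)
        with pytest.raises(ValueError):
            powerlaw_fit(g)

    def test_preferential_attachment_fits_well(self):
        r2s = [
            powerlaw_fit(nx.barabasi_albert_graph(1000, 1, seed=s))[1]
            for s in range(20)
        ]
        assert np.mean(r2s) > 0.8


def module_enrichment(seed):
    config = SyntheticConfig(seed=seed)
    network = generate_master_network(config)
    expr, truth = generate_expression(config, network)
    scores = compute_scores(expr, ClrConfig())
    k = 200
    net = top_k_network(scores, k)
    membership = truth.module_membership
    within = sum(
        1
        for u, v in net.edges
        if membership.get(u) is not None and membership.get(u) == membership.get(v)
    )
    n = len(scores.genes)
    total_pairs = n * (n - 1) // 2
    module_pairs = config.n_modules * (
        config.module_size * (config.module_size - 1) // 2
    )
    expected_fraction = module_pairs / total_pairs
    return (within / k) / expected_fraction


def test_planted_modules_enriched_in_top_edges():
    """Top-k edges concentrate inside planted modules far beyond chance."""
    enrichments = [module_enrichment(seed) for seed in range(5)]
    assert min(enrichments) >= 5.0
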