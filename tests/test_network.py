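"""Ensemble network: scoring, permutation null, bootstrap, Brown merge, BH,
and topology metrics."""

import networkx as nx
import numpy as np
import pytest
from scipy.stats import kstest

from halocline.network import (
    NetworkConfig,
    bh_fdr,
    bootstrap_restore,
    brown_merge,
    build_network,
    edge_scores,
    permutation_null,
    topology,
)
from halocline.synthetic import SyntheticSpec, simulate_correlated
from halocline.tables import RelativeAbundanceTable, to_relative
from .conftest import make_table, random_table


def ra_from_rows(rows):
    x = np.asarray(rows, dtype=float)
    x = x / x.sum(axis=0, keepdims=True)
    return RelativeAbundanceTable(
        [f"T{i}" for i in range(x.shape[0])],
        [f"S{j}" for j in range(x.shape[1])],
        x,
    )


class TestEdgeScores:
    def test_identical_rows_self_similarity(self):
        ra = ra_from_rows([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        df = edge_scores(ra).set_index(["taxon_a", "taxon_b"])
        row = df.loc[("T0", "T1")]
        assert row["pearson"] == pytest.approx(1.0)
        assert row["spearman"] == pytest.approx(1.0)
        assert row["kl"] == pytest.approx(0.0, abs=1e-12)
        assert row["bray_curtis"] == pytest.approx(1.0)

    def test_affine_transform_perfect_pearson(self):
        # rows affinely related, columns already closed to 1
        x = np.array([0.10, 0.20, 0.30, 0.25])
        y = 2 * x + 0.05
        z = 1 - x - y
        ra = RelativeAbundanceTable(
            ["T0", "T1", "T2"], ["s1", "s2", "s3", "s4"], np.vstack([x, y, z])
        )
        df = edge_scores(ra).set_index(["taxon_a", "taxon_b"])
        assert df.loc[("T0", "T1"), "pearson"] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        # raw profiles [1,2] vs [2,1] -> dissimilarity 1/3, similarity 2/3
        ra = RelativeAbundanceTable(
            ["a", "b"], ["s1", "s2", "s3", "s4"],
            np.array([[1 / 3, 2 / 3, 0.5, 0.5], [2 / 3, 1 / 3, 0.5, 0.5]]),
        )
        df = edge_scores(ra, methods=("bray_curtis",))
        x = np.array([1 / 3, 2 / 3, 0.5, 0.5])
        y = np.array([2 / 3, 1 / 3, 0.5, 0.5])
        expect = 1 - np.abs(x - y).sum() / (x + y).sum()
        assert df["bray_curtis"].iloc[0] == pytest.approx(expect)

    def test_constant_taxon_flagged_invalid(self):
        ra = ra_from_rows([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]])
        df = edge_scores(ra)
        flagged = df[~df["valid"]]
        assert set(flagged["taxon_a"]) | set(flagged["taxon_b"]) >= {"T0"}

    def test_too_few_samples_rejected(self):
        ra = ra_from_rows([[1, 2], [2, 1]])
        with pytest.raises(ValueError):
            edge_scores(ra)


class TestPermutationNull:
    def test_p_lower_bound(self, rng):
        t = random_table(rng, n_taxa=10, n_samples=12, lam=20)
        ra = to_relative(t)
        _, p = permutation_null(ra, ("OTU1", "OTU2"), "pearson", n_perm=99, seed=0)
        assert p >= 1 / 100

    def test_planted_correlation_detected(self):
        # median over a few datasets: robust to the occasional draw where the
        # planted pair lands at very low abundance and counting noise wins
        ps = []
        for seed in range(5):
            spec = SyntheticSpec(S=100, depth=10_000,
                                 planted_edges=((0, 1, 0.9),), seed=200 + seed)
            ra = to_relative(simulate_correlated(spec, n_samples=30))
            _, p = permutation_null(ra, ("OTU001", "OTU002"), "spearman",
                                    n_perm=999, seed=1)
            ps.append(p)
        assert np.median(ps) <= 0.01

    def test_null_p_approximately_uniform(self, rng):
        # independent taxa: permutation p over many pairs close to U(0,1)
        from halocline.network import _null_scores, _two_sided_p

        x = rng.lognormal(0, 1, size=(40, 25))
        x = x / x.sum(axis=0, keepdims=True)
        obs = np.corrcoef(x)[np.triu_indices(40, 1)]
        null = _null_scores(x, ("pearson",), 199, rng, True)["pearson"]
        p = _two_sided_p(obs, null)
        # pairs share taxa so not i.i.d.; a loose KS check still flags breakage
        assert kstest(p, "uniform").pvalue > 1e-4

    def test_tiny_n_perm_rejected(self, rng):
        ra = to_relative(random_table(rng, n_samples=6))
        with pytest.raises(ValueError):
            permutation_null(ra, ("OTU1", "OTU2"), "pearson", n_perm=5, seed=0)


class TestBootstrapRestore:
    def test_perfect_pair_kept(self):
        spec = SyntheticSpec(S=20, depth=10_000, planted_edges=((0, 1, 0.95),), seed=5)
        ra = to_relative(simulate_correlated(spec, n_samples=30))
        res = bootstrap_restore(ra, ("OTU01", "OTU02"), "pearson",
                                n_boot=100, seed=0, null_mean=0.0)
        assert res["keep"]
        assert res["interval"][0] > 0.0

    def test_independent_pairs_mostly_dropped(self, rng):
        drops = 0
        for k in range(100):
            x = rng.lognormal(0, 1, size=(10, 30))
            ra = RelativeAbundanceTable(
                [f"t{i}" for i in range(10)], [f"s{j}" for j in range(30)],
                x / x.sum(axis=0, keepdims=True),
            )
            # null mean estimated by the renormalized permutation null, which
            # absorbs the compositional negative bias of closed data
            res = bootstrap_restore(ra, ("t0", "t1"), "pearson",
                                    n_boot=100, seed=k, n_perm=300)
            drops += not res["keep"]
        assert drops >= 90

    def test_fixed_seed_repeatable(self, rng):
        ra = to_relative(random_table(rng, n_taxa=6, n_samples=10, lam=20))
        a = bootstrap_restore(ra, ("OTU1", "OTU2"), "spearman", n_boot=50, seed=4,
                              null_mean=0.0)
        b = bootstrap_restore(ra, ("OTU1", "OTU2"), "spearman", n_boot=50, seed=4,
                              null_mean=0.0)
        assert a["interval"] == b["interval"]


class TestBrownMerge:
    def test_perfectly_correlated_methods_recover_common_p(self, rng):
        null = rng.standard_normal(500)
        p = 0.04
        merged = brown_merge({"m1": p, "m2": p}, {"m1": null, "m2": null})
        assert merged == pytest.approx(p, rel=0.2)

    def test_independent_methods_match_fisher(self, rng):
        from scipy.stats import combine_pvalues

        pvals = {"m1": 0.03, "m2": 0.2, "m3": 0.5}
        nulls = {m: rng.standard_normal(1000) for m in pvals}
        merged = brown_merge(pvals, nulls)
        fisher = combine_pvalues(list(pvals.values()), method="fisher").pvalue
        assert merged == pytest.approx(fisher, rel=0.25)

    def test_no_signal_merges_to_one(self, rng):
        nulls = {m: rng.standard_normal(200) for m in ("a", "b")}
        merged = brown_merge({"a": 1.0, "b": 1.0}, nulls)
        assert merged > 0.9

    def test_too_few_replicates_rejected(self, rng):
        nulls = {m: rng.standard_normal(10) for m in ("a", "b")}
        with pytest.raises(ValueError):
            brown_merge({"a": 0.5, "b": 0.5}, nulls)


class TestBhFdr:
    def test_all_tiny_p_accepted(self):
        rej, _ = bh_fdr([0.001] * 5, q=0.05)
        assert rej.all()

    def test_step_up_by_hand(self):
        # thresholds k*q/m = 0.0125, 0.025, 0.0375, 0.05: the largest k with
        # p_(k) <= k q/m is 2, so exactly the two smallest are rejected
        rej, adj = bh_fdr([0.01, 0.02, 0.04, 0.8], q=0.05)
        assert rej.tolist() == [True, True, False, False]

    def test_adjusted_monotone_after_sorting(self, rng):
        p = rng.uniform(0.001, 1, size=50)
        _, adj = bh_fdr(p, q=0.1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5], q=0.05)


class TestBuildNetwork:
    def test_empty_edge_set_still_valid_topology(self, rng):
        # heavily shuffled independent data: expect an (almost) empty graph
        x = rng.poisson(20, size=(12, 10)) + 1
        t = make_table(x)
        net = build_network(t, NetworkConfig(n_perm=100, n_boot=30, seed=0))
        topo = topology(net)
        assert topo["nodes"] == 12
        if topo["edges"] == 0:
            assert topo["network_density"] == 0.0
            assert topo["network_diameter"] == 0

    def test_edge_count_monotone_in_q(self):
        spec = SyntheticSpec(
            S=30, depth=10_000,
            planted_edges=tuple((2 * k, 2 * k + 1, 0.9) for k in range(5)),
            seed=21,
        )
        t = simulate_correlated(spec, n_samples=25)
        lo = build_network(t, NetworkConfig(n_perm=200, n_boot=50, q=0.01, seed=2))
        hi = build_network(t, NetworkConfig(n_perm=200, n_boot=50, q=0.10, seed=2))
        assert lo.n_edges <= hi.n_edges

    def test_negative_planted_edge_sign_recovered(self):
        spec = SyntheticSpec(S=40, depth=10_000,
                             planted_edges=((0, 1, -0.9),), seed=31)
        t = simulate_correlated(spec, n_samples=30)
        net = build_network(t, NetworkConfig(n_perm=300, n_boot=60, seed=3))
        hit = net.edges[
            (net.edges.taxon_a == "OTU01") & (net.edges.taxon_b == "OTU02")
        ]
        assert len(hit) == 1 and hit["sign"].iloc[0] == "negative"

    def test_too_few_samples_rejected(self, rng):
        t = random_table(rng, n_samples=4)
        with pytest.raises(ValueError):
            build_network(t, NetworkConfig(n_perm=100, seed=0))


class TestTopology:
    def test_triangle_closed_form(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], sign="positive")
        topo = topology(g)
        assert topo["cluster_coefficient"] == pytest.approx(1.0)
        assert topo["network_diameter"] == 1
        assert topo["average_number_of_neighbors"] == pytest.approx(2.0)
        assert topo["positive_pct"] + topo["negative_pct"] == pytest.approx(100.0)

    def test_mean_degree_identity_random_graphs(self, rng):
        for k in range(10):
            n = int(rng.integers(5, 40))
            e = int(rng.integers(0, n * (n - 1) // 2))
            g = nx.gnm_random_graph(n, e, seed=int(rng.integers(1 << 30)))
            topo = topology(g)
            assert topo["average_number_of_neighbors"] == pytest.approx(2 * e / n)
            assert topo["network_density"] == pytest.approx(e / (n * (n - 1)))
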