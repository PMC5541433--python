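import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micromat.conet import (
    build_network,
    largest_component,
    neighbors_of,
    network_centralization,
    network_density,
    spearman_matrix,
    temporal_networks,
)
from micromat.simgen import generate_correlated_block


def exhaustive_spearman(x, y):
    """Average-rank Spearman via explicit rank computation + Pearson."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        for i, val in enumerate(v):
            less = sum(1 for u in v if u < val)
            equal = sum(1 for u in v if u == val)
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def graph_with_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, rho=0.5, q=0.01, sign="+")
    return g


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [10, 8, 6, 4, 2]],
            index=["up1", "up2", "down"],
        )
        res = spearman_matrix(df, n_permutations=19, seed=0)
        assert res.rho.at["up1", "up2"] == pytest.approx(1.0)
        assert res.rho.at["up1", "down"] == pytest.approx(-1.0)

    def test_matches_exhaustive_with_ties(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 4, size=(6, 12)).astype(float)  # heavy ties
        df = pd.DataFrame(data, index=[f"t{i}" for i in range(6)])
        res = spearman_matrix(df, n_permutations=9, seed=0)
        for i, j in itertools.combinations(range(6), 2):
            expected = exhaustive_spearman(data[i], data[j])
            assert res.rho.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(5, 20))
        res = spearman_matrix(pd.DataFrame(data), n_permutations=9, seed=0)
        ref, _ = stats.spearmanr(data.T)
        assert np.allclose(res.rho.to_numpy(), ref, atol=1e-12)

    def test_constant_taxon_excluded(self):
        df = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "up"])
        res = spearman_matrix(df, n_permutations=9, seed=0)
        assert res.excluded_taxa == ["flat"]
        assert np.isnan(res.rho.at["flat", "up"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(4, 15))
        res1 = spearman_matrix(pd.DataFrame(data), n_permutations=9, seed=1)
        res2 = spearman_matrix(pd.DataFrame(np.exp(data)), n_permutations=9, seed=1)
        pd.testing.assert_frame_equal(res1.rho, res2.rho)
        pd.testing.assert_frame_equal(res1.p, res2.p)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame([[1, 2, 3]]), seed=0)


class TestBuildNetwork:
    def test_unreachable_threshold_gives_empty_graph(self):
        df = generate_correlated_block(30, [(4, "+", 1.0)], seed=0)
        res = spearman_matrix(df, n_permutations=99, seed=0)
        net = build_network(res, min_abs_rho=1.01, max_q=1.0)
        assert net.number_of_edges() == 0
        assert network_density(net) == 0.0

    def test_planted_block_complete(self):
        df = generate_correlated_block(30, [(5, "+", 1.0)], seed=1)
        res = spearman_matrix(df, n_permutations=199, seed=1)
        net = build_network(res, min_abs_rho=0.3, max_q=0.05)
        assert network_density(net) == pytest.approx(1.0)

    def test_canonical_edges_no_duplicates(self):
        df = generate_correlated_block(40, [(6, "+", 0.9)], seed=2)
        res = spearman_matrix(df, n_permutations=199, seed=2)
        net = build_network(res)
        seen = set()
        for a, b in net.edges:
            key = tuple(sorted((a, b)))
            assert key not in seen
            seen.add(key)
            assert a != b

    def test_sign_attribute(self):
        df = generate_correlated_block(40, [(2, "-", 1.0)], seed=3)
        res = spearman_matrix(df, n_permutations=199, seed=3)
        net = build_network(res)
        assert net.edges["b0t0", "b0t1"]["sign"] == "-"


class TestClosedForms:
    def test_complete_graph_density(self):
        net = graph_with_edges(itertools.combinations(range(5), 2))
        assert network_density(net) == 1.0

    def test_edgeless_density(self):
        net = graph_with_edges([], nodes=range(5))
        assert network_density(net) == 0.0

    def test_star_centralization(self):
        net = graph_with_edges([(0, i) for i in range(1, 5)])
        assert network_centralization(net) == 1.0

    def test_complete_centralization_zero(self):
        net = graph_with_edges(itertools.combinations(range(5), 2))
        assert network_centralization(net) == 0.0

    def test_path4_centralization(self):
        net = graph_with_edges([(0, 1), (1, 2), (2, 3)])
        assert network_centralization(net) == pytest.approx(1 / 3)

    def test_random_graphs_vs_direct_formulas(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9), seed=int(rng.integers(1e6)))
            e = g.number_of_edges()
            assert network_density(g) == 2 * e / (n * (n - 1))
            degs = [d for _, d in g.degree()]
            expected = sum(max(degs) - d for d in degs) / ((n - 1) * (n - 2))
            assert network_centralization(g) == pytest.approx(expected)

    def test_errors_on_tiny_graphs(self):
        with pytest.raises(ValueError):
            network_density(graph_with_edges([], nodes=[0]))
        with pytest.raises(ValueError):
            network_centralization(graph_with_edges([(0, 1)]))


class TestComponentsAndNeighbors:
    def test_connected_graph_is_its_own_core(self):
        net = graph_with_edges([(0, 1), (1, 2)])
        core = largest_component(net)
        assert set(core.nodes) == {0, 1, 2}

    def test_largest_component_wins(self):
        net = graph_with_edges([(0, 1), (1, 2), (2, 3), (3, 4), (10, 11), (11, 12)])
        assert set(largest_component(net).nodes) == {0, 1, 2, 3, 4}

    def test_tie_break_lexicographic(self):
        net = graph_with_edges([("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")])
        assert set(largest_component(net).nodes) == {"A", "B", "C"}

    def test_empty_graph(self):
        assert largest_component(nx.Graph()).number_of_nodes() == 0

    def test_isolated_node_query(self):
        net = graph_with_edges([(0, 1)], nodes=[0, 1, 2])
        pos, neg = neighbors_of(net, [2])
        assert pos == [] and neg == []

    def test_negative_hub_neighbors(self):
        df = generate_correlated_block(60, [(15, "-", 1.0)], seed=4)
        res = spearman_matrix(df, n_permutations=199, seed=4)
        net = build_network(res, min_abs_rho=0.3, max_q=0.05)
        pos, neg = neighbors_of(net, ["b0t0"])
        assert len(neg) == 14 and pos == []

    def test_missing_node_warns_not_fatal(self):
        net = graph_with_edges([(0, 1)])
        pos, neg = neighbors_of(net, ["nope"])
        assert pos == [] and neg == []


class TestTemporalNetworks:
    def make_cohort(self, strengths, n=12, seed=0):
        """One correlated block per period plus dominant independent
        background taxa (the block signal must survive compositional
        closure, which cancels a factor shared by a large share of the
        total)."""
        from micromat.tablesio import AbundanceTable, SampleMetadata

        frames, meta_rows = [], []
        for day, strength in strengths.items():
            df = generate_correlated_block(
                n, [(6, "+", strength), (20, "+", 0.0)], seed=seed + day
            )
            df.iloc[6:] *= 50.0
            df.columns = [f"d{day}_{c}" for c in df.columns]
            frames.append(df)
            for c in df.columns:
                meta_rows.append(
                    {"sample_id": c, "subject_id": c, "group": "g", "age_days": day}
                )
        table = AbundanceTable(pd.concat(frames, axis=1), kind="counts")
        return table, SampleMetadata(pd.DataFrame(meta_rows))

    def test_single_period_equals_pooled(self):
        table, meta = self.make_cohort({7: 0.9})
        out = temporal_networks(
            table, meta, [7], n_permutations=99, seed=1, min_mean_abundance=0.0
        )
        pooled = out["pooled"]
        per = out["periods"][7]
        assert pooled["n_edges"] == per["n_edges"]
        assert pooled["density"] == per["density"]

    def test_decreasing_strength_decreases_mean_rho(self):
        hits = 0
        for seed in range(5):
            table, meta = self.make_cohort({7: 0.95, 28: 0.6}, n=30, seed=100 * seed)
            out = temporal_networks(
                table, meta, [7, 28], n_permutations=999, seed=seed,
                min_abs_rho=0.3, max_q=0.25, min_prevalence=0.0, min_mean_abundance=0.0,
            )
            m7 = out["periods"][7]["mean_abs_rho"]
            m28 = out["periods"][28]["mean_abs_rho"]
            hits += bool(np.isfinite(m28) and m7 > m28)
        assert hits >= 4

    def test_short_period_skipped(self):
        table, meta = self.make_cohort({7: 0.9}, n=12)
        meta.data.loc[3:, "age_days"] = 28  # leaves 3 samples on day 7
        out = temporal_networks(
            table, meta, [7, 28], n_permutations=99, seed=1, min_mean_abundance=0.0
        )
        assert 7 not in out["periods"]


class TestPermutationP:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(25):  # 25 matrices x 10 taxa -> 45 pairs each
            data = rng.normal(size=(10, 30))
            res = spearman_matrix(pd.DataFrame(data), n_permutations=199, seed=int(rng.integers(1e9)))
            iu = np.triu_indices(10, 1)
            pvals.extend(res.p.to_numpy()[iu])
        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01
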