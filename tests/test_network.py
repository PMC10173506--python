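import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichewebs import FeatureTable, bh_fdr, build_network, spearman_all_pairs
from nichewebs.network import network_input_filter, qvalues_matrix


def bh_oracle(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestInputFilter:
    def test_low_max_abundance_dropped(self):
        n = 30
        counts = np.vstack([np.full(n, 1), np.full(n, 10000)])
        t = FeatureTable(pd.DataFrame(counts, index=["x", "big"],
                                      columns=[f"s{i}" for i in range(n)]))
        mask = network_input_filter(t)  # x is ~0.01% everywhere
        assert not mask["x"] and mask["big"]

    def test_single_spike_keeps(self):
        n = 30
        counts = np.vstack([np.full(n, 1), np.full(n, 900)])
        counts[0, 0] = 30  # >0.05% in one sample (30/930 ~ 3%)
        t = FeatureTable(pd.DataFrame(counts, index=["x", "big"],
                                      columns=[f"s{i}" for i in range(n)]))
        assert network_input_filter(t, min_prevalence=25)["x"]

    def test_empty_table(self):
        t = FeatureTable(pd.DataFrame(index=pd.Index([]), columns=["s1"], dtype=int))
        assert network_input_filter(t).sum() == 0


class TestSpearman:
    def test_monotone_pairs(self):
        X = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 9], [9, 6, 4, 2]],
                         index=["x", "y", "z"], dtype=float)
        res = spearman_all_pairs(X)
        assert res.rho.loc["x", "y"] == pytest.approx(1.0)
        assert res.rho.loc["x", "z"] == pytest.approx(-1.0)
        assert res.p.loc["x", "y"] == 0.0

    def test_p_value_t_approximation(self):
        # rho = 0.5 at n = 30: t = 0.5*sqrt(28/0.75), two-sided p from t(28)
        t = 0.5 * np.sqrt(28 / 0.75)
        expected = 2 * stats.t.sf(t, 28)
        assert expected == pytest.approx(0.0049, abs=5e-4)
        from nichewebs.network import _p_from_rho

        assert float(_p_from_rho(np.array(0.5), 30)) == pytest.approx(expected, rel=1e-12)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(50, 25)))
        res = spearman_all_pairs(X)
        for i in range(0, 50, 7):
            for j in range(i + 1, 50, 11):
                ri = stats.rankdata(X.iloc[i])
                rj = stats.rankdata(X.iloc[j])
                oracle = np.corrcoef(ri, rj)[0, 1]
                assert res.rho.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        X = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "x"], dtype=float)
        res = spearman_all_pairs(X)
        assert np.isnan(res.rho.loc["flat", "x"])

    def test_pairwise_complete_with_missing(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(3, 20)))
        X.iloc[0, :15] = np.nan  # only 5 complete obs with others
        res = spearman_all_pairs(X, min_n=10)
        assert np.isnan(res.rho.iloc[0, 1])  # too few complete pairs
        assert res.n.iloc[0, 1] == 5
        assert res.n.iloc[1, 2] == 20
        assert np.isfinite(res.rho.iloc[1, 2])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            spearman_all_pairs(pd.DataFrame([[1, 2, 3]]))


class TestBH:
    def test_hand_oracle_examples(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_fdr([0.001, 1.0]), [0.002, 1.0])
        assert np.allclose(bh_fdr([0.2]), [0.2])

    def test_matches_independent_stepup(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200) ** 2
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_q_dominates_p_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(size=60))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()


def _mats(entries, ids=("a", "b", "c")):
    rho = pd.DataFrame(np.eye(len(ids)), index=list(ids), columns=list(ids))
    p = pd.DataFrame(np.zeros((len(ids),) * 2), index=list(ids), columns=list(ids))
    for (u, v), (r, pv) in entries.items():
        rho.loc[u, v] = rho.loc[v, u] = r
        p.loc[u, v] = p.loc[v, u] = pv
    return rho, p


class TestBuildNetwork:
    def test_threshold_rules(self):
        rho, p = _mats({
            ("a", "b"): (0.6, 1e-5),
            ("a", "c"): (-0.9, 1e-9),
            ("b", "c"): (0.5, 1e-9),  # boundary rho: strict > rejects
        })
        net = build_network(rho, p, p)
        assert net.graph.has_edge("a", "b")
        assert not net.graph.has_edge("a", "c")  # positive_only
        assert not net.graph.has_edge("b", "c")  # rho == 0.5 rejected
        assert net.n_nodes == 2  # isolated c dropped

    def test_signed_mode_keeps_negative(self):
        rho, p = _mats({("a", "c"): (-0.9, 1e-9)})
        net = build_network(rho, p, p, positive_only=False)
        assert net.graph.has_edge("a", "c")

    def test_nonsymmetric_rejected(self):
        rho, p = _mats({("a", "b"): (0.7, 1e-5)})
        rho.loc["a", "b"] = 0.9  # break symmetry
        with pytest.raises(ValueError, match="symmetric"):
            build_network(rho, p, p)

    def test_no_self_edges_simple_graph(self):
        rho, p = _mats({("a", "b"): (0.9, 1e-9), ("b", "c"): (0.8, 1e-9)})
        net = build_network(rho, p, p)
        assert all(u != v for u, v in net.graph.edges)

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(2)
        n = 12
        r = np.clip((lambda A: (A + A.T) / 2)(rng.uniform(-1, 1, (n, n))), -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        ids = [f"v{i}" for i in range(n)]
        rho = pd.DataFrame(r, index=ids, columns=ids)
        pv = pd.DataFrame((lambda A: (A + A.T) / 2)(rng.uniform(0, 0.01, (n, n))),
                          index=ids, columns=ids)
        strict = build_network(rho, pv, pv, rho_min=0.6, alpha=0.003)
        loose = build_network(rho, pv, pv, rho_min=0.4, alpha=0.008)
        assert set(map(frozenset, strict.graph.edges)) <= set(
            map(frozenset, loose.graph.edges)
        )

    def test_env_env_edges_flagged(self):
        rho, p = _mats({("a", "b"): (0.9, 1e-9)})
        meta = pd.DataFrame({"kind": ["environment", "environment", "asv"]},
                            index=["a", "b", "c"])
        net = build_network(rho, p, p, meta)
        assert net.graph.edges["a", "b"]["env_env"] is True

    def test_qvalues_matrix_family(self):
        rho, p = _mats({("a", "b"): (0.9, 0.01), ("a", "c"): (0.9, 0.02),
                        ("b", "c"): (0.9, 0.03)})
        q = qvalues_matrix(p)
        assert q.loc["a", "b"] == pytest.approx(0.03)
        assert np.allclose(q.to_numpy(), q.to_numpy().T)


def test_planted_blocks_have_denser_within_edges(default_community):
    """On latent-factor synthetic data, within-block edge density exceeds
    between-block density in the built network."""
    table, _, truth = default_community
    table = table.filter_low_count(4)
    mask = network_input_filter(table)
    sub = table.subset(table.counts.index[mask])
    res = spearman_all_pairs(sub.relative_abundance())
    net = build_network(res.rho, res.p, qvalues_matrix(res.p))
    blocks = truth.asv["module"]
    within = between = 0
    pw = pb = 0
    nodes = list(net.graph.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            same = blocks[u] == blocks[v]
            has = net.graph.has_edge(u, v)
            if same:
                pw += 1
                within += has
            else:
                pb += 1
                between += has
    assert within / pw > between / pb
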