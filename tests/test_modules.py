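from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nichewebs import FeatureTable, feature_scale, major_modules, module_pattern
from nichewebs.modules import (
    between_density,
    env_subnetwork,
    format_pct,
    intermodule_edges,
    linkage_to_newick,
    module_env_correlation,
    module_patterns,
    ward_cluster,
    within_density,
)
from nichewebs.network import CoNetwork
from nichewebs.tables import SampleMetadata


def ward_oracle(X):
    """Exhaustive Ward (ward.D2) agglomeration from cluster means/sizes."""
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    nxt = len(X)
    ids = list(clusters)

    def cost(a, b):
        ca, cb = X[clusters[a]].mean(axis=0), X[clusters[b]].mean(axis=0)
        na, nb = len(clusters[a]), len(clusters[b])
        return np.sqrt(2.0 * na * nb / (na + nb) * np.sum((ca - cb) ** 2))

    while len(ids) > 1:
        a, b = min(combinations(ids, 2), key=lambda pr: cost(*pr))
        heights.append(cost(a, b))
        clusters[nxt] = clusters[a] + clusters[b]
        ids = [i for i in ids if i not in (a, b)] + [nxt]
        nxt += 1
    return np.array(heights)


class TestMajorModules:
    def test_published_size_profile(self):
        sizes = [283, 257, 203, 268, 196, 181, 30, 43]
        part = {}
        node = 0
        for m, s in enumerate(sizes):
            for _ in range(s):
                part[node] = m
                node += 1
        flags, coverage = major_modules(part)
        # every module with >= max(5, 2% of 1461) ~ 29.2 nodes is major
        assert all(flags[m] for m in range(8))
        assert coverage == 1.0
        flags2, cov2 = major_modules(part, min_size=50)
        assert not flags2[6] and not flags2[7]
        assert cov2 == pytest.approx(sum(sizes[:6]) / sum(sizes))

    def test_single_module(self):
        flags, cov = major_modules({0: 0, 1: 0, 2: 0, 3: 0, 4: 0})
        assert flags[0] and cov == 1.0

    def test_all_singletons_no_majors(self):
        flags, cov = major_modules({i: i for i in range(10)}, min_size=5)
        assert not any(flags.values()) and cov == 0.0


class TestFeatureScale:
    def test_simple(self):
        assert np.allclose(feature_scale([2, 4, 6]), [0, 0.5, 1])

    def test_constant_warns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = feature_scale([5, 5, 5])
        assert np.allclose(out, 0)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        out = feature_scale(rng.normal(size=50))
        assert out.min() == 0.0 and out.max() == 1.0


class TestModulePattern:
    def _table(self, rows, ids):
        return FeatureTable(
            pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(len(rows[0]))])
        )

    def test_single_member(self):
        t = self._table([[1, 2, 3], [5, 5, 5]], ["a", "b"])
        pat = module_pattern(t, ["a"])
        rel = t.relative_abundance().loc["a"]
        assert np.allclose(pat, feature_scale(rel))

    def test_identical_profiles(self):
        # a and b share a relative-abundance profile (filler varies depth)
        t = self._table([[1, 2, 3], [1, 2, 3], [10, 10, 10]], ["a", "b", "f"])
        pat = module_pattern(t, ["a", "b"])
        shared = feature_scale(t.relative_abundance().loc["a"])
        assert np.allclose(pat, shared)

    def test_anticorrelated_pair_flat(self):
        t = self._table([[4, 0], [0, 4]], ["a", "b"])
        pat = module_pattern(t, ["a", "b"])
        assert np.allclose(pat, [0.5, 0.5])

    def test_scale_invariance_of_member_profile(self):
        # doubling a member's abundance profile (at fixed sample depths)
        # leaves the pattern unchanged: min-max scaling absorbs the scale
        t1 = self._table([[1, 2, 3], [9, 8, 7]], ["a", "b"])
        t2 = self._table([[2, 4, 6], [8, 6, 4]], ["a", "b"])
        assert np.allclose(module_pattern(t1, ["a"]), module_pattern(t2, ["a"]))

    def test_empty_module_error(self):
        t = self._table([[1, 2]], ["a"])
        with pytest.raises(ValueError):
            module_pattern(t, [])


class TestWard:
    def test_identical_patterns_merge_at_zero(self):
        pats = pd.DataFrame([[1, 2, 3], [1, 2, 3], [5, 5, 5]], dtype=float)
        Z = ward_cluster(pats)
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(4, 6))
        Z = ward_cluster(pd.DataFrame(X))
        assert np.allclose(np.sort(Z[:, 2]), np.sort(ward_oracle(X)), atol=1e-10)

    def test_heights_nondecreasing_both_variants(self):
        rng = np.random.default_rng(23)
        pats = pd.DataFrame(rng.normal(size=(6, 10)))
        for variant in ("ward.D2", "ward.D"):
            Z = ward_cluster(pats, variant=variant)
            assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_newick_structure(self):
        pats = pd.DataFrame(np.eye(3), index=["A", "B", "C"])
        Z = ward_cluster(pats)
        nwk = linkage_to_newick(Z, pats.index)
        assert nwk.endswith(";") and nwk.count("(") == 2
        for label in "ABC":
            assert label in nwk


class TestModuleEnvCorrelation:
    def test_perfect_and_inverse(self):
        samples = [f"s{i}" for i in range(8)]
        vals = np.arange(8, dtype=float)
        pats = pd.DataFrame({s: [v, 7 - v] for s, v in zip(samples, vals)},
                            index=["m0", "m1"])
        meta = SampleMetadata(pd.DataFrame({"cov": vals},
                                           index=pd.Index(samples, name="sample_id")))
        rho, p = module_env_correlation(pats, meta)
        assert rho.loc["m0", "cov"] == pytest.approx(1.0)
        assert rho.loc["m1", "cov"] == pytest.approx(-1.0)


class TestIntermoduleEdges:
    def test_published_density_arithmetic(self):
        # printed inter-module table values follow from the density formulas
        assert format_pct(within_density(4194, 283)) == 10.5
        assert format_pct(between_density(305, 283, 257)) == 0.4
        assert format_pct(within_density(4200, 268)) == 11.7
        assert format_pct(within_density(794, 196)) == 4.2
        assert format_pct(between_density(449, 268, 181)) == 0.9

    def test_clique_module_full_density(self):
        g = nx.complete_graph(5)
        counts, dens, pct = intermodule_edges(g, {v: 0 for v in g.nodes})
        assert dens.loc[0, 0] == 1.0 and pct.loc[0, 0] == 100.0

    def test_counts_conserve_total_edges(self):
        g = nx.gnm_random_graph(40, 150, seed=5)
        part = {v: v % 4 for v in g.nodes}
        counts, _, _ = intermodule_edges(g, part)
        arr = counts.to_numpy()
        total = np.triu(arr).sum()
        assert total == g.number_of_edges()

    def test_symmetry(self):
        g = nx.gnm_random_graph(20, 50, seed=2)
        counts, dens, _ = intermodule_edges(g, {v: v % 3 for v in g.nodes})
        assert (counts.to_numpy() == counts.to_numpy().T).all()


class TestEnvSubnetwork:
    def _net(self):
        g = nx.Graph()
        g.add_node("env1", kind="environment")
        g.add_node("env2", kind="environment")
        for i, cat in enumerate(["generalist", "generalist", "common"]):
            g.add_node(f"a{i}", kind="asv", category=cat)
        g.add_edges_from([("env1", "a0"), ("env1", "a1"), ("env1", "a2"),
                          ("a0", "a1")])
        return CoNetwork(g)

    def test_neighbors_and_edge_pruning(self):
        with pytest.warns(UserWarning, match="env2"):
            sub, comp = env_subnetwork(self._net())
        assert sub.number_of_nodes() == 4
        assert sub.number_of_edges() == 3  # a0-a1 pruned by default
        sub2, _ = env_subnetwork(self._net(), include_asv_asv=True)
        assert sub2.number_of_edges() == 4

    def test_composition_fractions(self):
        with pytest.warns(UserWarning):
            _, comp = env_subnetwork(self._net())
        row = comp[(comp.environment == "env1") & (comp.category == "generalist")]
        assert row["fraction_of_neighbors"].iloc[0] == pytest.approx(2 / 3)
        assert row["fraction_of_category"].iloc[0] == pytest.approx(1.0)

    def test_no_env_nodes_error(self):
        g = nx.path_graph(3)
        nx.set_node_attributes(g, "asv", "kind")
        with pytest.raises(ValueError):
            env_subnetwork(CoNetwork(g))


def test_module_patterns_exclude_environment(default_community):
    table, _, truth = default_community
    part = {a: int(m) for a, m in truth.asv["module"].items()}
    part["moisture"] = 0
    g = nx.Graph()
    g.add_nodes_from(part)
    nx.set_node_attributes(g, "asv", "kind")
    g.nodes["moisture"]["kind"] = "environment"
    pats = module_patterns(table, part, graph=g, major_only=False)
    assert (pats.to_numpy() >= 0).all() and (pats.to_numpy() <= 1).all()
    assert pats.shape[1] == table.n_samples
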