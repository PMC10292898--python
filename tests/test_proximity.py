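from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from netprox import (
    build_interactome,
    distance_closest,
    distance_shortest,
    make_degree_bins,
    proximity_profile,
    proximity_zscore,
    rank_compounds,
)
from netprox.proximity import ProximityResult
from netprox.similarity import TargetSet
from oracles import enumerate_degree_matched, oracle_closest, oracle_shortest

from conftest import path_graph, star_graph


def ts(name, genes):
    return TargetSet.from_iterable(name, genes)


def random_named_graph(seed, n=40, p=0.12):
    base = nx.gnp_random_graph(n, p, seed=seed)
    edges = [(f"N{u:02d}", f"N{v:02d}") for u, v in base.edges]
    return build_interactome(edges), edges


class TestDistances:
    def test_closest_on_path_endpoints(self):
        g = path_graph("A", "B", "C", "D")
        assert distance_closest(g, ts("s", ["A"]), ts("t", ["D"])) == 3.0

    def test_closest_zero_when_T_subset_of_S(self):
        g = path_graph("A", "B", "C", "D")
        assert distance_closest(g, ts("s", ["A", "D"]), ts("t", ["A", "D"])) == 0.0

    def test_closest_on_star_leaves(self):
        g = star_graph("X", ["L1", "L2", "L3", "L4"])
        assert distance_closest(g, ts("s", ["L1"]), ts("t", ["L2", "L3"])) == 2.0

    def test_shortest_on_path(self):
        g = path_graph("A", "B", "C")
        assert distance_shortest(g, ts("s", ["A"]), ts("t", ["C"])) == 2.0

    def test_shortest_averages_pairs(self):
        g = path_graph("A", "B", "C")
        assert distance_shortest(g, ts("s", ["A", "C"]), ts("t", ["B"])) == 1.0

    def test_disconnected_sets_raise(self):
        g = build_interactome([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="disconnected"):
            distance_closest(g, ts("s", ["A"]), ts("t", ["C"]))

    def test_closest_leq_shortest_property(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            g, edges = random_named_graph(seed)
            nodes = sorted(g.nodes)
            S = set(rng.choice(nodes, size=4, replace=False))
            T = set(rng.choice(nodes, size=5, replace=False))
            try:
                dc = distance_closest(g, ts("s", S), ts("t", T))
                ds = distance_shortest(g, ts("s", S), ts("t", T))
            except ValueError:
                continue
            assert dc <= ds + 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracles(self, seed):
        g, edges = random_named_graph(seed)
        rng = np.random.default_rng(100 + seed)
        nodes = sorted(g.nodes)
        S = set(rng.choice(nodes, size=4, replace=False))
        T = set(rng.choice(nodes, size=5, replace=False))
        try:
            expected_c = oracle_closest(edges, S, T)
        except ZeroDivisionError:
            pytest.skip("disconnected draw")
        assert distance_closest(g, ts("s", S), ts("t", T)) == pytest.approx(expected_c)
        assert distance_shortest(g, ts("s", S), ts("t", T)) == pytest.approx(
            oracle_shortest(edges, S, T)
        )

    def test_adding_target_never_increases_closest(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            g, _ = random_named_graph(seed, n=30, p=0.15)
            nodes = sorted(g.nodes)
            S = list(rng.choice(nodes, size=3, replace=False))
            T = set(rng.choice(nodes, size=4, replace=False))
            extra = next(n for n in nodes if n not in S)
            try:
                before = distance_closest(g, ts("s", S), ts("t", T))
                after = distance_closest(g, ts("s", S + [extra]), ts("t", T))
            except ValueError:
                continue
            assert after <= before + 1e-12


class TestZScores:
    def test_null_draw_scores_near_zero(self, default_bundle):
        """A target set drawn by the null sampler itself must be typical
        under the null."""
        from netprox.null_models import sample_degree_matched

        g, bins = default_bundle.interactome, default_bundle.bins
        T = default_bundle.disease
        zs = []
        for seed in range(10):
            S = sample_degree_matched(set(default_bundle.compounds[3].members), bins, rng=seed)
            res = proximity_zscore(g, ts("rand", S), T, bins, n_reps=500, seed=seed + 50)
            zs.append(res.z_closest)
        assert abs(np.mean(zs)) < 1.0

    def test_z_matches_exhaustive_enumeration_on_toy(self):
        g = build_interactome([("A", "B"), ("B", "C"), ("C", "D"), ("C", "E"), ("A", "F")])
        bins = make_degree_bins(g, min_bin_size=2)
        edges = [tuple(e) for e in g.edge_set()]
        S, T = {"B", "D"}, {"E", "F"}
        vals = [oracle_closest(edges, s, T) for s in enumerate_degree_matched(S, bins)]
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        d_obs = oracle_closest(edges, S, T)
        res = proximity_zscore(g, ts("s", S), ts("t", T), bins, metric="closest",
                               n_reps=4000, seed=2)
        assert res.d_closest == pytest.approx(d_obs)
        assert res.null_closest.mu == pytest.approx(mu, abs=3 * sd / np.sqrt(4000))
        assert res.z_closest == pytest.approx((d_obs - mu) / sd, abs=0.25)

    def test_profile_fills_both_metrics_consistently(self, default_bundle):
        res = proximity_profile(
            default_bundle.interactome, default_bundle.compounds[0],
            default_bundle.disease, default_bundle.bins, n_reps=200, seed=3,
        )
        assert res.d_closest <= res.d_shortest
        assert res.null_closest.n_reps == res.null_shortest.n_reps == 200

    def test_z_invariant_under_node_relabeling(self):
        import warnings

        from netprox.interactome import restrict_to_lcc

        g, _ = random_named_graph(3, n=60, p=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = restrict_to_lcc(g)
        nodes = sorted(g.nodes)
        mapping = {n: f"Z{i:03d}" for i, n in enumerate(reversed(nodes))}
        g2 = build_interactome([(mapping[u], mapping[v]) for u, v in map(tuple, g.edge_set())])
        bins = make_degree_bins(g, min_bin_size=10)
        bins2 = make_degree_bins(g2, min_bin_size=10)
        S, T = set(nodes[:4]), set(nodes[10:15])
        r1 = proximity_zscore(g, ts("s", S), ts("t", T), bins, n_reps=3000, seed=1)
        r2 = proximity_zscore(
            g2, ts("s", {mapping[s] for s in S}), ts("t", {mapping[t] for t in T}),
            bins2, n_reps=3000, seed=1,
        )
        assert r1.d_closest == pytest.approx(r2.d_closest)
        assert r1.z_closest == pytest.approx(r2.z_closest, abs=0.25)


class TestRanking:
    def _mk(self, name, z, d=1.0):
        return ProximityResult(compound=name, n_S=5, n_T=10, d_closest=d, z_closest=z)

    def test_most_negative_z_first(self):
        out = rank_compounds([self._mk("a", -1.0), self._mk("b", -3.0)], k=2)
        assert [r.compound for r in out] == ["b", "a"]

    def test_tie_broken_by_distance(self):
        out = rank_compounds([self._mk("a", -2.0, d=1.5), self._mk("b", -2.0, d=1.2)], k=2)
        assert [r.compound for r in out] == ["b", "a"]

    def test_k_larger_than_results_warns_and_returns_all(self):
        with pytest.warns(UserWarning):
            out = rank_compounds([self._mk("a", -1.0)], k=8)
        assert len(out) == 1
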