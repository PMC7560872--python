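from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from topostates.data import AbundanceTable, DistanceMatrix, pairwise_distances
from topostates.mapper import (
    MapperConfig,
    build_nerve,
    check_hyperparameters,
    interval_starts,
    local_cluster,
    make_cover,
    pcoa_filter,
    rank_transform,
    run_mapper,
)

from conftest import euclidean_dm, random_compositions


def graph_fingerprint(g):
    """Graph up to vertex relabeling: member-ID multiset and edge set."""
    def key(v):
        return tuple(sorted(g.graph.nodes[v]["label_members"]))

    verts = sorted(key(v) for v in g.graph.nodes)
    edges = sorted(tuple(sorted((key(u), key(v)))) for u, v in g.graph.edges)
    return verts, edges


class TestMapperConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MapperConfig(n_intervals=(0, 2))
        with pytest.raises(ValueError):
            MapperConfig(overlap_pct=0)
        with pytest.raises(ValueError):
            MapperConfig(overlap_pct=100)
        with pytest.raises(ValueError):
            MapperConfig(n_hist_bins=1)

    def test_dict_roundtrip(self):
        cfg = MapperConfig(n_intervals=(5, 7), overlap_pct=60.0, n_hist_bins=8)
        assert MapperConfig.from_dict(cfg.to_dict()) == cfg


class TestPcoaFilter:
    def test_collinear_points_distances_preserved(self):
        dm = euclidean_dm(np.array([[0.0], [1.0], [3.0]]))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords = pcoa_filter(dm, n_components=2)
        assert coords.shape[1] == 1
        got = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(got, dm.d, atol=1e-9)

    def test_duplicate_samples_identical_coords(self, rng):
        pts = rng.random((5, 3))
        pts[3] = pts[1]
        coords = pcoa_filter(euclidean_dm(pts), n_components=2)
        np.testing.assert_allclose(coords[3], coords[1], atol=1e-9)

    def test_euclidean_2d_exact(self, rng):
        pts = rng.random((8, 2))
        coords = pcoa_filter(euclidean_dm(pts), n_components=2)
        diff = coords[:, None, :] - coords[None, :, :]
        got = np.sqrt((diff**2).sum(axis=-1))
        np.testing.assert_allclose(got, euclidean_dm(pts).d, atol=1e-8)

    def test_js_matrix_matches_independent_eigendecomposition(self, rng):
        x = random_compositions(rng, 12, 6, zeros=0.3)
        t = AbundanceTable(samples=[f"s{i}" for i in range(12)],
                           taxa=[f"t{j}" for j in range(6)], values=x)
        dm = pairwise_distances(t)
        coords = pcoa_filter(dm, n_components=2)
        # independent oracle: direct dense eigendecomposition
        n = dm.n
        j = np.eye(n) - 1 / n
        b = -0.5 * j @ (dm.d**2) @ j
        vals, vecs = np.linalg.eigh((b + b.T) / 2)
        top = np.argsort(vals)[::-1][:2]
        expected = vecs[:, top] * np.sqrt(vals[top])
        for c in range(2):
            dot = np.abs(expected[:, c] @ coords[:, c])
            assert dot == pytest.approx(
                np.linalg.norm(expected[:, c]) * np.linalg.norm(coords[:, c]),
                rel=1e-8,
            )

    def test_sign_convention_deterministic(self, rng):
        pts = rng.random((7, 3))
        a = pcoa_filter(euclidean_dm(pts))
        b = pcoa_filter(euclidean_dm(pts))
        np.testing.assert_array_equal(a, b)
        for c in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, c])), c] > 0

    def test_too_few_samples(self):
        dm = DistanceMatrix(ids=["a", "b"], d=[[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            pcoa_filter(dm)


class TestRankTransform:
    def test_basic(self):
        np.testing.assert_array_equal(
            rank_transform([0.5, -1.2, 3.3]), [2, 1, 3]
        )

    def test_all_equal_uses_input_order(self):
        np.testing.assert_array_equal(rank_transform([7.0] * 4), [1, 2, 3, 4])

    def test_increasing_input_is_identity(self):
        np.testing.assert_array_equal(
            rank_transform([1.0, 2.0, 5.0, 9.0]), [1, 2, 3, 4]
        )

    def test_monotone(self, rng):
        v = rng.random(30)
        r1 = rank_transform(v)
        r2 = rank_transform(2 * v + 5)
        np.testing.assert_array_equal(r1, r2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([1.0, np.nan])


class TestMakeCover:
    def test_single_interval_single_bin(self, rng):
        filters = np.column_stack([rank_transform(rng.random(10)),
                                   rank_transform(rng.random(10))])
        cfg = MapperConfig(n_intervals=(1, 1), overlap_pct=30.0)
        bins = make_cover(filters, cfg)
        assert len(bins) == 1
        assert set(bins[0].members) == set(range(10))

    def test_hand_worked_one_dimension(self):
        # ranks 1..10, 2 intervals, 50% overlap:
        # L = span / ((n-1)(1-g) + 1) = 9 / 1.5 = 6 -> [1, 7] and [4, 10]
        starts, length = interval_starts(1.0, 10.0, 2, 50.0)
        assert length == pytest.approx(6.0)
        np.testing.assert_allclose(starts, [1.0, 4.0])
        ranks = np.arange(1, 11)
        filters = np.column_stack([ranks, np.ones(10, dtype=int)])
        cfg = MapperConfig(n_intervals=(2, 1), overlap_pct=50.0)
        bins = make_cover(filters, cfg)
        members = {b.bin_id: set(np.array(b.members) + 1) for b in bins}
        assert members[(0, 0)] == set(range(1, 8))
        assert members[(1, 0)] == set(range(4, 11))

    def test_cover_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            filters = np.column_stack(
                [rank_transform(rng.random(n)), rank_transform(rng.random(n))]
            )
            cfg = MapperConfig(
                n_intervals=(int(rng.integers(1, 8)), int(rng.integers(1, 8))),
                overlap_pct=float(rng.uniform(5, 95)),
            )
            bins = make_cover(filters, cfg)
            covered = set()
            for b in bins:
                covered.update(b.members)
            assert covered == set(range(n))

    def test_at_most_four_bins_below_half_overlap(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            filters = np.column_stack(
                [rank_transform(rng.random(n)), rank_transform(rng.random(n))]
            )
            cfg = MapperConfig(n_intervals=(5, 5),
                               overlap_pct=float(rng.uniform(5, 49.9)))
            counts = np.zeros(n, dtype=int)
            for b in make_cover(filters, cfg):
                counts[list(b.members)] += 1
            assert counts.min() >= 1
            assert counts.max() <= 4

    def test_monotone_cover_in_overlap(self, rng):
        n = 30
        filters = np.column_stack(
            [rank_transform(rng.random(n)), rank_transform(rng.random(n))]
        )
        lo = make_cover(filters, MapperConfig(n_intervals=(4, 4), overlap_pct=20))
        hi = make_cover(filters, MapperConfig(n_intervals=(4, 4), overlap_pct=60))

        def comemberships(bins):
            pairs = set()
            for b in bins:
                pairs.update(combinations(sorted(b.members), 2))
            return pairs

        assert comemberships(lo) <= comemberships(hi)

    def test_degenerate_more_intervals_than_samples(self):
        filters = np.array([[1, 1], [2, 2], [3, 3]])
        bins = make_cover(filters, MapperConfig(n_intervals=(7, 7), overlap_pct=30))
        covered = set()
        for b in bins:
            covered.update(b.members)
        assert covered == {0, 1, 2}


class TestLocalCluster:
    def test_singleton_bin(self, rng):
        dm = euclidean_dm(rng.random((4, 2)))
        assert local_cluster((2,), dm) == [(2,)]

    def test_two_separated_groups(self):
        # within-group distances <= 0.1, between >= 5; 10 histogram bins
        pts = np.array([[0.0], [0.05], [0.1], [5.0], [5.05]])
        dm = euclidean_dm(pts)
        clusters = local_cluster((0, 1, 2, 3, 4), dm, n_hist_bins=10)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2], [3, 4]]

    def test_two_separated_groups_cutoff_oracle(self):
        # direct dendrogram inspection: merge heights {0.05, 0.05, 0.05, 4.9},
        # diameter 5.05; the first histogram gap opens just above the small
        # heights, so the cut must fall strictly between 0.05 and 4.9
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        pts = np.array([[0.0], [0.05], [0.1], [5.0], [5.05]])
        dm = euclidean_dm(pts)
        z = linkage(squareform(dm.d, checks=False), method="single")
        heights = sorted(z[:, 2])
        assert max(h for h in heights if h < 1) <= 0.1
        assert min(h for h in heights if h > 1) >= 4.9

    def test_all_equal_distances_single_cluster(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        dm = euclidean_dm(np.zeros((4, 1)))
        dm = dm.__class__(ids=dm.ids, d=d)
        assert local_cluster((0, 1, 2, 3), dm) == [(0, 1, 2, 3)]

    def test_pair_bin_single_cluster(self, rng):
        dm = euclidean_dm(rng.random((3, 2)))
        assert local_cluster((0, 2), dm) == [(0, 2)]

    def test_clusters_are_disjoint_and_exhaustive(self, rng):
        dm = euclidean_dm(rng.random((12, 3)))
        members = tuple(range(12))
        clusters = local_cluster(members, dm)
        flat = [i for c in clusters for i in c]
        assert sorted(flat) == list(members)
        assert len(flat) == len(set(flat))


class TestBuildNerve:
    def test_shared_sample_gives_edge(self):
        g = build_nerve([((0, 0), [(1, 2)]), ((1, 0), [(2, 3)])], n_samples=4)
        assert g.n_vertices == 2
        assert g.n_edges == 1

    def test_disjoint_clusters_no_edge(self):
        g = build_nerve([((0, 0), [(1, 2)]), ((1, 0), [(3, 4)])], n_samples=5)
        assert g.n_edges == 0

    def test_quadratic_intersection_oracle(self, rng):
        clusters_per_bin = []
        for b in range(8):
            k = int(rng.integers(1, 4))
            clusters = []
            pool = rng.permutation(50)
            at = 0
            for _ in range(k):
                size = int(rng.integers(1, 8))
                clusters.append(tuple(int(i) for i in pool[at:at + size]))
                at += size
            clusters_per_bin.append(((b, 0), clusters))
        g = build_nerve(clusters_per_bin, n_samples=50)
        sets = {v: set(g.members(v)) for v in g.vertices()}
        expected = {
            frozenset((u, v))
            for u, v in combinations(sets, 2)
            if sets[u] & sets[v]
        }
        got = {frozenset(e) for e in g.graph.edges}
        assert got == expected

    def test_no_self_loops(self, rng):
        g = build_nerve([((0, 0), [(1, 2), (2, 3)])], n_samples=4)
        assert all(u != v for u, v in g.graph.edges)


def _two_cluster_table(rng, n=40):
    x = np.vstack([
        rng.dirichlet([40, 5, 1, 1, 1], size=n // 2),
        rng.dirichlet([1, 1, 1, 5, 40], size=n // 2),
    ])
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    t = AbundanceTable(samples=[f"s{i}" for i in range(n)],
                       taxa=[f"t{j}" for j in range(5)], values=x)
    return t, labels


class TestRunMapper:
    def test_two_clusters_vertex_purity(self, rng):
        t, labels = _two_cluster_table(rng, n=60)
        dm = pairwise_distances(t)
        g = run_mapper(dm, MapperConfig(n_intervals=(6, 6), overlap_pct=50))
        purities = []
        for v in g.vertices():
            mem = np.array(g.members(v))
            frac = labels[mem].mean()
            purities.append(max(frac, 1 - frac))
        assert np.mean(purities) >= 0.9

    def test_single_bin_matches_local_clustering(self, rng):
        x = random_compositions(rng, 5, 4)
        t = AbundanceTable(samples=list("abcde"),
                           taxa=[f"t{j}" for j in range(4)], values=x)
        dm = pairwise_distances(t)
        cfg = MapperConfig(n_intervals=(1, 1), overlap_pct=50)
        g = run_mapper(dm, cfg)
        expected = local_cluster(tuple(range(5)), dm, cfg.n_hist_bins)
        got = sorted(g.members(v) for v in g.vertices())
        assert got == sorted(expected)

    def test_every_sample_in_some_vertex(self, rng):
        x = random_compositions(rng, 35, 6, zeros=0.2)
        t = AbundanceTable(samples=[f"s{i}" for i in range(35)],
                           taxa=[f"t{j}" for j in range(6)], values=x)
        dm = pairwise_distances(t)
        g = run_mapper(dm, MapperConfig(n_intervals=(4, 4), overlap_pct=40))
        covered = set()
        for v in g.vertices():
            covered.update(g.members(v))
        assert covered == set(range(35))

    def test_determinism(self, rng):
        x = random_compositions(rng, 25, 5)
        t = AbundanceTable(samples=[f"s{i}" for i in range(25)],
                           taxa=[f"t{j}" for j in range(5)], values=x)
        dm = pairwise_distances(t)
        cfg = MapperConfig(n_intervals=(4, 4), overlap_pct=55)
        g1, g2 = run_mapper(dm, cfg), run_mapper(dm, cfg)
        assert sorted(g1.members(v) for v in g1.vertices()) == sorted(
            g2.members(v) for v in g2.vertices()
        )
        assert sorted(map(sorted, g1.graph.edges)) == sorted(
            map(sorted, g2.graph.edges)
        )

    def test_permutation_isomorphism(self, rng):
        x = random_compositions(rng, 30, 5)
        samples = [f"s{i}" for i in range(30)]
        t = AbundanceTable(samples=samples,
                           taxa=[f"t{j}" for j in range(5)], values=x)
        cfg = MapperConfig(n_intervals=(4, 4), overlap_pct=50)
        perm = rng.permutation(30)
        t2 = t.subset([samples[i] for i in perm])
        g1 = run_mapper(pairwise_distances(t), cfg)
        g2 = run_mapper(pairwise_distances(t2), cfg)
        for g, tab in ((g1, t), (g2, t2)):
            for v in g.graph.nodes:
                g.graph.nodes[v]["label_members"] = [
                    tab.samples[i] for i in g.members(v)
                ]
        assert graph_fingerprint(g1) == graph_fingerprint(g2)


class TestCheckHyperparameters:
    def _graph_with_sizes(self, sizes, n_samples):
        clusters, at = [], 0
        for s in sizes:
            clusters.append(tuple(range(at, at + s)))
            at += s
        return build_nerve([((0, 0), clusters)], n_samples=n_samples)

    def test_exactly_ten_percent_passes(self):
        g = self._graph_with_sizes([2, 2], 20)
        rep = check_hyperparameters(g, 20)
        assert rep.largest_vertex_fraction == pytest.approx(0.10)
        assert rep.passed

    def test_quarter_fails(self):
        g = self._graph_with_sizes([5, 2], 20)
        rep = check_hyperparameters(g, 20)
        assert rep.largest_vertex_fraction == pytest.approx(0.25)
        assert not rep.passed

    def test_singleton_components_counted(self):
        g = build_nerve(
            [((0, 0), [(0,)]), ((1, 0), [(1,)]), ((2, 0), [(2,)])], n_samples=3
        )
        rep = check_hyperparameters(g, 3)
        assert rep.n_singleton_components == 3


class TestExport:
    def test_graphml_roundtrip(self, tmp_path, rng):
        x = random_compositions(rng, 15, 4)
        samples = [f"s{i}" for i in range(15)]
        t = AbundanceTable(samples=samples, taxa=list("wxyz"), values=x)
        dm = pairwise_distances(t)
        cfg = MapperConfig(n_intervals=(3, 3), overlap_pct=50)
        g = run_mapper(dm, cfg)
        g.to_graphml(tmp_path / "g.graphml", sample_ids=samples)
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == g.n_vertices
        assert back.number_of_edges() == g.n_edges
        assert back.graph["overlap_pct"] == cfg.overlap_pct
        members = {
            frozenset(data["members"].split(";")) for _, data in back.nodes(data=True)
        }
        expected = {
            frozenset(samples[i] for i in g.members(v)) for v in g.vertices()
        }
        assert members == expected

    def test_json_export(self, tmp_path, rng):
        import json

        x = random_compositions(rng, 10, 4)
        t = AbundanceTable(samples=[f"s{i}" for i in range(10)],
                           taxa=list("wxyz"), values=x)
        g = run_mapper(pairwise_distances(t),
                       MapperConfig(n_intervals=(2, 2), overlap_pct=50))
        g.to_json(tmp_path / "g.json", sample_ids=t.samples)
        payload = json.loads((tmp_path / "g.json").read_text())
        assert len(payload["vertices"]) == g.n_vertices
        assert len(payload["edges"]) == g.n_edges
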