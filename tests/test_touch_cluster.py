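"""Supervoxel geometry, absorption, touching-area clustering, assignment."""

import numpy as np
import pytest

import memseg3d as m
from memseg3d.touch_cluster import TouchingGraph


def make_graph(volume, surface, edges):
    return TouchingGraph(
        volume=dict(volume),
        surface=dict(surface),
        edges={tuple(sorted(k)): v for k, v in edges.items()},
        members={u: [u] for u in volume},
    )


def random_graph(rng, max_nodes=12):
    n = int(rng.integers(2, max_nodes + 1))
    ids = list(range(1, n + 1))
    volume = {u: int(rng.integers(1, 100)) for u in ids}
    surface = {u: int(rng.integers(20, 200)) for u in ids}
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                cap = min(surface[ids[i]], surface[ids[j]])
                edges[(ids[i], ids[j])] = int(rng.integers(1, cap + 1))
    return make_graph(volume, surface, edges)


def brute_force_partition(graph, min_area):
    """Transitive closure over qualifying edges by repeated scanning."""
    clusters = [{u} for u in graph.volume]
    changed = True
    while changed:
        changed = False
        for (u, v), s in graph.edges.items():
            if s < min_area:
                continue
            cu = next(c for c in clusters if u in c)
            cv = next(c for c in clusters if v in c)
            if cu is not cv:
                cu |= cv
                clusters.remove(cv)
                changed = True
    return sorted(sorted(c) for c in clusters)


class TestWatershed:
    def test_empty_foreground(self):
        sv = m.watershed_supervoxels(np.zeros((5, 5, 5), dtype=bool))
        assert not (sv.labels > 0).any()

    def test_solid_sphere_single_supervoxel(self):
        z, y, x = np.indices((21, 21, 21))
        sphere = (z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 64
        sv = m.watershed_supervoxels(sphere)
        assert np.array_equal(sv.labels > 0, sphere)  # every fg voxel labeled
        assert len(sv.label_ids()) == 1

    def test_bridged_spheres_split_across_bridge(self):
        z, y, x = np.indices((17, 17, 41))
        a = (z - 8) ** 2 + (y - 8) ** 2 + (x - 8) ** 2 <= 36
        b = (z - 8) ** 2 + (y - 8) ** 2 + (x - 32) ** 2 <= 36
        bridge = (z == 8) & (y == 8) & (x >= 8) & (x <= 32)
        fg = a | b | bridge
        sv = m.watershed_supervoxels(fg)
        assert np.array_equal(sv.labels > 0, fg)
        assert len(sv.label_ids()) >= 2
        # the two sphere centers belong to different supervoxels
        assert sv.labels[8, 8, 8] != sv.labels[8, 8, 32]


class TestTouchingGraph:
    def test_single_voxel_surface_six(self):
        arr = np.zeros((3, 3, 3), dtype=int)
        arr[1, 1, 1] = 1
        g = m.build_touching_graph(arr)
        assert g.surface[1] == 6
        assert g.edges == {}

    def test_two_cubes_share_nine_faces(self):
        arr = np.zeros((3, 6, 3), dtype=int)
        arr[:, :3, :] = 1
        arr[:, 3:, :] = 2
        g = m.build_touching_graph(arr)
        assert g.edges[(1, 2)] == 9
        assert g.surface[1] == 6 * 27 - 2 * (2 * 9 * 3)  # exposed faces of a 3^3 cube block
        assert g.volume[1] == 27

    def test_volume_border_faces_count_toward_surface(self):
        arr = np.ones((1, 1, 1), dtype=int)
        g = m.build_touching_graph(arr)
        assert g.surface[1] == 6

    def test_edge_diagonal_contact_is_no_edge(self):
        arr = np.zeros((2, 2, 2), dtype=int)
        arr[0, 0, 0] = 1
        arr[0, 1, 1] = 2  # touch along an edge, not a face
        g = m.build_touching_graph(arr)
        assert g.edges == {}

    def test_invariants_on_random_labels(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 6, (8, 8, 8))
        g = m.build_touching_graph(arr)
        g.validate()  # S_uv <= min(S_u, S_v), positive areas
        for u in g.volume:
            assert sum(g.neighbors(u).values()) <= g.surface[u]


class TestAbsorption:
    def test_fully_enclosed_supervoxel_merged(self):
        arr = np.ones((5, 5, 5), dtype=int)
        arr[2, 2, 2] = 2  # S_2v == S_2
        g = m.absorb_engulfed_supervoxels(m.build_touching_graph(arr))
        assert set(g.volume) == {1}
        assert sorted(g.members[1]) == [1, 2]
        assert g.volume[1] == 125

    def test_equal_cubes_not_merged(self):
        arr = np.zeros((3, 6, 3), dtype=int)
        arr[:, :3, :] = 1
        arr[:, 3:, :] = 2
        g = m.absorb_engulfed_supervoxels(m.build_touching_graph(arr))
        assert set(g.volume) == {1, 2}  # 9 shared faces < half of 90

    def test_chain_reaches_fixpoint(self):
        # A absorbable by B; once merged, (A+B) absorbable by C
        graph = make_graph(
            volume={1: 4, 2: 10, 3: 500},
            surface={1: 16, 2: 36, 3: 600},
            edges={(1, 2): 10, (2, 3): 17},
        )
        out = m.absorb_engulfed_supervoxels(graph)
        assert set(out.volume) == {3}
        assert sorted(out.members[3]) == [1, 2, 3]

    def test_input_graph_not_modified(self):
        arr = np.ones((5, 5, 5), dtype=int)
        arr[2, 2, 2] = 2
        g0 = m.build_touching_graph(arr)
        m.absorb_engulfed_supervoxels(g0)
        assert set(g0.volume) == {1, 2}


class TestClustering:
    def test_threshold_rule(self):
        graph = make_graph(
            volume={1: 10, 2: 10, 3: 10},
            surface={1: 60, 2: 60, 3: 60},
            edges={(1, 2): 40, (2, 3): 10},
        )
        assert m.cluster_by_touching_area(graph, min_area=30) == [[1, 2], [3]]

    def test_no_qualifying_edges_all_singletons(self):
        graph = make_graph(
            volume={1: 1, 2: 1, 3: 1},
            surface={1: 6, 2: 6, 3: 6},
            edges={(1, 2): 2},
        )
        assert m.cluster_by_touching_area(graph, min_area=30) == [[1], [2], [3]]

    def test_oracle_equivalence_and_order_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            graph = random_graph(rng)
            min_area = int(rng.integers(1, 120))
            got = sorted(m.cluster_by_touching_area(graph, min_area))
            assert got == brute_force_partition(graph, min_area)
            # relabeling nodes by a random permutation permutes the partition
            for _ in range(5):
                perm = {u: int(v) for u, v in
                        zip(graph.volume, rng.permutation(list(graph.volume)))}
                pg = make_graph(
                    {perm[u]: v for u, v in graph.volume.items()},
                    {perm[u]: s for u, s in graph.surface.items()},
                    {(perm[u], perm[v]): s for (u, v), s in graph.edges.items()},
                )
                pgot = m.cluster_by_touching_area(pg, min_area)
                unmapped = sorted(sorted(perm_inv[x] for x in c) for c in pgot
                                  for perm_inv in [{v: k for k, v in perm.items()}])
                assert sorted(unmapped) == got


class TestAssignment:
    def test_six_adjacent_voxel_takes_neighbor_label(self):
        inst = np.zeros((3, 3, 3), dtype=int)
        inst[1, 1, 0] = 5
        todo = np.zeros_like(inst, dtype=bool)
        todo[1, 1, 1] = True
        out = m.assign_unlabeled_voxels(inst, membrane=todo)
        assert out.labels[1, 1, 1] == 5

    def test_equidistant_tie_takes_smaller_id(self):
        inst = np.zeros((1, 1, 5), dtype=int)
        inst[0, 0, 0] = 7
        inst[0, 0, 4] = 2
        todo = np.zeros_like(inst, dtype=bool)
        todo[0, 0, 2] = True
        out = m.assign_unlabeled_voxels(inst, membrane=todo)
        assert out.labels[0, 0, 2] == 2

    def test_matches_exhaustive_nearest_search(self):
        rng = np.random.default_rng(8)
        inst = np.zeros((6, 6, 6), dtype=int)
        inst[0, 0, 0] = 1
        inst[5, 5, 5] = 2
        inst[0, 5, 0] = 3
        todo = (rng.random((6, 6, 6)) < 0.3) & (inst == 0)
        out = m.assign_unlabeled_voxels(inst, membrane=todo)
        coords = {lab: np.argwhere(inst == lab) for lab in (1, 2, 3)}
        for idx in np.argwhere(todo):
            best = min(
                (float(np.sum((coords[lab][0] - idx) ** 2)), lab) for lab in (1, 2, 3)
            )
            assert out.labels[tuple(idx)] == best[1]

    def test_no_instances_warns_and_leaves_zero(self):
        todo = np.ones((2, 2, 2), dtype=bool)
        with pytest.warns(UserWarning, match="no instances"):
            out = m.assign_unlabeled_voxels(np.zeros((2, 2, 2), dtype=int),
                                            membrane=todo)
        assert not (out.labels > 0).any()


class TestSegmentInstances:
    def test_single_cell(self):
        labels = np.zeros((12, 12, 12), dtype=int)
        labels[2:10, 2:10, 2:10] = 1
        masks = m.semantic_masks_from_labels(labels, 2.0)
        res = m.segment_instances(masks, min_area=30)
        assert res.n_instances == 1

    def test_conservation_of_labeled_volume(self, small_phantom):
        _, _, _, masks = small_phantom
        res = m.segment_instances(masks, min_area=30)
        labeled = int((res.labels.labels > 0).sum())
        assert labeled == int(masks.foreground.sum() + masks.membrane.sum())

    def test_instance_ids_consecutive_by_volume(self, small_phantom):
        _, _, _, masks = small_phantom
        res = m.segment_instances(masks, min_area=30)
        ids, vols = np.unique(res.labels.labels[res.labels.labels > 0],
                              return_counts=True)
        assert ids.tolist() == list(range(1, len(ids) + 1))

    def test_dbscan_baseline_agreement(self, small_phantom):
        """On hole-free phantoms a density-based voxel clustering gives the
        same instance count as touching-area clustering."""
        from sklearn.cluster import DBSCAN

        spec, _, _, masks = small_phantom
        res = m.segment_instances(masks, min_area=30)
        pts = np.argwhere(masks.foreground)
        db = DBSCAN(eps=1.0, min_samples=1).fit(pts)  # eps=1: 6-connectivity
        n_db = len(set(db.labels_))
        assert res.n_instances == n_db == spec.n_cells
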