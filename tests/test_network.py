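"""Element extraction: segmentation, skeleton graph, tube/node/mesh taxonomy."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from angiomorph.network import (IntensityImage, classify_nodes, classify_tubes,
                                extract_meshes, extract_network,
                                measure_thickness, segment_and_skeletonize,
                                skeleton_to_graph)
from angiomorph.simulate import NetworkDesign, simulate_network_image

from conftest import make_graph, skeleton_from_segments


def draw_tubes(segments, shape=(128, 128), width=5, intensity=200.0):
    sk = skeleton_from_segments(segments, shape)
    mask = ndimage.binary_dilation(sk, structure=disk(width // 2))
    img = np.zeros(shape)
    img[mask] = intensity
    return IntensityImage(img)


def branch_and_end_pixels(skel):
    k = np.ones((3, 3), int)
    k[1, 1] = 0
    nc = ndimage.convolve(skel.astype(int), k, mode="constant")
    ends = skel & (nc == 1)
    branches = skel & (nc >= 3)
    n_branch_clusters = ndimage.label(branches, structure=np.ones((3, 3)))[1]
    return n_branch_clusters, int(ends.sum())


class TestSegmentation:
    def test_blank_image_yields_empty_masks(self):
        mask, skel = segment_and_skeletonize(IntensityImage(np.zeros((64, 64))))
        assert not mask.any() and not skel.any()

    def test_constant_image_yields_empty_masks(self):
        mask, skel = segment_and_skeletonize(IntensityImage(np.full((64, 64), 7.0)))
        assert not mask.any() and not skel.any()

    def test_y_shape_has_one_branch_and_three_ends(self):
        img = draw_tubes([((64, 10), (64, 64)), ((64, 64), (20, 110)),
                          ((64, 64), (108, 110))])
        mask, skel = segment_and_skeletonize(img)
        n_branch, n_ends = branch_and_end_pixels(skel)
        assert n_branch == 1
        assert n_ends == 3

    def test_straight_tube_has_two_ends_no_branches(self):
        img = draw_tubes([((64, 10), (64, 118))])
        _, skel = segment_and_skeletonize(img)
        n_branch, n_ends = branch_and_end_pixels(skel)
        assert (n_branch, n_ends) == (0, 2)

    def test_skeleton_is_one_pixel_wide_and_inside_mask(self):
        img = draw_tubes([((64, 10), (64, 64)), ((64, 64), (20, 110)),
                          ((64, 64), (108, 110))])
        mask, skel = segment_and_skeletonize(img)
        assert not (skel & ~mask).any()
        # no 2x2 all-true block
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not blocks.any()


class TestSkeletonToGraph:
    def test_straight_line(self):
        sk = skeleton_from_segments([((60, 10), (60, 100))])
        g = skeleton_to_graph(sk)
        assert (g.n_vertices, g.n_edges) == (2, 1)

    def test_y_shape(self):
        sk = skeleton_from_segments([((60, 10), (60, 60)), ((60, 60), (20, 100)),
                                     ((60, 60), (100, 100))])
        g = skeleton_to_graph(sk)
        assert (g.n_vertices, g.n_edges) == (4, 3)

    def test_two_disjoint_lines(self):
        sk = skeleton_from_segments([((20, 10), (20, 100)), ((80, 10), (80, 100))])
        g = skeleton_to_graph(sk)
        assert (g.n_vertices, g.n_edges) == (4, 2)
        assert len(g.components) == 2

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            skeleton_to_graph(np.arange(9.0).reshape(3, 3))

    def test_path_pixels_cover_skeleton(self):
        sk = skeleton_from_segments([((60, 10), (60, 60)), ((60, 60), (20, 100)),
                                     ((60, 60), (100, 100)), ((20, 30), (40, 30))])
        g = skeleton_to_graph(sk)
        total_path = sum(e.n_pixels for e in g.edges.values())
        assert abs(total_path - int(sk.sum())) <= g.n_vertices


class TestNodeClassification:
    def test_y_shape_nodes(self):
        sk = skeleton_from_segments([((60, 10), (60, 60)), ((60, 60), (20, 100)),
                                     ((60, 60), (100, 100))])
        g = skeleton_to_graph(sk)
        nodes = classify_nodes(g)
        assert nodes.count("extremity") == 3
        assert nodes.count("junction") == 1
        assert nodes.junction_degree_counts() == {"2way": 0, "3way": 1, "4way_plus": 0}
        assert nodes.master_junctions == []

    def test_close_junctions_fuse_into_master(self):
        g = make_graph(
            {0: (50, 50), 1: (50, 52),             # two junctions 2 px apart
             2: (10, 50), 3: (90, 50), 4: (10, 52), 5: (90, 52)},
            [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)])
        nodes = classify_nodes(g, fusion_radius_px=5)
        assert len(nodes.master_junctions) == 1
        assert nodes.master_junctions[0]["members"] == [0, 1]
        r, c = nodes.master_junctions[0]["coordinate"]
        assert (r, c) == (50.0, 51.0)

    def test_isolated_line_has_two_extremities(self):
        sk = skeleton_from_segments([((30, 10), (30, 90))])
        nodes = classify_nodes(skeleton_to_graph(sk))
        assert nodes.count("extremity") == 2
        assert nodes.count("junction") == 0

    def test_negative_radius_rejected(self):
        sk = skeleton_from_segments([((30, 10), (30, 90))])
        with pytest.raises(ValueError):
            classify_nodes(skeleton_to_graph(sk), fusion_radius_px=-1)


class TestTubeClassification:
    def test_y_shape_is_three_twigs(self):
        sk = skeleton_from_segments([((60, 10), (60, 60)), ((60, 60), (20, 100)),
                                     ((60, 60), (100, 100))])
        g = skeleton_to_graph(sk)
        tubes = classify_tubes(g, classify_nodes(g))
        assert tubes.count("twig") == 3
        assert tubes.count("segment") == 0 and tubes.count("isolated") == 0

    def test_triangle_with_pendant(self):
        sk = skeleton_from_segments([((20, 20), (20, 90)), ((20, 90), (80, 55)),
                                     ((80, 55), (20, 20)), ((80, 55), (110, 55))],
                                    shape=(128, 128))
        g = skeleton_to_graph(sk)
        tubes = classify_tubes(g, classify_nodes(g))
        assert tubes.count("segment") == 3
        assert tubes.count("twig") == 1
        assert tubes.n_master_segments == 3

    def test_lone_line_is_isolated(self):
        sk = skeleton_from_segments([((30, 10), (30, 90))])
        g = skeleton_to_graph(sk)
        tubes = classify_tubes(g, classify_nodes(g))
        assert tubes.count("isolated") == 1

    def test_classification_is_total(self, simulated_net):
        g = skeleton_to_graph(
            segment_and_skeletonize(simulated_net.image)[1])
        tubes = classify_tubes(g, classify_nodes(g))
        total = sum(tubes.count(c) for c in ("segment", "twig", "isolated"))
        assert total == g.n_edges


class TestMeshes:
    def test_triangle_has_one_mesh(self):
        sk = skeleton_from_segments([((20, 20), (20, 90)), ((20, 90), (80, 55)),
                                     ((80, 55), (20, 20))])
        g = skeleton_to_graph(sk)
        meshes, n_pre = extract_meshes(g)
        assert (len(meshes), n_pre) == (1, 1)
        assert meshes[0].area > 0

    def test_two_triangles_sharing_an_edge(self):
        # abstract V=4, E=5 double triangle, hand-built with straight paths
        g = make_graph({0: (10, 50), 1: (60, 10), 2: (60, 90), 3: (110, 50)},
                       [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)])
        meshes, n_pre = extract_meshes(g, min_mesh_area_px2=1.0)
        assert n_pre == 2
        assert len(meshes) == 2

    def test_tree_has_no_meshes(self):
        sk = skeleton_from_segments([((60, 10), (60, 60)), ((60, 60), (20, 100)),
                                     ((60, 60), (100, 100))])
        meshes, n_pre = extract_meshes(skeleton_to_graph(sk))
        assert (len(meshes), n_pre) == (0, 0)

    def test_mesh_count_equals_cycle_rank(self, simulated_net):
        g = skeleton_to_graph(segment_and_skeletonize(simulated_net.image)[1])
        _, n_pre = extract_meshes(g, min_mesh_area_px2=0.0)
        assert n_pre == g.cycle_rank()

    @pytest.mark.parametrize("seed", range(20))
    def test_euler_identity_on_random_networks(self, seed):
        gt = simulate_network_image(
            NetworkDesign(n_seeds=20, mesh_fraction=0.4), seed=seed)
        g = skeleton_to_graph(segment_and_skeletonize(gt.image)[1])
        _, n_pre = extract_meshes(g, min_mesh_area_px2=0.0)
        assert n_pre == g.n_edges - g.n_vertices + len(g.components)


class TestThickness:
    def _ribbon(self, width, shape=(64, 128)):
        mask = np.zeros(shape, dtype=bool)
        r0 = shape[0] // 2
        half = width // 2
        mask[r0 - half: r0 - half + width, 10:118] = True
        sk = np.zeros(shape, dtype=bool)
        sk[r0, 12:116] = True
        return mask, skeleton_to_graph(sk)

    def test_width_seven_ribbon(self):
        mask, g = self._ribbon(7)
        th = measure_thickness(g, mask)
        assert abs(list(th.values())[0] - 7) <= 1

    def test_single_pixel_line(self):
        sk = skeleton_from_segments([((30, 10), (30, 90)),], shape=(64, 128))
        g = skeleton_to_graph(sk)
        th = measure_thickness(g, sk)
        assert 1.0 <= list(th.values())[0] <= 2.0

    def test_width_ratio_three_to_nine(self):
        m3, g3 = self._ribbon(3)
        m9, g9 = self._ribbon(9)
        t3 = list(measure_thickness(g3, m3).values())[0]
        t9 = list(measure_thickness(g9, m9).values())[0]
        assert t9 / t3 == pytest.approx(3.0, rel=0.15)

    def test_path_outside_mask_rejected(self):
        mask, g = self._ribbon(7)
        with pytest.raises(ValueError):
            measure_thickness(g, np.zeros_like(mask))


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_element_conservation(self, seed):
        gt = simulate_network_image(NetworkDesign(n_seeds=18), seed=seed)
        el = extract_network(gt.image)
        tubes, nodes, g = el.tubes, el.nodes, el.graph
        assert (tubes.count("segment") + tubes.count("twig")
                + tubes.count("isolated")) == g.n_edges
        assert nodes.count("junction") + nodes.count("extremity") == g.n_vertices

    def test_added_disconnected_tube_is_monotone(self):
        base = [((30, 10), (30, 60)), ((30, 60), (10, 100)), ((30, 60), (60, 100))]
        extra = [((100, 10), (100, 100))]
        g1 = skeleton_to_graph(skeleton_from_segments(base))
        g2 = skeleton_to_graph(skeleton_from_segments(base + extra))
        t1 = classify_tubes(g1, classify_nodes(g1))
        t2 = classify_tubes(g2, classify_nodes(g2))
        assert t2.count("isolated") >= t1.count("isolated")
        assert len(g2.components) >= len(g1.components)

    @pytest.mark.parametrize("seed", range(12))
    def test_classes_match_rule_by_rule_oracle(self, seed):
        """Exhaustive re-evaluation of the taxonomy rules on small graphs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        coords = rng.choice(100, size=(n, 2), replace=False)
        vertices = {i: tuple(coords[i]) for i in range(n)}
        edges = []
        for _ in range(int(rng.integers(n - 1, 2 * n))):
            u, v = rng.integers(0, n, size=2)
            if u != v and (u, v) not in edges and (v, u) not in edges:
                edges.append((int(u), int(v)))
        g = make_graph(vertices, edges)
        nodes = classify_nodes(g, fusion_radius_px=0.0)
        tubes = classify_tubes(g, nodes)
        # oracle: direct rule evaluation on the incidence sets
        incident = {v: set() for v in vertices}
        for eid, (u, v) in enumerate(edges):
            incident[u].add(eid)
            incident[v].add(eid)
        for v in vertices:
            want = "junction" if len(incident[v]) >= 2 else "extremity"
            if incident[v]:
                assert nodes.classes[v] == want
        for eid, (u, v) in enumerate(edges):
            sides = sum(len(incident[w]) >= 2 for w in (u, v))
            want = {2: "segment", 1: "twig", 0: "isolated"}[sides]
            assert tubes.classes[eid] == want
            if want == "segment":
                flanked = all(
                    any(sum(len(incident[w]) >= 2 for w in edges[o]) == 2
                        for o in incident[x] if o != eid)
                    for x in (u, v))
                assert tubes.master_segment[eid] == flanked
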