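"""Morphometry: the 101-feature catalog and its constituent blocks."""

import math

import numpy as np
import pytest

from angiomorph.features import (branch_angle_features, extract_feature_vector,
                                 fractal_dimension, glcm_texture,
                                 graph_topology_features, load_catalog,
                                 voronoi_features)
from angiomorph.network import (IntensityImage, NetworkElements, classify_nodes,
                                classify_tubes, extract_network)
from angiomorph.simulate import NetworkDesign, simulate_network_image

from conftest import make_graph, skeleton_from_segments


def elements_from_graph(g, thickness=None):
    nodes = classify_nodes(g)
    tubes = classify_tubes(g, nodes)
    return NetworkElements(graph=g, nodes=nodes, tubes=tubes, meshes=[],
                           thickness=thickness or {}, n_meshes_prefilter=0)


class TestCatalog:
    def test_exactly_101_unique_names(self):
        cat = load_catalog()
        assert len(cat) == 101
        assert len(set(cat.names)) == 101

    def test_category_partition(self):
        cat = load_catalog()
        cats = [f["category"] for f in cat.features]
        assert set(cats) == {"tube_formation", "tube_morphology", "node", "mesh",
                             "connectivity", "symmetry", "topology", "complexity",
                             "texture"}


class TestElementStatistics:
    def test_three_tube_arithmetic(self):
        from angiomorph.features import element_statistics

        g = make_graph({0: (10, 10), 1: (10, 20), 2: (40, 10), 3: (40, 40),
                        4: (80, 10), 5: (80, 40)},
                       [(0, 1, 10.0), (2, 3, 20.0), (4, 5, 30.0)])
        stats = element_statistics(elements_from_graph(g), image_area_px2=1e4)
        assert stats["n_tubes"] == 3
        assert stats["total_tube_length"] == pytest.approx(60.0)
        assert stats["mean_tube_length"] == pytest.approx(20.0)
        assert stats["sd_tube_length"] == pytest.approx(10.0)   # sample SD

    def test_no_meshes_yields_zero_counts_missing_means(self):
        from angiomorph.features import element_statistics

        g = make_graph({0: (10, 10), 1: (10, 60)}, [(0, 1)])
        stats = element_statistics(elements_from_graph(g), 1e4)
        assert stats["n_meshes"] == 0
        assert stats["total_mesh_area"] == 0.0
        assert math.isnan(stats["mean_mesh_area"])

    def test_single_mesh_has_missing_sd(self):
        from angiomorph.features import element_statistics
        from angiomorph.network import Mesh

        g = make_graph({0: (10, 10), 1: (10, 60)}, [(0, 1)])
        el = elements_from_graph(g)
        el.meshes = [Mesh(boundary=np.array([[0, 0], [0, 10], [10, 10]]),
                          area=100.0, perimeter=40.0)]
        stats = element_statistics(el, 1e4)
        assert stats["total_mesh_area"] == pytest.approx(100.0)
        assert stats["mean_mesh_area"] == pytest.approx(100.0)
        assert math.isnan(stats["sd_mesh_area"])


class TestConnectivity:
    def test_connected_network(self):
        from angiomorph.features import connectivity_features

        g = make_graph({0: (10, 10), 1: (10, 60), 2: (40, 40)},
                       [(0, 1), (1, 2), (0, 2)])
        feats = connectivity_features(elements_from_graph(g))
        assert feats["n_components"] == 1
        assert feats["largest_component_length_fraction"] == pytest.approx(1.0)

    def test_triangle_plus_isolated_line(self):
        from angiomorph.features import connectivity_features

        g = make_graph({0: (10, 10), 1: (10, 60), 2: (40, 40),
                        3: (90, 10), 4: (90, 60)},
                       [(0, 1), (1, 2), (0, 2), (3, 4)])
        feats = connectivity_features(elements_from_graph(g))
        assert feats["n_components"] == 2
        assert feats["n_isolated_tubes"] == 1

    def test_empty_graph(self):
        from angiomorph.features import connectivity_features

        g = make_graph({}, [])
        feats = connectivity_features(elements_from_graph(g))
        assert feats["n_components"] == 0
        assert feats["n_isolated_tubes"] == 0


class TestBranchAngles:
    def _angles(self, segments):
        from angiomorph.network import skeleton_to_graph

        g = skeleton_to_graph(skeleton_from_segments(segments, shape=(160, 160)))
        return branch_angle_features(elements_from_graph(g), tangent_window_px=12)

    def test_symmetric_y(self):
        c = (80, 80)
        arms = [((80, 20), c),                       # 180 deg
                ((28, 110), c),                      # ~ 60 deg
                ((132, 110), c)]                     # ~ -60 deg
        f = self._angles(arms)
        assert f["mean_largest_angle_3way"] == pytest.approx(120, abs=5)
        assert f["mean_smallest_angle_3way"] == pytest.approx(120, abs=5)

    def test_t_junction(self):
        c = (80, 80)
        arms = [((80, 20), c), ((80, 140), c), ((20, 80), c)]
        f = self._angles(arms)
        assert f["mean_largest_angle_3way"] == pytest.approx(180, abs=5)
        assert f["mean_smallest_angle_3way"] == pytest.approx(90, abs=5)

    def test_angles_sum_to_360(self):
        c = (80, 80)
        arms = [((80, 20), c), ((30, 130), c), ((140, 100), c)]
        f = self._angles(arms)
        total = (f["mean_largest_angle_3way"] + f["mean_smallest_angle_3way"]
                 + f["mean_middle_angle_3way"])
        assert total == pytest.approx(360.0, abs=1e-9)

    def test_no_three_way_nodes_is_missing(self):
        from angiomorph.network import skeleton_to_graph

        g = skeleton_to_graph(skeleton_from_segments([((30, 10), (30, 90))]))
        f = branch_angle_features(elements_from_graph(g))
        assert math.isnan(f["mean_largest_angle_3way"])


class TestGraphTopology:
    def test_path_graph_mean_shortest_path(self):
        g = make_graph({0: (0, 0), 1: (0, 10), 2: (0, 20)},
                       [(0, 1, 1.0), (1, 2, 1.0)])
        f = graph_topology_features(g)
        assert f["mean_shortest_path_length"] == pytest.approx(4 / 3)

    def test_triangle_mst_drops_heaviest(self):
        g = make_graph({0: (0, 0), 1: (0, 10), 2: (10, 5)},
                       [(0, 1, 1.0), (1, 2, 2.0), (0, 2, 3.0)])
        f = graph_topology_features(g)
        assert f["total_mst_weight"] == pytest.approx(3.0)

    def test_star_closeness(self):
        g = make_graph({0: (50, 50), 1: (10, 50), 2: (90, 50), 3: (50, 90)},
                       [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        f = graph_topology_features(g)
        # centre 3/(1+1+1) = 1.0, leaves 3/(1+2+2) = 0.6
        assert f["mean_closeness"] == pytest.approx((1.0 + 3 * 0.6) / 4)

    def test_disconnected_graph_stays_finite(self):
        g = make_graph({0: (0, 0), 1: (0, 10), 2: (50, 0), 3: (50, 10)},
                       [(0, 1, 1.0), (2, 3, 2.0)])
        f = graph_topology_features(g)
        for v in f.values():
            assert v is None or not math.isinf(v)
        assert f["total_mst_weight"] == pytest.approx(3.0)


class TestFractal:
    def test_straight_line_is_one_dimensional(self):
        m = np.zeros((512, 512), bool)
        m[256, :] = True
        d, r2 = fractal_dimension(m)
        assert d == pytest.approx(1.0, abs=0.1)

    def test_filled_square_is_two_dimensional(self):
        m = np.ones((512, 512), bool)
        d, _ = fractal_dimension(m)
        assert d == pytest.approx(2.0, abs=0.1)

    def test_sierpinski_triangle(self):
        i, j = np.meshgrid(np.arange(512), np.arange(512), indexing="ij")
        m = (i & j) == 0          # depth-9 Sierpinski pattern
        d, _ = fractal_dimension(m)
        assert d == pytest.approx(math.log(3) / math.log(2), abs=0.05)

    def test_too_few_scales_rejected(self):
        m = np.ones((16, 16), bool)
        with pytest.raises(ValueError):
            fractal_dimension(m)

    def test_correlates_with_total_tube_length(self):
        ds, lengths = [], []
        for seed in range(50):
            n = 8 + (seed % 5) * 8
            gt = simulate_network_image(
                NetworkDesign(n_seeds=n, mesh_fraction=0.4), seed=seed)
            el = extract_network(gt.image)
            skel = np.zeros(gt.image.pixels.shape, bool)
            for e in el.graph.edges.values():
                skel[e.path[:, 0], e.path[:, 1]] = True
            ds.append(fractal_dimension(skel)[0])
            lengths.append(sum(e.length for e in el.graph.edges.values()))
        r = np.corrcoef(ds, lengths)[0, 1]
        assert r > 0.5

    def test_monotone_from_tree_to_dense_mesh(self):
        ds = []
        for n, frac in [(8, 0.0), (20, 0.5), (45, 1.0)]:
            gt = simulate_network_image(
                NetworkDesign(n_seeds=n, mesh_fraction=frac,
                              min_separation_px=40.0), seed=11)
            _, skel = __import__("angiomorph").segment_and_skeletonize(gt.image)
            ds.append(fractal_dimension(skel)[0])
        assert ds[0] <= ds[1] + 0.05 <= ds[2] + 0.10


class TestVoronoi:
    def test_four_quadrant_seeds(self):
        f = voronoi_features(np.array([[25, 25], [25, 75], [75, 25], [75, 75]]),
                             (100, 100))
        assert f["n_voronoi_polygons"] == 4
        assert f["mean_voronoi_area"] == pytest.approx(2500.0)
        assert f["sd_voronoi_area"] == pytest.approx(0.0, abs=1e-9)

    def test_single_seed_owns_the_frame(self):
        f = voronoi_features(np.array([[30, 60]]), (100, 100))
        assert f["n_voronoi_polygons"] == 1
        assert f["mean_voronoi_area"] == pytest.approx(1e4)

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_conservation(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(int(rng.integers(2, 40)), 2))
        f = voronoi_features(pts, (100, 100))
        assert f["_voronoi_total_area"] == pytest.approx(1e4, rel=1e-6)

    def test_no_seeds_is_missing(self):
        f = voronoi_features(np.empty((0, 2)), (100, 100))
        assert f["n_voronoi_polygons"] == 0
        assert math.isnan(f["mean_voronoi_area"])


class TestGLCM:
    def test_constant_image(self):
        f = glcm_texture(IntensityImage(np.full((64, 64), 9.0)))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_homogeneity"] == 1.0
        assert f["glcm_entropy"] == pytest.approx(0.0)
        assert math.isnan(f["glcm_correlation"])

    def test_checkerboard_single_offset(self):
        i, j = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img = IntensityImage(((i + j) % 2).astype(float))
        f = glcm_texture(img, levels=2, offsets=((0, 1),))
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)

    def test_energy_bounded(self, extracted_net):
        img, _ = extracted_net
        f = glcm_texture(img)
        assert 0 < f["glcm_energy"] <= 1
        assert f["glcm_contrast"] >= 0


class TestFeatureVector:
    def test_has_exactly_101_values(self, extracted_net):
        img, el = extracted_net
        fv = extract_feature_vector(img, el)
        assert len(fv.values) == 101

    def test_deterministic(self, extracted_net):
        img, el = extracted_net
        a = extract_feature_vector(img, el)
        b = extract_feature_vector(img, el)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_empty_image_gives_zero_counts(self):
        img = IntensityImage(np.zeros((128, 128)))
        el = extract_network(img)
        fv = extract_feature_vector(img, el)
        d = fv.as_dict(load_catalog())
        assert d["n_tubes"] == 0
        assert d["total_tube_length"] == 0
        assert math.isnan(d["mean_tube_length"])

    def test_scale_equivariance(self):
        """Doubling tube lengths doubles totals and MST, keeps counts."""
        from angiomorph.features import element_statistics, graph_topology_features

        v1 = {0: (10, 10), 1: (10, 40), 2: (40, 25), 3: (70, 25)}
        e = [(0, 1), (1, 2), (0, 2), (2, 3)]
        g1 = make_graph(v1, e)
        g2 = make_graph({k: (2 * r, 2 * c) for k, (r, c) in v1.items()}, e)
        s1 = element_statistics(elements_from_graph(g1), 1e4)
        s2 = element_statistics(elements_from_graph(g2), 1e4)
        assert s2["total_tube_length"] == pytest.approx(2 * s1["total_tube_length"])
        assert s2["mean_tube_length"] == pytest.approx(2 * s1["mean_tube_length"])
        assert s2["n_tubes"] == s1["n_tubes"]
        t1 = graph_topology_features(g1)
        t2 = graph_topology_features(g2)
        assert t2["total_mst_weight"] == pytest.approx(2 * t1["total_mst_weight"])
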