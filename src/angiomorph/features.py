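"""Morphometry: the named 101-feature phenotypic profile of one well.

The feature catalog (``data/feature_catalog.json``) is the versioned source
of truth: 101 named descriptors across nine categories — tube formation,
tube morphology, nodes, meshes, connectivity, symmetry (SDs of element
measurements, quantifying spatial homogeneity), graph topology (centrality,
shortest paths, minimum spanning tree), complexity (box-counting fractal
dimension and Voronoi tessellation of branch points) and image texture
(grey-level co-occurrence statistics).

A feature is *missing* (NaN) only when its defining element set is empty,
e.g. mean mesh area with no meshes, or sample SDs with fewer than two
elements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi

from .network import IntensityImage, NetworkElements, SkeletonGraph

__all__ = [
    "FeatureCatalog",
    "FeatureVector",
    "load_catalog",
    "element_statistics",
    "connectivity_features",
    "branch_angle_features",
    "graph_topology_features",
    "fractal_dimension",
    "voronoi_features",
    "glcm_texture",
    "extract_feature_vector",
]

MISSING = float("nan")


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, versioned list of the 101 feature descriptors."""

    version: str
    features: tuple[dict, ...]

    def __post_init__(self):
        names = [f["name"] for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        if len(names) != 101:
            raise ValueError(f"catalog must contain exactly 101 features, got {len(names)}")

    @property
    def names(self) -> list[str]:
        return [f["name"] for f in self.features]

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class FeatureVector:
    """Values of one well in catalog order; NaN encodes missing."""

    well_id: str
    values: np.ndarray
    catalog_version: str

    def as_dict(self, catalog: FeatureCatalog) -> dict[str, float]:
        return dict(zip(catalog.names, self.values.tolist()))


def load_catalog() -> FeatureCatalog:
    """Load the packaged feature catalog."""
    text = resources.files("angiomorph").joinpath("data/feature_catalog.json").read_text()
    raw = json.loads(text)
    return FeatureCatalog(version=raw["version"], features=tuple(raw["features"]))


def _sd(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if len(x) >= 2 else MISSING


def _mean(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.mean(x)) if len(x) else MISSING


# ---------------------------------------------------------------------------
# element statistics (tube / node / mesh blocks, incl. symmetry SDs)
# ---------------------------------------------------------------------------

def element_statistics(elements: NetworkElements, image_area_px2: float) -> dict[str, float]:
    """Counts, totals, means and SDs of the classified elements.

    Empty classes yield count 0 and total 0 but missing mean/SD, so a well
    without meshes has ``n_meshes = 0`` and ``mean_mesh_area = NaN``.
    """
    g = elements.graph
    lengths = {eid: e.length for eid, e in g.edges.items()}
    cls = elements.tubes.classes
    by = {c: [lengths[eid] for eid, tc in cls.items() if tc == c]
          for c in ("segment", "twig", "isolated")}
    master_len = [lengths[eid] for eid, m in elements.tubes.master_segment.items() if m]
    all_len = list(lengths.values())
    thick = [elements.thickness.get(eid, MISSING) for eid in g.edges]
    thick = [t for t in thick if not math.isnan(t)]
    seg_th = [elements.thickness[eid] for eid, tc in cls.items()
              if tc == "segment" and eid in elements.thickness]
    twig_th = [elements.thickness[eid] for eid, tc in cls.items()
               if tc == "twig" and eid in elements.thickness]

    tort, chord = [], []
    for e in g.edges.values():
        c = float(np.hypot(*(e.path[-1].astype(float) - e.path[0].astype(float))))
        chord.append(c)
        if c > 0:
            tort.append(e.length / c)
    lt_ratio = [lengths[eid] / elements.thickness[eid]
                for eid in g.edges if eid in elements.thickness and elements.thickness[eid] > 0]

    nodes = elements.nodes
    jdeg = [nodes.degrees[v] for v, c in nodes.classes.items() if c == "junction"]
    degc = nodes.junction_degree_counts()
    n_tubes = len(lengths)
    n_nodes = len(nodes.classes)
    total_len = float(sum(all_len))

    areas = [m.area for m in elements.meshes]
    perims = [m.perimeter for m in elements.meshes]
    circ = [4 * math.pi * m.area / m.perimeter**2 for m in elements.meshes if m.perimeter > 0]
    mj_sizes = [len(m["members"]) for m in nodes.master_junctions]

    out = {
        # tube formation
        "n_tubes": n_tubes,
        "total_tube_length": total_len,
        "n_segments": len(by["segment"]),
        "total_segment_length": float(sum(by["segment"])),
        "n_master_segments": elements.tubes.n_master_segments,
        "total_master_segment_length": float(sum(master_len)),
        "n_twigs": len(by["twig"]),
        "total_twig_length": float(sum(by["twig"])),
        "total_isolated_tube_length": float(sum(by["isolated"])),
        "tube_density": total_len / image_area_px2,
        "segment_fraction": len(by["segment"]) / n_tubes if n_tubes else MISSING,
        "twig_fraction": len(by["twig"]) / n_tubes if n_tubes else MISSING,
        # tube morphology
        "mean_tube_length": _mean(all_len),
        "median_tube_length": float(np.median(all_len)) if all_len else MISSING,
        "min_tube_length": float(min(all_len)) if all_len else MISSING,
        "max_tube_length": float(max(all_len)) if all_len else MISSING,
        "mean_segment_length": _mean(by["segment"]),
        "mean_master_segment_length": _mean(master_len),
        "mean_twig_length": _mean(by["twig"]),
        "mean_isolated_tube_length": _mean(by["isolated"]),
        "mean_tube_thickness": _mean(thick),
        "median_tube_thickness": float(np.median(thick)) if thick else MISSING,
        "min_tube_thickness": float(min(thick)) if thick else MISSING,
        "max_tube_thickness": float(max(thick)) if thick else MISSING,
        "mean_segment_thickness": _mean(seg_th),
        "mean_twig_thickness": _mean(twig_th),
        "mean_tube_tortuosity": _mean(tort),
        "max_tube_tortuosity": float(max(tort)) if tort else MISSING,
        "mean_length_thickness_ratio": _mean(lt_ratio),
        "mean_tube_chord_length": _mean(chord),
        # node
        "n_nodes": n_nodes,
        "n_junctions": len(jdeg),
        "n_extremities": nodes.count("extremity"),
        "n_master_junctions": len(nodes.master_junctions),
        "n_2way_junctions": degc["2way"],
        "n_3way_junctions": degc["3way"],
        "n_4way_plus_junctions": degc["4way_plus"],
        "mean_junction_degree": _mean(jdeg),
        "max_junction_degree": float(max(jdeg)) if jdeg else MISSING,
        "junctions_per_tube": len(jdeg) / n_tubes if n_tubes else MISSING,
        "extremity_fraction": nodes.count("extremity") / n_nodes if n_nodes else MISSING,
        "node_density": n_nodes / image_area_px2,
        "mean_junctions_per_master_junction": _mean(mj_sizes),
        # mesh
        "n_meshes": len(areas),
        "total_mesh_area": float(sum(areas)),
        "mean_mesh_area": _mean(areas),
        "median_mesh_area": float(np.median(areas)) if areas else MISSING,
        "min_mesh_area": float(min(areas)) if areas else MISSING,
        "max_mesh_area": float(max(areas)) if areas else MISSING,
        "mesh_area_fraction": float(sum(areas)) / image_area_px2,
        "mean_mesh_perimeter": _mean(perims),
        "mean_mesh_circularity": _mean(circ),
        "meshes_per_tube": len(areas) / n_tubes if n_tubes else MISSING,
        # symmetry (SD block)
        "sd_tube_length": _sd(all_len),
        "sd_segment_length": _sd(by["segment"]),
        "sd_twig_length": _sd(by["twig"]),
        "sd_isolated_tube_length": _sd(by["isolated"]),
        "sd_tube_thickness": _sd(thick),
        "sd_tube_tortuosity": _sd(tort),
        "sd_mesh_area": _sd(areas),
        "sd_mesh_perimeter": _sd(perims),
        "sd_junction_degree": _sd(jdeg),
    }
    return out


def connectivity_features(elements: NetworkElements) -> dict[str, float]:
    """Connected-component structure of the network."""
    g = elements.graph
    comp_of = {}
    for ci, comp in enumerate(g.components):
        for v in comp:
            comp_of[v] = ci
    comp_len = [0.0] * len(g.components)
    comp_ntubes = [0] * len(g.components)
    for e in g.edges.values():
        ci = comp_of[e.u]
        comp_len[ci] += e.length
        comp_ntubes[ci] += 1
    total = float(sum(comp_len))
    iso_len = sum(e.length for eid, e in g.edges.items()
                  if elements.tubes.classes[eid] == "isolated")
    n_comp = len(g.components)
    return {
        "n_components": n_comp,
        "n_isolated_tubes": elements.tubes.count("isolated"),
        "largest_component_length_fraction": (max(comp_len) / total) if total > 0 else MISSING,
        "largest_component_tube_count": float(max(comp_ntubes)) if comp_ntubes else 0.0,
        "mean_component_tube_count": _mean(comp_ntubes) if n_comp else 0.0,
        "mean_component_length": _mean(comp_len) if n_comp else 0.0,
        "isolated_tube_length_fraction": (iso_len / total) if total > 0 else MISSING,
        "cyclomatic_number": g.cycle_rank() if n_comp else 0,
        "sd_component_length": _sd(comp_len),
    }


# ---------------------------------------------------------------------------
# branch angles at 3-way junctions
# ---------------------------------------------------------------------------

def branch_angle_features(elements: NetworkElements, tangent_window_px: int = 5) -> dict[str, float]:
    """Inter-tube angles at 3-way junctions.

    Tube directions are tangents estimated from the first
    ``tangent_window_px`` path pixels leaving the node; the three gaps
    between sorted directions sum to 360 degrees by construction.
    """
    g = elements.graph
    nodes = elements.nodes
    inc = g.incident()
    largest, smallest, middle = [], [], []
    for v, c in nodes.classes.items():
        if c != "junction" or nodes.degrees[v] != 3:
            continue
        eids = inc[v]
        if any(g.edges[e].u == g.edges[e].v for e in eids):
            continue  # self-loop geometry is not a 3-way branch
        angs = []
        for eid in eids:
            e = g.edges[eid]
            end = 0 if e.u == v else 1
            path = e.path if end == 0 else e.path[::-1]
            k = min(tangent_window_px, len(path) - 1)
            origin = np.array(g.vertices[v])
            d = path[k].astype(float) - origin
            angs.append(math.degrees(math.atan2(d[0], d[1])) % 360.0)
        angs.sort()
        gaps = [angs[1] - angs[0], angs[2] - angs[1], 360.0 - (angs[2] - angs[0])]
        gaps.sort()
        smallest.append(gaps[0])
        middle.append(gaps[1])
        largest.append(gaps[2])
    return {
        "mean_largest_angle_3way": _mean(largest),
        "mean_smallest_angle_3way": _mean(smallest),
        "mean_middle_angle_3way": _mean(middle),
        "sd_largest_angle_3way": _sd(largest),
        "sd_smallest_angle_3way": _sd(smallest),
    }


# ---------------------------------------------------------------------------
# graph topology
# ---------------------------------------------------------------------------

def _as_nx(graph: SkeletonGraph) -> nx.MultiGraph:
    G = nx.MultiGraph()
    G.add_nodes_from(graph.vertices)
    for eid, e in graph.edges.items():
        G.add_edge(e.u, e.v, key=eid, weight=e.length)
    return G


def graph_topology_features(graph: SkeletonGraph) -> dict[str, float]:
    """Centrality, shortest-path and spanning-tree statistics.

    Distances are tube lengths.  Disconnected graphs are handled per
    component (closeness uses reachable count / sum of distances within the
    component; mean path length averages over connected pairs only), so all
    values stay finite.
    """
    out = {k: MISSING for k in (
        "mean_shortest_path_length", "graph_diameter", "mean_closeness",
        "sd_closeness", "mean_betweenness", "sd_betweenness", "max_betweenness",
        "total_mst_weight", "mst_weight_fraction", "network_efficiency",
        "mean_eccentricity", "mean_degree_centrality")}
    if not graph.edges:
        return out
    G = _as_nx(graph)

    dists, inv, ecc = [], [], []
    for v in G.nodes:
        sp = nx.single_source_dijkstra_path_length(G, v, weight="weight")
        reach = [d for u, d in sp.items() if u != v]
        if reach:
            dists.extend(reach)
            inv.extend(1.0 / d for d in reach if d > 0)
            ecc.append(max(reach))
        else:
            ecc.append(0.0)
    # each unordered pair counted twice above; means are unaffected
    out["mean_shortest_path_length"] = _mean(dists) if dists else MISSING
    out["graph_diameter"] = float(max(dists)) if dists else MISSING
    out["network_efficiency"] = _mean(inv) if inv else MISSING
    out["mean_eccentricity"] = _mean(ecc)

    close = nx.closeness_centrality(G, distance="weight", wf_improved=False)
    cvals = list(close.values())
    out["mean_closeness"] = _mean(cvals)
    out["sd_closeness"] = _sd(cvals)

    btw = nx.betweenness_centrality(G, weight="weight", normalized=True)
    bvals = list(btw.values())
    out["mean_betweenness"] = _mean(bvals)
    out["sd_betweenness"] = _sd(bvals)
    out["max_betweenness"] = float(max(bvals)) if bvals else MISSING

    mst_w = sum(e[-1]["weight"] for e in
                nx.minimum_spanning_edges(G, weight="weight", data=True))
    total = sum(e.length for e in graph.edges.values())
    out["total_mst_weight"] = float(mst_w)
    out["mst_weight_fraction"] = float(mst_w / total) if total > 0 else MISSING

    n = G.number_of_nodes()
    if n > 1:
        degs = [G.degree(v) for v in G.nodes]
        out["mean_degree_centrality"] = float(np.mean(degs) / (n - 1))
    return out


# ---------------------------------------------------------------------------
# fractal dimension
# ---------------------------------------------------------------------------

def fractal_dimension(mask: np.ndarray, box_sizes: list[int] | None = None) -> tuple[float, float]:
    """Box-counting dimension of a binary set.

    Counts occupied boxes N(s) for s in {2, 4, 8, ..., min(shape)/4} and
    fits log N(s) against log(1/s); returns ``(D, R^2)``.  Requires at
    least 3 scales and at least 2 occupied boxes at the smallest scale.
    """
    mask = np.asarray(mask, dtype=bool)
    if box_sizes is None:
        smax = min(mask.shape) // 4
        box_sizes, s = [], 2
        while s <= smax:
            box_sizes.append(s)
            s *= 2
    if len(box_sizes) < 3:
        raise ValueError("need at least 3 box scales")
    counts = []
    for s in box_sizes:
        nr = -(-mask.shape[0] // s)
        nc = -(-mask.shape[1] // s)
        padded = np.zeros((nr * s, nc * s), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        occ = padded.reshape(nr, s, nc, s).any(axis=(1, 3)).sum()
        counts.append(occ)
    if counts[0] < 2:
        raise ValueError("fewer than 2 occupied boxes at the smallest scale")
    x = np.log(1.0 / np.asarray(box_sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


# ---------------------------------------------------------------------------
# Voronoi tessellation of branch points
# ---------------------------------------------------------------------------

def voronoi_features(seeds: np.ndarray, frame_shape: tuple[int, int]) -> dict[str, float]:
    """Areas of Voronoi cells of the branch points, clipped to the frame.

    The frame rectangle is [0, H] x [0, W].  Exact clipping is obtained by
    mirroring every seed across the four frame edges: each original seed's
    cell is then finite and the cells tile the rectangle exactly, so the
    areas sum to the frame area to machine precision.
    """
    h, w = float(frame_shape[0]), float(frame_shape[1])
    frame_area = h * w
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.size == 0:
        return {"n_voronoi_polygons": 0, "mean_voronoi_area": MISSING,
                "sd_voronoi_area": MISSING, "voronoi_area_cv": MISSING}
    # a seed exactly on a frame edge would coincide with its mirror image
    seeds = np.column_stack([np.clip(seeds[:, 0], 0.25, h - 0.25),
                             np.clip(seeds[:, 1], 0.25, w - 0.25)])
    seeds = np.unique(seeds, axis=0)
    n = len(seeds)
    if n == 1:
        return {"n_voronoi_polygons": 1, "mean_voronoi_area": frame_area,
                "sd_voronoi_area": MISSING, "voronoi_area_cv": MISSING}
    r, c = seeds[:, 0], seeds[:, 1]
    mirrored = np.vstack([
        seeds,
        np.column_stack([-r, c]),            # across row = 0
        np.column_stack([2 * h - r, c]),     # across row = H
        np.column_stack([r, -c]),            # across col = 0
        np.column_stack([r, 2 * w - c]),     # across col = W
    ])
    vor = Voronoi(mirrored)
    areas = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = vor.vertices[region]
        x, y = poly[:, 1], poly[:, 0]
        areas.append(abs(0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))))
    areas = np.array(areas)
    mean = float(areas.mean())
    sd = _sd(areas)
    return {
        "n_voronoi_polygons": n,
        "mean_voronoi_area": mean,
        "sd_voronoi_area": sd,
        "voronoi_area_cv": sd / mean if (mean > 0 and not math.isnan(sd)) else MISSING,
        "_voronoi_total_area": float(areas.sum()),   # for conservation checks
        "_voronoi_frame_area": frame_area,
    }


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_texture(image: IntensityImage, levels: int = 64,
                 offsets: tuple[tuple[int, int], ...] = _GLCM_OFFSETS) -> dict[str, float]:
    """Grey-level co-occurrence texture of the intensity field.

    The image is quantised to ``levels`` grey levels; the symmetric,
    normalised co-occurrence matrix is averaged over the unit offsets
    (default (0,1), (1,0), (1,1), (1,-1)).  Statistics: contrast,
    correlation (missing for a constant image), energy (angular second
    moment), homogeneity, and Shannon entropy in bits, plus the raw
    intensity mean and SD.
    """
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        q = np.floor((px - lo) / (hi - lo) * levels).astype(int)
        q[q == levels] = levels - 1
    else:
        q = np.zeros(px.shape, dtype=int)
    mats = []
    for dr, dc in offsets:
        # pair each pixel with its (dr, dc) neighbour
        r0, r1 = max(dr, 0), q.shape[0] + min(dr, 0)
        c0, c1 = max(dc, 0), q.shape[1] + min(dc, 0)
        src = q[r0 - dr: r1 - dr, c0 - dc: c1 - dc].ravel()
        dst = q[r0:r1, c0:c1].ravel()
        M = np.zeros((levels, levels))
        np.add.at(M, (src, dst), 1.0)
        M = M + M.T                      # symmetric
        M /= M.sum()
        mats.append(M)
    P = np.mean(mats, axis=0)
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float(np.sum(P * (i - j) ** 2))
    energy = float(np.sum(P ** 2))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    pi_ = P.sum(axis=1)
    mu_i = float(np.sum(np.arange(levels) * pi_))
    var_i = float(np.sum((np.arange(levels) - mu_i) ** 2 * pi_))
    if var_i > 0:
        corr = float(np.sum(P * (i - mu_i) * (j - mu_i)) / var_i)
    else:
        corr = MISSING
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
        "glcm_entropy": entropy,
        "intensity_mean": float(px.mean()),
        "intensity_sd": float(px.std(ddof=1)),
    }


# ---------------------------------------------------------------------------
# assembling the vector
# ---------------------------------------------------------------------------

def extract_feature_vector(
    image: IntensityImage,
    elements: NetworkElements,
    catalog: FeatureCatalog | None = None,
    *,
    well_id: str = "well",
    tangent_window_px: int = 5,
    glcm_levels: int = 64,
) -> FeatureVector:
    """Compute the full 101-feature profile of one well.

    Deterministic for a fixed input and configuration; raises if any
    catalog name is not produced by the feature blocks.
    """
    if catalog is None:
        catalog = load_catalog()
    shape = image.pixels.shape
    area = float(shape[0] * shape[1])
    blocks: dict[str, float] = {}
    blocks.update(element_statistics(elements, area))
    blocks.update(connectivity_features(elements))
    blocks.update(branch_angle_features(elements, tangent_window_px))
    blocks.update(graph_topology_features(elements.graph))

    skel = np.zeros(shape, dtype=bool)
    for e in elements.graph.edges.values():
        skel[e.path[:, 0], e.path[:, 1]] = True
    try:
        d, r2 = fractal_dimension(skel)
    except ValueError:
        d, r2 = MISSING, MISSING
    blocks["fractal_dimension"] = d
    blocks["fractal_fit_r2"] = r2

    junctions = np.array([elements.graph.vertices[v]
                          for v, c in elements.nodes.classes.items() if c == "junction"])
    blocks.update(voronoi_features(junctions, shape))
    blocks.update(glcm_texture(image, levels=glcm_levels))

    missing_names = [n for n in catalog.names if n not in blocks]
    if missing_names:
        raise ValueError(f"feature blocks did not produce: {missing_names}")
    values = np.array([blocks[n] for n in catalog.names], dtype=float)
    return FeatureVector(well_id=well_id, values=values, catalog_version=catalog.version)
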