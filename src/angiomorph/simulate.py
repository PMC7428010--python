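"""Ground-truthed synthetic inputs for every analysis stage.

Three generators, each a pure function of (design, seed):

* :func:`simulate_network_image` — a planar tube network with known
  element counts, rendered to an intensity image.  The planted graph is a
  Gabriel proximity graph on well-separated random points (so edges never
  cross); the number of independent cycles — and hence meshes — is
  controlled directly by keeping a fraction of the cycle-closing edges.
  Presets: ``tree`` (no meshes), ``honeycomb`` (hexagonal lattice with an
  exact face count), ``dense_mesh``.
* :func:`simulate_screen` — a plate-based well x feature screen with DMSO
  control wells, plate-specific baselines, and planted phenotypic
  clusters whose effect vectors are expressed in z units (multiples of
  the well-to-well noise SD).
* :func:`simulate_expression` — a genes x samples study with a latent
  angiogenic axis: pro-angiogenic genes load positively, a designated
  anti-angiogenic (glutamate-receptor) set negatively, and high Braak
  stage is drawn with a logistic link on the axis.  Patients fall into
  three planted groups along the axis, mirroring the low/intermediate/
  high-expression patient clusters the analysis should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .features import load_catalog
from .network import IntensityImage, NetworkElements
from .omics import ExpressionStudy
from .screen import PlateLayout

__all__ = [
    "NetworkDesign",
    "NetworkGroundTruth",
    "ScreenDesign",
    "ExpressionDesign",
    "simulate_network_image",
    "simulate_screen",
    "simulate_expression",
    "recovered_counts",
]


# ---------------------------------------------------------------------------
# network images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkDesign:
    """Parameters of a planted tube network.

    ``mesh_fraction`` is the fraction of independent cycles of the
    proximity graph that survive (0 gives a forest); ``min_separation_px``
    keeps branch points apart so the rendered image resolves them.
    """

    n_seeds: int = 30
    mesh_fraction: float = 0.5
    tube_width: int = 5
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (384, 384)
    min_separation_px: float = 45.0
    min_bend_deg: float = 100.0        # no hairpin bends at pass-through points
    tube_intensity: float = 200.0
    margin_px: int = 25
    preset: str | None = None          # None | 'tree' | 'honeycomb' | 'dense_mesh'
    honeycomb_cells: tuple[int, int] = (3, 3)


@dataclass
class NetworkGroundTruth:
    """Planted graph, its expected element counts, and the rendered image.

    Counts are taken on the degree-2-contracted planted graph, because
    image extraction contracts degree-2 points: a chain through such a
    point is one tube.  The counts satisfy the Euler identity
    n_meshes = E - V + C by construction.
    """

    image: IntensityImage
    vertices: np.ndarray               # (n, 2) row/col coordinates
    edges: list[tuple[int, int]]       # planted (pre-contraction) edges
    expected: dict[str, int]

    def check_euler(self) -> bool:
        e = self.expected
        return e["n_meshes"] == e["n_tubes"] - e["n_nodes"] + e["n_components"]


def _sample_points(rng, n, shape, margin, min_sep) -> np.ndarray:
    pts = []
    for _ in range(20000):
        if len(pts) == n:
            break
        p = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    if len(pts) < n:
        raise ValueError("could not place seeds; lower n_seeds or min_separation_px")
    return np.array(pts)


def _gabriel_edges(pts: np.ndarray) -> list[tuple[int, int]]:
    """Gabriel graph: Delaunay edges whose diameter-disk holds no third point."""
    from scipy.spatial import Delaunay

    tri = Delaunay(pts)
    cand = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            cand.add((a, b))
    edges = []
    for a, b in sorted(cand):
        mid = (pts[a] + pts[b]) / 2
        r2 = np.sum((pts[a] - pts[b]) ** 2) / 4
        d2 = np.sum((pts - mid) ** 2, axis=1)
        d2[[a, b]] = np.inf
        if np.all(d2 > r2):
            edges.append((a, b))
    return edges


def _contracted_counts(n_vertices: int, edges: list[tuple[int, int]]) -> dict[str, int]:
    """Element counts after contracting degree-2 vertices (extraction's view)."""
    G = nx.MultiGraph()
    G.add_edges_from(edges)   # isolated planted vertices carry no tube: dropped
    changed = True
    while changed:
        changed = False
        for v in list(G.nodes):
            if v not in G:
                continue
            if G.degree(v) == 2 and G.number_of_edges(v, v) == 0:
                nbrs = [u for _, u, _ in G.edges(v, keys=True)]
                a, b = nbrs[0], nbrs[1]
                G.remove_node(v)
                G.add_edge(a, b)
                changed = True
    n_tubes = G.number_of_edges()
    # degree counts number of incident tubes; a self-loop is one tube
    deg = {v: len(list(G.edges(v))) for v in G.nodes}  # self-loop = one incident tube
    n_junctions = sum(1 for v in G.nodes if deg[v] >= 2)
    n_extremities = sum(1 for v in G.nodes if deg[v] == 1)
    n_components = nx.number_connected_components(G) if G.number_of_nodes() else 0
    n_nodes = G.number_of_nodes()
    return {
        "n_tubes": n_tubes,
        "n_nodes": n_nodes,
        "n_junctions": n_junctions,
        "n_extremities": n_extremities,
        "n_components": n_components,
        "n_meshes": n_tubes - n_nodes + n_components,
    }


def _remove_hairpins(pts: np.ndarray, edges: list[tuple[int, int]],
                     min_bend_deg: float) -> list[tuple[int, int]]:
    """Drop one edge of any degree-2 vertex whose bend is sharper than the floor.

    A pass-through point with a hairpin bend rasterises into a blob the
    skeletonizer cannot resolve as a smooth tube; endothelial tubes do not
    hairpin, so the generator avoids planting them.
    """
    edges = list(edges)
    changed = True
    while changed:
        changed = False
        deg: dict[int, list[tuple[int, int]]] = {}
        for e in edges:
            deg.setdefault(e[0], []).append(e)
            deg.setdefault(e[1], []).append(e)
        for v, inc in deg.items():
            if len(inc) != 2:
                continue
            vecs = []
            for a, b in inc:
                u = b if a == v else a
                d = pts[u] - pts[v]
                vecs.append(d / np.hypot(*d))
            ang = math.degrees(math.acos(float(np.clip(np.dot(vecs[0], vecs[1]), -1, 1))))
            if ang < min_bend_deg:
                # drop the shorter of the two edges
                def elen(e):
                    return float(np.hypot(*(pts[e[0]] - pts[e[1]])))
                edges.remove(min(inc, key=elen))
                changed = True
                break
    return edges


def _honeycomb(design: NetworkDesign) -> tuple[np.ndarray, list[tuple[int, int]]]:
    m, n = design.honeycomb_cells
    G = nx.hexagonal_lattice_graph(m, n)
    pos = nx.get_node_attributes(G, "pos")
    nodes = sorted(G.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    xy = np.array([pos[v] for v in nodes], dtype=float)
    # map lattice coordinates into the image frame with margins
    h, w = design.image_shape
    mg = design.margin_px
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    rows = mg + (xy[:, 1] - lo[1]) / span[1] * (h - 2 * mg)
    cols = mg + (xy[:, 0] - lo[0]) / span[0] * (w - 2 * mg)
    pts = np.column_stack([rows, cols])
    edges = [(idx[a], idx[b]) for a, b in G.edges()]
    return pts, edges


def simulate_network_image(design: NetworkDesign = NetworkDesign(),
                           seed: int = 0) -> NetworkGroundTruth:
    """Render a planted planar tube network with known element counts.

    A spanning forest of the proximity graph is always kept; of the
    remaining cycle-closing edges a ``mesh_fraction`` (rounded) survives,
    so the planted mesh count is exact.  Tubes are drawn as straight
    strokes of ``tube_width`` px at ``tube_intensity`` on a dark
    background, with optional Gaussian noise.
    """
    if design.tube_width >= min(design.image_shape):
        raise ValueError("tube_width must be smaller than the image")
    if design.n_seeds < 3:
        raise ValueError("need at least 3 seeds")
    rng = np.random.default_rng(seed)
    preset = design.preset
    if preset == "honeycomb":
        pts, edges = _honeycomb(design)
    else:
        mesh_fraction = {None: design.mesh_fraction,
                         "tree": 0.0, "dense_mesh": 1.0}[preset]
        pts = _sample_points(rng, design.n_seeds, design.image_shape,
                             design.margin_px, design.min_separation_px)
        all_edges = _gabriel_edges(pts)
        # spanning forest first; then a controlled share of cycle closers
        parent = list(range(len(pts)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        forest, closers = [], []
        for a, b in all_edges:
            ra, rb = find(a), find(b)
            if ra == rb:
                closers.append((a, b))
            else:
                parent[ra] = rb
                forest.append((a, b))
        n_keep = int(round(mesh_fraction * len(closers)))
        keep_idx = rng.choice(len(closers), size=n_keep, replace=False) if n_keep else []
        edges = forest + [closers[i] for i in sorted(keep_idx)]
        edges = _remove_hairpins(pts, edges, design.min_bend_deg)

    expected = _contracted_counts(len(pts), edges)

    img = np.zeros(design.image_shape, dtype=float)
    stroke = np.zeros(design.image_shape, dtype=bool)
    for a, b in edges:
        r0, c0 = np.round(pts[a]).astype(int)
        r1, c1 = np.round(pts[b]).astype(int)
        rr, cc = draw_line(r0, c0, r1, c1)
        stroke[rr, cc] = True
    radius = max(design.tube_width // 2, 0)
    if radius:
        stroke = ndimage.binary_dilation(stroke, structure=disk(radius))
    img[stroke] = design.tube_intensity
    if design.noise_sd > 0:
        img = img + rng.normal(0.0, design.noise_sd, size=img.shape)
        img += rng.normal(0.0, design.noise_sd * 0.1, size=img.shape) * stroke
    img = np.clip(img, 0, None)
    return NetworkGroundTruth(image=IntensityImage(pixels=img),
                              vertices=pts, edges=list(edges), expected=expected)


def recovered_counts(elements: NetworkElements, fusion_radius_px: float | None = None) -> dict[str, int]:
    """Element counts of an extracted network, fusion-aware.

    Rasterisation can split one planted multi-way branch point into two
    nearby junctions joined by a sliver tube; counting each master-junction
    group once (and discounting the within-group sliver tubes) restores
    the planted topology's counts.  ``n_meshes`` is the area-filtered mesh
    count (sliver faces fall below the area floor).
    """
    nodes = elements.nodes
    n_junc = nodes.count("junction")
    n_ext = nodes.count("extremity")
    n_tubes = len(elements.graph.edges)
    in_group: dict[int, int] = {}
    for gi, m in enumerate(nodes.master_junctions):
        for v in m["members"]:
            in_group[v] = gi
        n_junc -= len(m["members"]) - 1
    for e in elements.graph.edges.values():
        if (e.u in in_group and e.v in in_group
                and in_group[e.u] == in_group[e.v] and e.u != e.v):
            n_tubes -= 1
    # a 2-way junction at a tube bend (a pruning artifact) is a degree-2
    # point: the planted counts are degree-2-contracted, so contract here too
    inc = elements.graph.incident()
    for v, cls in nodes.classes.items():
        if (cls == "junction" and v not in in_group and nodes.degrees[v] == 2
                and not any(elements.graph.edges[e].u == elements.graph.edges[e].v
                            for e in inc[v])):
            n_junc -= 1
            n_tubes -= 1
    return {
        "n_tubes": n_tubes,
        "n_junctions": n_junc,
        "n_extremities": n_ext,
        "n_components": len(elements.graph.components),
        "n_meshes": len(elements.meshes),
    }


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenDesign:
    """A plate-based screen with planted phenotypic clusters.

    ``effects`` maps cluster name -> {feature name: effect in z units};
    ``memberships`` maps cluster name -> list of compound ids and must
    partition the non-control compounds.  Effects in z units are scaled by
    ``noise_sd`` into feature units, so a +5 effect lands 5 DMSO-SDs from
    the control mean.
    """

    n_compounds: int = 60
    n_plates: int = 4
    replicates: int = 2
    dmso_per_plate: int = 16
    noise_sd: float = 1.0
    plate_shift_sd: float = 2.0
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    memberships: dict[str, list[str]] = field(default_factory=dict)
    n_features: int | None = None      # default: the full 101-feature catalog

    def compounds(self) -> list[str]:
        return [f"C{i:04d}" for i in range(1, self.n_compounds + 1)]


def default_screen_design(n_clusters: int = 4, effect_z: float = 5.0,
                          n_effect_features: int = 10, **kwargs) -> ScreenDesign:
    """A screen with ``n_clusters`` planted phenotypes on disjoint feature blocks."""
    base = ScreenDesign(**kwargs)
    names = load_catalog().names
    comps = base.compounds()
    per = len(comps) // n_clusters
    memberships, effects = {}, {}
    for ci in range(n_clusters):
        cname = f"pheno{ci + 1}"
        lo = ci * per
        hi = (ci + 1) * per if ci < n_clusters - 1 else len(comps)
        memberships[cname] = comps[lo:hi]
        feats = names[ci * n_effect_features:(ci + 1) * n_effect_features]
        sign = 1.0 if ci % 2 == 0 else -1.0
        effects[cname] = {f: sign * effect_z for f in feats}
    return ScreenDesign(**{**base.__dict__, "effects": effects,
                           "memberships": memberships})


def simulate_screen(design: ScreenDesign, seed: int = 0
                    ) -> tuple[pd.DataFrame, PlateLayout, pd.Series]:
    """Simulate a well x feature screen with DMSO controls.

    Every well draws its feature vector from the plate baseline plus
    Gaussian noise; treated wells add their planted cluster's effect
    vector.  Returns (well matrix, plate layout, planted cluster label per
    compound).  Deterministic in (design, seed).
    """
    rng = np.random.default_rng(seed)
    names = load_catalog().names
    if design.n_features is not None:
        names = names[: design.n_features]
    comps = design.compounds()
    cluster_of: dict[str, str] = {}
    for cname, members in design.memberships.items():
        for c in members:
            if c in cluster_of:
                raise ValueError(f"compound {c} in two clusters")
            cluster_of[c] = cname
    effect_vec = {}
    for cname, eff in design.effects.items():
        v = np.zeros(len(names))
        for f, z in eff.items():
            if not np.isfinite(z):
                raise ValueError("effects must be finite")
            if f in names:
                v[names.index(f)] = z * design.noise_sd
        effect_vec[cname] = v

    plates = [f"plate{p + 1}" for p in range(design.n_plates)]
    baseline = {p: 10.0 + rng.normal(0.0, design.plate_shift_sd, size=len(names))
                for p in plates}
    rows, meta = [], []
    wid = 0
    # compound replicate wells, spread across plates
    for rep in range(design.replicates):
        for i, c in enumerate(comps):
            p = plates[(i + rep) % len(plates)]
            x = baseline[p] + rng.normal(0.0, design.noise_sd, size=len(names))
            x = x + effect_vec.get(cluster_of.get(c, ""), 0.0)
            rows.append(x)
            meta.append({"well": f"W{wid:05d}", "plate": p, "compound": c,
                         "replicate": rep + 1, "is_dmso": False})
            wid += 1
    for p in plates:
        for j in range(design.dmso_per_plate):
            x = baseline[p] + rng.normal(0.0, design.noise_sd, size=len(names))
            rows.append(x)
            meta.append({"well": f"W{wid:05d}", "plate": p, "compound": "DMSO",
                         "replicate": j + 1, "is_dmso": True})
            wid += 1
    layout = pd.DataFrame(meta).set_index("well")
    data = pd.DataFrame(rows, index=layout.index, columns=names)
    planted = pd.Series({c: cluster_of.get(c, "none") for c in comps}, name="planted")
    return data, PlateLayout(layout), planted


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

PRO_ANGIOGENIC = ["TIE1", "ITGB5", "ESAM", "S1PR1", "CDH5", "VWF", "KDR"]
CLUSTER4_TARGETS = ["GRM1", "GRM5", "GRIA1", "GRIA2", "GRIN3A", "GRIK2", "GRM3", "GRIK5"]
CLUSTER5_TARGETS = ["GRIN1", "GRINA"]


@dataclass(frozen=True)
class ExpressionDesign:
    """A study with a latent angiogenic axis and three patient groups.

    Pro-angiogenic genes load ``+loading`` on the axis, the designated
    anti-angiogenic (glutamate receptor) set ``-loading``; high Braak
    stage (5-6) is drawn with probability expit(braak_link * axis).
    Patients belong to three planted groups centred at
    ``group_centres`` on the axis (the high-axis group is the planted
    low-anti-angiogenic-expression subgroup).
    """

    n_patients: int = 301
    regions: tuple[str, ...] = ("BM10", "BM22", "BM36", "BM44")
    loading: float = 0.6
    noise_sd: float = 0.5
    braak_link: float = 2.0
    group_centres: tuple[float, ...] = (-2.0, 0.0, 2.0)
    group_sd: float = 0.25
    region_shift_sd: float = 0.1
    n_null_genes: int = 20
    n_low_genes: int = 5
    baseline_range: tuple[float, float] = (2.0, 6.0)


def simulate_expression(design: ExpressionDesign = ExpressionDesign(),
                        seed: int = 0) -> tuple[ExpressionStudy, pd.Series]:
    """Simulate an expression study; returns (study, planted patient group).

    Each patient contributes one sample per region sharing the patient's
    latent axis value; expression = baseline + loading * axis + noise,
    truncated at zero.  A handful of genes sit below the mean-expression
    cutoff of 1.0 to exercise the filter.
    """
    rng = np.random.default_rng(seed)
    n = design.n_patients
    k = len(design.group_centres)
    groups = rng.integers(0, k, size=n)
    axis = np.array([design.group_centres[g] for g in groups]) \
        + rng.normal(0.0, design.group_sd, size=n)

    genes = PRO_ANGIOGENIC + CLUSTER4_TARGETS + CLUSTER5_TARGETS
    loadings = ([design.loading] * len(PRO_ANGIOGENIC)
                + [-design.loading] * len(CLUSTER4_TARGETS)
                + [design.loading * 0.6] * len(CLUSTER5_TARGETS))
    for i in range(design.n_null_genes):
        genes.append(f"NULL{i + 1:03d}")
        loadings.append(0.0)
    low_genes = [f"LOW{i + 1:03d}" for i in range(design.n_low_genes)]

    baselines = rng.uniform(*design.baseline_range, size=len(genes))
    region_shift = {r: rng.normal(0.0, design.region_shift_sd, size=len(genes))
                    for r in design.regions}

    from scipy.special import expit
    p_high = expit(design.braak_link * axis)
    is_high = rng.random(n) < p_high
    braak = np.where(is_high, rng.integers(5, 7, size=n), rng.integers(1, 5, size=n))

    cols, meta = [], []
    X = []
    for r in design.regions:
        for i in range(n):
            sid = f"{r}_S{i + 1:04d}"
            cols.append(sid)
            meta.append({"sample": sid, "patient": f"PT{i + 1:04d}",
                         "region": r, "braak": int(braak[i])})
            noise = rng.normal(0.0, design.noise_sd, size=len(genes))
            x = baselines + np.array(loadings) * axis[i] + region_shift[r] + noise
            X.append(np.clip(x, 0.0, None))
    expr = pd.DataFrame(np.array(X).T, index=genes, columns=cols)
    for g in low_genes:
        expr.loc[g] = np.clip(rng.normal(0.4, 0.2, size=expr.shape[1]), 0.0, None)
    meta_df = pd.DataFrame(meta).set_index("sample")
    study = ExpressionStudy(
        expression=expr, metadata=meta_df,
        gene_sets={"pro_angiogenic": list(PRO_ANGIOGENIC),
                   "cluster4_targets": list(CLUSTER4_TARGETS),
                   "cluster5_targets": list(CLUSTER5_TARGETS)})
    planted = pd.Series(groups, index=[f"PT{i + 1:04d}" for i in range(n)],
                        name="planted_group")
    return study, planted
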