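"""Network extraction: from a well image to classified vascular elements.

Endothelial cells plated on basement-membrane matrix self-organise into a
capillary-like network.  This module turns a single-channel image of such a
network into

1. a binary mask and a 1-pixel-wide skeleton (``segment_and_skeletonize``),
2. a contracted planar graph whose vertices are branching points / tips and
   whose edges are tubes carrying their ordered pixel paths
   (``skeleton_to_graph``),
3. the element taxonomy used in tube-formation assays
   (``classify_nodes`` / ``classify_tubes`` / ``extract_meshes``):

   * nodes: *junctions* (>= 2 incident tubes), *extremities* (exactly 1),
     and *master junctions* (groups of junctions in close proximity);
   * tubes: *segments* (connected to the network at both ends), *twigs*
     (one end), *isolated tubes* (neither end), and *master segments*
     (segments flanked by other segments at both ends);
   * *meshes*: bounded faces of the planar network.

Coordinates are 0-based ``(row, col)``; pixel connectivity is 8-connected;
lengths are Euclidean polyline lengths in pixels unless a physical pixel
size is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "IntensityImage",
    "SkeletonGraph",
    "Edge",
    "NodeClasses",
    "TubeClasses",
    "Mesh",
    "NetworkElements",
    "segment_and_skeletonize",
    "skeleton_to_graph",
    "classify_nodes",
    "classify_tubes",
    "extract_meshes",
    "measure_thickness",
    "extract_network",
]

# 8-connected neighbour offsets, orthogonal first.
_ORTHO = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityImage:
    """A single-channel well image (e.g. the Phalloidin channel).

    Parameters
    ----------
    pixels : 2-D array of non-negative, finite intensities, at least 64x64.
    pixel_size : micrometres per pixel; 1.0 means "report in pixels".
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 64:
            raise ValueError("image must be 2-D and at least 64x64")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("image intensities must be finite and non-negative")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class Edge:
    """A tube: a maximal skeleton path between two vertices."""

    u: int
    v: int
    path: np.ndarray        # (n, 2) ordered pixel coordinates, endpoints at u and v
    length: float           # Euclidean polyline length, px (>= 1)
    n_pixels: int


@dataclass
class SkeletonGraph:
    """Contracted graph of a 1-px skeleton.

    ``vertices`` maps vertex id to its (row, col) coordinate (centroid of the
    branch-pixel cluster).  ``edges`` maps edge id to :class:`Edge`.
    ``components`` partitions vertex ids into connected components; a
    component may consist of a single vertex carrying a self-loop edge
    (an isolated ring).
    """

    vertices: dict[int, tuple[float, float]]
    edges: dict[int, Edge]
    components: list[set[int]] = field(default_factory=list)

    def incident(self) -> dict[int, list[int]]:
        """Vertex id -> incident edge ids (self-loops listed once)."""
        inc: dict[int, list[int]] = {v: [] for v in self.vertices}
        for eid, e in self.edges.items():
            inc[e.u].append(eid)
            if e.v != e.u:
                inc[e.v].append(eid)
        return inc

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def cycle_rank(self) -> int:
        """Sum of E_c - V_c + 1 over connected components (= planted mesh count)."""
        return len(self.edges) - len(self.vertices) + len(self.components)


@dataclass
class NodeClasses:
    """Per-vertex node classification plus master-junction fusion groups."""

    classes: dict[int, str]                 # vertex id -> 'junction' | 'extremity'
    degrees: dict[int, int]                 # number of incident tubes
    master_junctions: list[dict]            # {'members': [vid...], 'coordinate': (r, c)}

    def count(self, cls: str) -> int:
        return sum(1 for c in self.classes.values() if c == cls)

    def junction_degree_counts(self) -> dict[str, int]:
        """Junction counts by how many tubes meet there (2-way / 3-way / >=4-way)."""
        out = {"2way": 0, "3way": 0, "4way_plus": 0}
        for vid, cls in self.classes.items():
            if cls != "junction":
                continue
            d = self.degrees[vid]
            if d == 2:
                out["2way"] += 1
            elif d == 3:
                out["3way"] += 1
            else:
                out["4way_plus"] += 1
        return out


@dataclass
class TubeClasses:
    """Per-tube classification; ``master_segment`` is a flag on segments."""

    classes: dict[int, str]                 # edge id -> 'segment' | 'twig' | 'isolated'
    master_segment: dict[int, bool]

    def count(self, cls: str) -> int:
        return sum(1 for c in self.classes.values() if c == cls)

    @property
    def n_master_segments(self) -> int:
        return sum(bool(v) for v in self.master_segment.values())


@dataclass(frozen=True)
class Mesh:
    """A bounded face of the planar network."""

    boundary: np.ndarray    # (n, 2) polygon of pixel-centre coordinates
    area: float             # shoelace area, px^2
    perimeter: float


@dataclass
class NetworkElements:
    """Classified tubes, nodes and meshes of one well, with measurements."""

    graph: SkeletonGraph
    nodes: NodeClasses
    tubes: TubeClasses
    meshes: list[Mesh]
    thickness: dict[int, float]             # edge id -> mean tube thickness, px
    n_meshes_prefilter: int = 0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_and_skeletonize(
    image: IntensityImage,
    *,
    background_sigma: float = 25.0,
    min_object_px: int = 50,
    max_hole_px: int = 25,
    min_spur_px: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment the tube foreground and reduce it to a 1-px skeleton.

    Recipe: Gaussian background subtraction, Otsu global threshold, removal
    of specks below ``min_object_px``, filling of holes below ``max_hole_px``,
    1-px skeletonisation, and pruning of terminal spurs shorter than
    ``min_spur_px``.  An empty or constant image yields all-false masks (a
    "no network detected" result), never an exception.

    Returns ``(mask, skeleton)`` with ``skeleton ⊆ mask``.
    """
    px = image.pixels
    if px.max() == px.min():
        empty = np.zeros(px.shape, dtype=bool)
        return empty, empty.copy()
    bg = ndimage.gaussian_filter(px, sigma=background_sigma)
    flat = np.clip(px - bg, 0, None)
    if flat.max() == 0:
        empty = np.zeros(px.shape, dtype=bool)
        return empty, empty.copy()
    thr = filters.threshold_otsu(flat)
    mask = flat > thr
    # thresholds are exclusive: objects/holes strictly below them go
    mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    mask = morphology.remove_small_holes(mask, max_size=max_hole_px - 1)
    if not mask.any():
        return mask, np.zeros_like(mask)
    skel = morphology.skeletonize(mask)
    skel = _prune_spurs(skel, min_spur_px)
    skel &= mask
    return mask, skel


def _neighbour_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


def _prune_spurs(skel: np.ndarray, min_spur_px: int) -> np.ndarray:
    """Iteratively remove terminal branches shorter than ``min_spur_px``."""
    if min_spur_px <= 0:
        return skel
    skel = skel.copy()
    for _ in range(min_spur_px):
        nc = _neighbour_count(skel)
        tips = skel & (nc == 1)
        if not tips.any():
            break
        # only trim tips that belong to a structure with a branch point,
        # so plain lines are not eaten away
        branch = skel & (nc >= 3)
        if not branch.any():
            break
        lbl, _ = ndimage.label(skel, structure=np.ones((3, 3)))
        branch_labels = set(np.unique(lbl[branch]))
        trim = tips & np.isin(lbl, list(branch_labels))
        if not trim.any():
            break
        skel[trim] = False
    return skel


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

def _pixel_adjacency(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """8-connected adjacency with spurious diagonals dropped.

    A diagonal link is kept only when the two pixels share no orthogonal
    skeleton neighbour; this removes the 1-px triangles thin skeletons
    produce where a diagonal shortcut doubles an orthogonal step.
    """
    on = set(zip(*np.nonzero(skel)))
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in on}
    for (r, c) in on:
        for dr, dc in _ORTHO:
            q = (r + dr, c + dc)
            if q in on:
                adj[(r, c)].append(q)
        for dr, dc in _DIAG:
            q = (r + dr, c + dc)
            if q in on:
                if ((r, c + dc) in on) or ((r + dr, c) in on):
                    continue  # shortcut across an orthogonal step
                adj[(r, c)].append(q)
    return adj


def _polyline_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 1.0
    d = np.diff(path.astype(float), axis=0)
    return float(max(np.hypot(d[:, 0], d[:, 1]).sum(), 1.0))


def skeleton_to_graph(skeleton: np.ndarray) -> SkeletonGraph:
    """Contract a 1-px skeleton into a vertex/tube graph.

    Vertices are clusters of skeleton pixels with != 2 neighbours
    (branch-point clusters and tips), plus one representative pixel per
    isolated cycle.  Edges are the maximal degree-2 paths between vertices,
    carrying their ordered pixel path.
    """
    if skeleton.dtype != bool:
        uniq = np.unique(skeleton)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("skeleton must be a binary mask")
        skeleton = skeleton.astype(bool)
    adj = _pixel_adjacency(skeleton)
    node_px = {p for p, nbs in adj.items() if len(nbs) != 2}

    # cluster adjacent node pixels into vertices
    px_vertex: dict[tuple[int, int], int] = {}
    vertices: dict[int, tuple[float, float]] = {}
    clusters: dict[int, list[tuple[int, int]]] = {}
    vid = 0
    for p in sorted(node_px):
        if p in px_vertex:
            continue
        stack, members = [p], []
        px_vertex[p] = vid
        while stack:
            q = stack.pop()
            members.append(q)
            for nb in adj[q]:
                if nb in node_px and nb not in px_vertex:
                    px_vertex[nb] = vid
                    stack.append(nb)
        arr = np.array(members, dtype=float)
        vertices[vid] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
        clusters[vid] = members
        vid += 1

    edges: dict[int, Edge] = {}
    eid = 0
    visited: set[tuple[int, int]] = set()
    seen_direct: set[tuple] = set()

    def add_edge(u: int, v: int, path: list[tuple[int, int]]):
        nonlocal eid
        arr = np.array(path, dtype=int)
        edges[eid] = Edge(u=u, v=v, path=arr,
                          length=_polyline_length(arr), n_pixels=len(arr))
        eid += 1

    for u in sorted(clusters):
        for p in clusters[u]:
            for nb in adj[p]:
                if nb in node_px:
                    v = px_vertex[nb]
                    if v == u:
                        continue  # within-cluster link
                    key = (min(u, v), max(u, v), min(p, nb), max(p, nb))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        add_edge(u, v, [p, nb])
                elif nb not in visited:
                    # walk along degree-2 pixels to the next vertex
                    path = [p, nb]
                    visited.add(nb)
                    prev, cur = p, nb
                    while True:
                        nxt = [q for q in adj[cur] if q != prev]
                        if not nxt:           # dead-end pixel inside path (shouldn't happen)
                            add_edge(u, u if cur not in px_vertex else px_vertex[cur], path)
                            break
                        q = nxt[0]
                        path.append(q)
                        if q in node_px:
                            add_edge(u, px_vertex[q], path)
                            break
                        if q in visited:      # closed back on the walk (loop)
                            add_edge(u, px_vertex.get(q, u), path)
                            break
                        visited.add(q)
                        prev, cur = cur, q

    # isolated cycles: components made only of degree-2 pixels
    for p in sorted(adj):
        if p in node_px or p in visited:
            continue
        # p starts an untouched pure cycle
        vertices[vid] = (float(p[0]), float(p[1]))
        px_vertex[p] = vid
        path = [p]
        visited.add(p)
        prev, cur = None, p
        while True:
            nxt = [q for q in adj[cur] if q != prev]
            if not nxt:
                break
            q = nxt[0]
            if q == p:
                path.append(q)
                break
            path.append(q)
            visited.add(q)
            prev, cur = cur, q
        add_edge(vid, vid, path)
        vid += 1

    g = SkeletonGraph(vertices=vertices, edges=edges)
    g.components = _components(g)
    return g


def _components(g: SkeletonGraph) -> list[set[int]]:
    parent = {v: v for v in g.vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in g.edges.values():
        ru, rv = find(e.u), find(e.v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[int, set[int]] = {}
    for v in g.vertices:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


# ---------------------------------------------------------------------------
# node / tube classification
# ---------------------------------------------------------------------------

def classify_nodes(graph: SkeletonGraph, fusion_radius_px: float = 5.0) -> NodeClasses:
    """Classify vertices as junctions or extremities and fuse master junctions.

    A vertex incident to >= 2 tubes is a junction, to exactly 1 an extremity.
    Junctions within ``fusion_radius_px`` of each other (transitive closure)
    form a master junction whose coordinate is the member centroid.
    """
    if fusion_radius_px < 0:
        raise ValueError("fusion_radius_px must be >= 0")
    inc = graph.incident()
    degrees = {v: len(eids) for v, eids in inc.items()}
    classes = {v: ("junction" if d >= 2 else "extremity") for v, d in degrees.items()}

    junctions = [v for v, c in classes.items() if c == "junction"]
    parent = {v: v for v in junctions}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    coords = {v: np.array(graph.vertices[v]) for v in junctions}
    for i, a in enumerate(junctions):
        for b in junctions[i + 1:]:
            if np.hypot(*(coords[a] - coords[b])) <= fusion_radius_px:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for v in junctions:
        groups.setdefault(find(v), []).append(v)
    masters = []
    for members in groups.values():
        if len(members) >= 2:
            arr = np.array([graph.vertices[m] for m in members])
            masters.append({"members": sorted(members),
                            "coordinate": (float(arr[:, 0].mean()), float(arr[:, 1].mean()))})
    return NodeClasses(classes=classes, degrees=degrees, master_junctions=masters)


def classify_tubes(graph: SkeletonGraph, nodes: NodeClasses) -> TubeClasses:
    """Assign each tube to exactly one of segment / twig / isolated.

    A tube is connected "on a side" when that endpoint is a junction.  A
    segment is flagged master when both its endpoint junctions touch at
    least one *other* segment.
    """
    classes: dict[int, str] = {}
    for eid, e in graph.edges.items():
        if e.u == e.v:
            sides = 2 if nodes.classes[e.u] == "junction" else 0
        else:
            sides = sum(nodes.classes[v] == "junction" for v in (e.u, e.v))
        classes[eid] = {2: "segment", 1: "twig", 0: "isolated"}[sides]

    inc = graph.incident()
    master: dict[int, bool] = {}
    for eid, e in graph.edges.items():
        if classes[eid] != "segment":
            master[eid] = False
            continue
        ok = True
        for v in {e.u, e.v}:
            if not any(classes[o] == "segment" for o in inc[v] if o != eid):
                ok = False
                break
        master[eid] = ok
    return TubeClasses(classes=classes, master_segment=master)


# ---------------------------------------------------------------------------
# meshes: bounded faces of the planar embedding
# ---------------------------------------------------------------------------

def _departure_angle(e: Edge, from_vertex_end: int, window: int = 4) -> float:
    """Angle (atan2 on (row, col) treated as (y, x)) leaving along the path."""
    path = e.path if from_vertex_end == 0 else e.path[::-1]
    k = min(window, len(path) - 1)
    dr = float(path[k][0] - path[0][0])
    dc = float(path[k][1] - path[0][1])
    return math.atan2(dr, dc)


def extract_meshes(
    graph: SkeletonGraph,
    mask: np.ndarray | None = None,
    min_mesh_area_px2: float = 25.0,
) -> tuple[list[Mesh], int]:
    """Bounded faces of the planar network, with shoelace areas.

    Walks the rotation system of the embedded graph (half-edge successor =
    next incident half-edge clockwise from the reversed arrival direction);
    in each connected component the face of largest absolute signed area is
    the unbounded outer face and is dropped.  Faces below
    ``min_mesh_area_px2`` are discarded after counting.

    Returns ``(meshes, n_faces_before_area_filter)``; the pre-filter count
    equals the cycle rank sum(E_c - V_c + 1).
    """
    # half-edges: (edge_id, end) with end 0 meaning "leaves from e.u"
    half_out: dict[int, list[tuple[int, int]]] = {v: [] for v in graph.vertices}
    for eid, e in graph.edges.items():
        half_out[e.u].append((eid, 0))
        half_out[e.v].append((eid, 1))
    angle: dict[tuple[int, int], float] = {}
    for eid, e in graph.edges.items():
        angle[(eid, 0)] = _departure_angle(e, 0)
        angle[(eid, 1)] = _departure_angle(e, 1)
    for v in half_out:
        half_out[v].sort(key=lambda h: (angle[h], h))

    def origin(h):
        eid, end = h
        e = graph.edges[eid]
        return e.u if end == 0 else e.v

    def target(h):
        eid, end = h
        e = graph.edges[eid]
        return e.v if end == 0 else e.u

    def successor(h):
        """Half-edge following h in a face walk."""
        eid, end = h
        v = target(h)
        rev = (eid, 1 - end)
        ring = half_out[v]
        i = ring.index(rev)
        return ring[(i - 1) % len(ring)]   # next clockwise

    unused = {(eid, end) for eid in graph.edges for end in (0, 1)}
    vid_comp = {}
    for ci, comp in enumerate(graph.components):
        for v in comp:
            vid_comp[v] = ci
    faces_by_comp: dict[int, list[tuple[float, np.ndarray]]] = {}
    while unused:
        h0 = min(unused)
        walk = []
        h = h0
        while True:
            unused.discard(h)
            walk.append(h)
            h = successor(h)
            if h == h0:
                break
        pts = []
        for (eid, end) in walk:
            e = graph.edges[eid]
            p = e.path if end == 0 else e.path[::-1]
            pts.append(p[:-1])
        poly = np.concatenate(pts).astype(float)
        area = _shoelace(poly)
        ci = vid_comp[origin(h0)]
        faces_by_comp.setdefault(ci, []).append((area, poly))

    meshes: list[Mesh] = []
    n_prefilter = 0
    for ci, faces in faces_by_comp.items():
        if len(faces) <= 1:
            continue  # a tree: only the outer face
        outer = max(range(len(faces)), key=lambda i: abs(faces[i][0]))
        for i, (area, poly) in enumerate(faces):
            if i == outer:
                continue
            n_prefilter += 1
            a = abs(area)
            if a >= min_mesh_area_px2:
                meshes.append(Mesh(boundary=poly, area=a, perimeter=_perimeter(poly)))
    return meshes, n_prefilter


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 1], poly[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def measure_thickness(graph: SkeletonGraph, mask: np.ndarray) -> dict[int, float]:
    """Mean tube thickness from the Euclidean distance transform of the mask.

    Thickness at a centreline pixel is ``2*EDT - 1`` (the drawn width of a
    ribbon whose centreline passes through it), floored at 1 px; a tube's
    thickness is the mean over its path pixels.  A path pixel outside the
    mask is a contract violation.
    """
    edt = ndimage.distance_transform_edt(mask)
    out: dict[int, float] = {}
    for eid, e in graph.edges.items():
        vals = edt[e.path[:, 0], e.path[:, 1]]
        if np.any(vals == 0):
            raise ValueError(f"tube {eid} path leaves the mask")
        out[eid] = float(np.maximum(2.0 * vals - 1.0, 1.0).mean())
    return out


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

def extract_network(
    image: IntensityImage,
    *,
    fusion_radius_px: float = 5.0,
    min_mesh_area_px2: float = 25.0,
    min_spur_px: int = 5,
    **seg_kwargs,
) -> NetworkElements:
    """Full chain: segment, skeletonise, build graph, classify everything."""
    mask, skel = segment_and_skeletonize(image, min_spur_px=min_spur_px, **seg_kwargs)
    graph = skeleton_to_graph(skel)
    nodes = classify_nodes(graph, fusion_radius_px=fusion_radius_px)
    tubes = classify_tubes(graph, nodes)
    meshes, n_pre = extract_meshes(graph, mask, min_mesh_area_px2=min_mesh_area_px2)
    thickness = measure_thickness(graph, mask | skel) if graph.edges else {}
    return NetworkElements(graph=graph, nodes=nodes, tubes=tubes, meshes=meshes,
                           thickness=thickness, n_meshes_prefilter=n_pre)
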