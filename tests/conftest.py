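import numpy as np
import pytest
from skimage.draw import line as draw_line

from angiomorph.network import Edge, SkeletonGraph


def skeleton_from_segments(segments, shape=(120, 120)):
    """Rasterise straight segments ((r0, c0), (r1, c1)) into a skeleton mask."""
    sk = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in segments:
        rr, cc = draw_line(r0, c0, r1, c1)
        sk[rr, cc] = True
    return sk


def make_graph(vertices, edges):
    """Build a SkeletonGraph from {vid: (r, c)} and [(u, v)] or [(u, v, length)].

    Edge paths are straight two-point polylines; an explicit length
    overrides the Euclidean one (for weighted-topology tests).
    """
    vs = {int(k): (float(r), float(c)) for k, (r, c) in vertices.items()}
    es = {}
    for eid, e in enumerate(edges):
        u, v = e[0], e[1]
        p = np.array([vs[u], vs[v]])
        length = float(e[2]) if len(e) > 2 else float(np.hypot(*(p[1] - p[0])))
        es[eid] = Edge(u=u, v=v, path=p.astype(int), length=max(length, 1.0),
                       n_pixels=2)
    g = SkeletonGraph(vertices=vs, edges=es)
    from angiomorph.network import _components

    g.components = _components(g)
    return g


@pytest.fixture(scope="session")
def simulated_net():
    """One deterministic rendered network with ground truth."""
    from angiomorph.simulate import NetworkDesign, simulate_network_image

    return simulate_network_image(NetworkDesign(n_seeds=25, mesh_fraction=0.5), seed=3)


@pytest.fixture(scope="session")
def extracted_net(simulated_net):
    from angiomorph.network import extract_network

    return simulated_net.image, extract_network(simulated_net.image)
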