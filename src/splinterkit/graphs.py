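"""Distance-based bond perception and hydrogen assignment.

The molecular graph used throughout is the *heavy-atom* graph: nodes are the
indices of non-hydrogen atoms (carrying an ``element`` attribute), and an
edge joins two heavy atoms whose distance is below the covalent-radius sum
plus 0.4 Å.  Hydrogens never enter the graph; each is assigned to its
nearest heavy atom, which is what proton-transfer detection consumes.
Stereochemistry, bond orders and atomic charges are deliberately ignored:
only element-labeled graph isomorphism is ever compared.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .elements import BOND_TOLERANCE, covalent_radius


def bond_graph(elements, coords) -> nx.Graph:
    """Heavy-atom bond graph from elements and Cartesian coordinates (Å)."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    heavy = [i for i, el in enumerate(elements) if el != "H"]
    rad = np.array([covalent_radius(elements[i]) for i in heavy])
    g = nx.Graph()
    for i in heavy:
        g.add_node(i, element=elements[i])
    if len(heavy) > 1:
        pts = coords[heavy]
        d = cdist(pts, pts)
        cut = rad[:, None] + rad[None, :] + BOND_TOLERANCE
        for a in range(len(heavy)):
            for b in range(a + 1, len(heavy)):
                if d[a, b] < cut[a, b]:
                    g.add_edge(heavy[a], heavy[b])
    return g


def full_adjacency(elements, coords) -> nx.Graph:
    """All-atom adjacency under the same covalent-radius rule (H included)."""
    coords = np.asarray(coords, dtype=float)
    g = nx.Graph()
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    n = len(elements)
    if n > 1:
        rad = np.array([covalent_radius(el) for el in elements])
        d = cdist(coords, coords)
        cut = rad[:, None] + rad[None, :] + BOND_TOLERANCE
        for a in range(n):
            for b in range(a + 1, n):
                if d[a, b] < cut[a, b]:
                    g.add_edge(a, b)
    return g


def assign_hydrogens(elements, coords) -> dict[int, int]:
    """Map each hydrogen index to the index of its nearest heavy atom."""
    coords = np.asarray(coords, dtype=float)
    hs = [i for i, el in enumerate(elements) if el == "H"]
    heavy = [i for i, el in enumerate(elements) if el != "H"]
    if hs and not heavy:
        raise ValueError("cannot assign hydrogens without heavy atoms")
    out: dict[int, int] = {}
    if hs:
        d = cdist(coords[hs], coords[heavy])
        nearest = np.argmin(d, axis=1)
        for k, h in enumerate(hs):
            out[h] = heavy[nearest[k]]
    return out


def _element_match(a, b) -> bool:
    return a["element"] == b["element"]


def graphs_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    """Element-labeled heavy-graph isomorphism."""
    return nx.is_isomorphic(g1, g2, node_match=_element_match)


def graph_automorphisms(g: nx.Graph, cap: int = 10000) -> list[dict[int, int]]:
    """Element-preserving automorphisms of a heavy-atom graph, capped.

    Returns node->node mappings; the identity is always first.  When the
    cap is hit the list is truncated (a warning is the caller's business:
    diversity metrics degrade gracefully with a partial symmetry group).
    """
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g, node_match=_element_match)
    autos: list[dict[int, int]] = [{n: n for n in g.nodes}]
    for mapping in matcher.isomorphisms_iter():
        if mapping not in autos:
            autos.append(mapping)
        if len(autos) >= cap:
            break
    return autos
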