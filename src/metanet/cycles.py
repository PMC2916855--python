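"""Cycle calculus of dispersal networks.

Persistence of a metapopulation is decided entirely by the directed cycles of
its dispersal network: juveniles only "return home" along cycles.  A *cyclic
component* is a nontrivial strongly connected component (SCC, size >= 2 — the
adjacency has no self-loops) of the directed graph; an edge lies on a directed
cycle iff both endpoints share an SCC.  Edges on no cycle are *lonely links*:
removing them leaves the spectral radius, and hence the persistence
threshold, unchanged.  The component with the largest spectral radius (the
*dominant* cyclic component) alone sets ``rho(A)``; its *critical links* are
the edges whose removal reduces ``rho`` the most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import UnsupportedSizeError
from .network import DispersalNetwork, spectral_radius

__all__ = [
    "CyclicComponent",
    "CyclicDecomposition",
    "decompose",
    "prune_lonely",
    "critical_link_ranking",
    "characteristic_polynomial",
]


@dataclass(frozen=True)
class CyclicComponent:
    """One nontrivial strongly connected component of the dispersal digraph."""

    patches: tuple[int, ...]
    internal_links: tuple[tuple[int, int], ...]  # (source, target) pairs
    rho: float
    simple: bool  # True iff the component is a single directed cycle


@dataclass(frozen=True)
class CyclicDecomposition:
    """Partition of a network into cyclic components and lonely links."""

    components: tuple[CyclicComponent, ...]
    lonely_links: tuple[tuple[int, int], ...]
    acyclic_patches: tuple[int, ...]
    dominant: int | None  # index into components, None if acyclic

    @property
    def dominant_component(self) -> CyclicComponent | None:
        return None if self.dominant is None else self.components[self.dominant]

    @property
    def rho(self) -> float:
        """Spectral radius of the whole adjacency = max over components."""
        return max((c.rho for c in self.components), default=0.0)


def decompose(net: DispersalNetwork) -> CyclicDecomposition:
    """Break a network into nonoverlapping cyclic components and lonely links.

    Undirected input is treated as bidirectional: every symmetric pair is a
    2-cycle, so even a single undirected edge forms a cyclic component.  The
    dominant component maximizes ``rho``; ties go to the component with more
    patches, then to the one containing the lowest patch id (persistence is
    unaffected by the tie-break since the radii are equal).
    """
    g = net.to_networkx()
    if not g.is_directed():
        g = g.to_directed()
    sccs = [sorted(c) for c in nx.strongly_connected_components(g) if len(c) >= 2]
    sccs.sort(key=lambda c: c[0])

    components = []
    internal: set[tuple[int, int]] = set()
    for nodes in sccs:
        node_set = set(nodes)
        links = tuple(
            sorted((s, t) for s, t in g.edges(nodes) if t in node_set and s in node_set)
        )
        internal.update(links)
        idx = np.asarray(nodes)
        sub = net.adjacency[np.ix_(idx, idx)].astype(float)
        indeg = sub.sum(axis=1)
        outdeg = sub.sum(axis=0)
        simple = bool((indeg == 1).all() and (outdeg == 1).all())
        rho = 1.0 if simple else spectral_radius(sub)
        components.append(
            CyclicComponent(
                patches=tuple(nodes), internal_links=links, rho=rho, simple=simple
            )
        )

    all_links = {(s, t) for s, t in g.edges()}
    lonely = tuple(sorted(all_links - internal))
    in_component = {p for c in components for p in c.patches}
    acyclic = tuple(p for p in range(net.n) if p not in in_component)

    dominant = None
    if components:
        dominant = max(
            range(len(components)),
            key=lambda i: (
                components[i].rho,
                len(components[i].patches),
                -min(components[i].patches),
            ),
        )
    return CyclicDecomposition(
        components=tuple(components),
        lonely_links=lonely,
        acyclic_patches=acyclic,
        dominant=dominant,
    )


def prune_lonely(net: DispersalNetwork) -> DispersalNetwork:
    """Remove every lonely link, keeping all patches.

    The spectral radius is unchanged (lonely links contribute nothing to any
    cycle), and the operation is idempotent.  The result is returned as a
    directed network when the input is directed; undirected input stays
    undirected because lonely links cannot occur among bidirectional pairs
    alone — an undirected edge is always a 2-cycle — unless the edge connects
    to nothing else, which still forms a 2-cycle.  In practice undirected
    networks therefore prune to themselves.
    """
    dec = decompose(net)
    if net.directed:
        keep = sorted({l for c in dec.components for l in c.internal_links})
        return DispersalNetwork.from_edges(net.n, keep, directed=True)
    # every undirected edge is a 2-cycle, nothing is lonely
    return DispersalNetwork(n=net.n, directed=False, adjacency=net.adjacency.copy())


def critical_link_ranking(
    net: DispersalNetwork,
) -> list[tuple[tuple[int, int], float]]:
    """Rank links of the dominant cyclic component by spectral-radius drop.

    For each internal link ``e`` of the dominant component,
    ``delta_rho(e) = rho(A) - rho(A with e removed)``, recomputed exactly by a
    dense eigensolve per removal.  Lonely links are appended with
    ``delta_rho = 0`` without recomputation (their removal provably leaves
    ``rho`` unchanged).  Sorted by descending ``delta_rho``, ties broken by
    lexicographic edge order.  For undirected networks a link is the
    bidirectional pair and removal drops both directions.
    """
    dec = decompose(net)
    if dec.dominant is None:
        warnings.warn("network has no cyclic component; ranking is empty", stacklevel=2)
        return []
    rho_full = dec.rho
    dom = dec.dominant_component
    links = dom.internal_links
    if not net.directed:
        links = tuple(sorted({(min(s, t), max(s, t)) for s, t in links}))
    ranking = []
    for link in links:
        pruned = net.remove_edges([link])
        ranking.append((link, rho_full - spectral_radius(pruned.adjacency)))
    lonely = dec.lonely_links
    if not net.directed:
        lonely = tuple(sorted({(min(s, t), max(s, t)) for s, t in lonely}))
    ranking.extend((link, 0.0) for link in lonely)
    ranking.sort(key=lambda item: (-item[1], item[0]))
    return ranking


def characteristic_polynomial(matrix: np.ndarray) -> np.ndarray:
    """Monic coefficients of ``det(lambda I - A)``, highest degree first.

    Report-oriented: supports ``n <= 64``.  The largest-magnitude real root
    equals the spectral radius (to ~1e-6) for nonnegative matrices.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise UnsupportedSizeError(f"matrix must be square, got shape {A.shape}")
    if A.shape[0] > 64:
        raise UnsupportedSizeError(
            f"characteristic polynomial supports n <= 64, got n = {A.shape[0]}"
        )
    return np.poly(A)
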