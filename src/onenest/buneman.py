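"""Buneman graphs (median networks) and their structure theory.

The Buneman graph ``G(Sigma)`` of a split system has as vertices the maps
``phi`` choosing one side of every split such that any two chosen sides
intersect, and as edges the pairs of maps differing on exactly one split.
It is an isometric subgraph of a hypercube; graph distance equals the number
of splits on which two maps disagree.

Structure used here: with all trivial splits present, the degree-one
vertices are the Kuratowski maps ``phi_x`` (choose the side containing
``x``) and are identified with the taxa; the blocks (maximal 2-connected
subgraphs) are in bijection with the connected components of the
incompatibility graph; each block is gated, and for a maximal circular
component the gates span a distinguished subgraph called a marguerite whose
external vertices become the cycle of the reconstructed 1-nested network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import networkx as nx

from .splits import (
    CircularOrdering,
    EmptySystemError,
    Split,
    SplitSystem,
    are_compatible,
    incompatibility_components,
    interval_splits,
    make_split,
    natural_key,
)

__all__ = [
    "BunemanGraph",
    "buneman_graph",
    "kuratowski_map",
    "bu_displayed_splits",
    "max_side",
    "blocks_and_components",
    "gate",
    "gates_of",
    "Marguerite",
    "marguerite",
    "embed_network",
    "BunemanCapError",
]


class BunemanCapError(ValueError):
    """The split system is too large for explicit vertex enumeration."""


Selection = Tuple[bool, ...]  # True = the canonical block side of the split


@dataclass
class BunemanGraph:
    """``G(Sigma)`` with vertices encoded as side-choice tuples.

    A vertex is a tuple of booleans aligned with ``splits`` (True picks the
    canonical side).  ``graph`` is the underlying networkx graph; each edge
    carries the split on which its endpoints differ under the key
    ``"split"``.
    """

    system: SplitSystem
    splits: Tuple[Split, ...]
    graph: nx.Graph
    kuratowski: Dict[str, Selection]

    @property
    def ground(self) -> frozenset:
        return self.system.ground

    def side(self, vertex: Selection, split: Split) -> frozenset:
        i = self.splits.index(split)
        return self.splits[i].block if vertex[i] else self.splits[i].complement

    def image(self, vertex: Selection) -> Tuple[frozenset, ...]:
        return tuple(
            s.block if choice else s.complement
            for s, choice in zip(self.splits, vertex)
        )

    def delta(self, u: Selection, v: Selection) -> List[Split]:
        """The splits on which two vertices disagree; graph distance is its
        length."""
        return [s for s, a, b in zip(self.splits, u, v) if a != b]


def _consistent_vertices(splits: Tuple[Split, ...]) -> List[Selection]:
    sides = [(s.block, s.complement) for s in splits]
    out: List[Selection] = []
    choice: List[bool] = []
    chosen: List[frozenset] = []

    def extend(i: int) -> None:
        if i == len(sides):
            out.append(tuple(choice))
            return
        for flag in (True, False):
            side = sides[i][0] if flag else sides[i][1]
            if all(not side.isdisjoint(prev) for prev in chosen):
                choice.append(flag)
                chosen.append(side)
                extend(i + 1)
                choice.pop()
                chosen.pop()

    extend(0)
    return out


def buneman_graph(sigma: SplitSystem, cap: int = 25) -> BunemanGraph:
    """Enumerate ``G(Sigma)`` by backtracking over side choices.

    Splits are processed smallest side first so inconsistent branches die
    early.  The vertex count can grow exponentially with the number of
    splits, hence the cap on ``|Sigma|`` (trivial splits are cheap and do
    not count against it).
    """
    if len(sigma) == 0:
        raise EmptySystemError("Buneman graph of an empty system")
    if len(sigma.nontrivial()) > cap:
        raise BunemanCapError(
            f"{len(sigma.nontrivial())} nontrivial splits exceed the cap of {cap}"
        )
    splits = tuple(sorted(sigma.splits, key=Split.sort_key))
    vertices = _consistent_vertices(splits)
    vset = set(vertices)
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for v in vertices:
        for i, s in enumerate(splits):
            w = v[:i] + (not v[i],) + v[i + 1 :]
            if w in vset and v < w:
                g.add_edge(v, w, split=s)
    kura = {x: kuratowski_selection(x, splits) for x in sigma.ground}
    return BunemanGraph(system=sigma, splits=splits, graph=g, kuratowski=kura)


def kuratowski_selection(x: str, splits: Tuple[Split, ...]) -> Selection:
    return tuple(x in s.block for s in splits)


def kuratowski_map(x: str, bg: BunemanGraph) -> Selection:
    """The vertex choosing, for every split, the side containing ``x``."""
    if x not in bg.ground:
        raise KeyError(f"taxon {x!r} not in ground set")
    return bg.kuratowski[x]


def bu_displayed_splits(bg: BunemanGraph) -> SplitSystem:
    """Splits displayed by ladders of parallel edges.

    For each split the edges tagged with it form a ladder whose deletion
    leaves two components partitioning the Kuratowski maps the way the split
    partitions the taxa.  For every Buneman graph the result is the defining
    system itself.
    """
    found = set()
    for s in bg.splits:
        ladder = [
            (u, v) for u, v, d in bg.graph.edges(data=True) if d["split"] == s
        ]
        h = bg.graph.copy()
        h.remove_edges_from(ladder)
        comps = list(nx.connected_components(h))
        if len(comps) != 2:
            continue
        side = {x for x, kv in bg.kuratowski.items() if kv in comps[0]}
        other = {x for x, kv in bg.kuratowski.items() if kv in comps[1]}
        if side and other and make_split(side, bg.ground) == s:
            found.add(s)
    return SplitSystem.from_splits(found, bg.ground)


def max_side(split: Split, collection) -> frozenset:
    """``max(S | Sigma')``: the side of ``split`` meeting both sides of every
    split in ``collection``.

    For a split compatible with a whole incompatibility component the choice
    is the same for every member; the general form (checking all members) is
    what cycle split systems need, where compatible m-splits ride along.
    Raises if no single side works.
    """
    candidates = [
        side
        for side in split.sides
        if all(
            not side.isdisjoint(s.block) and not side.isdisjoint(s.complement)
            for s in collection
        )
    ]
    if len(candidates) != 1:
        raise ValueError(
            "max(S|Sigma') is ill defined: "
            f"{len(candidates)} qualifying sides for {split}"
        )
    return candidates[0]


def blocks_and_components(bg: BunemanGraph) -> Dict[frozenset, frozenset]:
    """The bijection between incompatibility components and blocks of G.

    Maps each component ``Sigma0`` to its block's vertex set
    ``B(Sigma0) = { phi : phi(S) = max(S|Sigma0) for all S outside Sigma0 }``.
    """
    comps = incompatibility_components(bg.system)
    out: Dict[frozenset, frozenset] = {}
    for comp in comps:
        required = {}
        for i, s in enumerate(bg.splits):
            if s not in comp:
                required[i] = max_side(s, comp) == s.block
        members = frozenset(
            v
            for v in bg.graph.nodes
            if all(v[i] == flag for i, flag in required.items())
        )
        out[comp] = members
    return out


def gate(bg: BunemanGraph, phi: Selection, collection) -> Selection:
    """The gate of ``phi`` in the block of ``collection``: keep the choices
    on the collection's splits, clamp everything else to ``max(S|Sigma')``.
    The gate lies on a shortest path from ``phi`` to every vertex of the
    block."""
    collection = set(collection)
    out = list(phi)
    for i, s in enumerate(bg.splits):
        if s not in collection:
            out[i] = max_side(s, collection) == s.block
    return tuple(out)


def gates_of(bg: BunemanGraph, include_leaves: bool = False) -> FrozenSet[Selection]:
    """Gates of Kuratowski maps across all blocks of the graph.

    By default the Kuratowski maps themselves are excluded (a leaf is its own
    gate in its pendant block); the remaining gates are exactly the images of
    the internal vertices of the displaying network.
    """
    kura = set(bg.kuratowski.values())
    out = set()
    for comp in incompatibility_components(bg.system):
        for x in bg.ground:
            g = gate(bg, bg.kuratowski[x], comp)
            if include_leaves or g not in kura:
                out.add(g)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Marguerites


@dataclass
class Marguerite:
    """The marguerite of the maximal circular system on ``k`` singletons.

    ``system`` is Sigma_k (all interval splits of 1..k minus the trivial
    ones).  Vertices are selection tuples on Sigma_k; ``phi[(i, j)]`` and
    ``psi[(i, j)]`` index them (identifications are by value, so the
    boundary maps of neighbouring petals coincide automatically).  External
    vertices phi_i^0 become the cycle of the reconstructed network.
    """

    k: int
    system: SplitSystem
    splits: Tuple[Split, ...]
    graph: nx.Graph
    phi: Dict[Tuple[int, int], Selection]
    psi: Dict[Tuple[int, int], Selection]
    external_vertices: Tuple[Selection, ...]
    external_edges: Tuple[tuple, ...]


def _interval_labels(i: int, j: int, k: int) -> frozenset:
    """Labels of the cyclic interval [i-j, i] on 1..k (1-based, mod k)."""
    return frozenset(str((i - d - 1) % k + 1) for d in range(j + 1))


def marguerite(k: int) -> Marguerite:
    """Construct the k-marguerite as a verified subgraph of ``G(Sigma_k)``.

    Every map is checked to be a consistent side selection; the induced
    edges among the maps are computed directly (they are hypercube edges, so
    no enumeration of the full graph is needed).
    """
    if k < 4:
        raise ValueError("marguerites need k >= 4")
    taxa = [str(i) for i in range(1, k + 1)]
    ordering = CircularOrdering.from_sequence(taxa)
    sigma_k = interval_splits(ordering).nontrivial()
    splits = tuple(sorted(sigma_k.splits, key=Split.sort_key))

    def phi_map(i: int, j: int) -> Selection:
        out = []
        window = _interval_labels(i, j, k)
        x = str(i)
        for s in splits:
            side = s.side_of(x)
            chosen = (s.ground - side) if side <= window else side
            out.append(chosen == s.block)
        return tuple(out)

    def flip(sel: Selection, split: Split) -> Selection:
        i = splits.index(split)
        return sel[:i] + (not sel[i],) + sel[i + 1 :]

    phi: Dict[Tuple[int, int], Selection] = {}
    for i in range(1, k + 1):
        for j in range(0, k - 3):
            phi[(i, j)] = phi_map(i, j)
        phi[(i, k - 3)] = phi_map(i, k - 3)  # identified with phi_{i+1}^0 by value
    psi: Dict[Tuple[int, int], Selection] = {}
    for i in range(1, k + 1):
        s_plus = make_split({str(i), str(i % k + 1)}, frozenset(taxa))
        for j in range(1, k - 3):
            psi[(i, j)] = flip(phi[(i, j)], s_plus)

    vertices = set(phi.values()) | set(psi.values())
    for v in vertices:
        _assert_consistent(v, splits)
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for v in vertices:
        for idx, s in enumerate(splits):
            w = v[:idx] + (not v[idx],) + v[idx + 1 :]
            if w in vertices and v < w:
                g.add_edge(v, w, split=s)
    external_vertices = tuple(phi[(i, 0)] for i in range(1, k + 1))
    external_edges = tuple(
        (phi[(i, j)], phi[(i, j + 1)]) for i in range(1, k + 1) for j in range(k - 3)
    )
    return Marguerite(
        k=k,
        system=sigma_k,
        splits=splits,
        graph=g,
        phi=phi,
        psi=psi,
        external_vertices=external_vertices,
        external_edges=external_edges,
    )


def _assert_consistent(sel: Selection, splits: Tuple[Split, ...]) -> None:
    sides = [
        s.block if flag else s.complement for s, flag in zip(splits, sel)
    ]
    for a, b in itertools.combinations(sides, 2):
        if a.isdisjoint(b):
            raise AssertionError("inconsistent side selection in marguerite")


# ---------------------------------------------------------------------------
# Embedding a network into its Buneman graph


def embed_network(net) -> Tuple[BunemanGraph, Dict[object, Selection]]:
    """The bijection from non-leaf vertices of a maximal partially resolved
    1-nested network onto the gates of ``G(Sigma(N))``.

    A tree vertex maps through the component of one of its cut-edge splits;
    a cycle vertex through the component of its cycle's nontrivial splits.
    In both cases the image is the gate of the Kuratowski map of a taxon on
    the vertex's side.
    """
    from .network import maximal_partial_resolution, splits_of, validate

    diag = validate(net)
    if not diag.is_1_nested:
        raise ValueError("embedding requires a 1-nested network")
    member = net.cycle_membership()
    for v, cycs in member.items():
        if len(cycs) > 1:
            raise ValueError("network must be partially resolved (shared cycle vertex)")
    shown = splits_of(net)
    sigma = shown.system
    bg = buneman_graph(sigma)
    comps = incompatibility_components(sigma)
    # each cycle's incompatible splits form one component inside Sigma(C)-;
    # its compatible m-splits are singleton components (cut-edge-like) and
    # must not be clamped with the block
    cycle_comp: Dict[tuple, frozenset] = {}
    for cyc, csys in shown.per_cycle:
        inside = [
            c for c in comps if len(c) >= 2 and c <= csys.nontrivial().splits
        ]
        if len(inside) != 1:
            raise ValueError("cycle does not carry exactly one incompatibility component")
        cycle_comp[tuple(cyc)] = inside[0]

    g = net.graph
    xi: Dict[object, Selection] = {}
    for v in g.nodes:
        if net.is_leaf(v):
            continue
        cycs = member.get(v, [])
        if cycs:
            cyc = tuple(cycs[0])
            x_v = _taxon_avoiding(net, v, set(_cycle_edges(cyc)))
            xi[v] = gate(bg, bg.kuratowski[x_v], cycle_comp[cyc])
        else:
            e_v = sorted(
                ((v, u) for u in g.neighbors(v)), key=lambda e: repr(e[1])
            )[0]
            split = _edge_split(net, e_v)
            x_v = _taxon_avoiding(net, v, {frozenset(e_v)})
            xi[v] = gate(bg, bg.kuratowski[x_v], {split})
    return bg, xi


def _cycle_edges(cyc: tuple):
    k = len(cyc)
    return [frozenset((cyc[i], cyc[(i + 1) % k])) for i in range(k)]


def _taxon_avoiding(net, v, forbidden_edges) -> str:
    """A taxon reachable from ``v`` without crossing any forbidden edge."""
    g = net.graph
    seen = {v}
    stack = [v]
    while stack:
        cur = stack.pop()
        if net.is_leaf(cur):
            return net.taxon_of(cur)
        for w in g.neighbors(cur):
            if w in seen or frozenset((cur, w)) in forbidden_edges:
                continue
            seen.add(w)
            stack.append(w)
    raise ValueError("no taxon on this side")


def _edge_split(net, edge) -> Split:
    g2 = net.graph.copy()
    g2.remove_edge(*edge)
    comps = list(nx.connected_components(g2))
    side = {net.taxon_of(w) for w in comps[0] if net.is_leaf(w)}
    return make_split(side, net.taxa)
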