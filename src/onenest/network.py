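"""Uprooted phylogenetic networks as leaf-labelled graphs.

An uprooted network on a taxon set ``X`` is a simple connected graph whose
degree-one vertices are bijectively labelled by ``X``, with no degree-two
vertex and no cycle shorter than four.  It is *1-nested* when no two cycles
share an edge (every block is an edge or a chordless cycle, i.e. the graph
is a cactus), *level-1* when no two cycles even share a vertex, and *simple*
when its only cut edges are the pendant ones.

A split is displayed by the network when some inclusion-minimal edge cut
separates its two sides; in a 1-nested network every minimal cut is a single
cut edge or a pair of edges of one cycle, and a given split can be induced
by one, two or three distinct minimal cuts (its multiplicity).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

from .splits import (
    CircularOrdering,
    Split,
    SplitSystem,
    make_split,
    natural_key,
)

__all__ = [
    "UprootedNetwork",
    "NetworkDiagnostics",
    "DisplayedSplits",
    "validate",
    "splits_of",
    "enumerate_minimal_cuts",
    "partially_resolve",
    "unresolve",
    "maximal_partial_resolution",
    "canonical_unresolved_form",
    "isomorphic_up_to_resolution",
    "simple_level1_from_ordering",
    "leaf_cyclic_order",
    "NotOneNestedError",
]


class NotOneNestedError(ValueError):
    """Raised when an operation needs a 1-nested network and got something else."""


TAXON_KEY = "taxon"


class UprootedNetwork:
    """A leaf-labelled graph; leaf nodes carry a ``taxon`` attribute.

    Internal vertex ids are opaque (integers by convention); only leaf
    labels are semantic, so isomorphism checks pin leaves and ignore ids.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    def copy(self) -> "UprootedNetwork":
        return UprootedNetwork(self.graph.copy())

    # -- basic structure ----------------------------------------------------

    @property
    def taxa(self) -> frozenset:
        return frozenset(
            d[TAXON_KEY] for _, d in self.graph.nodes(data=True) if TAXON_KEY in d
        )

    def leaf_nodes(self) -> dict:
        """Map taxon -> node id."""
        return {
            d[TAXON_KEY]: v for v, d in self.graph.nodes(data=True) if TAXON_KEY in d
        }

    def taxon_of(self, node) -> Optional[str]:
        return self.graph.nodes[node].get(TAXON_KEY)

    def is_leaf(self, node) -> bool:
        return TAXON_KEY in self.graph.nodes[node]

    def cycles(self) -> List[list]:
        """The cycles of a cactus, each as an ordered vertex list.

        Every biconnected component with three or more vertices must be a
        chordless cycle; anything else raises :class:`NotOneNestedError`.
        """
        out = []
        for comp in nx.biconnected_components(self.graph):
            if len(comp) < 3:
                continue
            sub = self.graph.subgraph(comp)
            if sub.number_of_edges() != len(comp) or any(
                d != 2 for _, d in sub.degree()
            ):
                raise NotOneNestedError("a block is neither an edge nor a cycle")
            out.append(_walk_cycle(sub))
        out.sort(key=lambda cyc: sorted(cyc)[0] if cyc else -1)
        return out

    def cycle_membership(self) -> Dict[object, list]:
        """node -> list of cycles (as ordered vertex lists) containing it."""
        member: Dict[object, list] = {}
        for cyc in self.cycles():
            for v in cyc:
                member.setdefault(v, []).append(cyc)
        return member

    def fresh_node(self) -> int:
        ints = [v for v in self.graph.nodes if isinstance(v, int)]
        return (max(ints) + 1) if ints else 0

    def __repr__(self) -> str:
        return (
            f"UprootedNetwork(n_taxa={len(self.taxa)}, "
            f"|V|={self.graph.number_of_nodes()}, |E|={self.graph.number_of_edges()})"
        )


def _walk_cycle(sub: nx.Graph) -> list:
    start = sorted(sub.nodes)[0]
    order = [start]
    prev, cur = None, start
    while True:
        nbrs = [u for u in sub.neighbors(cur) if u != prev]
        nxt = sorted(nbrs)[0] if prev is None else nbrs[0]
        if nxt == start:
            return order
        order.append(nxt)
        prev, cur = cur, nxt


@dataclass
class NetworkDiagnostics:
    errors: List[str] = field(default_factory=list)
    is_uprooted: bool = False
    is_1_nested: bool = False
    is_level_1: bool = False
    is_simple: bool = False

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(net: UprootedNetwork) -> NetworkDiagnostics:
    """Check the uprooted-network invariants and classify the structure."""
    g = net.graph
    diag = NetworkDiagnostics()
    if g.number_of_nodes() == 0:
        diag.errors.append("empty graph")
        return diag
    if not nx.is_connected(g):
        diag.errors.append("graph is not connected")
    for v, d in g.degree():
        if d == 2:
            diag.errors.append(f"vertex {v!r} has degree two")
        if d == 0 and g.number_of_nodes() > 1:
            diag.errors.append(f"vertex {v!r} is isolated")
    labelled = [v for v, d in g.nodes(data=True) if TAXON_KEY in d]
    for v in labelled:
        if g.degree(v) != 1:
            diag.errors.append(f"labelled vertex {v!r} is not a leaf")
    for v, d in g.degree():
        if d == 1 and TAXON_KEY not in g.nodes[v]:
            diag.errors.append(f"leaf {v!r} carries no taxon label")
    labels = [g.nodes[v][TAXON_KEY] for v in labelled]
    if len(labels) != len(set(labels)):
        diag.errors.append("duplicate taxon labels")
    # cycle lengths: every cycle must have length >= 4
    blocks_ok = True
    for comp in nx.biconnected_components(g):
        if len(comp) < 3:
            continue
        sub = g.subgraph(comp)
        if sub.number_of_edges() == len(comp) and all(d == 2 for _, d in sub.degree()):
            if len(comp) == 3:
                diag.errors.append("cycle of length three")
        else:
            blocks_ok = False
            if min(len(c) for c in nx.minimum_cycle_basis(sub)) < 4:
                diag.errors.append("cycle shorter than four inside a block")
    diag.is_uprooted = not diag.errors
    diag.is_1_nested = diag.is_uprooted and blocks_ok
    if diag.is_1_nested:
        member = {}
        shared = False
        for cyc in net.cycles():
            for v in cyc:
                if v in member:
                    shared = True
                member[v] = True
        diag.is_level_1 = not shared
        diag.is_simple = all(
            net.is_leaf(u) or net.is_leaf(v) for u, v in nx.bridges(g)
        )
    return diag


# ---------------------------------------------------------------------------
# Displayed splits


@dataclass
class DisplayedSplits:
    """Sigma(N) with per-split multiplicities and per-cycle subsystems."""

    system: SplitSystem
    multiplicity: Dict[Split, int]
    per_cycle: List[Tuple[tuple, SplitSystem]]  # (cycle vertex tuple, Sigma(C))


def _leaf_partition(net: UprootedNetwork, removed_edges) -> Optional[Split]:
    g = net.graph.copy()
    g.remove_edges_from(removed_edges)
    comps = list(nx.connected_components(g))
    if len(comps) != 2:
        return None
    side = {
        net.taxon_of(v) for v in comps[0] if net.is_leaf(v)
    }
    if not side or len(side) == len(net.taxa):
        return None
    return make_split(side, net.taxa)


def splits_of(net: UprootedNetwork) -> DisplayedSplits:
    """Enumerate Sigma(N) for a 1-nested network via its minimal cuts.

    Minimal cuts are exactly the cut edges plus the unordered pairs of
    distinct edges within each cycle; the multiplicity of a split counts the
    distinct minimal cuts inducing it.
    """
    diag = validate(net)
    if not diag.is_1_nested:
        raise NotOneNestedError(
            "splits_of requires a valid 1-nested network: " + "; ".join(diag.errors)
        )
    mult: Dict[Split, int] = {}
    for e in nx.bridges(net.graph):
        s = _leaf_partition(net, [e])
        assert s is not None
        mult[s] = mult.get(s, 0) + 1
    per_cycle = []
    for cyc in net.cycles():
        k = len(cyc)
        edges = [(cyc[i], cyc[(i + 1) % k]) for i in range(k)]
        cycle_splits = set()
        for e1, e2 in itertools.combinations(edges, 2):
            s = _leaf_partition(net, [e1, e2])
            assert s is not None
            mult[s] = mult.get(s, 0) + 1
            cycle_splits.add(s)
        per_cycle.append(
            (tuple(cyc), SplitSystem.from_splits(cycle_splits, net.taxa))
        )
    system = SplitSystem.from_splits(mult.keys(), net.taxa)
    return DisplayedSplits(system=system, multiplicity=mult, per_cycle=per_cycle)


def enumerate_minimal_cuts(net: UprootedNetwork, max_size: int = 2):
    """Brute-force enumeration of all minimal cuts with at most ``max_size``
    edges, by testing every edge subset for 2-component separation and
    inclusion-minimality.  Independent of the structured route in
    :func:`splits_of`; intended for cross-checking on small networks."""
    g = net.graph
    edges = list(g.edges())
    found = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(edges, size):
            h = g.copy()
            h.remove_edges_from(subset)
            if nx.number_connected_components(h) != 2:
                continue
            minimal = True
            for r in range(1, size):
                for sub2 in itertools.combinations(subset, r):
                    h2 = g.copy()
                    h2.remove_edges_from(sub2)
                    if not nx.is_connected(h2):
                        minimal = False
            if minimal:
                split = _leaf_partition(net, subset)
                if split is not None:
                    found.append((frozenset(frozenset(e) for e in subset), split))
    return found


# ---------------------------------------------------------------------------
# Partial resolution


def _noncycle_edges_at(net: UprootedNetwork, v, cyc) -> list:
    on_cycle = set(cyc)
    k = len(cyc)
    cycle_edges = {
        frozenset((cyc[i], cyc[(i + 1) % k])) for i in range(k)
    }
    return [
        (v, u) for u in net.graph.neighbors(v) if frozenset((v, u)) not in cycle_edges
    ]


def partially_resolve(net: UprootedNetwork, vertex, edges=None) -> UprootedNetwork:
    """Pull structure off a cycle vertex without changing Sigma(N).

    If ``vertex`` lies on one cycle and has two or more non-cycle edges, the
    non-cycle edges (all of them, or the subset ``edges``) move to a new
    pendant vertex joined to ``vertex`` by a cut edge.  If ``vertex`` is
    shared by two cycles, one cycle is pushed onto a new vertex joined to
    ``vertex`` by a cut edge.  The displayed split *set* is unchanged; the
    multiset is not.
    """
    out = net.copy()
    member = out.cycle_membership()
    cycles_here = member.get(vertex, [])
    if len(cycles_here) >= 2:
        # separate two cycles sharing the vertex
        cyc = cycles_here[0]
        i = cyc.index(vertex)
        a, b = cyc[i - 1], cyc[(i + 1) % len(cyc)]
        new = out.fresh_node()
        out.graph.add_node(new)
        out.graph.remove_edge(vertex, a)
        out.graph.remove_edge(vertex, b)
        out.graph.add_edge(new, a)
        out.graph.add_edge(new, b)
        out.graph.add_edge(vertex, new)
        return out
    if len(cycles_here) == 1:
        pendant = _noncycle_edges_at(out, vertex, cycles_here[0])
        if edges is not None:
            chosen = [e for e in pendant if frozenset(e) in {frozenset(x) for x in edges}]
        else:
            chosen = pendant
        if len(chosen) < 2:
            raise ValueError("resolution needs at least two non-cycle edges to pull out")
        new = out.fresh_node()
        out.graph.add_node(new)
        for v, u in chosen:
            out.graph.remove_edge(v, u)
            out.graph.add_edge(new, u)
        out.graph.add_edge(vertex, new)
        return out
    raise ValueError(f"vertex {vertex!r} is not eligible for partial resolution")


def _contractible_edges(net: UprootedNetwork) -> list:
    """Cut edges between two internal vertices, at least one on a cycle."""
    on_cycle = set(net.cycle_membership())
    out = []
    for u, v in nx.bridges(net.graph):
        if net.is_leaf(u) or net.is_leaf(v):
            continue
        if u in on_cycle or v in on_cycle:
            out.append((u, v))
    return out


def unresolve(net: UprootedNetwork, edge) -> UprootedNetwork:
    """Contract a cut edge between internal vertices, one on a cycle.

    This is the inverse of :func:`partially_resolve` and likewise preserves
    the displayed split set.
    """
    u, v = edge
    if frozenset(edge) not in {frozenset(e) for e in _contractible_edges(net)}:
        raise ValueError(f"edge {edge!r} is not an unresolvable cut edge")
    out = net.copy()
    on_cycle = set(out.cycle_membership())
    keep, gone = (u, v) if u in on_cycle else (v, u)
    for w in list(out.graph.neighbors(gone)):
        if w != keep:
            out.graph.add_edge(keep, w)
    out.graph.remove_node(gone)
    return out


def maximal_partial_resolution(net: UprootedNetwork) -> UprootedNetwork:
    """Apply resolutions until every cycle vertex has exactly one non-cycle
    edge and no vertex lies on two cycles."""
    out = net.copy()
    changed = True
    while changed:
        changed = False
        member = out.cycle_membership()
        for v, cycs in member.items():
            if len(cycs) >= 2:
                out = partially_resolve(out, v)
                changed = True
                break
            if len(_noncycle_edges_at(out, v, cycs[0])) >= 2:
                out = partially_resolve(out, v)
                changed = True
                break
    return out


def canonical_unresolved_form(net: UprootedNetwork) -> UprootedNetwork:
    """Contract every eligible cut edge to a fixpoint.

    Networks differing only by partial resolution reach the same fixpoint
    (up to isomorphism), which makes this the canonical representative used
    by :func:`isomorphic_up_to_resolution`.
    """
    out = net.copy()
    while True:
        edges = _contractible_edges(out)
        if not edges:
            return out
        out = unresolve(out, edges[0])


def isomorphic_up_to_resolution(n1: UprootedNetwork, n2: UprootedNetwork) -> bool:
    """Leaf-label-respecting isomorphism of the canonical unresolved forms."""
    a = canonical_unresolved_form(n1)
    b = canonical_unresolved_form(n2)
    return nx.is_isomorphic(
        a.graph,
        b.graph,
        node_match=lambda x, y: x.get(TAXON_KEY) == y.get(TAXON_KEY),
    )


# ---------------------------------------------------------------------------
# Constructions and traversals


def simple_level1_from_ordering(ordering: CircularOrdering) -> UprootedNetwork:
    """The simple level-1 network with one cycle carrying all taxa in order.

    Displays exactly the interval splits of the ordering, n(n-1)/2 of them.
    For n = 3 the cycle would be a triangle, which uprooted networks forbid,
    so the star tree (which displays every split system on 3 taxa) is
    returned instead.
    """
    seq = ordering.sequence
    n = len(seq)
    g = nx.Graph()
    if n == 3:
        g.add_node(0)
        for i, t in enumerate(seq, start=1):
            g.add_node(i, taxon=t)
            g.add_edge(0, i)
        return UprootedNetwork(g)
    for i in range(n):
        g.add_node(i)
        g.add_node(n + i, taxon=seq[i])
        g.add_edge(i, n + i)
    for i in range(n):
        g.add_edge(i, (i + 1) % n)
    return UprootedNetwork(g)


def tree_from_compatible(*args, **kwargs):  # pragma: no cover - convenience alias
    from .construct import buneman_tree

    return buneman_tree(*args, **kwargs)


def leaf_cyclic_order(net: UprootedNetwork) -> CircularOrdering:
    """A circular ordering of the taxa displaying Sigma(N).

    Reads the leaves off a planar traversal of the maximal partial
    resolution: tree vertices emit their subtrees in turn; each cycle is
    walked once around, emitting the pendant subtree of every cycle vertex.
    """
    res = maximal_partial_resolution(net)
    member = res.cycle_membership()
    g = res.graph
    order: List[str] = []
    root = res.leaf_nodes()[min(res.taxa, key=natural_key)]

    def emit(v, parent) -> None:
        if res.is_leaf(v):
            order.append(res.taxon_of(v))
            return
        cycs = member.get(v, [])
        if cycs and parent not in set(cycs[0]):
            cyc = cycs[0]
            k = len(cyc)
            i = cyc.index(v)
            for step in range(1, k):
                u = cyc[(i + step) % k]
                for w in g.neighbors(u):
                    if w not in set(cyc):
                        emit(w, u)
            return
        for w in sorted(g.neighbors(v), key=repr):
            if w != parent:
                emit(w, v)

    start = next(iter(g.neighbors(root)))
    order.append(res.taxon_of(root))
    emit(start, root)
    return CircularOrdering.from_sequence(order)
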