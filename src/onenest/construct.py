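"""Reconstruction of networks from split systems.

Two routes to the same object.  ``minimal_1nested`` quotients each connected
component of the incompatibility graph, recovers the cyclic ordering of its
blocks from the I-closure's 2-splits, assembles a compatible backbone system
(m-splits + cut-edge splits + trivial splits), builds its unique tree and
expands the cycle vertices.  ``network_from_buneman`` builds the Buneman
graph of the input, wires each block's gates into a cycle and deletes the
block interiors.  Both produce a 1-nested network ``N`` with
``Sigma <= Sigma(N)`` and ``|Sigma(N)|`` minimal, unique up to isomorphism
and partial resolution — the 1-nested analogue of the splits equivalence
theorem for trees.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .closure import i_closure
from .network import (
    TAXON_KEY,
    UprootedNetwork,
    canonical_unresolved_form,
    maximal_partial_resolution,
    splits_of,
    unresolve,
    _contractible_edges,
)
from .splits import (
    CircularOrdering,
    EmptySystemError,
    Split,
    SplitSystem,
    all_splits,
    are_compatible,
    incompatibility_components,
    interval_splits,
    make_split,
    natural_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NotCircularError",
    "ComponentQuotient",
    "buneman_tree",
    "component_quotient",
    "minimal_1nested",
    "network_from_buneman",
    "resolve_by_splits",
    "no_missing_compatible_split",
]


class NotCircularError(ValueError):
    """The input split system admits no circular ordering."""


# ---------------------------------------------------------------------------
# Trees from compatible systems


def buneman_tree(sigma: SplitSystem) -> UprootedNetwork:
    """The unique unrooted phylogenetic tree displaying a compatible system.

    Requires all trivial splits (every leaf forces its own).  Construction:
    fix a reference taxon ``r``; the sides avoiding ``r`` form a laminar
    family whose Hasse diagram, rooted at ``X - r`` with ``r`` attached as a
    pendant leaf, is the tree.  Each edge displays exactly one input split.
    """
    if len(sigma) == 0:
        raise EmptySystemError("cannot build a tree from an empty system")
    if not sigma.has_all_trivial():
        raise ValueError("buneman_tree requires all trivial splits")
    if not sigma.is_compatible():
        raise ValueError("buneman_tree requires a compatible split system")
    taxa = sorted(sigma.ground, key=natural_key)
    r = taxa[0]
    fam = sorted(
        {s.block if r not in s.block else s.complement for s in sigma.splits},
        key=lambda a: (len(a), sorted(a, key=natural_key)),
    )
    g = nx.Graph()
    node_of: Dict[frozenset, int] = {}
    for i, a in enumerate(fam):
        node_of[a] = i
        g.add_node(i)
        if len(a) == 1:
            g.nodes[i][TAXON_KEY] = next(iter(a))
    for a in fam:
        # parent: smallest strict superset in the family
        parents = [b for b in fam if a < b]
        if parents:
            parent = min(parents, key=len)
            g.add_edge(node_of[a], node_of[parent])
    root = len(fam)
    g.add_node(root, **{TAXON_KEY: r})
    g.add_edge(root, node_of[frozenset(taxa) - {r}])
    return UprootedNetwork(g)


# ---------------------------------------------------------------------------
# Component quotients


@dataclass
class ComponentQuotient:
    """A connected incompatibility component seen through its block partition.

    Taxa with identical side signatures across the component collapse into
    blocks; the component's splits descend to the quotient, whose I-closure
    must be the maximal circular system of a unique cyclic block ordering.
    """

    component: frozenset  # frozenset[Split]
    blocks: Dict[str, frozenset]  # representative -> taxa of the block
    quotient_system: SplitSystem
    block_ordering: CircularOrdering  # on representatives

    def msplits(self, ground: frozenset) -> List[Split]:
        """The m-splits of the induced cycle on the full taxon set: one split
        per block, separating that block's taxa from everything else."""
        return [make_split(self.blocks[rep], ground) for rep in self.block_ordering]


def component_quotient(component, ground) -> ComponentQuotient:
    """Quotient a component with >= 2 splits and recover its block cycle.

    Raises :class:`NotCircularError` when the quotient closure overflows the
    maximal-circular size bound or its 2-splits fail to trace one Hamiltonian
    cycle on the blocks.
    """
    comp = sorted(component, key=Split.sort_key)
    if len(comp) < 2:
        raise ValueError("component quotient needs a component with >= 2 splits")
    taxa = sorted(ground, key=natural_key)
    sig = {x: tuple(x in s.block for s in comp) for x in taxa}
    blocks: Dict[tuple, set] = {}
    for x in taxa:
        blocks.setdefault(sig[x], set()).add(x)
    block_map = {
        min(members, key=natural_key): frozenset(members) for members in blocks.values()
    }
    reps = sorted(block_map, key=natural_key)
    m = len(reps)
    if m < 4:
        raise NotCircularError("an incompatible pair needs at least four blocks")
    rep_of = {x: rep for rep, members in block_map.items() for x in members}
    qground = frozenset(reps)
    qsplits = {
        make_split({rep_of[x] for x in s.block}, qground) for s in comp
    }
    qsystem = SplitSystem.from_splits(qsplits, qground)
    cap = m * (m - 1) // 2
    closed = i_closure(qsystem, cap=cap)
    if closed.truncated:
        raise NotCircularError("component closure exceeds the circular size bound")
    # 2-splits of the closure trace the block cycle
    adjacency = nx.Graph()
    adjacency.add_nodes_from(reps)
    for s in closed.closed_system:
        for side in s.sides:
            if len(side) == 2:
                a, b = sorted(side, key=natural_key)
                adjacency.add_edge(a, b)
    if adjacency.number_of_edges() != m or not all(
        d == 2 for _, d in adjacency.degree()
    ) or not nx.is_connected(adjacency):
        raise NotCircularError("closure 2-splits do not form a single block cycle")
    ordering = CircularOrdering.from_sequence(_cycle_order(adjacency))
    if closed.closed_system.splits != interval_splits(ordering).splits:
        raise NotCircularError("component closure is not maximal circular")
    return ComponentQuotient(
        component=frozenset(component),
        blocks=block_map,
        quotient_system=qsystem,
        block_ordering=ordering,
    )


def _cycle_order(adjacency: nx.Graph) -> list:
    start = sorted(adjacency.nodes, key=natural_key)[0]
    order = [start]
    prev, cur = None, start
    while True:
        nbrs = [u for u in adjacency.neighbors(cur) if u != prev]
        nxt = sorted(nbrs, key=natural_key)[0] if prev is None else nbrs[0]
        if nxt == start:
            return order
        order.append(nxt)
        prev, cur = cur, nxt


# ---------------------------------------------------------------------------
# The polynomial reconstruction route


def minimal_1nested(sigma: SplitSystem) -> UprootedNetwork:
    """Build the minimal 1-nested network displaying ``sigma``.

    The result is maximal partially resolved; use
    :func:`~onenest.network.canonical_unresolved_form` or
    :func:`resolve_by_splits` for other resolution states.  Trivial splits
    are required by the theory and added automatically with a warning.
    Raises :class:`NotCircularError` on non-circular input.
    """
    if len(sigma) == 0:
        raise EmptySystemError("cannot reconstruct from an empty system")
    if not sigma.has_all_trivial():
        logger.warning("adding missing trivial splits before reconstruction")
        sigma = sigma.with_trivial()
    ground = sigma.ground
    comps = incompatibility_components(sigma)
    quotients: List[ComponentQuotient] = []
    backbone = set()
    for comp in comps:
        if len(comp) == 1:
            backbone.add(next(iter(comp)))
        else:
            quotients.append(component_quotient(comp, ground))
    for q in quotients:
        backbone.update(q.msplits(ground))
    backbone.update(make_split({x}, ground) for x in ground)
    backbone_system = SplitSystem.from_splits(backbone, ground)
    try:
        tree = buneman_tree(backbone_system)
    except ValueError as exc:
        raise NotCircularError(f"backbone system is not compatible: {exc}") from exc
    net = _expand_cycles(tree, quotients, ground)
    displayed = splits_of(net).system
    if not sigma.splits <= displayed.splits:
        raise NotCircularError("reconstruction does not display the input system")
    return net


def _expand_cycles(
    tree: UprootedNetwork, quotients: List[ComponentQuotient], ground
) -> UprootedNetwork:
    net = tree.copy()
    # map each backbone split to the tree edge displaying it, kept current
    # across expansions (an expansion replaces edges but preserves splits)
    edge_of: Dict[Split, tuple] = {}
    for e in nx.bridges(net.graph):
        g2 = net.graph.copy()
        g2.remove_edges_from([e])
        comps = list(nx.connected_components(g2))
        side = {net.taxon_of(v) for v in comps[0] if net.is_leaf(v)}
        edge_of[make_split(side, ground)] = e
    for q in quotients:
        msplits = q.msplits(ground)
        edges = [edge_of[s] for s in msplits]
        # the common endpoint is the centre to expand
        counts: Dict[object, int] = {}
        for u, v in edges:
            counts[u] = counts.get(u, 0) + 1
            counts[v] = counts.get(v, 0) + 1
        centre_candidates = [v for v, c in counts.items() if c == len(edges)]
        if len(centre_candidates) != 1:
            raise NotCircularError("cycle blocks do not meet at a single tree vertex")
        centre = centre_candidates[0]
        if net.graph.degree(centre) != len(edges):
            raise NotCircularError("extra structure at a cycle centre vertex")
        new_ids = {}
        base = net.fresh_node()
        for j, rep in enumerate(q.block_ordering):
            new_ids[rep] = base + j
            net.graph.add_node(base + j)
        for s, rep in zip(msplits, q.block_ordering):
            u, v = edge_of[s]
            far = v if u == centre else u
            net.graph.remove_edge(u, v)
            net.graph.add_edge(new_ids[rep], far)
            edge_of[s] = (new_ids[rep], far)
        net.graph.remove_node(centre)
        seq = list(q.block_ordering)
        for j in range(len(seq)):
            net.graph.add_edge(new_ids[seq[j]], new_ids[seq[(j + 1) % len(seq)]])
    return net


# ---------------------------------------------------------------------------
# The Buneman-graph route


def network_from_buneman(sigma: SplitSystem, cap: int = 25) -> UprootedNetwork:
    """Carve the minimal 1-nested network out of the Buneman graph.

    Replaces each leaf (Kuratowski map) by its taxon, wires each cyclic
    block's gates into a cycle in the block ordering, deletes the block
    interiors and suppresses the resulting degree-two vertices.  Agrees with
    :func:`minimal_1nested` up to partial resolution; the resolution state
    follows the rule that a cycle vertex keeps its cut edge exactly when the
    split its flanking cycle edges display is in ``sigma``.
    """
    from .buneman import blocks_and_components, buneman_graph, gate

    if len(sigma) == 0:
        raise EmptySystemError("cannot reconstruct from an empty system")
    if not sigma.has_all_trivial():
        logger.warning("adding missing trivial splits before reconstruction")
        sigma = sigma.with_trivial()
    bg = buneman_graph(sigma, cap=cap)
    ground = sigma.ground
    h = bg.graph.copy()
    for x, v in bg.kuratowski.items():
        h.nodes[v][TAXON_KEY] = x
    theta = blocks_and_components(bg)
    for comp, block_vertices in theta.items():
        if len(comp) < 2:
            continue
        q = component_quotient(comp, ground)
        gates_in_order = []
        for rep in q.block_ordering:
            gates_in_order.append(gate(bg, bg.kuratowski[rep], comp))
        keep = set(gates_in_order)
        for u, v in itertools.combinations(block_vertices, 2):
            if h.has_edge(u, v):
                h.remove_edge(u, v)
        for v in block_vertices:
            if v not in keep:
                h.remove_node(v)
        k = len(gates_in_order)
        for j in range(k):
            h.add_edge(gates_in_order[j], gates_in_order[(j + 1) % k])
    _suppress_degree_two(h)
    h = nx.convert_node_labels_to_integers(h)
    net = UprootedNetwork(h)
    displayed = splits_of(net).system
    if not sigma.splits <= displayed.splits:
        raise NotCircularError("reconstruction does not display the input system")
    return net


def _suppress_degree_two(g: nx.Graph) -> None:
    while True:
        deg2 = [v for v, d in g.degree() if d == 2 and TAXON_KEY not in g.nodes[v]]
        target = None
        for v in deg2:
            a, b = g.neighbors(v)
            if not g.has_edge(a, b):
                target = (v, a, b)
                break
        if target is None:
            return
        v, a, b = target
        g.remove_node(v)
        g.add_edge(a, b)


# ---------------------------------------------------------------------------
# Resolution by membership, and the level-1 certificate


def resolve_by_splits(net: UprootedNetwork, sigma: SplitSystem) -> UprootedNetwork:
    """Resolve exactly the cycle vertices whose flanking-edge split is in
    ``sigma``: starting from the maximal partial resolution, contract every
    cut edge whose displayed split is absent from ``sigma``."""
    shown = splits_of(net).system
    if not sigma.splits <= shown.splits:
        raise ValueError("network does not display the given system")
    out = maximal_partial_resolution(net)
    while True:
        progress = False
        for u, v in _contractible_edges(out):
            g2 = out.graph.copy()
            g2.remove_edge(u, v)
            comps = list(nx.connected_components(g2))
            side = {out.taxon_of(w) for w in comps[0] if out.is_leaf(w)}
            if make_split(side, out.taxa) not in sigma.splits:
                out = unresolve(out, (u, v))
                progress = True
                break
        if not progress:
            return out


def no_missing_compatible_split(net: UprootedNetwork) -> bool:
    """Exhaustively test that no split outside Sigma(N) is compatible with
    every split of Sigma(N).  For a maximal partially resolved 1-nested
    network this is equivalent to being level-1.  Exponential in n; meant
    for small fixtures."""
    shown = splits_of(net).system
    if len(net.taxa) > 12:
        raise ValueError("exhaustive split search is limited to n <= 12")
    for s in all_splits(net.taxa):
        if s in shown:
            continue
        if all(are_compatible(s, t) for t in shown):
            return False
    return True
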