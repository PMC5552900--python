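"""The classic eight-taxon worked example.

A split system on ``{1, ..., 8}`` whose optimal 1-nested representation
joins two cycles by a cut edge, together with the hand-built reference
network (one 4-cycle carrying 7, 8, 1 and one 6-cycle carrying 2..6).  The
reference network displays the example system plus three further splits
(20 in all), strictly fewer than the 28 a single-cycle network on eight
taxa would postulate — the motivating optimality gap.
"""

from __future__ import annotations

import networkx as nx

from .network import TAXON_KEY, UprootedNetwork
from .splits import SplitSystem

__all__ = ["eight_taxon_system", "eight_taxon_network"]

_NONTRIVIAL_SIDES = [
    {"8", "1"},
    {"7", "8"},
    {"7", "8", "1"},
    {"2", "3", "4"},
    {"3", "4"},
    {"3", "4", "5"},
    {"2", "3", "4", "5"},
    {"3", "4", "5", "6"},
    {"5", "6"},
]


def eight_taxon_system(with_trivial: bool = True) -> SplitSystem:
    """The eight-taxon example system: 9 nontrivial splits, plus the 8
    trivial ones unless ``with_trivial`` is False."""
    ground = {str(i) for i in range(1, 9)}
    system = SplitSystem.from_sides(_NONTRIVIAL_SIDES, ground)
    return system.with_trivial() if with_trivial else system


def eight_taxon_network() -> UprootedNetwork:
    """The reference network: a 4-cycle (taxa 7, 8, 1) and a 6-cycle
    (taxa 2..6) joined by a cut edge.  Its displayed system has 20 splits
    and contains :func:`eight_taxon_system`; the cut edge joining the two
    cycles induces a split of multiplicity three."""
    g = nx.Graph()
    cyc4 = ["a7", "a8", "a1", "aB"]
    cyc6 = ["b2", "b3", "b4", "b5", "b6", "bB"]
    for i in range(4):
        g.add_edge(cyc4[i], cyc4[(i + 1) % 4])
    for i in range(6):
        g.add_edge(cyc6[i], cyc6[(i + 1) % 6])
    g.add_edge("aB", "bB")
    for t, v in [
        ("7", "a7"), ("8", "a8"), ("1", "a1"),
        ("2", "b2"), ("3", "b3"), ("4", "b4"), ("5", "b5"), ("6", "b6"),
    ]:
        g.add_node("L" + t, **{TAXON_KEY: t})
        g.add_edge("L" + t, v)
    return UprootedNetwork(nx.convert_node_labels_to_integers(g))
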