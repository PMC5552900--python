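"""Random 1-nested networks and random circular split systems.

The generator is the test substrate for the whole package: every fixture is
produced by code at run time from a seed, so identical configurations give
identical outputs (a single numpy PRNG stream drives all choices in a fixed
order).

A random 1-nested network is grown as a random multifurcating tree whose
high-degree interior vertices are then expanded into cycles of length >= 4;
a random circular system is a subsample of the interval splits of a random
circular ordering (trivial splits always kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import networkx as nx
import numpy as np

from .network import TAXON_KEY, UprootedNetwork, validate
from .splits import CircularOrdering, SplitSystem, interval_splits

__all__ = [
    "GeneratorConfig",
    "InfeasibleConfigError",
    "random_1nested_network",
    "random_circular_system",
    "random_circular_ordering",
]


class InfeasibleConfigError(ValueError):
    """The requested structure cannot be realized (e.g. a mandatory cycle
    longer than any attachment point allows)."""


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic generators.

    ``n_cycles`` is an inclusive (min, max) range; the generator raises if
    it cannot place at least the minimum.  ``cycle_length`` is an inclusive
    range of cycle sizes, each capped by the degree of the expanded vertex.
    ``resolve_probability`` is the chance that a cycle vertex carrying
    several subtrees is partially resolved (pulled onto a pendant cut edge).
    ``subsample_fraction`` is the share of nontrivial interval splits kept
    when emitting a partial circular system.
    """

    n_taxa: int = 8
    n_cycles: Tuple[int, int] = (0, 3)
    cycle_length: Tuple[int, int] = (4, 8)
    resolve_probability: float = 0.5
    subsample_fraction: float = 0.5
    multifurcation_probability: float = 0.6
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_multifurcating_tree(
    rng: np.random.Generator, n: int, p_multi: float
) -> nx.Graph:
    """Random unrooted tree on leaves "1".."n" with interior multifurcations
    (needed so that cycle expansion has degree->=4 vertices to work with)."""
    g = nx.Graph()
    g.add_node(0)
    for i in range(1, min(n, 3) + 1):
        g.add_node(-i, **{TAXON_KEY: str(i)})
        g.add_edge(0, -i)
    next_internal = 1
    for i in range(4, n + 1):
        leaf = -i
        g.add_node(leaf, **{TAXON_KEY: str(i)})
        internals = sorted(v for v in g.nodes if v >= 0)
        if rng.random() < p_multi and internals:
            v = internals[rng.integers(len(internals))]
            g.add_edge(v, leaf)
        else:
            edges = sorted((min(e), max(e)) for e in g.edges())
            u, w = edges[rng.integers(len(edges))]
            g.remove_edge(u, w)
            mid = next_internal
            next_internal += 1
            g.add_node(mid)
            g.add_edge(u, mid)
            g.add_edge(w, mid)
            g.add_edge(mid, leaf)
    return g


def random_1nested_network(cfg: GeneratorConfig) -> UprootedNetwork:
    """A random valid 1-nested network on taxa "1".."n_taxa".

    Grows a random tree, then expands randomly chosen interior vertices of
    degree >= 4 into cycles, distributing the incident subtrees around the
    cycle; each cycle vertex with more than one subtree is resolved onto a
    pendant cut edge with ``resolve_probability``.
    """
    if cfg.n_taxa < 3:
        raise InfeasibleConfigError("need at least 3 taxa")
    rng = cfg.rng()
    g = _random_multifurcating_tree(rng, cfg.n_taxa, cfg.multifurcation_probability)
    lo, hi = cfg.n_cycles
    target = int(rng.integers(lo, hi + 1))
    placed = 0
    on_cycle: set = set()
    next_id = max(v for v in g.nodes) + 1
    for _ in range(target):
        candidates = sorted(
            v for v in g.nodes if v >= 0 and v not in on_cycle and g.degree(v) >= 4
        )
        if not candidates:
            break
        v = candidates[rng.integers(len(candidates))]
        d = g.degree(v)
        k = int(rng.integers(cfg.cycle_length[0], cfg.cycle_length[1] + 1))
        k = min(k, d)
        if k < 4:
            continue
        nbrs = sorted(g.neighbors(v), key=repr)
        order = [nbrs[j] for j in rng.permutation(len(nbrs))]
        groups = [order[j::k] for j in range(k)]
        cycle_nodes = []
        for j in range(k):
            c = next_id
            next_id += 1
            g.add_node(c)
            cycle_nodes.append(c)
            group = groups[j]
            if len(group) >= 2 and rng.random() < cfg.resolve_probability:
                hub = next_id
                next_id += 1
                g.add_node(hub)
                g.add_edge(c, hub)
                for u in group:
                    g.add_edge(hub, u)
            else:
                for u in group:
                    g.add_edge(c, u)
        g.remove_node(v)
        for j in range(k):
            g.add_edge(cycle_nodes[j], cycle_nodes[(j + 1) % k])
        on_cycle.update(cycle_nodes)
        placed += 1
    if placed < lo:
        raise InfeasibleConfigError(
            f"could only place {placed} of the required {lo} cycles"
        )
    net = UprootedNetwork(g)
    diag = validate(net)
    assert diag.is_1_nested, f"generator produced an invalid network: {diag.errors}"
    return net


def random_circular_ordering(cfg: GeneratorConfig, rng=None) -> CircularOrdering:
    rng = cfg.rng() if rng is None else rng
    taxa = [str(i) for i in range(1, cfg.n_taxa + 1)]
    perm = [taxa[j] for j in rng.permutation(len(taxa))]
    return CircularOrdering.from_sequence(perm)


def random_circular_system(
    cfg: GeneratorConfig, return_ordering: bool = False
):
    """A random circular split system: all trivial splits plus a random
    subsample of the nontrivial interval splits of a random ordering."""
    rng = cfg.rng()
    ordering = random_circular_ordering(cfg, rng=rng)
    full = interval_splits(ordering)
    nontrivial = sorted(full.nontrivial().splits, key=lambda s: s.sort_key())
    keep = int(round(cfg.subsample_fraction * len(nontrivial)))
    chosen = (
        [nontrivial[j] for j in rng.choice(len(nontrivial), size=keep, replace=False)]
        if keep
        else []
    )
    system = SplitSystem.from_splits(
        set(chosen) | full.trivial_part().splits, full.ground
    )
    if return_ordering:
        return system, ordering
    return system
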