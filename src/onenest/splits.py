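"""Splits, split systems and circular orderings.

A *split* is an unordered bipartition ``{A, X-A}`` of a finite taxon set
``X`` into two nonempty parts.  Split systems are the combinatorial currency
of unrooted phylogenetics: a tree displays a compatible system, a 1-nested
network displays a circular one.  This module provides the canonical split
and split-system containers, compatibility and the incompatibility graph,
circular orderings and their interval splits, and an exact circularity test.

Taxa are plain strings ordered naturally (embedded integers compare
numerically), so ``"2" < "10"``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

__all__ = [
    "natural_key",
    "Split",
    "make_split",
    "are_compatible",
    "SplitSystem",
    "IncompatibilityComponents",
    "incompatibility_graph",
    "incompatibility_components",
    "CircularOrdering",
    "interval_splits",
    "adjacent_pair_system",
    "is_circular",
    "all_splits",
    "InvalidSplitError",
    "GroundSetMismatchError",
    "EmptySystemError",
]

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(label: str):
    """Sort key ordering numeral chunks numerically: ``"2" < "10" < "a"``."""
    return tuple(
        (0, int(tok)) if tok.isdigit() else (1, tok)
        for tok in _NAT_SPLIT.split(str(label))
        if tok != ""
    )


class InvalidSplitError(ValueError):
    """A side that is empty or equals the whole ground set."""


class GroundSetMismatchError(ValueError):
    """Two objects defined over different taxon sets were combined."""


class EmptySystemError(ValueError):
    """An operation that requires a nonempty split system got an empty one."""


def _min_taxon(taxa: Iterable[str]) -> str:
    return min(taxa, key=natural_key)


@dataclass(frozen=True)
class Split:
    """A bipartition of a ground set, stored canonically.

    ``block`` is the side containing the minimum taxon, which makes equality
    and hashing independent of which side a caller named first.
    """

    ground: frozenset
    block: frozenset

    def __post_init__(self) -> None:
        if not self.block or self.block >= self.ground:
            raise InvalidSplitError(
                f"split side must be a nonempty proper subset: {set(self.block)!r}"
            )
        if not self.block <= self.ground:
            raise InvalidSplitError("split side not contained in the ground set")
        if _min_taxon(self.ground) not in self.block:
            raise InvalidSplitError("canonical side must contain the minimum taxon")

    @property
    def complement(self) -> frozenset:
        return self.ground - self.block

    @property
    def sides(self) -> tuple:
        return (self.block, self.complement)

    def side_of(self, taxon: str) -> frozenset:
        """The side containing ``taxon`` (``S(x)`` in the usual notation)."""
        if taxon in self.block:
            return self.block
        if taxon in self.ground:
            return self.complement
        raise KeyError(f"taxon {taxon!r} not in ground set")

    @property
    def size(self) -> int:
        return min(len(self.block), len(self.ground) - len(self.block))

    @property
    def is_trivial(self) -> bool:
        return self.size == 1

    def separates(self, x: str, y: str) -> bool:
        return (x in self.block) != (y in self.block)

    def sort_key(self):
        return (
            self.size,
            tuple(sorted((natural_key(t) for t in self.block))),
            tuple(sorted((natural_key(t) for t in self.complement))),
        )

    def __str__(self) -> str:
        fmt = lambda side: " ".join(sorted(side, key=natural_key))
        return f"{fmt(self.block)} | {fmt(self.complement)}"

    def __repr__(self) -> str:
        return f"Split({str(self)})"


def make_split(side: Iterable[str], ground: Iterable[str]) -> Split:
    """Build the canonical :class:`Split` with one side ``side``.

    ``make_split(A, X)`` and ``make_split(X - A, X)`` return equal objects.
    Raises :class:`InvalidSplitError` if ``side`` is empty or all of ``X``.
    """
    ground = frozenset(str(t) for t in ground)
    side = frozenset(str(t) for t in side)
    if not side <= ground:
        raise InvalidSplitError(f"side {set(side)!r} not contained in ground set")
    if not side or side == ground:
        raise InvalidSplitError("side must be a nonempty proper subset of the ground set")
    if _min_taxon(ground) not in side:
        side = ground - side
    return Split(ground=ground, block=side)


def are_compatible(s1: Split, s2: Split) -> bool:
    """True iff some pair of sides of ``s1`` and ``s2`` is disjoint.

    For distinct splits this is equivalent to one side strictly containing a
    side of the other; equal splits are defined to be compatible so that
    compatibility of a whole system reduces to pairwise checks.
    """
    if s1.ground != s2.ground:
        raise GroundSetMismatchError("splits live on different ground sets")
    if s1 == s2:
        return True
    a1, b1 = s1.sides
    a2, b2 = s2.sides
    return (
        a1.isdisjoint(a2)
        or a1.isdisjoint(b2)
        or b1.isdisjoint(a2)
        or b1.isdisjoint(b2)
    )


@dataclass(frozen=True)
class SplitSystem:
    """A set of splits over one ground set."""

    ground: frozenset
    splits: frozenset

    @classmethod
    def from_splits(
        cls, splits: Iterable[Split], ground: Optional[Iterable[str]] = None
    ) -> "SplitSystem":
        splits = frozenset(splits)
        if ground is None:
            if not splits:
                raise EmptySystemError(
                    "cannot infer a ground set from an empty split collection"
                )
            ground = next(iter(splits)).ground
        ground = frozenset(str(t) for t in ground)
        for s in splits:
            if s.ground != ground:
                raise GroundSetMismatchError(
                    f"split {s} not on ground set {sorted(ground, key=natural_key)}"
                )
        return cls(ground=ground, splits=splits)

    @classmethod
    def from_sides(
        cls, sides: Iterable[Iterable[str]], ground: Iterable[str]
    ) -> "SplitSystem":
        ground = frozenset(str(t) for t in ground)
        return cls.from_splits([make_split(side, ground) for side in sides], ground)

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self) -> Iterator[Split]:
        return iter(sorted(self.splits, key=Split.sort_key))

    def __contains__(self, split: Split) -> bool:
        return split in self.splits

    def __or__(self, other: "SplitSystem") -> "SplitSystem":
        if self.ground != other.ground:
            raise GroundSetMismatchError("cannot union systems on different ground sets")
        return SplitSystem(self.ground, self.splits | other.splits)

    @property
    def n_taxa(self) -> int:
        return len(self.ground)

    def nontrivial(self) -> "SplitSystem":
        """The system with all trivial splits removed (may be empty)."""
        return SplitSystem(self.ground, frozenset(s for s in self.splits if not s.is_trivial))

    def trivial_part(self) -> "SplitSystem":
        return SplitSystem(self.ground, frozenset(s for s in self.splits if s.is_trivial))

    def with_trivial(self) -> "SplitSystem":
        """The system together with every trivial split of the ground set."""
        triv = {make_split({x}, self.ground) for x in self.ground}
        return SplitSystem(self.ground, self.splits | frozenset(triv))

    def has_all_trivial(self) -> bool:
        return all(make_split({x}, self.ground) in self.splits for x in self.ground)

    def is_compatible(self) -> bool:
        return all(
            are_compatible(s1, s2) for s1, s2 in itertools.combinations(self.splits, 2)
        )

    def separates(self, x: str, y: str) -> bool:
        return any(s.separates(x, y) for s in self.splits)


def all_splits(ground: Iterable[str]) -> SplitSystem:
    """Every split of the ground set: 2^(n-1) - 1 of them."""
    taxa = sorted({str(t) for t in ground}, key=natural_key)
    first, rest = taxa[0], taxa[1:]
    sides = []
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            sides.append({first, *combo})
    return SplitSystem.from_sides(sides, taxa)


# ---------------------------------------------------------------------------
# Incompatibility graph


@dataclass(frozen=True)
class IncompatibilityComponents:
    """Partition of a split system into connected components of Incomp."""

    system: SplitSystem
    components: tuple  # tuple of frozenset[Split]

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self.components)

    def singletons(self) -> list:
        return [c for c in self.components if len(c) == 1]

    def nontrivial_components(self) -> list:
        """Components with at least two splits (the cycle-generating ones)."""
        return [c for c in self.components if len(c) >= 2]

    def component_of(self, split: Split) -> frozenset:
        for c in self.components:
            if split in c:
                return c
        raise KeyError(f"{split} not in system")


def incompatibility_graph(sigma: SplitSystem) -> nx.Graph:
    """Graph on the splits of ``sigma``; edges join incompatible pairs."""
    if len(sigma) == 0:
        raise EmptySystemError("incompatibility graph of an empty system")
    g = nx.Graph()
    g.add_nodes_from(sigma.splits)
    for s1, s2 in itertools.combinations(sigma.splits, 2):
        if not are_compatible(s1, s2):
            g.add_edge(s1, s2)
    return g


def incompatibility_components(sigma: SplitSystem) -> IncompatibilityComponents:
    g = incompatibility_graph(sigma)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(s.sort_key() for s in c))
    return IncompatibilityComponents(system=sigma, components=tuple(comps))


# ---------------------------------------------------------------------------
# Circular orderings


@dataclass(frozen=True)
class CircularOrdering:
    """A cyclic arrangement of the taxa, canonical up to rotation/reflection.

    Canonical form: the sequence starts at the minimum taxon and its second
    element precedes its last (natural order), fixing rotation and mirror.
    """

    sequence: tuple

    @classmethod
    def from_sequence(cls, seq: Sequence[str]) -> "CircularOrdering":
        seq = tuple(str(t) for t in seq)
        if len(seq) != len(set(seq)):
            raise ValueError("ordering repeats a taxon")
        if len(seq) < 3:
            raise ValueError("need at least 3 taxa for a circular ordering")
        i = seq.index(_min_taxon(seq))
        rot = seq[i:] + seq[:i]
        if natural_key(rot[-1]) < natural_key(rot[1]):
            rot = (rot[0],) + tuple(reversed(rot[1:]))
        return cls(sequence=rot)

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)

    def positions(self) -> dict:
        return {t: i for i, t in enumerate(self.sequence)}

    def displays(self, split: Split) -> bool:
        """True iff both sides of ``split`` are arcs of this ordering."""
        if split.ground != self.taxa:
            raise GroundSetMismatchError("split and ordering on different taxa")
        pos = self.positions()
        n = len(self.sequence)
        idx = {pos[t] for t in split.block}
        return sum(1 for i in idx if (i + 1) % n not in idx) == 1

    def displays_system(self, sigma: SplitSystem) -> bool:
        return all(self.displays(s) for s in sigma)

    def __str__(self) -> str:
        return " ".join(self.sequence)


def interval_splits(ordering: CircularOrdering) -> SplitSystem:
    """All n(n-1)/2 splits whose sides are arcs of ``ordering``.

    This is the unique maximal circular split system for the ordering.
    """
    seq = ordering.sequence
    n = len(seq)
    sides = set()
    for i in range(n):
        for length in range(1, n):
            arc = frozenset(seq[(i + k) % n] for k in range(length))
            sides.add(arc)
    system = SplitSystem.from_sides(sides, seq)
    assert len(system) == n * (n - 1) // 2
    return system


def adjacent_pair_system(ordering: CircularOrdering) -> SplitSystem:
    """The splits separating each pair of neighbours from the rest.

    For n >= 5 there are n of them; at n = 4 opposite pairs coincide and the
    deduplicated system has 2 splits.
    """
    seq = ordering.sequence
    n = len(seq)
    if n < 4:
        raise ValueError("adjacent-pair system needs at least 4 taxa")
    sides = [{seq[i], seq[(i + 1) % n]} for i in range(n)]
    return SplitSystem.from_sides(sides, seq)


def _brute_force_circular(sigma: SplitSystem) -> Optional[CircularOrdering]:
    taxa = sorted(sigma.ground, key=natural_key)
    first, rest = taxa[0], taxa[1:]
    for perm in itertools.permutations(rest):
        if natural_key(perm[-1]) < natural_key(perm[0]):
            continue  # skip mirror images
        ordering = CircularOrdering((first,) + perm)
        if ordering.displays_system(sigma):
            return ordering
    return None


def is_circular(sigma: SplitSystem) -> Optional[CircularOrdering]:
    """A witness ordering displaying every split of ``sigma``, or ``None``.

    Exact for every input: small ground sets (n <= 8) are settled by
    enumerating all (n-1)!/2 canonical orderings; larger ones by attempting
    the optimal 1-nested construction, which succeeds exactly on circular
    systems, and reading the ordering off the resulting network.  The witness
    is always verified before being returned.
    """
    if len(sigma) == 0:
        raise EmptySystemError("circularity of an empty system")
    if sigma.n_taxa <= 8:
        return _brute_force_circular(sigma)
    # constructive route for larger ground sets
    from .construct import NotCircularError, minimal_1nested
    from .network import leaf_cyclic_order

    try:
        net = minimal_1nested(sigma.with_trivial())
    except NotCircularError:
        return None
    ordering = leaf_cyclic_order(net)
    if not ordering.displays_system(sigma):  # pragma: no cover - safety net
        return None
    return ordering
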