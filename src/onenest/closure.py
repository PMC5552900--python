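"""Split intersections and the two closures built from them.

The intersection of two distinct splits ``S1 = {A1, comp(A1)}`` and
``S2 = {A2, comp(A2)}`` with respect to a choice of sides is the split
``A1 n A2 | comp(A1) u comp(A2)`` (defined whenever ``A1 n A2`` is
nonempty).  Collecting all side choices gives ``int(S1, S2)``; restricted
to incompatible pairs the operation is written ``iota(S1, S2)`` and called
the incompatible intersection, or I-intersection.

Two least fixpoints matter here.  ``Int(Sigma)`` closes a system under all
pairwise intersections; ``I(Sigma)`` only under I-intersections of
incompatible pairs.  ``I(Sigma)`` preserves circularity and is exactly the
closure a 1-nested network imposes on the splits it displays: a system with
all trivial splits equals ``Sigma(N)`` for some 1-nested network ``N`` iff
it is circular and I-intersection closed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

from .splits import (
    EmptySystemError,
    GroundSetMismatchError,
    Split,
    SplitSystem,
    are_compatible,
    incompatibility_components,
    interval_splits,
    is_circular,
    make_split,
)

__all__ = [
    "ClosureResult",
    "intersections",
    "iota",
    "intersection_closure",
    "i_closure",
    "is_i_closed",
    "is_maximal_circular_closure",
    "default_cap",
]


@dataclass(frozen=True)
class ClosureResult:
    """Outcome of a closure computation.

    ``truncated`` means the safety cap was hit and ``closed_system`` is only
    a partial superset of the input, with no claim of closedness.
    """

    closed_system: SplitSystem
    generations: int
    truncated: bool

    def __iter__(self):
        return iter(self.closed_system)

    def __len__(self) -> int:
        return len(self.closed_system)


def intersections(s1: Split, s2: Split) -> SplitSystem:
    """The set ``int(S1, S2)`` of splits over all side choices.

    For a compatible pair the result has exactly 3 elements and contains
    both inputs; for an incompatible pair it is ``iota(S1, S2)``.
    """
    if s1.ground != s2.ground:
        raise GroundSetMismatchError("splits live on different ground sets")
    if s1 == s2:
        raise ValueError("intersections are defined for distinct splits only")
    ground = s1.ground
    out = set()
    for a1 in s1.sides:
        for a2 in s2.sides:
            inter = a1 & a2
            if inter:
                out.add(make_split(inter, ground))
    return SplitSystem.from_splits(out, ground)


def iota(s1: Split, s2: Split) -> SplitSystem:
    """The I-intersection of an incompatible pair.

    Always a compatible system of exactly four splits, excluding both
    inputs; every member is compatible with both inputs.
    """
    if are_compatible(s1, s2):
        raise ValueError("iota requires an incompatible pair of splits")
    return intersections(s1, s2)


def default_cap(n_taxa: int) -> int:
    """Hard upper bound on closure size: all splits for small n, 10*n^2 after."""
    if n_taxa <= 16:
        return 2 ** (n_taxa - 1) - 1
    return 10 * n_taxa * n_taxa


def _fixpoint(
    sigma: SplitSystem, cap: Optional[int], incompatible_only: bool
) -> ClosureResult:
    # Worklist of unordered pairs; the fixpoint is order-independent, so the
    # processing order only needs to be deterministic, not canonical.
    if len(sigma) == 0:
        raise EmptySystemError("closure of an empty system")
    if cap is None:
        cap = default_cap(sigma.n_taxa)
    current = set(sigma.splits)
    pending = list(itertools.combinations(sorted(current, key=Split.sort_key), 2))
    generations = 0
    while pending:
        generations += 1
        new_splits = set()
        for s1, s2 in pending:
            if incompatible_only and are_compatible(s1, s2):
                continue
            for s in intersections(s1, s2).splits:
                if s not in current and s not in new_splits:
                    new_splits.add(s)
        if not new_splits:
            break
        if len(current) + len(new_splits) > cap:
            current |= new_splits
            return ClosureResult(
                SplitSystem(sigma.ground, frozenset(current)), generations, True
            )
        old = sorted(current, key=Split.sort_key)
        new = sorted(new_splits, key=Split.sort_key)
        pending = [(a, b) for a in old for b in new]
        pending.extend(itertools.combinations(new, 2))
        current |= new_splits
    return ClosureResult(SplitSystem(sigma.ground, frozenset(current)), generations, False)


def intersection_closure(sigma: SplitSystem, cap: Optional[int] = None) -> ClosureResult:
    """Least superset of ``sigma`` closed under all pairwise intersections."""
    return _fixpoint(sigma, cap, incompatible_only=False)


def i_closure(sigma: SplitSystem, cap: Optional[int] = None) -> ClosureResult:
    """Least superset of ``sigma`` closed under I-intersections.

    Computed per connected component of the incompatibility graph (the
    closure decomposes over components, and splitting first bounds the pair
    counts); compatible components pass through untouched.
    """
    if len(sigma) == 0:
        raise EmptySystemError("closure of an empty system")
    comps = incompatibility_components(sigma)
    if len(comps) == 1:
        return _fixpoint(sigma, cap, incompatible_only=True)
    out = set()
    generations = 0
    truncated = False
    for comp in comps:
        if len(comp) == 1:
            out |= comp
            continue
        res = _fixpoint(
            SplitSystem(sigma.ground, comp), cap, incompatible_only=True
        )
        out |= res.closed_system.splits
        generations = max(generations, res.generations)
        truncated = truncated or res.truncated
    return ClosureResult(SplitSystem(sigma.ground, frozenset(out)), generations, truncated)


def is_i_closed(sigma: SplitSystem) -> bool:
    """True iff every incompatible pair's I-intersection lies inside ``sigma``."""
    if len(sigma) == 0:
        raise EmptySystemError("closedness of an empty system")
    for s1, s2 in itertools.combinations(sigma.splits, 2):
        if not are_compatible(s1, s2):
            if not iota(s1, s2).splits <= sigma.splits:
                return False
    return True


def is_maximal_circular_closure(sigma: SplitSystem) -> bool:
    """Whether ``I(sigma)`` is a maximal circular split system.

    For a circular system this holds iff (i) every pair of distinct taxa is
    separated by some nontrivial split and (ii) the incompatibility graph of
    the nontrivial part is connected.  Raises on non-circular input.
    """
    if is_circular(sigma) is None:
        raise ValueError("is_maximal_circular_closure requires a circular system")
    nontrivial = sigma.nontrivial()
    taxa = sorted(sigma.ground)
    for x, y in itertools.combinations(taxa, 2):
        if not nontrivial.separates(x, y):
            return False
    if len(nontrivial) == 0:
        return False  # unreachable for n >= 3 once separation holds; kept for safety
    return len(incompatibility_components(nontrivial)) == 1


def closure_is_maximal_circular(sigma: SplitSystem) -> bool:
    """Direct route: compute ``I(sigma)`` and compare with the interval system
    of a witness ordering.  Exponentially slower than the two-condition test;
    used as its cross-check."""
    witness = is_circular(sigma)
    if witness is None:
        raise ValueError("requires a circular system")
    closed = i_closure(sigma)
    if closed.truncated:
        return False
    return closed.closed_system.splits == interval_splits(witness).splits
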