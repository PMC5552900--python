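# Methods

## The objects

A **split** `A|B` is a bipartition of a finite taxon set `X` (n >= 3) into
two nonempty parts; a **split system** is a set of splits on one ground
set.  Splits are stored canonically: the recorded side is the one holding
the minimum taxon under natural (numeral-aware) string order, so `12|345`
and `345|12` are one object.  Two distinct splits are **compatible** when
some side of one is disjoint from some side of the other (equivalently, one
side strictly contains a side of the other); equal splits are defined
compatible so that system-level compatibility reduces to pairwise checks.
A system is **circular** when some cyclic arrangement of the taxa turns
both sides of every split into arcs; the interval splits of one ordering
number n(n-1)/2 and form the unique maximal circular system for it.

An **uprooted 1-nested network** is a simple connected leaf-labelled graph
with no degree-2 vertex, all cycles of length >= 4, and edge-disjoint
cycles (a cactus); **level-1** strengthens this to vertex-disjoint cycles.
The network displays the split system `Sigma(N)` of its inclusion-minimal
edge cuts: single cut edges and pairs of edges within one cycle.  The
**multiplicity** of a split counts the distinct minimal cuts inducing it
and lies in {1, 2, 3}; the value 3 occurs exactly for a cut edge both of
whose endpoints sit on cycles.

## Closures and the characterization

The intersection of splits `S1`, `S2` with respect to chosen sides
`A1`, `A2` (when `A1 n A2` is nonempty) is `A1 n A2 | comp(A1) u comp(A2)`.
Over all side choices this yields `int(S1,S2)`: three splits including both
inputs when the pair is compatible, and — written `iota(S1,S2)` — four
splits excluding both inputs when it is incompatible, themselves pairwise
compatible and compatible with both inputs.

`Int(Sigma)` and `I(Sigma)` are the least fixpoints under all intersections
and under iota of incompatible pairs, respectively.  Both are genuine
closure operators (extensive, idempotent, monotone) and order-independent,
so the implementation uses a deterministic worklist of unordered pairs with
a deduplicating set; newly produced splits enqueue new pairs.  `I`
decomposes over the connected components of the **incompatibility graph**
(vertices = splits, edges = incompatible pairs) and is computed per
component.  `I` preserves circularity, which gives the central
characterization used throughout: a split system containing all trivial
splits equals `Sigma(N)` for a (then unique up to isomorphism and partial
resolution) 1-nested network iff it is circular and I-intersection closed.

Safety caps: closures stop with a `truncated` flag once the system would
exceed `2^(n-1) - 1` splits (all splits of `X`) for n <= 16, else `10 n^2`.
On a quotient with m blocks the cap is `m(m-1)/2`, sound because the
I-closure of a circular system stays circular and circular systems cannot
exceed that size; overflow therefore certifies non-circularity.

## Circularity testing

`is_circular` returns a verified witness ordering or `None`.  For n <= 8 it
enumerates the (n-1)!/2 canonical orderings (first position pinned to the
minimum taxon, reflection fixed by comparing the second and last entries)
and checks every split's arc property — exact by construction, and the
independent oracle for the constructive route.  For larger n it runs the
reconstruction below on the input plus trivial splits: the construction
succeeds exactly on circular systems, and the witness is read off the
resulting network by a planar traversal (cycles walked once around,
pendant subtrees emitted in cyclic position) and verified before being
returned, so a failure soundly reports non-circularity.

## Reconstruction

`minimal_1nested` builds, for a circular system with all trivial splits, a
1-nested network `N` with `Sigma <= Sigma(N)` and `|Sigma(N)|` minimal:

1. split `Sigma` into incompatibility components;
2. quotient each component with >= 2 splits by the equivalence "same side
   of every component split"; the component's splits descend to the block
   partition, their I-closure (cap `m(m-1)/2`) must be the maximal circular
   system of a unique block cycle, read off the closure's 2-splits (at
   m = 4 both size-2 sides of a split contribute adjacencies);
3. assemble the compatible backbone system: each singleton component's
   split, each cycle's m-splits (one block against the rest), and all
   trivial splits;
4. build the unique tree for the backbone (fix a reference taxon `r`; the
   sides avoiding `r` form a laminar family whose Hasse diagram, with `r`
   attached as a pendant leaf at the top, is the tree — each edge displays
   exactly one backbone split);
5. expand each cycle's centre vertex — the single tree vertex where all its
   m-split edges meet — into the block cycle, attaching each subtree at its
   cyclic position.

The output is maximal partially resolved (every cycle vertex carries
exactly one pendant cut edge); `Sigma <= Sigma(N)` is verified before
returning, and any structural failure along the way raises
`NotCircularError`, which is what makes the constructive circularity test
exact.

`network_from_buneman` reaches the same object through the **Buneman
graph** `G(Sigma)`: vertices are side selections with pairwise-intersecting
images (enumerated by backtracking, smallest sides first, capped at 25
nontrivial splits by default because the vertex count can be exponential);
edges join selections differing on one split.  Blocks of `G(Sigma)` biject
with incompatibility components; each cyclic block's gates (Kuratowski maps
clamped outside the component to the side meeting both sides of every
component member) are wired into a cycle in the block ordering, the block
interiors deleted, leaves replaced by their taxa, and degree-2 vertices
suppressed.  The two routes share only the block-ordering primitive of
step 2; their agreement on random circular systems is a standing
cross-check.

Partial resolution moves (pulling a cycle vertex's pendant edges onto a cut
edge, or separating two cycles sharing a vertex) never change the displayed
split *set*, only the multiset.  Networks are compared up to these moves by
contracting every cut edge between internal vertices with an endpoint on a
cycle to a fixpoint and then testing leaf-label-respecting isomorphism
(networkx VF2 with labels pinned).  `resolve_by_splits` realizes the
canonical resolution state in which a cycle vertex keeps its cut edge
exactly when the split its flanking cycle edges display belongs to the
input system.

One definitional nuance: the "no absent compatible split" certificate
characterizes *binary* level-1 networks among maximal partial resolutions —
any multifurcating tree vertex admits an absent split (group two of its
parts) compatible with everything displayed, so vertex-disjoint cycles
alone do not suffice.

## Marguerites

For the maximal circular system on k >= 4 singleton blocks (trivial splits
removed), the k-marguerite is the subgraph of the Buneman graph spanned by
the petal maps `phi_i^j` (0 <= j < k-3, flipping the splits whose `i`-side
lies in the trailing window `[i-j, i]`) and `psi_i^l` (1 <= l < k-3,
additionally flipped at the adjacent-pair split at `i`).  Maps are
deduplicated by value, so the petal boundary identifications
(`phi_i^{k-3} = phi_{i+1}^0`, and the psi analogues whose printed index
ranges are self-contradictory) emerge from equality rather than being
assumed; every constructed map is verified to be a consistent selection.
The marguerite equals the whole Buneman graph for k = 4, 5 and is a proper
subgraph from k = 6 on; external vertices `phi_i^0` are exactly the gates
and become the reconstructed cycle.  The embedding of a maximal partially
resolved network into its Buneman graph sends a cycle vertex to the gate,
in its cycle's component block, of any taxon behind it, and a tree vertex
to the gate across one of its cut edges; the clamping set must be the
incompatibility component, not the full cycle split system — an m-split
shared with a pendant cut edge is compatible with everything, forms its own
singleton component, and clamping it with the block collapses the
embedding.

## Synthetic data

The generator is the package's only data source; all fixtures are built at
run time from one seeded numpy PRNG stream, so identical configurations
give byte-identical outputs.  A random network grows a random tree on taxa
`"1".."n"` (new leaves attach to a uniformly chosen interior vertex with
probability 0.6, else subdivide a uniformly chosen edge — the
multifurcation bias keeps degree >= 4 vertices available for cycle
expansion), then expands up to the requested number of non-cycle interior
vertices of degree >= 4 into cycles whose length is drawn from the
configured range and capped by the vertex degree; subtrees are distributed
around the cycle, and each cycle vertex holding several subtrees is
resolved onto a pendant cut edge with probability 0.5.  A random circular
system keeps all trivial splits of a uniformly random ordering plus a
`subsample_fraction` (default 0.5) of its nontrivial interval splits,
circular by construction.

Defaults — eight taxa, up to three cycles, cycle lengths 4..8 — mirror the
desk scale of the worked examples (every published example here has
n <= 8); the test suite spans n = 5..10.  What the generator does not
emulate: weighted splits, noise (systems that are *nearly* circular), or
splits estimated from sequence data.  Green tests therefore certify the
combinatorial machinery — closures, characterizations, optimality,
uniqueness — not robustness of any inference from real alignments, which
is out of scope by design.

## Problem sizes and numerics

Everything is exact set combinatorics; there are no tolerances.  Sizes were
chosen so the full suite runs in seconds: round-trip and equivalence checks
use 50 random instances at n = 5..10, route agreement 25 instances at
n = 5..7 (inside the Buneman cap), brute-force oracles (all orderings, all
edge subsets, all 2^|Sigma| selections) run at n <= 8.  Degenerate inputs:
n = 3 admits no cycle of length >= 4, so the simple level-1 network and all
reconstructions return the star tree; empty split systems are rejected;
missing trivial splits are added with a logged warning before
reconstruction, since any displaying network forces them.

## Known limitations

- Buneman-graph enumeration is exponential in the number of splits; the
  cap (25 nontrivial splits, overridable) keeps it at desk scale, and the
  component route remains the polynomial default.
- Graph isomorphism uses VF2 with leaves pinned — fine for desk-scale
  cactus graphs, quadratic-ish in practice, with no canonical-form
  guarantees beyond what the tests exercise.
- Multi-set split equivalence (reconstruction from splits *with*
  multiplicities) and level-2 generalizations are not implemented.
- The NEXUS dialect covers the SplitsTree4 SPLITS block subset (TAXA +
  SPLITS, optional CYCLE, weights parsed and ignored); unknown blocks are
  skipped.
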