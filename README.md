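# onenest

Circular split systems, Buneman graphs, and provably optimal 1-nested
phylogenetic network reconstruction.

## The problem

Reticulate evolution (hybridization, recombination, lateral transfer)
breaks the tree model: the signal extracted from data is a *split system*
Σ — a set of bipartitions `A|B` of the taxon set `X` — that no single tree
can display.  The mildest network generalization is the **uprooted
1-nested network**: a connected leaf-labelled graph with no degree-2
vertices, all cycles of length ≥ 4, and edge-disjoint cycles.  Such a
network `N` displays the split system `Σ(N)` of its minimal edge cuts
(single cut edges, and pairs of edges within one cycle).

This package implements the combinatorial theory that makes those networks
as tractable as trees, for anyone working with splits from
SplitsTree-style analyses or studying phylogenetic networks:

- **Compatibility, circularity, incompatibility graph.** A system is
  circular iff some cyclic ordering of `X` turns every split into a pair
  of arcs; `is_circular` returns a verified witness ordering or `None`.
- **Closures.** The intersection of `S1 = A1|B1` and `S2 = A2|B2` w.r.t.
  chosen sides is `A1 ∩ A2 | B1 ∪ B2`.  For an incompatible pair the four
  resulting splits form the *I-intersection* ι(S1,S2); closing under ι
  gives `I(Σ)`, the key operator: **Σ (with all trivial splits) equals
  Σ(N) for a 1-nested network N iff Σ is circular and I-intersection
  closed**, and then N is unique up to isomorphism and partial resolution —
  the 1-nested analogue of the splits equivalence theorem for trees.
- **Reconstruction.** For any circular Σ, `minimal_1nested(Σ)` builds in
  polynomial time the unique 1-nested network with `Σ ⊆ Σ(N)` and
  `|Σ(N)|` minimal, by quotienting each connected component of the
  incompatibility graph into its cycle of blocks and expanding the unique
  compatible backbone tree.  `network_from_buneman(Σ)` reaches the same
  network independently from the **Buneman graph** (median network) `G(Σ)`
  by wiring each block's gates — the external vertices of its *marguerite*
  subgraph — into a cycle and deleting the block interiors.
- **Structure theory.** Buneman graph enumeration, Kuratowski maps,
  Bu-displayed ladders, the block ↔ incompatibility-component bijection,
  gates, marguerites, and the embedding of a network into the Buneman
  graph of its own split system.
- **Synthetic data.** Seeded generators for random 1-nested networks and
  random circular split systems, the substrate of the whole test suite.

See `docs/methods.md` for the model, algorithms, parameter defaults and
limitations.

## Worked example

The classic eight-taxon system: nine nontrivial splits plus the eight
trivial ones.

```python
from onenest import SplitSystem, minimal_1nested, splits_of, is_circular, is_i_closed

sigma = SplitSystem.from_sides(
    [{"8", "1"}, {"7", "8"}, {"7", "8", "1"}, {"2", "3", "4"}, {"3", "4"},
     {"3", "4", "5"}, {"2", "3", "4", "5"}, {"3", "4", "5", "6"}, {"5", "6"}],
    ground={str(i) for i in range(1, 9)},
).with_trivial()

print("splits:", len(sigma))
print("circular ordering:", is_circular(sigma))
print("I-intersection closed:", is_i_closed(sigma))
net = minimal_1nested(sigma)
print("cycle lengths:", sorted(len(c) for c in net.cycles()))
print("displayed splits:", len(splits_of(net).system))
```

prints

```
splits: 17
circular ordering: 1 2 3 4 5 6 7 8
I-intersection closed: True
cycle lengths: [4, 5]
displayed splits: 17
```

Reading the output: the 17 splits fit the circle 1..8; because the system
is already I-intersection closed, the unique minimal network displays
*exactly* the input — nothing extra is postulated.  It carries two cycles:
a 4-cycle (the crossing pair 81|234567, 78|123456 around taxa 7, 8, 1) and
a 5-cycle for the five-split component around taxa 2..6, in which taxa 3
and 4 hang off one cycle vertex since no nontrivial split separates them.
A naive single-cycle representation of the same system would display
`C(8,2) = 28` splits — the optimality gap the reconstruction closes.  The
same objects are available from the shell:

```sh
onenest check --in sigma.nex            # circular? I-closed? maximality conditions
onenest build --in sigma.nex --out net.graphml --report report.json
onenest extract --in net.graphml --out splits.nex --multiplicities mult.tsv
onenest buneman --in sigma.nex --out buneman.graphml
onenest simulate --n 8 --cycles 1 3 --seed 7 --out random.graphml
```

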