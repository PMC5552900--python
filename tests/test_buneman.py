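"""Buneman graph construction, blocks, gates, marguerites, embedding."""

import itertools

import networkx as nx
import pytest

from onenest.buneman import (
    BunemanCapError,
    blocks_and_components,
    bu_displayed_splits,
    buneman_graph,
    embed_network,
    gate,
    gates_of,
    kuratowski_map,
    marguerite,
    max_side,
)
from onenest.examples import eight_taxon_network, eight_taxon_system
from onenest.network import maximal_partial_resolution, splits_of
from onenest.simulate import GeneratorConfig, random_1nested_network
from onenest.splits import (
    CircularOrdering,
    SplitSystem,
    incompatibility_components,
    interval_splits,
    make_split,
)

G3 = frozenset("123")
G4 = frozenset("1234")


def trivial_system(ground):
    return SplitSystem.from_sides([{x} for x in ground], ground)


class TestEnumeration:
    def test_three_trivial_splits_give_a_star(self):
        bg = buneman_graph(trivial_system(G3))
        assert bg.graph.number_of_nodes() == 4
        assert bg.graph.number_of_edges() == 3
        leaves = [v for v, d in bg.graph.degree() if d == 1]
        assert set(leaves) == set(bg.kuratowski.values())

    def test_one_incompatible_pair_gives_a_square(self):
        sigma = SplitSystem.from_sides([{"1", "2"}, {"2", "3"}], G4)
        bg = buneman_graph(sigma)
        assert bg.graph.number_of_nodes() == 4
        assert nx.is_isomorphic(bg.graph, nx.cycle_graph(4))

    @pytest.mark.parametrize("n_splits", [5, 8, 11])
    def test_backtracking_agrees_with_exhaustive_filter(self, n_splits):
        import random

        rng = random.Random(n_splits)
        o = CircularOrdering.from_sequence("123456")
        pool = sorted(interval_splits(o).splits, key=lambda s: s.sort_key())
        sigma = SplitSystem.from_splits(rng.sample(pool, n_splits), o.taxa)
        bg = buneman_graph(sigma)
        splits = bg.splits
        expected = set()
        for bits in itertools.product([True, False], repeat=len(splits)):
            sides = [
                s.block if b else s.complement for s, b in zip(splits, bits)
            ]
            if all(
                not a.isdisjoint(b) for a, b in itertools.combinations(sides, 2)
            ):
                expected.add(bits)
        assert set(bg.graph.nodes) == expected

    def test_cap_guards_enumeration(self):
        o = CircularOrdering.from_sequence([str(i) for i in range(1, 10)])
        with pytest.raises(BunemanCapError):
            buneman_graph(interval_splits(o), cap=20)

    def test_graph_distance_equals_disagreement_count(self):
        bg = buneman_graph(eight_taxon_system())
        nodes = list(bg.graph.nodes)
        lengths = dict(nx.all_pairs_shortest_path_length(bg.graph))
        for u in nodes[:8]:
            for v in nodes:
                assert lengths[u][v] == len(bg.delta(u, v))


class TestKuratowski:
    def test_choices_follow_the_taxon(self, worked_system):
        sigma = worked_system.with_trivial()
        bg = buneman_graph(sigma)
        phi = kuratowski_map("4", bg)
        for s, choice in zip(bg.splits, phi):
            assert ("4" in s.block) == choice

    def test_leaves_of_a_compatible_system_tree(self):
        sigma = SplitSystem.from_sides(
            [{"1"}, {"2"}, {"3"}, {"4"}, {"1", "2"}], G4
        )
        bg = buneman_graph(sigma)
        for x in G4:
            assert bg.graph.degree(bg.kuratowski[x]) == 1

    def test_pairwise_distance_counts_separating_splits(self):
        sigma = eight_taxon_system()
        bg = buneman_graph(sigma)
        for x, y in [("1", "2"), ("3", "7"), ("5", "6")]:
            expected = sum(1 for s in sigma if s.separates(x, y))
            assert len(bg.delta(bg.kuratowski[x], bg.kuratowski[y])) == expected


class TestBuDisplay:
    def test_displayed_system_is_the_input(self):
        for sigma in (
            eight_taxon_system(),
            trivial_system(G4),
            SplitSystem.from_sides([{"1", "2"}, {"2", "3"}], G4).with_trivial(),
        ):
            bg = buneman_graph(sigma)
            assert bu_displayed_splits(bg).splits == sigma.splits

    def test_tree_ladders_are_single_edges(self):
        sigma = trivial_system(G4)
        bg = buneman_graph(sigma)
        for s in bg.splits:
            ladder = [e for *e, d in bg.graph.edges(data=True) if d["split"] == s]
            assert len(ladder) == 1

    def test_cycle_split_ladder_has_parallel_edges(self):
        sigma = splits_of(eight_taxon_network()).system
        bg = buneman_graph(sigma)
        s = make_split({"2", "3", "4"}, sigma.ground)
        ladder = [e for *e, d in bg.graph.edges(data=True) if d["split"] == s]
        assert len(ladder) > 1


class TestBlocksAndGates:
    def test_block_count_matches_component_count(self):
        sigma = eight_taxon_system()
        theta = blocks_and_components(buneman_graph(sigma))
        bicomps = list(nx.biconnected_components(buneman_graph(sigma).graph))
        assert len(theta) == len(incompatibility_components(sigma))
        assert len(theta) == len(bicomps)
        assert sorted(map(len, theta.values())) == sorted(map(len, bicomps))

    def test_compatible_system_blocks_are_edges(self):
        sigma = trivial_system(G4)
        theta = blocks_and_components(buneman_graph(sigma))
        assert all(len(v) == 2 for v in theta.values())

    def test_single_incompatible_pair_yields_one_square_block(self):
        sigma = SplitSystem.from_sides([{"1", "2"}, {"2", "3"}], G4).with_trivial()
        theta = blocks_and_components(buneman_graph(sigma))
        sizes = sorted(len(v) for v in theta.values())
        assert sizes == [2, 2, 2, 2, 4]

    def test_cyclic_block_count_matches_network_cycles(self):
        for seed in (0, 1, 3):
            net = random_1nested_network(
                GeneratorConfig(n_taxa=7, n_cycles=(1, 2), seed=seed)
            )
            sigma = splits_of(net).system
            theta = blocks_and_components(buneman_graph(sigma))
            cyclic_blocks = [b for b in theta.values() if len(b) > 2]
            assert len(cyclic_blocks) == len(net.cycles())

    def test_block_is_isometric_to_component_buneman_graph(self):
        # the block of a component carries an isometric copy of G(Sigma0)
        sigma = eight_taxon_system()
        bg = buneman_graph(sigma)
        theta = blocks_and_components(bg)
        for comp, block in theta.items():
            if len(comp) < 2:
                continue
            sub = bg.graph.subgraph(block)
            inner = buneman_graph(SplitSystem.from_splits(comp, sigma.ground))
            assert sub.number_of_nodes() == inner.graph.number_of_nodes()
            assert nx.is_isomorphic(sub, inner.graph)

    def test_gate_is_identity_inside_the_block(self):
        sigma = eight_taxon_system()
        bg = buneman_graph(sigma)
        theta = blocks_and_components(bg)
        for comp, block in theta.items():
            for phi in block:
                assert gate(bg, phi, comp) == phi

    def test_gate_metric_identity(self):
        # D(psi, phi) = D(psi, gate) + D(gate, phi) for psi in the block
        sigma = eight_taxon_system()
        bg = buneman_graph(sigma)
        theta = blocks_and_components(bg)
        for comp, block in theta.items():
            if len(comp) < 2:
                continue
            for x in ("1", "4", "6"):
                phi = bg.kuratowski[x]
                g = gate(bg, phi, comp)
                for psi in block:
                    assert len(bg.delta(psi, phi)) == len(bg.delta(psi, g)) + len(
                        bg.delta(g, phi)
                    )

    def test_degree_law(self):
        # the degree of a vertex equals the number of inclusion-minimal
        # elements of its image
        sigma = eight_taxon_system()
        bg = buneman_graph(sigma)
        for v in bg.graph.nodes:
            image = set(bg.image(v))
            minimal = [
                a for a in image if not any(b < a for b in image if b != a)
            ]
            preimages = [
                s for s, side in zip(bg.splits, bg.image(v)) if side in minimal
            ]
            assert bg.graph.degree(v) == len(preimages)


class TestMaxSide:
    def test_well_defined_across_a_component(self):
        sigma = eight_taxon_system()
        comps = incompatibility_components(sigma.nontrivial())
        comp = next(c for c in comps if len(c) >= 2)
        outside = [s for s in sigma if s not in comp]
        for s in outside:
            per_member = {
                next(
                    side
                    for side in s.sides
                    if not side.isdisjoint(m.block)
                    and not side.isdisjoint(m.complement)
                )
                for m in comp
            }
            assert per_member == {max_side(s, comp)}


class TestMarguerite:
    @pytest.mark.parametrize("k", [4, 5])
    def test_coincides_with_the_full_buneman_graph(self, k):
        m = marguerite(k)
        full = buneman_graph(m.system)
        assert set(m.graph.nodes) == set(full.graph.nodes)
        assert {frozenset(e) for e in m.graph.edges} == {
            frozenset(e) for e in full.graph.edges
        }

    def test_k6_is_a_proper_subgraph(self):
        m = marguerite(6)
        full = buneman_graph(m.system)
        assert set(m.graph.nodes) < set(full.graph.nodes)

    @pytest.mark.parametrize("k", [4, 5, 6, 7, 8])
    def test_vertices_and_edges_live_in_the_buneman_graph(self, k):
        m = marguerite(k)
        full = buneman_graph(m.system)
        assert set(m.graph.nodes) <= set(full.graph.nodes)
        assert all(full.graph.has_edge(u, v) for u, v in m.graph.edges)

    @pytest.mark.parametrize("k", [5, 6, 7])
    def test_petal_boundary_identifications(self, k):
        m = marguerite(k)
        for i in range(1, k + 1):
            assert m.phi[(i, k - 3)] == m.phi[(i % k + 1, 0)]

    def test_nontrivial_nonadjacent_splits_have_four_edge_ladders(self):
        k = 6
        m = marguerite(k)
        external = {frozenset(e) for e in m.external_edges}
        for s in m.splits:
            if s.size == 2:
                continue  # adjacent-pair splits
            ladder = [
                frozenset((u, v))
                for u, v, d in m.graph.edges(data=True)
                if d["split"] == s
            ]
            assert len(ladder) == 4
            assert sum(1 for e in ladder if e in external) == 2

    def test_k_below_four_rejected(self):
        with pytest.raises(ValueError):
            marguerite(3)


class TestEmbedding:
    def test_tree_internal_vertices_map_onto_steiner_gates(self):
        tree = random_1nested_network(GeneratorConfig(n_taxa=7, n_cycles=(0, 0), seed=3))
        bg, xi = embed_network(tree)
        nonleaf = [v for v in tree.graph.nodes if not tree.is_leaf(v)]
        assert len(set(xi.values())) == len(nonleaf)
        assert set(xi.values()) == set(gates_of(bg))

    def test_simple_level1_cycle_maps_to_marguerite_externals(self):
        from onenest.network import simple_level1_from_ordering

        o = CircularOrdering.from_sequence("123456")
        net = simple_level1_from_ordering(o)
        bg, xi = embed_network(net)
        cycle_vertices = set(net.cycles()[0])
        images = {xi[v] for v in cycle_vertices}
        assert images == set(gates_of(bg))

    @pytest.mark.parametrize("seed", [0, 2, 5])
    def test_bijection_onto_gates_for_random_networks(self, seed):
        net = maximal_partial_resolution(
            random_1nested_network(GeneratorConfig(n_taxa=7, n_cycles=(1, 2), seed=seed))
        )
        bg, xi = embed_network(net)
        nonleaf = [v for v in net.graph.nodes if not net.is_leaf(v)]
        assert len(set(xi.values())) == len(nonleaf)
        assert set(xi.values()) == set(gates_of(bg))

    def test_cycle_edges_become_paths_between_consecutive_gates(self):
        net = eight_taxon_network()
        bg, xi = embed_network(net)
        for cyc in net.cycles():
            k = len(cyc)
            for i in range(k):
                u, v = cyc[i], cyc[(i + 1) % k]
                # consecutive cycle vertices sit k-3 apart: the phi-chain of
                # the marguerite petal replaces the cycle edge
                assert len(bg.delta(xi[u], xi[v])) == k - 3
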