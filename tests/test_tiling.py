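"""Iteration-space slicing: instances, dependences, closure, tile correction."""

import numpy as np
import pytest

from tilefold import (
    Instance,
    ScheduleError,
    TileId,
    TileSize,
    build_dependence_graph,
    build_valid_tiles,
    check_wavefronts,
    enumerate_instances,
    fill_reference,
    lexicographic_order,
    max_source_tile,
    original_tile_of,
    reaches,
    tiled_fill,
    transitive_closure,
    validate_schedule,
    wavefronts,
)
from tilefold.tiling import S1, S2

from conftest import FIXTURE_TILE_SIZES, seeded_sequence


class TestInstances:
    def test_n1_is_empty(self):
        assert enumerate_instances(1) == []

    def test_n2_serial_order(self):
        assert enumerate_instances(2) == [Instance(S1, 0, 1, 0), Instance(S2, 0, 1, 0)]

    def test_n4_statement_counts(self):
        insts = enumerate_instances(4)
        assert sum(1 for q in insts if q.stmt == S1) == 10  # sum of j-i over i<j
        assert sum(1 for q in insts if q.stmt == S2) == 6  # C(4,2) cells

    def test_timestamps_are_a_bijection(self):
        insts = enumerate_instances(7)
        assert len(set(insts)) == len(insts)
        # serial order: i descending, then j ascending, k ascending, s2 last
        for a, b in zip(insts, insts[1:]):
            assert (-a.i, a.j, a.k + (a.j - a.i if a.stmt == S2 else 0)) < (
                -b.i, b.j, b.k + (b.j - b.i if b.stmt == S2 else 0)
            )

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            enumerate_instances(0)


class TestDependenceGraph:
    def test_n2_single_edge(self):
        g = build_dependence_graph(2)
        assert g.edges == [(Instance(S1, 0, 1, 0), Instance(S2, 0, 1, 0))]

    def test_n4_contains_cross_cell_flow(self):
        g = build_dependence_graph(4)
        assert (Instance(S2, 2, 3, 0), Instance(S1, 1, 3, 0)) in set(g.edges)

    def test_edges_respect_serial_order(self):
        g = build_dependence_graph(9)
        for u, v in g.edges:
            assert g.timestamps[u] < g.timestamps[v]

    def test_diagonal_and_lower_reads_produce_no_edges(self):
        g = build_dependence_graph(6)
        cells = {(q.i, q.j) for e in g.edges for q in e}
        assert all(i < j for i, j in cells)


class TestClosure:
    def test_n2_closure(self):
        g = build_dependence_graph(2)
        assert transitive_closure(g) == {(Instance(S1, 0, 1, 0), Instance(S2, 0, 1, 0))}

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_closed_form_equals_brute_force(self, n):
        g = build_dependence_graph(n)
        assert transitive_closure(g, "brute") == transitive_closure(g, "closed_form")

    def test_closed_form_sampled_at_n25(self):
        import networkx as nx

        g = build_dependence_graph(25)
        dig = g.digraph()
        rng = np.random.default_rng(0)
        nodes = g.nodes
        for idx in rng.choice(len(nodes), size=60, replace=False):
            p = nodes[int(idx)]
            reachable = nx.descendants(dig, p)
            for q in nodes:
                assert reaches(p, q) == (q in reachable), (p, q)

    def test_closure_contains_every_edge_and_is_transitive(self):
        g = build_dependence_graph(7)
        cl = transitive_closure(g)
        assert set(g.edges) <= cl
        # spot-check transitivity on the relation itself
        rng = np.random.default_rng(1)
        pairs = list(cl)
        for idx in rng.choice(len(pairs), size=200):
            a, b = pairs[int(idx)]
            for c, d in pairs[:50]:
                if b == c:
                    assert (a, d) in cl


class TestOriginalTiles:
    def test_degenerate_tile_covers_everything(self):
        n = 9
        B = TileSize(n, n, n)
        tiles = {original_tile_of(q, B, n) for q in enumerate_instances(n)}
        assert tiles == {TileId(0, 0, 0)}

    def test_formula_example(self):
        assert original_tile_of(Instance(S1, 0, 1, 0), TileSize(1, 1, 1), 4) == TileId(3, 0, 0)

    def test_s2_takes_last_k_block(self):
        # cell (0, 7): k runs 0..6, so with b3=2 the last block is kk=3
        assert original_tile_of(Instance(S2, 0, 7, 0), TileSize(2, 2, 2), 8).kk == 3

    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_tiles_partition_instances(self, B):
        n = 11
        insts = enumerate_instances(n)
        by_tile: dict = {}
        for q in insts:
            by_tile.setdefault(original_tile_of(q, TileSize(*B), n), []).append(q)
        assert sum(map(len, by_tile.values())) == len(insts)
        assert all(t >= (0, 0, 0) for t in by_tile)


def literal_slicing(n, B, graph):
    """Literal TILE_ITR / TVLD_LT / TILE_VLD sets from the brute closure.

    Independent oracle for build_valid_tiles: evaluates the slicing set
    equations tile by tile and asserts the result is a partition.
    """
    B = TileSize(*B)
    insts = graph.nodes
    succ: dict = {}
    for u, v in transitive_closure(graph, "brute"):
        succ.setdefault(u, set()).add(v)
    orig = {q: original_tile_of(q, B, n) for q in insts}
    assign = {}
    for II in sorted(set(orig.values())):
        tile = [q for q in insts if orig[q] == II]
        lt = {q for q in insts if orig[q] < II}
        img_gt: set = set()
        for p in insts:
            if orig[p] > II:
                img_gt |= succ.get(p, set())
        itr = [q for q in tile if q not in img_gt]
        img_itr: set = set()
        for p in itr:
            img_itr |= succ.get(p, set())
        tvld = (img_itr & lt) - img_gt
        for q in list(itr) + sorted(tvld):
            assert q not in assign, f"instance {q} assigned twice"
            assign[q] = II
    assert set(assign) == set(insts), "TILE_VLD sets do not partition"
    return assign


class TestValidTiles:
    def test_degenerate_single_tile(self):
        n = 8
        tm = build_valid_tiles(n, TileSize(n, n, n))
        assert tm.nonempty_corrected() == [TileId(0, 0, 0)]
        assert tm.moved() == []
        assert len(tm.tiles[TileId(0, 0, 0)]["tile_itr"]) == len(enumerate_instances(n))

    @pytest.mark.parametrize("n", [4, 6, 8])
    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_matches_literal_set_equations(self, n, B):
        """The instance-wise correction equals the literal slicing sets
        computed from brute-force closure."""
        g = build_dependence_graph(n)
        lit = literal_slicing(n, B, g)
        tm = build_valid_tiles(n, TileSize(*B))
        assert lit == tm.corrected

    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_partition_and_monotone_forward_correction(self, B):
        for n in (5, 9, 14, 20):
            tm = build_valid_tiles(n, TileSize(*B))
            insts = enumerate_instances(n)
            assert sorted(tm.corrected) == sorted(insts)
            assert sum(len(d["tile_vld"]) for d in tm.tiles.values()) == len(insts)
            for q in insts:
                assert tm.corrected[q] >= tm.original[q]
            for q in tm.moved():
                assert tm.corrected[q] > tm.original[q]

    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_s2_correction_set_is_empty(self, B):
        """The diagonal-update statement never needs correction."""
        for n in (4, 9, 16, 20):
            tm = build_valid_tiles(n, TileSize(*B))
            assert all(q.stmt == S1 for q in tm.moved())

    def test_family_b1_equal_1_is_uncorrected(self):
        for B in [(1, 2, 2), (1, 4, 2), (1, 96, 8)]:
            tm = build_valid_tiles(18, TileSize(*B))
            assert tm.moved() == []

    def test_max_source_tile_matches_brute_closure(self):
        import networkx as nx

        n, B = 9, TileSize(2, 3, 2)
        g = build_dependence_graph(n)
        dig = g.digraph()
        for q in g.nodes:
            anc = nx.ancestors(dig, q)
            expected = max(
                (original_tile_of(p, B, n) for p in anc), default=None
            )
            assert max_source_tile(q, B, n) == expected, q


class TestScheduleValidation:
    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_lexicographic_order_is_valid(self, B):
        for n in (4, 7, 11, 16, 20):
            g = build_dependence_graph(n)
            tm = build_valid_tiles(n, TileSize(*B))
            assert validate_schedule(tm, g, lexicographic_order(tm)) == []

    def test_reversed_order_violates(self):
        n, B = 6, TileSize(1, 2, 2)
        g = build_dependence_graph(n)
        tm = build_valid_tiles(n, B)
        violations = validate_schedule(tm, g, lexicographic_order(tm)[::-1])
        assert violations
        v = violations[0]
        assert g.timestamps[v.source] < g.timestamps[v.target]

    def test_single_tile_any_order_valid(self):
        n = 5
        g = build_dependence_graph(n)
        tm = build_valid_tiles(n, TileSize(n, n, n))
        assert validate_schedule(tm, g, [TileId(0, 0, 0)]) == []

    def test_non_permutation_rejected(self):
        n = 6
        g = build_dependence_graph(n)
        tm = build_valid_tiles(n, TileSize(2, 2, 2))
        with pytest.raises(ValueError, match="permutation"):
            validate_schedule(tm, g, lexicographic_order(tm)[:-1])


class TestWavefronts:
    def test_degenerate_single_wavefront(self):
        n = 6
        tm = build_valid_tiles(n, TileSize(n, n, n))
        waves = wavefronts(tm)
        assert len(waves) == 1 and waves[0] == [[TileId(0, 0, 0)]]

    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_contract_holds_on_fixture_grid(self, B):
        for n in (4, 8, 12, 20):
            g = build_dependence_graph(n)
            tm = build_valid_tiles(n, TileSize(*B))
            check_wavefronts(tm, g)  # raises on any violation

    def test_wavefronts_ordered_and_cover_all_tiles(self):
        tm = build_valid_tiles(12, TileSize(1, 2, 2))
        waves = wavefronts(tm)
        flat = [t for wave in waves for macro in wave for t in macro]
        assert sorted(flat) == tm.nonempty_corrected()
        wave_ws = [{t.ii + t.jj for macro in wave for t in macro} for wave in waves]
        assert all(len(ws) == 1 for ws in wave_ws)  # one w per wavefront
        flat_ws = [ws.pop() for ws in wave_ws]
        assert flat_ws == sorted(flat_ws)  # ascending w


class TestTiledFill:
    def test_known_example(self):
        ref = fill_reference("GGGAAACCC")
        assert np.array_equal(tiled_fill("GGGAAACCC", B=TileSize(1, 4, 2)), ref)

    def test_degenerate_tile_equals_reference(self):
        seq = seeded_sequence(10, seed=2)
        n = len(seq)
        assert np.array_equal(tiled_fill(seq, B=TileSize(n, n, n)), fill_reference(seq))

    @pytest.mark.parametrize("B", FIXTURE_TILE_SIZES)
    def test_matches_reference_on_random_strands(self, B):
        for idx in range(8):
            seq = seeded_sequence(3 + 7 * idx, seed=idx)
            assert np.array_equal(tiled_fill(seq, B=TileSize(*B)), fill_reference(seq)), (
                len(seq), B,
            )

    def test_result_independent_of_wavefront_interleaving(self):
        seq = seeded_sequence(40, seed=8)
        ref = fill_reference(seq)
        for s in (0, 1, 2):
            got = tiled_fill(seq, B=TileSize(2, 3, 5), rng=np.random.default_rng(s))
            assert np.array_equal(got, ref)

    def test_workers_contract(self):
        seq = seeded_sequence(20, seed=9)
        assert np.array_equal(
            tiled_fill(seq, B=TileSize(1, 2, 2), workers=1),
            tiled_fill(seq, B=TileSize(1, 2, 2), workers=8),
        )
        with pytest.raises(ValueError):
            tiled_fill(seq, B=TileSize(1, 2, 2), workers=0)

    def test_out_of_family_beyond_desk_scale_refused(self):
        seq = seeded_sequence(64, seed=0)
        with pytest.raises(ScheduleError, match="desk-scale"):
            tiled_fill(seq, B=TileSize(2, 2, 2), desk_cap=32)

    def test_best_found_tile_size_at_n300(self, long_sequences):
        seq = long_sequences[300]
        ref = fill_reference(seq)
        got = tiled_fill(seq, B=TileSize(1, 96, 8))
        assert int(got[0, -1]) == int(ref[0, -1])
        assert np.array_equal(got, ref)
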