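"""Terrain graph: walkability, edge weights, and Dijkstra distances."""

import math

import numpy as np
import pytest

from _oracles import brute_force_distance, random_terrain
from voxelnav.terrain import (
    Block,
    MovementRules,
    TerrainMap,
    dijkstra,
    distance_field_to,
    edge_weight,
    is_walkable_edge,
    octile_distance,
)

SQRT2 = math.sqrt(2.0)


def cliff_map(dz):
    """2x1 terrain where the second cell sits dz blocks higher."""
    elevation = np.array([[5], [5 + dz]], dtype=np.int64)
    return TerrainMap(elevation, np.zeros((2, 1), dtype=bool))


class TestWalkability:
    @pytest.mark.parametrize("dz,expected", [
        (2, True),    # at the climb limit
        (3, False),   # cliffs higher than two blocks cannot be climbed
        (-3, True),   # at the fall limit
        (-4, False),  # falls beyond three blocks are not survivable steps
    ])
    def test_vertical_limits(self, rules, dz, expected):
        tm = cliff_map(dz)
        u, v = tm.block_at(0, 0), tm.block_at(1, 0)
        assert is_walkable_edge(tm, rules, u, v) is expected

    def test_directed_asymmetry(self, rules):
        tm = cliff_map(-3)  # legal 3-block drop, illegal 3-block climb
        down = is_walkable_edge(tm, rules, tm.block_at(0, 0), tm.block_at(1, 0))
        up = is_walkable_edge(tm, rules, tm.block_at(1, 0), tm.block_at(0, 0))
        assert down and not up

    def test_eight_neighborhood_only(self, flat_map, rules):
        u = flat_map.block_at(0, 0)
        assert is_walkable_edge(flat_map, rules, u, flat_map.block_at(1, 1))
        assert not is_walkable_edge(flat_map, rules, u, flat_map.block_at(2, 0))
        assert not is_walkable_edge(flat_map, rules, u, u)

    def test_obstructed_cells_are_unwalkable(self, rules):
        tm = TerrainMap(np.ones((2, 1), dtype=np.int64),
                        np.array([[False], [True]]))
        u = tm.block_at(0, 0)
        assert not is_walkable_edge(tm, rules, u, Block(1, 0, 1))
        assert not is_walkable_edge(tm, rules, Block(1, 0, 1), u)

    def test_out_of_bounds_raises(self, flat_map, rules):
        with pytest.raises(IndexError):
            is_walkable_edge(flat_map, rules, flat_map.block_at(0, 0),
                             Block(-1, 0, 1))


class TestEdgeWeight:
    def test_flat_orthogonal_and_diagonal(self, rules):
        u = Block(0, 0, 3)
        assert edge_weight(rules, u, Block(1, 0, 3)) == pytest.approx(1.0)
        assert edge_weight(rules, u, Block(1, 1, 3)) == pytest.approx(SQRT2)

    def test_vertical_surcharge(self):
        rules = MovementRules(alpha_up=2.0, alpha_down=1.0)
        u = Block(0, 0, 0)
        assert edge_weight(rules, u, Block(1, 0, 2)) == pytest.approx(5.0)
        assert edge_weight(rules, u, Block(1, 0, -2)) == pytest.approx(3.0)

    def test_non_edge_rejected(self, rules):
        with pytest.raises(ValueError):
            edge_weight(rules, Block(0, 0, 0), Block(2, 0, 0))

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            MovementRules(alpha_up=1.0, alpha_down=2.0)
        with pytest.raises(ValueError):
            MovementRules(alpha_up=1.0, alpha_down=0.0)


class TestDijkstra:
    def test_source_equals_target(self, flat_map, rules):
        b = flat_map.block_at(4, 4)
        result = dijkstra(flat_map, rules, b, b)
        assert result.distance == 0.0
        assert result.blocks == [b]

    def test_flat_octile_closed_form(self, flat_map, rules):
        result = dijkstra(flat_map, rules, flat_map.block_at(0, 0),
                          flat_map.block_at(3, 5))
        expected = 5 + 3 * (SQRT2 - 1)  # octile: max + (sqrt2-1)*min
        assert result.distance == pytest.approx(expected, abs=1e-12)

    def test_wall_detour_matches_brute_force(self, walled_map, rules):
        src, dst = (0, 0), (4, 0)
        result = dijkstra(walled_map, rules, walled_map.block_at(*src),
                          walled_map.block_at(*dst))
        expected = brute_force_distance(walled_map, rules, src, dst)
        assert result.distance == pytest.approx(expected, abs=1e-12)
        assert result.distance > octile_distance(4, 0)  # detour was needed

    def test_ramp_asymmetry(self, ramp_map, rules):
        bottom, top = ramp_map.block_at(0, 0), ramp_map.block_at(3, 0)
        d_up = dijkstra(ramp_map, rules, bottom, top).distance
        d_down = dijkstra(ramp_map, rules, top, bottom).distance
        assert d_up - d_down == pytest.approx(
            3 * (rules.alpha_up - rules.alpha_down)
        )

    def test_unreachable_is_flagged_not_raised(self, rules):
        obstructed = np.zeros((3, 3), dtype=bool)
        obstructed[1, :] = True  # full wall
        tm = TerrainMap(np.ones((3, 3), dtype=np.int64), obstructed)
        result = dijkstra(tm, rules, tm.block_at(0, 0), tm.block_at(2, 0))
        assert not result.reachable
        assert math.isinf(result.distance)
        assert result.blocks == []

    def test_path_edges_are_walkable_and_sum_to_distance(self, rules):
        rng = np.random.default_rng(5)
        tm = random_terrain(rng, 6, 6, max_height=3, obstruction_p=0.1)
        result = dijkstra(tm, rules, tm.block_at(0, 0), tm.block_at(5, 5))
        if result.reachable:
            total = 0.0
            for u, v in zip(result.blocks, result.blocks[1:]):
                assert is_walkable_edge(tm, rules, u, v)
                total += edge_weight(rules, u, v)
            assert total == pytest.approx(result.distance, abs=1e-9)

    def test_matches_enumeration_on_random_small_grids(self, rules):
        rng = np.random.default_rng(20)
        for _ in range(15):
            w, d = rng.integers(2, 6, size=2)
            tm = random_terrain(rng, int(w), int(d))
            cells = [(x, y) for x in range(tm.width) for y in range(tm.depth)
                     if not tm.obstructed[x, y]]
            if len(cells) < 2:
                continue
            src = cells[rng.integers(len(cells))]
            dst = cells[rng.integers(len(cells))]
            got = dijkstra(tm, rules, tm.block_at(*src),
                           tm.block_at(*dst)).distance
            expected = brute_force_distance(tm, rules, src, dst)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_triangle_inequality(self, rules):
        rng = np.random.default_rng(8)
        tm = random_terrain(rng, 5, 5, max_height=3, obstruction_p=0.1)
        cells = [(x, y) for x in range(5) for y in range(5)
                 if not tm.obstructed[x, y]]
        for _ in range(30):
            a, b, c = (cells[i] for i in rng.integers(len(cells), size=3))
            dab = dijkstra(tm, rules, tm.block_at(*a), tm.block_at(*b)).distance
            dbc = dijkstra(tm, rules, tm.block_at(*b), tm.block_at(*c)).distance
            dac = dijkstra(tm, rules, tm.block_at(*a), tm.block_at(*c)).distance
            assert dac <= dab + dbc + 1e-9

    def test_monotone_in_climb_cost(self, rules):
        rng = np.random.default_rng(13)
        tm = random_terrain(rng, 5, 5, max_height=3, obstruction_p=0.1)
        costly = MovementRules(alpha_up=4.0, alpha_down=1.0)
        cells = [(x, y) for x in range(5) for y in range(5)
                 if not tm.obstructed[x, y]]
        for _ in range(20):
            a, b = (cells[i] for i in rng.integers(len(cells), size=2))
            d1 = dijkstra(tm, rules, tm.block_at(*a), tm.block_at(*b)).distance
            d2 = dijkstra(tm, costly, tm.block_at(*a), tm.block_at(*b)).distance
            assert d2 >= d1 - 1e-9

    def test_reversed_path_swaps_up_and_down(self, rules):
        """Reversing a path exchanges ascents for descents in its cost."""
        rng = np.random.default_rng(3)
        tm = random_terrain(rng, 5, 5, max_height=2, obstruction_p=0.0)
        result = dijkstra(tm, rules, tm.block_at(0, 0), tm.block_at(4, 4))
        forward = sum(edge_weight(rules, u, v)
                      for u, v in zip(result.blocks, result.blocks[1:]))
        # reverse each edge and re-price with the up/down roles swapped
        reverse = 0.0
        for u, v in zip(result.blocks, result.blocks[1:]):
            dz = v.z - u.z
            horiz = SQRT2 if u.x != v.x and u.y != v.y else 1.0
            reverse += horiz + (rules.alpha_down * dz if dz > 0
                                else -rules.alpha_up * dz)
        total_up = sum(max(v.z - u.z, 0)
                       for u, v in zip(result.blocks, result.blocks[1:]))
        total_down = sum(max(u.z - v.z, 0)
                         for u, v in zip(result.blocks, result.blocks[1:]))
        assert forward - reverse == pytest.approx(
            (rules.alpha_up - rules.alpha_down) * (total_up - total_down)
        )


class TestDistanceField:
    def test_field_matches_pairwise_dijkstra(self, rules):
        rng = np.random.default_rng(2)
        tm = random_terrain(rng, 6, 6, max_height=3, obstruction_p=0.15)
        cells = [(x, y) for x in range(6) for y in range(6)
                 if not tm.obstructed[x, y]]
        target = cells[len(cells) // 2]
        field = distance_field_to(tm, rules, tm.block_at(*target))
        assert field[target] == 0.0
        for cell in cells:
            expected = dijkstra(tm, rules, tm.block_at(*cell),
                                tm.block_at(*target)).distance
            assert field[cell] == pytest.approx(expected, abs=1e-9)

    def test_flat_field_is_octile(self, flat_map, rules):
        target = flat_map.block_at(7, 3)
        field = distance_field_to(flat_map, rules, target)
        for x in range(flat_map.width):
            for y in range(flat_map.depth):
                assert field[x, y] == pytest.approx(
                    octile_distance(x - 7, y - 3), abs=1e-9
                )


class TestTerrainMapIO:
    def test_json_round_trip(self, tmp_path, ramp_map):
        path = tmp_path / "terrain.json"
        ramp_map.to_json(path)
        loaded = TerrainMap.from_json(path)
        assert np.array_equal(loaded.elevation, ramp_map.elevation)
        assert np.array_equal(loaded.obstructed, ramp_map.obstructed)

    def test_text_round_trip(self, tmp_path):
        elev = np.array([[1, 2, 3], [4, 5, 6]])  # 2 rows (y), 3 cols (x)
        obst = np.array([[0, 0, 1], [0, 1, 0]])
        (tmp_path / "elev.txt").write_text(
            "\n".join(" ".join(str(v) for v in row) for row in elev)
        )
        (tmp_path / "obst.txt").write_text(
            "\n".join(" ".join(str(v) for v in row) for row in obst)
        )
        tm = TerrainMap.from_text(tmp_path / "elev.txt", tmp_path / "obst.txt")
        assert (tm.width, tm.depth) == (3, 2)
        assert tm.elevation[2, 0] == 3  # x=2, y=0
        assert tm.obstructed[1, 1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TerrainMap(np.ones((3, 3), dtype=np.int64),
                       np.zeros((3, 4), dtype=bool))

    def test_non_integer_elevation_rejected(self):
        with pytest.raises(ValueError):
            TerrainMap(np.full((2, 2), 1.5), np.zeros((2, 2), dtype=bool))
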