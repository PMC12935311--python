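"""Voxel terrain as a weighted directed graph, with Dijkstra path costs.

The world is a rectangular grid of unit cubes ("blocks").  Each (x, y)
cell carries exactly one integer elevation z, so the walkable surface is
a height field.  An agent may step to any of its 8 horizontal neighbors
provided neither cell is obstructed and the elevation change is within
the permitted climb/fall limits.  Each step costs its 2D Euclidean
length plus a vertical surcharge that is larger for ascents than for
descents, which makes the graph *directed*: d(a, b) != d(b, a) in
general on sloped terrain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

SQRT2 = math.sqrt(2.0)

# 8-neighborhood offsets in lexicographic (dx, dy) order; this order is
# also the deterministic tie-break among equal-cost shortest paths.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


class Block(NamedTuple):
    """A unit cube of the world, addressed by integer cell coordinates.

    ``z`` is redundant with the terrain height field (one elevation per
    (x, y) cell) but is carried so that path costs can be computed from
    a block sequence alone.
    """

    x: int
    y: int
    z: int


@dataclass(frozen=True)
class MovementRules:
    """Movement constraints and vertical cost coefficients.

    Parameters
    ----------
    alpha_up, alpha_down
        Cost added per block of ascent / descent on top of the 2D
        Euclidean step length.  Climbing must be strictly costlier than
        descending, and both must add cost (``alpha_up > alpha_down > 0``).
    max_climb
        Largest single-step ascent, in blocks (default 2: an agent
        cannot climb a cliff higher than two blocks).
    max_fall
        Largest single-step descent, in blocks (default 3).
    """

    alpha_up: float = 2.0
    alpha_down: float = 1.0
    max_climb: int = 2
    max_fall: int = 3

    def __post_init__(self) -> None:
        if not (self.alpha_up > self.alpha_down > 0):
            raise ValueError(
                f"require alpha_up > alpha_down > 0, got "
                f"alpha_up={self.alpha_up}, alpha_down={self.alpha_down}"
            )
        if self.max_climb < 0 or self.max_fall < 0:
            raise ValueError("max_climb and max_fall must be non-negative")


@dataclass
class PathResult:
    """Outcome of a single-pair shortest-path query."""

    distance: float
    blocks: list[Block]
    reachable: bool


@dataclass
class TerrainMap:
    """Integer height field plus an obstruction mask.

    ``elevation`` and ``obstructed`` are arrays of shape
    ``(width, depth)`` indexed as ``[x, y]``.  Obstructed cells (water,
    trees, fences, cacti, ...) are not part of the walkable graph.
    """

    elevation: np.ndarray
    obstructed: np.ndarray
    _graph_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation)
        self.obstructed = np.asarray(self.obstructed, dtype=bool)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2D array")
        if self.elevation.shape != self.obstructed.shape:
            raise ValueError(
                f"elevation shape {self.elevation.shape} != obstructed "
                f"shape {self.obstructed.shape}"
            )
        if not np.issubdtype(self.elevation.dtype, np.integer):
            rounded = np.rint(self.elevation)
            if not np.array_equal(rounded, self.elevation):
                raise ValueError("elevation values must be integers (block units)")
            self.elevation = rounded.astype(np.int64)

    @property
    def width(self) -> int:
        return self.elevation.shape[0]

    @property
    def depth(self) -> int:
        return self.elevation.shape[1]

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.depth

    def block_at(self, x: int, y: int) -> Block:
        """The block occupying cell (x, y)."""
        if not self.in_bounds(x, y):
            raise IndexError(f"cell ({x}, {y}) outside {self.width}x{self.depth} map")
        return Block(int(x), int(y), int(self.elevation[x, y]))

    def node_index(self, x: int, y: int) -> int:
        return x * self.depth + y

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        """Write the map as a JSON object with row-major (y-major) lists."""
        obj = {
            "width": self.width,
            "depth": self.depth,
            "elevation": self.elevation.T.reshape(-1).tolist(),
            "obstructed": self.obstructed.T.reshape(-1).astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "TerrainMap":
        obj = json.loads(Path(path).read_text())
        w, d = int(obj["width"]), int(obj["depth"])
        elev = np.asarray(obj["elevation"], dtype=np.int64)
        obst = np.asarray(obj["obstructed"], dtype=bool)
        if elev.size != w * d or obst.size != w * d:
            raise ValueError(
                f"terrain JSON: expected {w * d} cells, got "
                f"{elev.size} elevations / {obst.size} obstruction flags"
            )
        # stored row-major by y (depth rows of width values)
        return cls(elev.reshape(d, w).T, obst.reshape(d, w).T)

    @classmethod
    def from_text(cls, elevation_path: str | Path,
                  obstruction_path: str | Path) -> "TerrainMap":
        """Read delimited text matrices (rows = y, columns = x)."""
        elev = np.loadtxt(elevation_path, dtype=np.int64, ndmin=2)
        obst = np.loadtxt(obstruction_path, dtype=np.int64, ndmin=2)
        if elev.shape != obst.shape:
            raise ValueError(
                f"elevation matrix {elev.shape} and obstruction matrix "
                f"{obst.shape} differ in shape"
            )
        return cls(elev.T, obst.T.astype(bool))


def is_walkable_edge(terrain: TerrainMap, rules: MovementRules,
                     u: Block, v: Block) -> bool:
    """Whether a single step from block ``u`` to block ``v`` is legal.

    The step must (i) connect two unobstructed cells, (ii) move to one
    of the 8 horizontal neighbors, and (iii) keep the elevation change
    within ``[-max_fall, +max_climb]``.  The predicate is directed:
    a legal drop of 3 blocks is an illegal climb on the way back.
    """
    for b in (u, v):
        if not terrain.in_bounds(b.x, b.y):
            raise IndexError(f"block {b} outside {terrain.width}x{terrain.depth} map")
    if terrain.obstructed[u.x, u.y] or terrain.obstructed[v.x, v.y]:
        return False
    dx, dy = v.x - u.x, v.y - u.y
    if (dx, dy) == (0, 0) or abs(dx) > 1 or abs(dy) > 1:
        return False
    dz = v.z - u.z
    return -rules.max_fall <= dz <= rules.max_climb


def edge_weight(rules: MovementRules, u: Block, v: Block) -> float:
    """Cost of one step: 2D Euclidean length plus the vertical surcharge.

    weight = sqrt(dx^2 + dy^2) + alpha_up * max(dz, 0) + alpha_down * max(-dz, 0)

    Flat orthogonal steps cost 1, flat diagonal steps sqrt(2); every
    block of ascent adds ``alpha_up`` and every block of descent adds
    ``alpha_down``, so climbing is costlier than dropping the same way.
    """
    dx, dy, dz = v.x - u.x, v.y - u.y, v.z - u.z
    if (dx, dy) == (0, 0) or abs(dx) > 1 or abs(dy) > 1:
        raise ValueError(f"({u} -> {v}) is not a single-step edge")
    horiz = SQRT2 if dx != 0 and dy != 0 else 1.0
    return horiz + rules.alpha_up * max(dz, 0) + rules.alpha_down * max(-dz, 0)


def octile_distance(dx: float, dy: float) -> float:
    """Closed-form shortest distance on a flat unobstructed 8-grid."""
    adx, ady = abs(dx), abs(dy)
    return max(adx, ady) + (SQRT2 - 1.0) * min(adx, ady)


# ----------------------------------------------------------------------
# graph construction (cached per terrain + rules)
# ----------------------------------------------------------------------

def _build_csgraph(terrain: TerrainMap, rules: MovementRules) -> csr_matrix:
    """Sparse directed adjacency matrix over flattened (x, y) cells."""
    key = (rules.alpha_up, rules.alpha_down, rules.max_climb, rules.max_fall)
    cached = terrain._graph_cache.get(key)
    if cached is not None:
        return cached

    w, d = terrain.width, terrain.depth
    elev = terrain.elevation
    free = ~terrain.obstructed
    rows, cols, data = [], [], []
    for dx, dy in NEIGHBOR_OFFSETS:
        # slices of source cells whose (dx,dy)-neighbor is in bounds
        sx = slice(max(0, -dx), w - max(0, dx))
        sy = slice(max(0, -dy), d - max(0, dy))
        tx = slice(max(0, dx), w + min(0, dx))
        ty = slice(max(0, dy), d + min(0, dy))
        dz = elev[tx, ty] - elev[sx, sy]
        ok = free[sx, sy] & free[tx, ty] & (dz <= rules.max_climb) & (dz >= -rules.max_fall)
        horiz = SQRT2 if dx != 0 and dy != 0 else 1.0
        weight = (horiz
                  + rules.alpha_up * np.maximum(dz, 0)
                  + rules.alpha_down * np.maximum(-dz, 0))
        src_x, src_y = np.nonzero(ok)
        src_x = src_x + sx.start
        src_y = src_y + sy.start
        rows.append(src_x * d + src_y)
        cols.append((src_x + dx) * d + (src_y + dy))
        data.append(weight[ok])
    n = w * d
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    terrain._graph_cache[key] = graph
    return graph


def distance_field_to(terrain: TerrainMap, rules: MovementRules,
                      target: Block) -> np.ndarray:
    """Cost-to-go field: ``field[x, y]`` = Dijkstra distance to ``target``.

    Because edge weights are direction-asymmetric, the field is computed
    by a single-source sweep from the target over the edge-reversed
    graph (the transpose of the adjacency matrix), which yields the cost
    of travelling *toward* the target from every cell.  Unreachable
    cells are ``inf``.
    """
    if not terrain.in_bounds(target.x, target.y):
        raise IndexError(f"target {target} outside map bounds")
    graph = _build_csgraph(terrain, rules)
    dist = _csgraph_dijkstra(graph.T, indices=terrain.node_index(target.x, target.y))
    return dist.reshape(terrain.width, terrain.depth)


def dijkstra(terrain: TerrainMap, rules: MovementRules,
             source: Block, target: Block) -> PathResult:
    """Minimal-cost path from ``source`` to ``target``.

    A textbook binary-heap Dijkstra over the directed walkability graph.
    Ties among equal-cost paths are broken by lexicographic (x, y)
    neighbor order so that results are reproducible.  An unreachable
    target yields ``reachable=False`` and infinite distance rather than
    an exception.
    """
    import heapq

    for b, name in ((source, "source"), (target, "target")):
        if not terrain.in_bounds(b.x, b.y):
            raise IndexError(f"{name} {b} outside map bounds")
    if terrain.obstructed[source.x, source.y] or terrain.obstructed[target.x, target.y]:
        return PathResult(math.inf, [], False)
    if (source.x, source.y) == (target.x, target.y):
        return PathResult(0.0, [terrain.block_at(source.x, source.y)], True)

    elev = terrain.elevation
    obstructed = terrain.obstructed
    w, d = terrain.width, terrain.depth
    dist: dict[tuple[int, int], float] = {(source.x, source.y): 0.0}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    heap: list[tuple[float, tuple[int, int]]] = [(0.0, (source.x, source.y))]
    goal = (target.x, target.y)
    done: set[tuple[int, int]] = set()

    while heap:
        du, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == goal:
            break
        ux, uy = u
        uz = elev[ux, uy]
        for dx, dy in NEIGHBOR_OFFSETS:
            vx, vy = ux + dx, uy + dy
            if not (0 <= vx < w and 0 <= vy < d) or obstructed[vx, vy]:
                continue
            dz = int(elev[vx, vy]) - int(uz)
            if dz > rules.max_climb or dz < -rules.max_fall:
                continue
            horiz = SQRT2 if dx != 0 and dy != 0 else 1.0
            cost = horiz + (rules.alpha_up * dz if dz > 0 else -rules.alpha_down * dz)
            alt = du + cost
            v = (vx, vy)
            if alt < dist.get(v, math.inf) - 1e-15:
                dist[v] = alt
                prev[v] = u
                heapq.heappush(heap, (alt, v))

    if goal not in done:
        return PathResult(math.inf, [], False)
    blocks = [terrain.block_at(*goal)]
    node = goal
    while node != (source.x, source.y):
        node = prev[node]
        blocks.append(terrain.block_at(*node))
    blocks.reverse()
    return PathResult(dist[goal], blocks, True)
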