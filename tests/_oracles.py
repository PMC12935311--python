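"""Independent oracles used by the test suite.

These deliberately avoid the package's own graph machinery: shortest
paths are found by exhaustive depth-first enumeration over simple paths
(with cost-bound pruning, which discards only provably suboptimal
continuations), and spline fits are re-derived from the normal
equations via a pseudoinverse.
"""

from __future__ import annotations

import math

import numpy as np

from voxelnav.terrain import MovementRules, TerrainMap

SQRT2 = math.sqrt(2.0)


def _neighbors(terrain: TerrainMap, rules: MovementRules, x: int, y: int):
    elev = terrain.elevation
    z = int(elev[x, y])
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nx, ny = x + dx, y + dy
            if not (0 <= nx < terrain.width and 0 <= ny < terrain.depth):
                continue
            if terrain.obstructed[nx, ny]:
                continue
            dz = int(elev[nx, ny]) - z
            if dz > rules.max_climb or dz < -rules.max_fall:
                continue
            horiz = SQRT2 if dx and dy else 1.0
            cost = horiz + (rules.alpha_up * dz if dz > 0
                            else -rules.alpha_down * dz)
            yield nx, ny, cost


def brute_force_distance(terrain: TerrainMap, rules: MovementRules,
                         source: tuple[int, int],
                         target: tuple[int, int]) -> float:
    """Minimum cost over all simple paths, by exhaustive DFS.

    Partial paths whose cost already meets the best known total are
    pruned; since edge weights are positive this discards only paths
    that cannot be optimal, so the search remains exhaustive over
    candidates.  Only usable on tiny grids.
    """
    if terrain.obstructed[source] or terrain.obstructed[target]:
        return math.inf
    best = math.inf
    visited = {source}

    def dfs(cell: tuple[int, int], cost: float) -> None:
        nonlocal best
        if cost >= best:
            return
        if cell == target:
            best = cost
            return
        for nx, ny, step in _neighbors(terrain, rules, *cell):
            nxt = (nx, ny)
            if nxt in visited or cost + step >= best:
                continue
            visited.add(nxt)
            dfs(nxt, cost + step)
            visited.remove(nxt)

    dfs(source, 0.0)
    return best


def pinv_spline_coefficients(design: np.ndarray,
                             values: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via the Moore-Penrose pseudoinverse."""
    return np.linalg.pinv(design) @ values


def random_terrain(rng: np.random.Generator, width: int, depth: int,
                   max_height: int = 4,
                   obstruction_p: float = 0.15) -> TerrainMap:
    """A small random integer terrain for oracle comparisons."""
    elevation = rng.integers(0, max_height + 1, size=(width, depth))
    obstructed = rng.random((width, depth)) < obstruction_p
    return TerrainMap(elevation, obstructed)
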