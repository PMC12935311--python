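"""Cost-difference curves: how far a traversal strays from the optimum.

For a segment with samples P(t_0) ... P(t_N) ending at an object, define
at each sample time the *actual cost-to-go*

    A(t_j) = sum_{k=j}^{N-1} c(P(t_k), P(t_{k+1}))

(the cost the participant actually still spends before reaching the
object) and the *optimal cost-to-go*

    O(t_j) = d(P(t_j), P(t_N))

(the Dijkstra distance from the current position to the segment's end).
The cost difference D(t) = A(t) - O(t) is non-negative (no path beats
the shortest path), non-increasing in t (each real step pays at least
as much as it can reduce the optimal cost-to-go, by the triangle
inequality), and exactly zero at the segment end.  An agent that walks
the optimal path has D identically zero; wandering shows up as mass
early (quick correction) or late (prolonged inefficiency) in the curve.

Curves of different durations are made comparable by linearly rescaling
time to a unified interval [0, T_unified] and resampling on a fixed
grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .path_io import Segment, snap_to_block
from .terrain import (
    Block,
    MovementRules,
    TerrainMap,
    dijkstra,
    distance_field_to,
    edge_weight,
    is_walkable_edge,
)

logger = logging.getLogger(__name__)

DEFAULT_T_UNIFIED = 100.0
DEFAULT_GRID_SIZE = 101


class UnreachableStepError(RuntimeError):
    """A consecutive pair of samples has no connecting path."""


@dataclass
class CostCurve:
    """Cost difference D(t) on the segment's own time axis."""

    times: np.ndarray
    values: np.ndarray
    segment: Segment | None = None
    optimal_cost: float = np.nan  # d(start, end): the segment's intrinsic difficulty
    actual_cost: float = np.nan   # total cost actually paid

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class NormalizedCurve:
    """D resampled on a fixed grid over the unified time interval."""

    grid: np.ndarray
    values: np.ndarray
    source_duration: float
    segment: Segment | None = None
    optimal_cost: float = np.nan
    meta: dict = field(default_factory=dict)


def step_cost(terrain: TerrainMap, rules: MovementRules,
              p: tuple[float, float], q: tuple[float, float]) -> float:
    """Cost of moving between two recorded positions one sample apart.

    Identical snapped blocks cost 0; a walkable edge costs its edge
    weight; anything else (the player covered more than one cell in a
    second, or took a non-edge transition) is charged the Dijkstra
    distance between the snapped blocks, which preserves the triangle
    inequality the curve invariants rely on.
    """
    bu = snap_to_block(terrain, p[0], p[1])
    bv = snap_to_block(terrain, q[0], q[1])
    return _block_step_cost(terrain, rules, bu, bv)


def _block_step_cost(terrain: TerrainMap, rules: MovementRules,
                     bu: Block, bv: Block) -> float:
    if (bu.x, bu.y) == (bv.x, bv.y):
        return 0.0
    if is_walkable_edge(terrain, rules, bu, bv):
        return edge_weight(rules, bu, bv)
    result = dijkstra(terrain, rules, bu, bv)
    if not result.reachable:
        raise UnreachableStepError(f"no path between consecutive samples {bu} -> {bv}")
    return result.distance


def cost_difference_curve(terrain: TerrainMap, rules: MovementRules,
                          segment: Segment,
                          distance_field: np.ndarray | None = None) -> CostCurve:
    """Compute D(t) = A(t) - O(t) for one segment.

    ``distance_field`` may carry a precomputed cost-to-go field for the
    segment's end block (as from :func:`distance_field_to`); passing it
    avoids recomputing the field when many segments share a target.

    Raises
    ------
    UnreachableStepError
        If any consecutive sample pair has no connecting path; callers
        exclude and count such segments.
    """
    xs = segment.samples["x"].to_numpy(dtype=float)
    ys = segment.samples["y"].to_numpy(dtype=float)
    ts = segment.samples["t"].to_numpy(dtype=float)
    n = len(ts)
    blocks = [snap_to_block(terrain, xs[j], ys[j]) for j in range(n)]

    end = blocks[-1]
    if distance_field is None:
        distance_field = distance_field_to(terrain, rules, end)
    optimal = np.array([distance_field[b.x, b.y] for b in blocks])
    if not np.isfinite(optimal).all():
        raise UnreachableStepError(
            f"segment {segment.participant_id}/{segment.session_id} "
            f"#{segment.index}: some samples cannot reach the end block {end}"
        )

    step = np.zeros(n - 1) if n > 1 else np.zeros(0)
    for j in range(n - 1):
        step[j] = _block_step_cost(terrain, rules, blocks[j], blocks[j + 1])
    # actual cost-to-go: reverse cumulative sum of step costs
    actual = np.concatenate([np.cumsum(step[::-1])[::-1], [0.0]])

    values = actual - optimal
    # clip away negative round-off; genuine violations would be a bug
    values = np.maximum(values, 0.0)
    return CostCurve(
        times=ts,
        values=values,
        segment=segment,
        optimal_cost=float(optimal[0]),
        actual_cost=float(actual[0]),
    )


def normalize_curve(curve: CostCurve | NormalizedCurve,
                    t_unified: float = DEFAULT_T_UNIFIED,
                    grid_size: int = DEFAULT_GRID_SIZE) -> NormalizedCurve:
    """Rescale a curve's time axis to [0, t_unified] and resample.

    Linear interpolation on the rescaled axis; endpoint values are
    preserved exactly and monotone non-increase survives interpolation.
    Applying the operation to an already-normalized curve on the same
    grid is the identity.
    """
    if isinstance(curve, NormalizedCurve):
        times = curve.grid
        values = curve.values
        duration = curve.source_duration
        segment = curve.segment
        optimal_cost = curve.optimal_cost
    else:
        times = curve.times
        values = curve.values
        duration = curve.duration
        segment = curve.segment
        optimal_cost = curve.optimal_cost
    if len(times) < 2:
        raise ValueError("cannot normalize a curve with fewer than 2 points")
    span = float(times[-1] - times[0])
    if span <= 0:
        raise ValueError("degenerate segment: zero duration")
    grid = np.linspace(0.0, t_unified, grid_size)
    rescaled = (np.asarray(times, dtype=float) - times[0]) * (t_unified / span)
    rescaled[-1] = t_unified  # guard against round-off at the right endpoint
    interpolated = np.interp(grid, rescaled, values)
    return NormalizedCurve(
        grid=grid,
        values=interpolated,
        source_duration=duration,
        segment=segment,
        optimal_cost=optimal_cost,
    )


def curves_for_segments(terrain: TerrainMap, rules: MovementRules,
                        segments: list[Segment],
                        t_unified: float = DEFAULT_T_UNIFIED,
                        grid_size: int = DEFAULT_GRID_SIZE,
                        ) -> tuple[list[NormalizedCurve], list[Segment]]:
    """Normalized curves for a batch of segments, sharing distance fields.

    Returns the computed curves and the list of segments excluded
    because of unreachable steps (counted, never silently dropped).
    """
    field_cache: dict[tuple[int, int], np.ndarray] = {}
    curves: list[NormalizedCurve] = []
    excluded: list[Segment] = []
    for seg in segments:
        last = seg.samples.iloc[-1]
        end = snap_to_block(terrain, float(last["x"]), float(last["y"]))
        key = (end.x, end.y)
        if key not in field_cache:
            field_cache[key] = distance_field_to(terrain, rules, end)
        try:
            curve = cost_difference_curve(terrain, rules, seg, field_cache[key])
        except UnreachableStepError as exc:
            logger.warning("excluding segment: %s", exc)
            excluded.append(seg)
            continue
        curves.append(normalize_curve(curve, t_unified, grid_size))
    return curves, excluded
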