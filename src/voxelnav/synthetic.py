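"""Synthetic terrains, agents, and cohorts for exercising the pipeline.

The study this package serves recorded people exploring a voxel world
(two 10-minute training sessions to find 12 hidden objects at 1 Hz
position sampling, then a placement test with randomized edge starts).
No such data ship with the package, so this module generates stand-ins
with known ground truth at every level:

* terrains — smoothed integer height fields with random obstructions,
  regenerated until the object cells are mutually reachable;
* agents — lattice walkers with four qualitative navigation styles
  (direct, corrective, prolonged wanderer, late adapter) whose
  cost-difference curves mirror the four empirically observed cluster
  shapes;
* archetype curves — noisy draws around the four idealized curve
  shapes, for planted-partition clustering checks;
* cohorts — full multi-participant datasets whose test outcomes follow
  the scalar-on-functional generative model, so regression recovery
  can be verified against known coefficients.

All randomness flows from a single master seed through named
sub-streams, so identical configurations reproduce identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .clustering import SplineBasis
from .cost_curves import (
    DEFAULT_GRID_SIZE,
    DEFAULT_T_UNIFIED,
    NormalizedCurve,
    curves_for_segments,
)
from .path_io import EventLog, TrackedPath, segment_training_path
from .sofr import (
    DEFAULT_COST_CUTOFF,
    ParticipantFeatures,
    classify_segment,
)
from .terrain import (
    NEIGHBOR_OFFSETS,
    MovementRules,
    TerrainMap,
    _build_csgraph,
    distance_field_to,
)

STYLES = ("direct", "corrective", "prolonged_wanderer", "late_adapter")

SEX_LEVELS = ("female", "male", "other")
SEX_PROBS = (0.50, 0.45, 0.05)
EXPERIENCE_LEVELS = ("both", "first_person", "third_person", "neither")
EXPERIENCE_PROBS = (0.35, 0.30, 0.20, 0.15)
SKILL_LEVELS = ("Expert", "Intermediate", "Novice")
SKILL_PROBS = (0.30, 0.45, 0.25)


@dataclass(frozen=True)
class AgentPolicy:
    """One of the four qualitative navigation styles.

    ``detour_prob`` applies to the corrective style (chance of a random
    sidestep instead of the optimal step); ``wander_frac`` is the
    fraction of a segment's total time the wandering styles spend
    random-walking before locking onto the optimal path; ``goal_bias``
    is the chance a wandering step follows the optimal direction
    anyway.
    """

    style: str = "direct"
    detour_prob: float = 0.30
    wander_frac: float = 0.30
    goal_bias: float = 0.08

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}; choose from {STYLES}")


@dataclass
class SynthConfig:
    """Study-scale defaults for the synthetic cohort generator.

    The fixed quantities mirror the emulated study design: 12 hidden
    objects, 1 Hz sampling, a 600 s cap per training session, two
    training sessions, four environments.  Free quantities (map size,
    terrain roughness, obstruction fraction, style mixture, generative
    regression coefficients) are package choices documented in the
    methods note.
    """

    width: int = 64
    depth: int = 64
    roughness: float = 2.5
    obstruction_fraction: float = 0.10
    n_objects: int = 12
    n_participants: int = 50
    n_environments: int = 4
    session_cap: float = 600.0
    n_sessions: int = 2
    policy_weights: tuple[float, float, float, float] = (0.55, 0.25, 0.10, 0.10)
    style_concentration: float = 10.0
    memory_error_scale: float = 4.0
    t_unified: float = DEFAULT_T_UNIFIED
    grid_size: int = DEFAULT_GRID_SIZE
    cutoff: float = DEFAULT_COST_CUTOFF
    gammas: dict = dc_field(default_factory=lambda: {
        "Y1": {"intercept": 8.0, "sex[male]": 1.0,
               "minecraft_skill[Intermediate]": -1.3,
               "minecraft_skill[Novice]": -1.7},
        "Y2": {"intercept": 30.0, "removed_curve_count": -2.7,
               "average_segment_time": 1.0},
        "Y3": {"intercept": 4.0, "minecraft_skill[Novice]": 1.25,
               "cluster2_proportion": -3.2},
    })
    beta_amplitudes: dict = dc_field(default_factory=lambda: {
        "Y1": 0.0, "Y2": 0.0, "Y3": -0.02,
    })
    sigmas: dict = dc_field(default_factory=lambda: {
        "Y1": 1.5, "Y2": 10.0, "Y3": 1.0,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.policy_weights) - 1.0) > 1e-9:
            raise ValueError("policy_weights must sum to 1")
        if self.obstruction_fraction >= 0.5:
            raise ValueError(
                "obstruction_fraction must be < 0.5 to keep maps connected"
            )
        for name in ("width", "depth", "n_objects", "n_participants",
                     "n_environments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def beta_curve(self, label: str, grid: np.ndarray) -> np.ndarray:
        """True functional coefficient for an outcome on a time grid.

        A smooth bump concentrated in the final fifth of the segment,
        scaled by the configured amplitude — late-segment behavior is
        where the functional effect is placed.
        """
        amp = self.beta_amplitudes.get(label, 0.0)
        t = np.asarray(grid, dtype=float)
        return amp * np.exp(-0.5 * ((t - 0.9 * self.t_unified) / (0.12 * self.t_unified)) ** 2)


@dataclass
class Environment:
    """One generated game environment with its object layout."""

    terrain: TerrainMap
    objects: dict[str, tuple[int, int]]
    start: tuple[int, int]
    test_starts: list[tuple[int, int]]


@dataclass
class Cohort:
    """A fully generated synthetic study."""

    config: SynthConfig
    environments: dict[str, Environment]
    paths: list[TrackedPath]
    train_logs: list[EventLog]
    test_logs: list[EventLog]
    covariates: pd.DataFrame
    outcomes: pd.DataFrame          # generative Y1/Y2/Y3 per participant
    features: list[ParticipantFeatures]
    curves: list[NormalizedCurve]
    curve_styles: list[str]         # generating style per curve
    curve_meta: pd.DataFrame
    true_beta: dict[str, np.ndarray]
    n_excluded_segments: int = 0


# ----------------------------------------------------------------------
# terrain
# ----------------------------------------------------------------------

def generate_terrain(config: SynthConfig, seed: int) -> TerrainMap:
    """Smoothed integer height field plus a random obstruction mask.

    Elevation is Gaussian-smoothed white noise scaled to roughly
    ``roughness`` blocks of standard deviation, rounded to integers and
    shifted positive.  Zero roughness gives a flat map; zero
    obstruction fraction leaves every cell walkable.
    """
    rng = np.random.default_rng(seed)
    w, d = config.width, config.depth
    if config.roughness > 0:
        noise = gaussian_filter(rng.standard_normal((w, d)), sigma=3.0,
                                mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * config.roughness
        elevation = np.rint(noise).astype(np.int64)
    else:
        elevation = np.zeros((w, d), dtype=np.int64)
    elevation = elevation - elevation.min() + 1  # positive block heights
    obstructed = rng.random((w, d)) < config.obstruction_fraction
    return TerrainMap(elevation, obstructed)


def _mutual_core(terrain: TerrainMap, rules: MovementRules) -> np.ndarray:
    """Mask of cells mutually reachable with a central reference cell."""
    free_x, free_y = np.nonzero(~terrain.obstructed)
    if len(free_x) == 0:
        return np.zeros((terrain.width, terrain.depth), dtype=bool)
    cx, cy = terrain.width / 2, terrain.depth / 2
    k = np.argmin((free_x - cx) ** 2 + (free_y - cy) ** 2)
    ref = terrain.node_index(int(free_x[k]), int(free_y[k]))
    graph = _build_csgraph(terrain, rules)
    from_ref = _csgraph_dijkstra(graph, indices=ref).reshape(terrain.width, -1)
    to_ref = _csgraph_dijkstra(graph.T, indices=ref).reshape(terrain.width, -1)
    return np.isfinite(from_ref) & np.isfinite(to_ref)


def generate_environment(config: SynthConfig, rules: MovementRules,
                         seed: int, max_retries: int = 50) -> Environment:
    """A terrain with mutually reachable objects, start, and test starts.

    Terrains are regenerated under fresh sub-seeds until the mutually
    reachable core covers at least half the map and can host all object
    cells; object cells are drawn with a minimum pairwise spacing when
    possible so layouts resemble spread-out hiding spots.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        terrain = generate_terrain(config, int(rng.integers(2**31 - 1)))
        core = _mutual_core(terrain, rules)
        if core.sum() < 0.5 * terrain.width * terrain.depth:
            continue
        xs, ys = np.nonzero(core)
        cells = list(zip(xs.tolist(), ys.tolist()))
        if len(cells) < config.n_objects + 5:
            continue
        objects = _spread_sample(cells, config.n_objects, rng,
                                 min_sep=max(2, min(config.width, config.depth) // 6))
        if objects is None:
            continue
        cx, cy = terrain.width / 2, terrain.depth / 2
        start = min(cells, key=lambda c: (c[0] - cx) ** 2 + (c[1] - cy) ** 2)
        edge_targets = [(cx, 0), (cx, terrain.depth - 1), (0, cy),
                        (terrain.width - 1, cy)]
        test_starts = [
            min(cells, key=lambda c: (c[0] - ex) ** 2 + (c[1] - ey) ** 2)
            for ex, ey in edge_targets
        ]
        return Environment(
            terrain=terrain,
            objects={f"obj{i:02d}": cell for i, cell in enumerate(objects)},
            start=start,
            test_starts=test_starts,
        )
    raise RuntimeError(
        f"could not generate a sufficiently connected terrain in "
        f"{max_retries} attempts"
    )


def _spread_sample(cells: list[tuple[int, int]], n: int,
                   rng: np.random.Generator,
                   min_sep: int) -> list[tuple[int, int]] | None:
    for sep in range(min_sep, 0, -1):
        chosen: list[tuple[int, int]] = []
        order = rng.permutation(len(cells))
        for idx in order:
            c = cells[idx]
            if all(max(abs(c[0] - o[0]), abs(c[1] - o[1])) >= sep for o in chosen):
                chosen.append(c)
                if len(chosen) == n:
                    return chosen
    return None


# ----------------------------------------------------------------------
# agents
# ----------------------------------------------------------------------

def _walkable_neighbors(terrain: TerrainMap, rules: MovementRules,
                        x: int, y: int) -> list[tuple[int, int, float]]:
    out = []
    elev = terrain.elevation
    z = int(elev[x, y])
    for dx, dy in NEIGHBOR_OFFSETS:
        nx, ny = x + dx, y + dy
        if not terrain.in_bounds(nx, ny) or terrain.obstructed[nx, ny]:
            continue
        dz = int(elev[nx, ny]) - z
        if dz > rules.max_climb or dz < -rules.max_fall:
            continue
        horiz = math.sqrt(2.0) if dx and dy else 1.0
        cost = horiz + (rules.alpha_up * dz if dz > 0 else -rules.alpha_down * dz)
        out.append((nx, ny, cost))
    return out


def _greedy_step(terrain: TerrainMap, rules: MovementRules,
                 field: np.ndarray, x: int, y: int) -> tuple[int, int]:
    """The optimal next step toward the field's target (lexicographic ties)."""
    best = None
    best_val = math.inf
    for nx, ny, cost in _walkable_neighbors(terrain, rules, x, y):
        val = cost + field[nx, ny]
        if val < best_val - 1e-12:
            best_val = val
            best = (nx, ny)
    if best is None or not math.isfinite(best_val):
        raise RuntimeError(f"no walkable step toward target from ({x}, {y})")
    return best


def _wander_step(terrain: TerrainMap, rules: MovementRules,
                 field: np.ndarray, x: int, y: int,
                 goal_bias: float, away_bias: float,
                 rng: np.random.Generator) -> tuple[int, int]:
    """One non-optimal step: goal-directed, away-directed, or uniform.

    ``away_bias`` is the chance of stepping toward *increasing*
    cost-to-go, which burns cost quickly (the step is paid and the
    optimal remainder grows); uniform wandering burns slowly.
    """
    r = rng.random()
    if r < goal_bias:
        return _greedy_step(terrain, rules, field, x, y)
    options = [
        (nx, ny) for nx, ny, _ in _walkable_neighbors(terrain, rules, x, y)
        if math.isfinite(field[nx, ny])
    ]
    if not options:
        return _greedy_step(terrain, rules, field, x, y)
    if r < goal_bias + away_bias:
        return max(options, key=lambda c: field[c])
    return options[rng.integers(len(options))]


def simulate_training_session(
    terrain: TerrainMap,
    rules: MovementRules,
    objects: dict[str, tuple[int, int]],
    policy,
    seed: int,
    start: tuple[int, int],
    participant_id: str = "p000",
    session_id: str = "training1",
    session_cap: float = 600.0,
    field_cache: dict | None = None,
) -> tuple[TrackedPath, EventLog, list[str]]:
    """Simulate one training session of object search at 1 Hz.

    The agent visits objects in nearest-next order (by cost-to-go,
    occasionally swapping in the second-nearest), moving one cell per
    second.  How it moves toward the current target depends on the
    policy style:

    * ``direct`` walks the optimal (Dijkstra) path;
    * ``corrective`` takes the optimal step but with probability
      ``detour_prob`` sidesteps randomly and then re-plans;
    * ``late_adapter`` random-walks (weak goal bias) for roughly
      ``wander_frac`` of the segment's eventual duration, then follows
      the optimal path;
    * ``prolonged_wanderer`` does the same with a large wander
      fraction, staying inefficient past the segment midpoint.

    ``policy`` is an :class:`AgentPolicy` or a callable
    ``rng -> AgentPolicy`` drawn fresh per segment.  The session is
    truncated at ``session_cap`` seconds; objects not yet found produce
    no event.  Returns the 1 Hz trajectory, the event log, and the
    style used for each completed segment.
    """
    rng = np.random.default_rng(seed)
    if field_cache is None:
        field_cache = {}

    def field_to(cell: tuple[int, int]) -> np.ndarray:
        if cell not in field_cache:
            field_cache[cell] = distance_field_to(
                terrain, rules, terrain.block_at(*cell)
            )
        return field_cache[cell]

    x, y = start
    t = 0
    times = [0.0]
    xs = [x + 0.5]
    ys = [y + 0.5]
    zs = [float(terrain.elevation[x, y])]
    events = [{"t": 0.0, "kind": "session_start", "object_id": "",
               "x": x + 0.5, "y": y + 0.5, "z": zs[0]}]
    styles: list[str] = []

    remaining = dict(objects)
    cap = int(session_cap)
    while remaining and t < cap:
        seg_policy = policy(rng) if callable(policy) else policy
        # nearest-next target, occasionally the second nearest
        dists = sorted(
            ((field_to(cell)[x, y], oid) for oid, cell in remaining.items())
        )
        pick = 1 if len(dists) > 1 and rng.random() < 0.2 else 0
        _, oid = dists[pick]
        target = remaining.pop(oid)
        fld = field_to(target)

        opt_steps = max(3, max(abs(target[0] - x), abs(target[1] - y)))
        detour_prob = 0.0
        away_bias = 0.0
        if seg_policy.style == "direct":
            wander_budget = 0
        elif seg_policy.style == "corrective":
            # a short guaranteed excursion plus occasional detours keeps
            # every corrective segment visibly but moderately inefficient
            away_bias = 0.4
            wander_budget = 8
            detour_prob = 0.25
        elif seg_policy.style == "late_adapter":
            # away-biased excursion: drop completed before the midpoint
            # with an amplitude well above corrective's; the step floor
            # keeps short segments distinguishable
            away_bias = 0.7
            wander_budget = 40
        else:  # prolonged_wanderer: slow-burn uniform wander, drop late
            away_bias = 0.0
            wander_budget = 115

        steps_in_segment = 0
        detours_done = 0
        max_detours = 8
        while (x, y) != target and t < cap:
            if steps_in_segment < wander_budget:
                nx, ny = _wander_step(terrain, rules, fld, x, y,
                                      seg_policy.goal_bias, away_bias, rng)
            elif (seg_policy.style == "corrective"
                  and detours_done < max_detours
                  and rng.random() < detour_prob):
                nx, ny = _wander_step(terrain, rules, fld, x, y, 0.0, 0.0, rng)
                detours_done += 1
            else:
                nx, ny = _greedy_step(terrain, rules, fld, x, y)
            x, y = nx, ny
            t += 1
            steps_in_segment += 1
            times.append(float(t))
            xs.append(x + 0.5)
            ys.append(y + 0.5)
            zs.append(float(terrain.elevation[x, y]))
        if (x, y) == target:
            events.append({"t": float(t), "kind": "object_found",
                           "object_id": oid, "x": x + 0.5, "y": y + 0.5,
                           "z": float(terrain.elevation[x, y])})
            styles.append(seg_policy.style)

    path = TrackedPath(
        participant_id, session_id,
        pd.DataFrame({"t": times, "x": xs, "y": ys, "z": zs}),
    )
    log = EventLog(participant_id, session_id, pd.DataFrame(events))
    return path, log, styles


def simulate_test_session(
    terrain: TerrainMap,
    rules: MovementRules,
    objects: dict[str, tuple[int, int]],
    memory_error_scale: float,
    seed: int,
    test_starts: list[tuple[int, int]],
    participant_id: str = "p000",
    session_id: str = "test",
    trial_cap: float = 180.0,
) -> EventLog:
    """Simulate the placement test: one trial per object, randomized order.

    Each trial teleports the agent to a random edge start, then records
    a placement at the true object cell displaced by a Gaussian kernel
    of scale ``memory_error_scale`` (zero scale places every object
    exactly).  Placement times are entry-to-placement intervals drawn
    from a shifted exponential capped at the 3-minute trial limit.
    """
    rng = np.random.default_rng(seed)
    events = []
    clock = 0.0
    order = rng.permutation(sorted(objects))
    for oid in order:
        ox, oy = objects[oid]
        sx, sy = test_starts[rng.integers(len(test_starts))]
        events.append({"t": clock, "kind": "trial_start", "object_id": oid,
                       "x": sx + 0.5, "y": sy + 0.5,
                       "z": float(terrain.elevation[sx, sy])})
        if memory_error_scale > 0:
            for _ in range(100):
                px = int(round(ox + rng.normal(0, memory_error_scale)))
                py = int(round(oy + rng.normal(0, memory_error_scale)))
                px = min(max(px, 0), terrain.width - 1)
                py = min(max(py, 0), terrain.depth - 1)
                if not terrain.obstructed[px, py]:
                    break
            else:
                px, py = ox, oy
        else:
            px, py = ox, oy
        duration = min(10.0 + rng.exponential(30.0), trial_cap)
        clock += duration
        events.append({"t": clock, "kind": "object_placed", "object_id": oid,
                       "x": px + 0.5, "y": py + 0.5,
                       "z": float(terrain.elevation[px, py])})
        clock += 1.0  # teleport to the next trial
    return EventLog(participant_id, session_id, pd.DataFrame(events))


# ----------------------------------------------------------------------
# archetype curves (planted-partition material for clustering checks)
# ----------------------------------------------------------------------

ARCHETYPE_WEIGHTS = (0.45, 0.30, 0.125, 0.125)


def archetype_mean(style: str, grid: np.ndarray,
                   t_max: float = DEFAULT_T_UNIFIED) -> np.ndarray:
    """Idealized cost-difference shape for one navigation style.

    * ``direct`` — identically zero (optimal navigation);
    * ``corrective`` — shallow, roughly linear decline;
    * ``prolonged_wanderer`` — high until late, dropping after ~75%;
    * ``late_adapter`` — sharp drop completed before the midpoint.
    """
    s = np.asarray(grid, dtype=float) / t_max
    if style == "direct":
        return np.zeros_like(s)
    if style == "corrective":
        return 30.0 * (1.0 - s)
    if style == "prolonged_wanderer":
        return 80.0 / (1.0 + np.exp((s - 0.80) / 0.06))
    if style == "late_adapter":
        return 80.0 / (1.0 + np.exp((s - 0.25) / 0.06))
    raise ValueError(f"unknown style {style!r}")


def generate_archetype_curves(
    n_curves: int,
    seed: int,
    weights: tuple[float, ...] = ARCHETYPE_WEIGHTS,
    noise_sd: float = 3.0,
    amplitude_sd: float = 0.15,
    t_unified: float = DEFAULT_T_UNIFIED,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[list[NormalizedCurve], np.ndarray]:
    """Noisy curves drawn around the four archetype shapes.

    Each curve picks a style from ``weights``, scales the style's mean
    shape by a log-normal amplitude factor (sd ``amplitude_sd`` on the
    log scale), and adds smooth noise of sd ``noise_sd`` that vanishes
    at the segment end (curves end at zero by construction).  Returns
    the curves and the 0-based style index of each.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, t_unified, grid_size)
    labels = rng.choice(len(weights), size=n_curves, p=np.asarray(weights))
    envelope = np.sqrt(np.clip(1.0 - grid / t_unified, 0.0, 1.0))
    curves = []
    for lab in labels:
        mean = archetype_mean(STYLES[lab], grid, t_unified)
        amp = float(np.exp(rng.normal(0.0, amplitude_sd)))
        smooth = gaussian_filter(rng.standard_normal(grid_size), sigma=5.0,
                                 mode="reflect")
        values = np.clip(amp * mean + noise_sd * smooth * envelope, 0.0, None)
        values[-1] = 0.0
        curves.append(NormalizedCurve(
            grid=grid, values=values, source_duration=float(t_unified),
            optimal_cost=30.0,
        ))
    return curves, labels


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------

def _draw_covariates(rng: np.random.Generator, pid: str, env: str) -> dict:
    return {
        "age": int(rng.integers(18, 41)),
        "sex": str(rng.choice(SEX_LEVELS, p=SEX_PROBS)),
        "game_experience": str(rng.choice(EXPERIENCE_LEVELS, p=EXPERIENCE_PROBS)),
        "minecraft_skill": str(rng.choice(SKILL_LEVELS, p=SKILL_PROBS)),
        "weekly_gaming_hours": float(np.round(rng.exponential(5.0), 1)),
        "environment": env,
    }


def _linear_predictor(gamma: dict[str, float], covariates: dict,
                      derived: dict[str, float]) -> float:
    """Evaluate a named-coefficient linear predictor on one participant.

    Keys are either numeric feature names (``age``,
    ``removed_curve_count``, ...) or indicator terms written
    ``covariate[level]``.
    """
    total = 0.0
    for key, coef in gamma.items():
        if key == "intercept":
            total += coef
        elif "[" in key:
            name, level = key[:-1].split("[")
            value = covariates.get(name, derived.get(name))
            total += coef * float(str(value) == level)
        else:
            value = covariates.get(key, derived.get(key))
            if value is None:
                raise KeyError(f"unknown generative coefficient {key!r}")
            total += coef * float(value)
    return total


def generate_cohort(config: SynthConfig,
                    rules: MovementRules | None = None) -> Cohort:
    """Generate a complete synthetic study with known ground truth.

    Participants are spread over the environments; each completes two
    training sessions whose per-segment navigation styles are drawn
    from a participant-specific mixture (a Dirichlet tilt of the
    configured global weights) and one placement test.  The three test
    outcomes are generated from the scalar-on-functional model

        y_i = z_i' gamma + int X_i(t) beta(t) dt + N(0, sigma^2)

    using the participant's own simulated mean low-cost curve as
    X_i(t), so the downstream regression can be checked against the
    generating coefficients.  Cluster-proportion terms in ``gammas``
    refer to the participant's generating style mixture shares.
    """
    rules = rules or MovementRules()
    master = np.random.default_rng(config.seed)
    env_seed, agent_seed, outcome_seed = master.integers(2**31 - 1, size=3)

    env_rng = np.random.default_rng(env_seed)
    environments = {
        f"env{e + 1}": generate_environment(
            config, rules, int(env_rng.integers(2**31 - 1))
        )
        for e in range(config.n_environments)
    }
    field_caches: dict[str, dict] = {name: {} for name in environments}

    agent_rng = np.random.default_rng(agent_seed)
    outcome_rng = np.random.default_rng(outcome_seed)
    grid = np.linspace(0.0, config.t_unified, config.grid_size)
    true_beta = {k: config.beta_curve(k, grid) for k in ("Y1", "Y2", "Y3")}

    paths: list[TrackedPath] = []
    train_logs: list[EventLog] = []
    test_logs: list[EventLog] = []
    cov_rows: list[dict] = []
    outcome_rows: list[dict] = []
    features: list[ParticipantFeatures] = []
    all_curves: list[NormalizedCurve] = []
    all_styles: list[str] = []
    meta_rows: list[dict] = []
    n_excluded = 0

    env_names = sorted(environments)
    for i in range(config.n_participants):
        pid = f"p{i:03d}"
        env_name = env_names[i % len(env_names)]
        env = environments[env_name]
        covs = _draw_covariates(agent_rng, pid, env_name)
        cov_rows.append({"participant_id": pid, **covs})

        mixture = agent_rng.dirichlet(
            config.style_concentration * np.asarray(config.policy_weights)
        )

        def draw_policy(rng: np.random.Generator) -> AgentPolicy:
            return AgentPolicy(style=STYLES[rng.choice(4, p=mixture)])

        participant_curves: list[NormalizedCurve] = []
        participant_styles: list[str] = []
        for s in range(config.n_sessions):
            sid = f"training{s + 1}"
            path, log, styles = simulate_training_session(
                env.terrain, rules, env.objects, draw_policy,
                int(agent_rng.integers(2**31 - 1)), env.start,
                participant_id=pid, session_id=sid,
                session_cap=config.session_cap,
                field_cache=field_caches[env_name],
            )
            paths.append(path)
            train_logs.append(log)
            segments = segment_training_path(path, log, environment=env_name)
            curves, excluded = curves_for_segments(
                env.terrain, rules, segments,
                config.t_unified, config.grid_size,
            )
            n_excluded += len(excluded)
            participant_curves.extend(curves)
            participant_styles.extend(styles[:len(curves)])
            for c in curves:
                meta_rows.append({
                    "participant_id": pid, "session_id": sid,
                    "environment": env_name,
                    "segment_index": c.segment.index,
                    "is_first": c.segment.is_first,
                    "is_last": c.segment.is_last,
                    "optimal_cost": c.optimal_cost,
                    "duration": c.source_duration,
                })

        test_logs.append(simulate_test_session(
            env.terrain, rules, env.objects, config.memory_error_scale,
            int(agent_rng.integers(2**31 - 1)), env.test_starts,
            participant_id=pid,
        ))

        all_curves.extend(participant_curves)
        all_styles.extend(participant_styles)

        low = [c for c in participant_curves
               if classify_segment(c.optimal_cost, config.cutoff) == "low"]
        removed = len(participant_curves) - len(low)
        mean_curve = (np.mean([c.values for c in low], axis=0)
                      if low else None)
        avg_time = (float(np.mean([c.source_duration
                                   for c in participant_curves]))
                    if participant_curves else 0.0)
        derived = {
            "removed_curve_count": removed,
            "average_segment_time": avg_time,
            "cluster2_proportion": float(mixture[1]),
            "cluster3_proportion": float(mixture[2]),
            "cluster4_proportion": float(mixture[3]),
        }
        features.append(ParticipantFeatures(
            participant_id=pid, covariates=covs,
            removed_curve_count=removed,
            cluster_proportions={2: derived["cluster2_proportion"],
                                 3: derived["cluster3_proportion"],
                                 4: derived["cluster4_proportion"]},
            average_segment_time=avg_time,
            mean_curve=mean_curve, grid=grid if low else None,
            n_segments=len(participant_curves), n_low_cost=len(low),
        ))

        out_row = {"participant_id": pid}
        for label in ("Y1", "Y2", "Y3"):
            lin = _linear_predictor(config.gammas.get(label, {}), covs, derived)
            if mean_curve is not None:
                lin += float(np.trapezoid(mean_curve * true_beta[label], grid))
            out_row[label] = lin + outcome_rng.normal(
                0.0, config.sigmas.get(label, 1.0)
            )
        outcome_rows.append(out_row)

    return Cohort(
        config=config,
        environments=environments,
        paths=paths,
        train_logs=train_logs,
        test_logs=test_logs,
        covariates=pd.DataFrame(cov_rows),
        outcomes=pd.DataFrame(outcome_rows),
        features=features,
        curves=all_curves,
        curve_styles=all_styles,
        curve_meta=pd.DataFrame(meta_rows),
        true_beta=true_beta,
        n_excluded_segments=n_excluded,
    )


# ----------------------------------------------------------------------
# direct SoFR datasets (regression recovery without agent simulation)
# ----------------------------------------------------------------------

def generate_sofr_dataset(
    n: int,
    seed: int,
    gamma: dict[str, float] | None = None,
    beta_fn=None,
    sigma: float = 1.0,
    t_unified: float = DEFAULT_T_UNIFIED,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[list[ParticipantFeatures], np.ndarray, dict[str, float], np.ndarray]:
    """Draw participants straight from the regression generative model.

    Functional predictors are random smooth non-negative curves (Gamma
    spline coefficients on a 10-function basis); scalar covariates are
    a compact set (age z-score, sex, removed curve count, cluster
    shares, average segment time).  Outcomes follow

        y_i = z_i' gamma + int X_i(t) beta(t) dt + N(0, sigma^2).

    Returns features, outcomes, the generating gamma (by design-column
    name), and the true beta evaluated on the grid.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, t_unified, grid_size)
    if gamma is None:
        gamma = {"intercept": 5.0, "age": 0.8, "sex[male]": 1.2,
                 "removed_curve_count": -0.5, "average_segment_time": 0.05,
                 "cluster2_proportion": 2.0, "cluster3_proportion": 0.0,
                 "cluster4_proportion": 0.0}
    if beta_fn is None:
        beta_fn = lambda t: 0.05 * np.sin(np.pi * t / t_unified)  # noqa: E731
    beta_true = np.asarray(beta_fn(grid), dtype=float)

    basis = SplineBasis(n_basis=10, t_max=t_unified)
    B = basis.design_matrix(grid)

    features = []
    y = np.empty(n)
    for i in range(n):
        covs = {
            "age": float(rng.normal(0.0, 1.0)),
            "sex": str(rng.choice(("female", "male"))),
        }
        shares = rng.dirichlet((8.0, 3.0, 1.0, 1.0))
        derived = {
            "removed_curve_count": int(rng.poisson(2.0)),
            "average_segment_time": float(rng.normal(45.0, 10.0)),
            "cluster2_proportion": float(shares[1]),
            "cluster3_proportion": float(shares[2]),
            "cluster4_proportion": float(shares[3]),
        }
        coeffs = rng.gamma(2.0, 5.0, size=basis.n_basis)
        curve = B @ coeffs
        curve = curve - curve[-1] * (grid / t_unified)  # end near zero
        curve = np.clip(curve, 0.0, None)
        f = ParticipantFeatures(
            participant_id=f"s{i:04d}", covariates=covs,
            removed_curve_count=derived["removed_curve_count"],
            cluster_proportions={2: derived["cluster2_proportion"],
                                 3: derived["cluster3_proportion"],
                                 4: derived["cluster4_proportion"]},
            average_segment_time=derived["average_segment_time"],
            mean_curve=curve, grid=grid,
            n_segments=20, n_low_cost=20 - derived["removed_curve_count"],
        )
        features.append(f)
        lin = _linear_predictor(gamma, covs, derived)
        lin += float(np.trapezoid(curve * beta_true, grid))
        y[i] = lin + rng.normal(0.0, sigma)
    return features, y, gamma, beta_true
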