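"""The synthetic generators: terrains, agents, test sessions, cohorts."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from voxelnav.clustering import SplineBasis, cluster_curves, coefficient_matrix
from voxelnav.cost_curves import curves_for_segments, normalize_curve
from voxelnav.path_io import segment_training_path, snap_to_block
from voxelnav.sofr import compute_outcomes
from voxelnav.synthetic import (
    STYLES,
    AgentPolicy,
    SynthConfig,
    archetype_mean,
    generate_archetype_curves,
    generate_cohort,
    generate_environment,
    generate_terrain,
    simulate_test_session,
    simulate_training_session,
)
from voxelnav.terrain import MovementRules, is_walkable_edge


class TestTerrainGeneration:
    def test_zero_roughness_is_flat(self):
        config = SynthConfig(width=20, depth=20, roughness=0.0)
        terrain = generate_terrain(config, seed=0)
        assert np.all(terrain.elevation == terrain.elevation[0, 0])

    def test_zero_obstruction_fraction_all_walkable(self):
        config = SynthConfig(width=20, depth=20, obstruction_fraction=0.0)
        terrain = generate_terrain(config, seed=0)
        assert not terrain.obstructed.any()

    def test_same_seed_identical_maps(self):
        config = SynthConfig(width=25, depth=25)
        a = generate_terrain(config, seed=7)
        b = generate_terrain(config, seed=7)
        assert np.array_equal(a.elevation, b.elevation)
        assert np.array_equal(a.obstructed, b.obstructed)

    def test_elevations_positive_integers(self):
        terrain = generate_terrain(SynthConfig(width=20, depth=20), seed=1)
        assert terrain.elevation.min() >= 1
        assert np.issubdtype(terrain.elevation.dtype, np.integer)

    def test_environment_objects_mutually_reachable(self, rules):
        from voxelnav.terrain import dijkstra

        config = SynthConfig(width=30, depth=30)
        env = generate_environment(config, rules, seed=5)
        assert len(env.objects) == config.n_objects
        cells = list(env.objects.values())[:4] + [env.start]
        for a in cells:
            for b in cells:
                r = dijkstra(env.terrain, rules,
                             env.terrain.block_at(*a), env.terrain.block_at(*b))
                assert r.reachable


@pytest.fixture(scope="module")
def train_setup():
    config = SynthConfig(width=40, depth=40, seed=9)
    rules = MovementRules()
    return config, rules, generate_environment(config, rules, seed=9)


@pytest.fixture(scope="module")
def test_env():
    config = SynthConfig(width=30, depth=30, seed=10)
    rules = MovementRules()
    return rules, generate_environment(config, rules, seed=10)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SynthConfig(n_participants=16, seed=21))


class TestTrainingSimulation:

    def test_every_step_is_walkable(self, train_setup):
        _, rules, env = train_setup
        for style in STYLES:
            path, _, _ = simulate_training_session(
                env.terrain, rules, env.objects, AgentPolicy(style),
                seed=3, start=env.start,
            )
            xs = path.samples["x"].to_numpy()
            ys = path.samples["y"].to_numpy()
            blocks = [snap_to_block(env.terrain, x, y) for x, y in zip(xs, ys)]
            for u, v in zip(blocks, blocks[1:]):
                if (u.x, u.y) != (v.x, v.y):
                    assert is_walkable_edge(env.terrain, rules, u, v)

    def test_session_cap_enforced(self, train_setup):
        _, rules, env = train_setup
        path, log, _ = simulate_training_session(
            env.terrain, rules, env.objects, AgentPolicy("prolonged_wanderer"),
            seed=4, start=env.start, session_cap=120.0,
        )
        assert path.samples["t"].max() <= 120.0
        assert log.events["t"].max() <= 120.0

    def test_found_events_match_object_cells(self, train_setup):
        _, rules, env = train_setup
        _, log, _ = simulate_training_session(
            env.terrain, rules, env.objects, AgentPolicy("direct"),
            seed=5, start=env.start,
        )
        found = log.events[log.events["kind"] == "object_found"]
        for _, ev in found.iterrows():
            ox, oy = env.objects[ev["object_id"]]
            assert (int(ev["x"]), int(ev["y"])) == (ox, oy)

    def test_late_adapter_drop_completes_before_midpoint(self, train_setup):
        _, rules, env = train_setup
        path, log, _ = simulate_training_session(
            env.terrain, rules, env.objects,
            AgentPolicy("late_adapter", wander_frac=0.3),
            seed=6, start=env.start,
        )
        segments = segment_training_path(path, log)
        curves, _ = curves_for_segments(env.terrain, rules, segments)
        # on segments long enough to show the pattern, the normalized
        # curve has shed most of its initial value by mid-grid
        long_curves = [c for c in curves if c.source_duration >= 60]
        assert long_curves
        for c in long_curves:
            mid = len(c.values) // 2
            assert c.values[mid] <= 0.4 * c.values[0] + 1e-9

    def test_wanderer_stays_high_past_midpoint(self, train_setup):
        _, rules, env = train_setup
        path, log, _ = simulate_training_session(
            env.terrain, rules, env.objects, AgentPolicy("prolonged_wanderer"),
            seed=7, start=env.start,
        )
        segments = segment_training_path(path, log)
        curves, _ = curves_for_segments(env.terrain, rules, segments)
        long_curves = [c for c in curves if c.source_duration >= 60]
        assert long_curves
        for c in long_curves:
            mid = len(c.values) // 2
            assert c.values[mid] >= 0.4 * c.values[0]


class TestTestSimulation:

    def test_perfect_memory_scores_perfectly(self, test_env):
        rules, env = test_env
        log = simulate_test_session(env.terrain, rules, env.objects,
                                    memory_error_scale=0.0, seed=1,
                                    test_starts=env.test_starts)
        truth = {oid: cell for oid, cell in env.objects.items()}
        out = compute_outcomes(env.terrain, rules, log, truth)
        assert out.y1 == 12
        assert out.y3 == pytest.approx(0.0)

    def test_trial_times_within_cap(self, test_env):
        rules, env = test_env
        log = simulate_test_session(env.terrain, rules, env.objects,
                                    memory_error_scale=5.0, seed=2,
                                    test_starts=env.test_starts)
        placed = log.events[log.events["kind"] == "object_placed"]
        starts = log.events[log.events["kind"] == "trial_start"]
        durations = placed["t"].to_numpy() - starts["t"].to_numpy()
        assert np.all(durations <= 180.0)
        assert np.all(durations > 0)

    def test_large_error_scale_degrades_score(self, test_env):
        rules, env = test_env
        truth = dict(env.objects)
        scores = []
        for scale in (0.0, 30.0):
            log = simulate_test_session(env.terrain, rules, env.objects,
                                        memory_error_scale=scale, seed=3,
                                        test_starts=env.test_starts)
            scores.append(compute_outcomes(env.terrain, rules, log, truth).y1)
        assert scores[1] < scores[0]


class TestArchetypeCurves:
    def test_shapes_match_their_descriptions(self):
        grid = np.linspace(0, 100, 101)
        assert np.all(archetype_mean("direct", grid) == 0)
        shallow = archetype_mean("corrective", grid)
        assert np.all(np.diff(shallow) < 0)
        late_drop = archetype_mean("prolonged_wanderer", grid)
        assert late_drop[50] > 0.9 * late_drop[0]  # still high at midpoint
        early_drop = archetype_mean("late_adapter", grid)
        assert early_drop[50] < 0.05 * early_drop[0]  # gone by midpoint

    def test_curves_end_at_zero_and_stay_nonnegative(self):
        curves, labels = generate_archetype_curves(200, seed=0)
        assert len(labels) == 200
        for c in curves:
            assert c.values[-1] == 0.0
            assert np.all(c.values >= 0)

    def test_deterministic_per_seed(self):
        a, la = generate_archetype_curves(50, seed=3)
        b, lb = generate_archetype_curves(50, seed=3)
        assert np.array_equal(la, lb)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))


class TestCohort:

    def test_structure(self, small_cohort):
        cohort = small_cohort
        assert len(cohort.features) == 16
        assert len(cohort.test_logs) == 16
        assert len(cohort.paths) == 32  # two training sessions each
        assert len(cohort.curves) == len(cohort.curve_styles)
        assert len(cohort.curve_meta) == len(cohort.curves)

    def test_deterministic_regeneration(self, small_cohort):
        cohort = small_cohort
        again = generate_cohort(SynthConfig(n_participants=16, seed=21))
        assert cohort.covariates.equals(again.covariates)
        assert cohort.outcomes.equals(again.outcomes)
        for a, b in zip(cohort.curves, again.curves):
            assert np.array_equal(a.values, b.values)

    def test_curve_invariants_across_cohort(self, small_cohort):
        cohort = small_cohort
        for c in cohort.curves:
            assert np.all(c.values >= 0)
            assert np.all(np.diff(c.values) <= 1e-9)
            assert c.values[-1] == pytest.approx(0.0, abs=1e-9)

    def test_policy_labels_recovered_by_clustering(self, small_cohort):
        cohort = small_cohort
        coeffs = coefficient_matrix(cohort.curves, SplineBasis(n_basis=12))
        truth = np.array([STYLES.index(s) for s in cohort.curve_styles])
        model = cluster_curves(coeffs, 4, seed=1)
        assert adjusted_rand_score(truth, model.assignments) >= 0.85

    def test_pure_direct_mixture_gives_flat_cluster(self):
        config = SynthConfig(n_participants=6, seed=30,
                             policy_weights=(1.0, 0.0, 0.0, 0.0),
                             style_concentration=1e6)
        cohort = generate_cohort(config)
        assert set(cohort.curve_styles) == {"direct"}
        values = np.vstack([c.values for c in cohort.curves])
        assert np.allclose(values, 0.0, atol=1e-9)

    def test_outcome_correlations_small(self):
        """Independent noise and (largely) disjoint drivers per outcome
        keep the outcomes close to uncorrelated, which is why they are
        modelled by separate regressions."""
        cohort = generate_cohort(SynthConfig(n_participants=48, seed=33))
        corr = cohort.outcomes[["Y1", "Y2", "Y3"]].corr().to_numpy()
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.5)

    def test_normalization_idempotent_on_cohort_curves(self, small_cohort):
        cohort = small_cohort
        for c in cohort.curves[:25]:
            again = normalize_curve(c, 100.0, 101)
            assert np.allclose(c.values, again.values, atol=1e-12)
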