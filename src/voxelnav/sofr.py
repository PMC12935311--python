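"""Participant-level features, test outcomes, and scalar-on-functional
regression (SoFR).

Segments are triaged by the Dijkstra cost of their optimal path: a
segment whose optimal start-to-end cost is below a cutoff (default 70)
is *low-cost* (a typical object-to-object hop); at or above the cutoff
it is *high-cost* (objects far apart or hard terrain).  A participant's
functional predictor X_i(t) is the pointwise mean of their low-cost
normalized cost-difference curves; the number of high-cost segments is
kept as the scalar "removed curve count".

Test performance is summarised by three outcomes: Y1, the number of
objects placed within a radius of their true location (correctness
judged by Dijkstra distance); Y2, the mean time to a correct placement;
Y3, the mean Dijkstra distance of correct placements from the truth.

Each outcome is regressed separately on the scalar covariates z_i and
the functional predictor:

    y_i = z_i' gamma + int_0^T X_i(t) beta(t) dt + eps_i

with beta(t) expanded on a cubic B-spline basis (default 10 functions)
and a roughness penalty lambda * int beta''(t)^2 dt (default lambda =
0.1).  The penalized least-squares solution is closed-form; standard
errors use the effective-degrees-of-freedom sandwich approximation and
are therefore approximate.  Pointwise 95% bands for beta(t) come from a
case-resampling bootstrap over participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import SplineBasis
from .cost_curves import NormalizedCurve
from .path_io import EventLog, snap_to_block
from .terrain import MovementRules, TerrainMap, distance_field_to

logger = logging.getLogger(__name__)

DEFAULT_COST_CUTOFF = 70.0
DEFAULT_CORRECT_RADIUS = 10.0
DEFAULT_SOFR_N_BASIS = 10
DEFAULT_LAMBDA = 0.1


def classify_segment(optimal_cost: float,
                     cutoff: float = DEFAULT_COST_CUTOFF) -> str:
    """Triage a segment by its optimal path cost: 'low' iff cost < cutoff.

    The boundary itself is high-cost (strictly-below reading of the
    cutoff).
    """
    if not np.isfinite(optimal_cost) or optimal_cost < 0:
        raise ValueError(f"optimal cost must be finite and >= 0, got {optimal_cost}")
    return "low" if optimal_cost < cutoff else "high"


@dataclass
class ParticipantFeatures:
    """Scalar and functional predictors for one participant."""

    participant_id: str
    covariates: dict
    removed_curve_count: int
    cluster_proportions: dict[int, float]  # shares of clusters 2, 3, 4
    average_segment_time: float
    mean_curve: np.ndarray | None          # on the unified grid; None if no low-cost segment
    grid: np.ndarray | None = None
    n_segments: int = 0
    n_low_cost: int = 0


@dataclass
class Outcomes:
    """Test-phase performance summary for one participant.

    ``y2`` and ``y3`` are NaN when no object was correctly placed.
    """

    participant_id: str
    y1: int
    y2: float
    y3: float
    n_trials: int = 0

    def get(self, label: str) -> float:
        value = {"Y1": self.y1, "Y2": self.y2, "Y3": self.y3}.get(label)
        if value is None:
            raise KeyError(f"unknown outcome label {label!r}")
        return float(value)


@dataclass
class SoFRFit:
    """Penalized scalar-on-functional regression fit for one outcome."""

    outcome_label: str
    gamma: pd.DataFrame           # estimate, se, t, p per scalar term
    beta_coeffs: np.ndarray       # functional coefficient on the spline basis
    basis: SplineBasis
    lambda_: float
    r_squared: float
    sigma2: float
    edf: float
    n: int
    grid: np.ndarray
    bootstrap_bands: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    def beta(self, t: np.ndarray | None = None) -> np.ndarray:
        """Reconstruct beta(t) on a time grid (default: the unified grid)."""
        t = self.grid if t is None else np.asarray(t, dtype=float)
        return self.basis.design_matrix(t) @ self.beta_coeffs


def participant_features(participant_id: str,
                         curves: list[NormalizedCurve],
                         assignments: np.ndarray,
                         covariates: dict,
                         n_clusters: int = 4,
                         cutoff: float = DEFAULT_COST_CUTOFF) -> ParticipantFeatures:
    """Aggregate one participant's segment curves into regression features.

    ``curves`` and ``assignments`` are aligned.  The mean curve uses
    only low-cost segments; the removed-curve count is the number of
    high-cost segments; cluster proportions and average segment time
    are computed over ALL segments.
    """
    if len(curves) != len(assignments):
        raise ValueError(
            f"{len(curves)} curves but {len(assignments)} cluster assignments"
        )
    if not curves:
        raise ValueError(f"participant {participant_id}: no curves")
    labels = np.asarray(assignments)
    low = [c for c in curves if classify_segment(c.optimal_cost, cutoff) == "low"]
    removed = len(curves) - len(low)
    proportions = {
        k: float(np.mean(labels == k)) for k in range(2, n_clusters + 1)
    }
    avg_time = float(np.mean([c.source_duration for c in curves]))
    if low:
        mean_curve = np.mean([c.values for c in low], axis=0)
        grid = low[0].grid
    else:
        logger.warning(
            "participant %s has no low-cost segments; excluded from the "
            "functional regression", participant_id,
        )
        mean_curve, grid = None, None
    return ParticipantFeatures(
        participant_id=participant_id,
        covariates=dict(covariates),
        removed_curve_count=removed,
        cluster_proportions=proportions,
        average_segment_time=avg_time,
        mean_curve=mean_curve,
        grid=grid,
        n_segments=len(curves),
        n_low_cost=len(low),
    )


def compute_outcomes(terrain: TerrainMap, rules: MovementRules,
                     test_log: EventLog,
                     true_locations: dict[str, tuple[float, float]],
                     correct_radius: float = DEFAULT_CORRECT_RADIUS,
                     metric: str = "dijkstra") -> Outcomes:
    """Score a test session against the true object locations.

    Each trial contributes a ``trial_start`` (teleport-in) and an
    ``object_placed`` event.  A placement is correct when its distance
    to the object's true block is at most ``correct_radius``; by
    default that distance is the Dijkstra distance, so a placement on
    the wrong side of an uncrossable river is wrong even if it is close
    as the crow flies.  ``metric='euclidean'`` switches to the 2D
    Euclidean distance.
    """
    if metric not in ("dijkstra", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    events = test_log.events
    placements = events[events["kind"] == "object_placed"]
    starts = events[events["kind"] == "trial_start"].set_index("object_id")

    distances, times = [], []
    n_trials = 0
    for _, ev in placements.iterrows():
        oid = str(ev["object_id"])
        if oid not in true_locations:
            raise ValueError(f"placement for unknown object {oid!r}")
        n_trials += 1
        tx, ty = true_locations[oid]
        true_block = snap_to_block(terrain, tx, ty)
        placed_block = snap_to_block(terrain, float(ev["x"]), float(ev["y"]))
        if metric == "dijkstra":
            fld = distance_field_to(terrain, rules, true_block)
            dist = float(fld[placed_block.x, placed_block.y])
        else:
            dist = math.hypot(placed_block.x - true_block.x,
                              placed_block.y - true_block.y)
        if dist <= correct_radius:
            distances.append(dist)
            if oid in starts.index:
                entry_t = float(np.atleast_1d(starts.loc[oid, "t"])[0])
            else:
                entry_t = 0.0
            times.append(float(ev["t"]) - entry_t)

    y1 = len(distances)
    return Outcomes(
        participant_id=test_log.participant_id,
        y1=y1,
        y2=float(np.mean(times)) if y1 else float("nan"),
        y3=float(np.mean(distances)) if y1 else float("nan"),
        n_trials=n_trials,
    )


# ----------------------------------------------------------------------
# design-matrix assembly
# ----------------------------------------------------------------------

def build_design(features: list[ParticipantFeatures],
                 outcomes: list[Outcomes] | np.ndarray,
                 outcome_label: str,
                 reference_levels: dict[str, str] | None = None,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (Z, X_curves, y, grid, column names) over complete cases.

    Scalar covariates are taken from each participant's covariate dict
    plus the derived features (removed curve count, cluster
    proportions, average segment time).  String-valued covariates are
    reference-coded; ``reference_levels`` picks the baseline level per
    covariate (default: lexicographically first).  Participants with a
    missing outcome or no low-cost segments are dropped.
    """
    if isinstance(outcomes, np.ndarray):
        y_all = outcomes.astype(float)
    else:
        by_id = {o.participant_id: o for o in outcomes}
        y_all = np.array([
            by_id[f.participant_id].get(outcome_label) if f.participant_id in by_id
            else float("nan")
            for f in features
        ])

    rows, curve_rows, ys = [], [], []
    grid = None
    for f, y in zip(features, y_all):
        if f.mean_curve is None or not np.isfinite(y):
            continue
        row = dict(f.covariates)
        row["removed_curve_count"] = f.removed_curve_count
        for k, v in sorted(f.cluster_proportions.items()):
            row[f"cluster{k}_proportion"] = v
        row["average_segment_time"] = f.average_segment_time
        rows.append(row)
        curve_rows.append(f.mean_curve)
        ys.append(y)
        grid = f.grid if grid is None else grid
    if not rows:
        raise ValueError(f"no complete cases for outcome {outcome_label}")

    df = pd.DataFrame(rows)
    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    for col in df.columns:
        if df[col].dtype == object or isinstance(df[col].dtype, pd.CategoricalDtype):
            levels = sorted(df[col].astype(str).unique())
            ref = (reference_levels or {}).get(col, levels[0])
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} not present for covariate {col!r}"
                )
            for lev in levels:
                if lev == ref:
                    continue
                parts.append(
                    (df[col].astype(str) == lev).astype(float).rename(f"{col}[{lev}]")
                )
        else:
            parts.append(df[col].astype(float))
    Z_df = pd.concat(parts, axis=1)
    # a covariate that never varies in this sample (e.g. nobody had a
    # high-cost segment) is collinear with the intercept; drop it
    constant = [c for c in Z_df.columns[1:] if Z_df[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant covariates: %s", constant)
        Z_df = Z_df.drop(columns=constant)
    return (
        Z_df.to_numpy(dtype=float),
        np.vstack(curve_rows),
        np.asarray(ys, dtype=float),
        np.asarray(grid, dtype=float),
        list(Z_df.columns),
    )


def functional_design(curves: np.ndarray, grid: np.ndarray,
                      basis: SplineBasis) -> np.ndarray:
    """W with W[i, j] = int X_i(t) B_j(t) dt by trapezoid on the grid.

    Trapezoid quadrature is exact for the piecewise-linear normalized
    curves against piecewise-polynomial bases up to the grid spacing.
    """
    B = basis.design_matrix(grid)                       # (G, nb)
    wts = np.zeros(len(grid))
    dg = np.diff(grid)
    wts[:-1] += dg / 2
    wts[1:] += dg / 2
    return (curves * wts) @ B                           # (n, nb)


def _penalized_solve(M: np.ndarray, y: np.ndarray, penalty: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    MtM = M.T @ M
    A = MtM + penalty
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular penalized design; increase lambda or reduce the "
            "number of basis functions"
        ) from exc
    theta = A_inv @ (M.T @ y)
    return theta, A_inv


def fit_sofr(features: list[ParticipantFeatures],
             outcomes: list[Outcomes] | np.ndarray,
             outcome_label: str = "Y1",
             n_basis: int = DEFAULT_SOFR_N_BASIS,
             lambda_: float = DEFAULT_LAMBDA,
             reference_levels: dict[str, str] | None = None) -> SoFRFit:
    """Fit the penalized scalar-on-functional regression for one outcome.

    Minimizes  sum_i (y_i - z_i' gamma - int X_i beta)^2
               + lambda * int beta''(t)^2 dt
    with beta on an ``n_basis``-function cubic B-spline basis.  The
    scalar block is unpenalized.  Reported p-values use a t reference
    with n - edf degrees of freedom and are approximate under
    penalization.
    """
    Z, curves, y, grid, names = build_design(
        features, outcomes, outcome_label, reference_levels
    )
    basis = SplineBasis(n_basis=n_basis, t_max=float(grid[-1]))
    W = functional_design(curves, grid, basis)
    M = np.hstack([Z, W])
    p = Z.shape[1]
    penalty = np.zeros((M.shape[1], M.shape[1]))
    penalty[p:, p:] = lambda_ * basis.penalty_matrix()

    n = len(y)
    n_coef = M.shape[1]
    if n < n_coef + 2:
        raise ValueError(
            f"{n} complete cases cannot support {n_coef} coefficients "
            "(need at least 2 more cases than coefficients)"
        )
    theta, A_inv = _penalized_solve(M, y, penalty)
    fitted = M @ theta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    edf = float(np.trace(A_inv @ (M.T @ M)))
    df_resid = max(n - edf, 1.0)
    sigma2 = rss / df_resid
    cov = sigma2 * (A_inv @ (M.T @ M) @ A_inv)  # EDF sandwich; approximate
    se = np.sqrt(np.diag(cov))

    gamma_hat = theta[:p]
    gamma_se = se[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = gamma_hat / gamma_se
    p_val = 2 * stats.t.sf(np.abs(t_stat), df_resid)
    gamma = pd.DataFrame(
        {"estimate": gamma_hat, "se": gamma_se, "t": t_stat, "p": p_val},
        index=names,
    )
    return SoFRFit(
        outcome_label=outcome_label,
        gamma=gamma,
        beta_coeffs=theta[p:],
        basis=basis,
        lambda_=lambda_,
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
        sigma2=sigma2,
        edf=edf,
        n=n,
        grid=grid,
        diagnostics={"rss": rss, "df_resid": df_resid},
    )


def bootstrap_beta_bands(features: list[ParticipantFeatures],
                         outcomes: list[Outcomes] | np.ndarray,
                         outcome_label: str = "Y1",
                         n_boot: int = 1000,
                         seed: int = 0,
                         n_basis: int = DEFAULT_SOFR_N_BASIS,
                         lambda_: float = DEFAULT_LAMBDA,
                         reference_levels: dict[str, str] | None = None,
                         ) -> pd.DataFrame:
    """Pointwise 95% bootstrap bands for beta(t).

    Case-resampling over participants: each replicate redraws n
    complete cases with replacement and refits; bands are the pointwise
    2.5 / 97.5 percentiles of the replicate beta curves on the unified
    grid.  Singular replicates are redrawn (counted in the log).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for percentile bands")
    Z, curves, y, grid, _ = build_design(
        features, outcomes, outcome_label, reference_levels
    )
    basis = SplineBasis(n_basis=n_basis, t_max=float(grid[-1]))
    W = functional_design(curves, grid, basis)
    M = np.hstack([Z, W])
    p = Z.shape[1]
    penalty = np.zeros((M.shape[1], M.shape[1]))
    penalty[p:, p:] = lambda_ * basis.penalty_matrix()
    B_grid = basis.design_matrix(grid)

    theta_full, _ = _penalized_solve(M, y, penalty)
    beta_hat = B_grid @ theta_full[p:]

    rng = np.random.default_rng(seed)
    n = len(y)
    betas = np.empty((n_boot, len(grid)))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Mb, yb = M[idx], y[idx]
        try:
            theta, _ = _penalized_solve(Mb, yb, penalty)
        except np.linalg.LinAlgError:
            n_redrawn += 1
            if n_redrawn > 10 * n_boot:
                raise RuntimeError("bootstrap: too many singular replicates")
            continue
        betas[b] = B_grid @ theta[p:]
        b += 1
    if n_redrawn:
        logger.info("bootstrap: %d singular replicates redrawn", n_redrawn)
    lower = np.percentile(betas, 2.5, axis=0)
    upper = np.percentile(betas, 97.5, axis=0)
    return pd.DataFrame({
        "t": grid,
        "beta": beta_hat,
        "lower": lower,
        "upper": upper,
    })
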