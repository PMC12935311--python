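"""Functional clustering of normalized cost-difference curves.

Each curve is reduced to the coefficient vector of a least-squares fit
against a cubic B-spline basis with equally spaced knots, and K-means
is run on the coefficient vectors.  The cluster count K is selected by
the mean silhouette score, and the stability of a chosen clustering is
quantified as the adjusted Rand index (ARI) between a reference run and
re-runs under different random seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .cost_curves import DEFAULT_T_UNIFIED, NormalizedCurve

DEFAULT_N_BASIS = 12


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis with equally spaced knots on [0, t_max].

    ``n_basis`` functions of order 4 (degree 3).  The knot vector is
    clamped at both ends, so the basis is a partition of unity on the
    whole interval.
    """

    n_basis: int = DEFAULT_N_BASIS
    t_max: float = DEFAULT_T_UNIFIED
    order: int = 4

    def __post_init__(self) -> None:
        if self.n_basis < self.order:
            raise ValueError(
                f"n_basis={self.n_basis} must be >= order={self.order}"
            )

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def knots(self) -> np.ndarray:
        """Full clamped knot vector."""
        n_interior = self.n_basis - self.order
        interior = np.linspace(0.0, self.t_max, n_interior + 2)[1:-1]
        return np.concatenate([
            np.zeros(self.order),
            interior,
            np.full(self.order, self.t_max),
        ])

    def design_matrix(self, t: np.ndarray) -> np.ndarray:
        """Basis functions evaluated at ``t`` (shape: len(t) x n_basis)."""
        t = np.asarray(t, dtype=float)
        return BSpline.design_matrix(
            t, self.knots, self.degree, extrapolate=False
        ).toarray()

    def penalty_matrix(self, n_quad: int = 2001) -> np.ndarray:
        """Gram matrix of second derivatives, int B_j''(t) B_k''(t) dt.

        Evaluated by composite trapezoid on a fine grid; second
        derivatives of cubic B-splines are piecewise linear, so the
        quadrature error vanishes quickly with n_quad.
        """
        t = np.linspace(0.0, self.t_max, n_quad)
        knots = self.knots
        d2 = np.empty((n_quad, self.n_basis))
        for j in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[j] = 1.0
            d2[:, j] = BSpline(knots, c, self.degree)(t, nu=2)
        return np.trapezoid(d2[:, :, None] * d2[:, None, :], t, axis=0)


@dataclass
class CurveCoefficients:
    """Spline-coefficient representation of one curve."""

    coefficients: np.ndarray
    curve: NormalizedCurve | None = None


@dataclass
class ClusterModel:
    """K-means result on spline coefficients, labels size-ordered.

    Labels are 1-based and relabelled so that cluster 1 is the largest,
    matching the convention that "cluster 1" names the dominant
    (most efficient) navigation pattern.
    """

    n_clusters: int
    centroids: np.ndarray        # (K, n_basis) coefficient vectors
    assignments: np.ndarray      # 1-based labels, length n_curves
    seed: int
    inertia: float

    def centroid_curves(self, basis: SplineBasis, grid: np.ndarray) -> np.ndarray:
        """Reconstruct centroid curves on a time grid (K x len(grid))."""
        return self.centroids @ basis.design_matrix(grid).T


def fit_spline_coefficients(curve: NormalizedCurve,
                            basis: SplineBasis) -> CurveCoefficients:
    """Ordinary least-squares spline coefficients for one curve."""
    coeffs = coefficient_matrix([curve], basis)[0]
    return CurveCoefficients(coefficients=coeffs, curve=curve)


def coefficient_matrix(curves: list[NormalizedCurve],
                       basis: SplineBasis) -> np.ndarray:
    """Least-squares coefficients for many curves sharing one grid.

    All curves must be sampled on the same grid (the unified grid), so
    a single design matrix serves every fit.  Returns an
    (n_curves, n_basis) array.
    """
    if not curves:
        raise ValueError("no curves to fit")
    grid = curves[0].grid
    for c in curves[1:]:
        if len(c.grid) != len(grid) or not np.allclose(c.grid, grid):
            raise ValueError("curves must share a common grid")
    if len(grid) < basis.n_basis:
        raise ValueError(
            f"grid of {len(grid)} points cannot identify {basis.n_basis} "
            "basis coefficients; reduce n_basis or refine the grid"
        )
    design = basis.design_matrix(grid)
    values = np.column_stack([c.values for c in curves])
    coeffs, *_ = np.linalg.lstsq(design, values, rcond=None)
    return coeffs.T


def cluster_curves(coefficients: np.ndarray | list[CurveCoefficients],
                   n_clusters: int, seed: int,
                   n_restarts: int = 10) -> ClusterModel:
    """K-means on coefficient vectors with size-ordered relabelling.

    Runs ``n_restarts`` random initialisations and keeps the
    best-inertia solution; the seed fixes the restart stream so the
    result is reproducible.
    """
    X = _as_matrix(coefficients)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(X) < n_clusters:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {len(X)} curves"
        )
    km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    # relabel by descending cluster size; ties broken by original label
    sizes = np.bincount(raw, minlength=n_clusters)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(n_clusters, dtype=int)
    relabel[order] = np.arange(1, n_clusters + 1)
    return ClusterModel(
        n_clusters=n_clusters,
        centroids=km.cluster_centers_[order],
        assignments=relabel[raw],
        seed=seed,
        inertia=float(km.inertia_),
    )


def select_k_silhouette(coefficients: np.ndarray | list[CurveCoefficients],
                        k_range: range | list[int] = range(2, 9),
                        seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Choose K by the mean silhouette score over coefficient vectors.

    Returns the maximizing K and the full silhouette-vs-K table so an
    elbow/score plot can be produced.
    """
    X = _as_matrix(coefficients)
    rows = []
    for k in k_range:
        model = cluster_curves(X, k, seed)
        score = silhouette_score(X, model.assignments)
        rows.append({"n_clusters": k, "silhouette": score})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["silhouette"].idxmax(), "n_clusters"])
    return best, table


def clustering_stability(coefficients: np.ndarray | list[CurveCoefficients],
                         n_clusters: int, n_repeats: int,
                         base_seed: int) -> tuple[float, float]:
    """Mean and SD of the ARI between a reference clustering and re-runs.

    The reference uses ``base_seed``; each repeat reseeds K-means and
    compares its partition to the reference with the adjusted Rand
    index (1 = identical up to label permutation).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    X = _as_matrix(coefficients)
    reference = cluster_curves(X, n_clusters, base_seed).assignments
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    aris = np.array([
        adjusted_rand_score(
            reference, cluster_curves(X, n_clusters, int(s)).assignments
        )
        for s in seeds
    ])
    return float(aris.mean()), float(aris.std(ddof=1))


def composition_tables(model: ClusterModel,
                       metadata: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cluster-share tables by session, environment, and segment position.

    ``metadata`` must have one row per clustered curve (same order as
    ``model.assignments``) with columns ``session_id``,
    ``environment``, ``is_first``, ``is_last``.  Each returned table
    holds row-normalized proportions (rows sum to 1): shares per
    training session, per environment, and for all / first / last
    segments.
    """
    required = ["session_id", "environment", "is_first", "is_last"]
    for col in required:
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if len(metadata) != len(model.assignments):
        raise ValueError(
            f"{len(metadata)} metadata rows for {len(model.assignments)} curves"
        )
    df = metadata.copy()
    df["cluster"] = model.assignments
    all_clusters = list(range(1, model.n_clusters + 1))

    def share_table(frame: pd.DataFrame, by: pd.Series) -> pd.DataFrame:
        counts = pd.crosstab(by, frame["cluster"])
        counts = counts.reindex(columns=all_clusters, fill_value=0)
        return counts.div(counts.sum(axis=1), axis=0)

    by_session = share_table(df, df["session_id"])
    by_environment = share_table(df, df["environment"])
    position = pd.Series(
        np.where(df["is_first"], "first",
                 np.where(df["is_last"], "final", "intermediate")),
        index=df.index, name="position",
    )
    by_position = share_table(df, position)
    overall = share_table(df, pd.Series("all", index=df.index, name="segments"))
    by_position = pd.concat([overall, by_position])
    return {
        "by_session": by_session,
        "by_environment": by_environment,
        "by_position": by_position,
    }


def _as_matrix(coefficients: np.ndarray | list[CurveCoefficients]) -> np.ndarray:
    if isinstance(coefficients, np.ndarray):
        return coefficients
    return np.vstack([c.coefficients for c in coefficients])
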