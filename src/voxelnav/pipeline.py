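"""End-to-end orchestration: simulate -> curves -> cluster -> regress.

Every stage writes plain CSV/JSON artifacts so any stage can be rerun
or inspected in isolation, and the whole run is a deterministic
function of the configuration (including its master seed): rerunning
with the same config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    SplineBasis,
    cluster_curves,
    clustering_stability,
    coefficient_matrix,
    composition_tables,
    select_k_silhouette,
)
from .cost_curves import DEFAULT_GRID_SIZE, DEFAULT_T_UNIFIED
from .sofr import (
    DEFAULT_COST_CUTOFF,
    DEFAULT_LAMBDA,
    DEFAULT_SOFR_N_BASIS,
    bootstrap_beta_bands,
    fit_sofr,
    participant_features,
)
from .synthetic import SynthConfig, generate_cohort
from .terrain import MovementRules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Defaults follow the analysis conventions throughout the package:
    cost cutoff 70 between low- and high-cost segments, ten basis
    functions and lambda = 0.1 for the functional regression, twelve
    basis functions for clustering, unified time scale 100 on a
    101-point grid.
    """

    out_dir: str = "voxelnav_run"
    seed: int = 0
    rules: MovementRules = field(default_factory=MovementRules)
    synth: SynthConfig = field(default_factory=SynthConfig)
    t_unified: float = DEFAULT_T_UNIFIED
    grid_size: int = DEFAULT_GRID_SIZE
    cluster_n_basis: int = 12
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_stability_repeats: int = 100
    cutoff: float = DEFAULT_COST_CUTOFF
    sofr_n_basis: int = DEFAULT_SOFR_N_BASIS
    lambda_: float = DEFAULT_LAMBDA
    n_boot: int = 200

    def __post_init__(self) -> None:
        self.synth = dataclasses.replace(
            self.synth, seed=self.seed,
            t_unified=self.t_unified, grid_size=self.grid_size,
            cutoff=self.cutoff,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rules = MovementRules(**raw.pop("rules", {}))
        synth = SynthConfig(**raw.pop("synth", {}))
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(rules=rules, synth=synth, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON).

    Stages: generate a synthetic cohort, compute normalized
    cost-difference curves per segment, cluster the pooled curves on
    spline coefficients (K chosen by silhouette, stability by ARI over
    reseeds), aggregate participant features, and fit the three
    scalar-on-functional regressions with bootstrap bands.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg = dataclasses.asdict(config.synth)
    synth_cfg["policy_weights"] = list(config.synth.policy_weights)
    report: dict = {"seed": config.seed, "synth_config": synth_cfg}

    # ---- stage 1: simulate ------------------------------------------------
    logger.info("stage simulate: %d participants", config.synth.n_participants)
    cohort = generate_cohort(config.synth, config.rules)
    for name, env in cohort.environments.items():
        env.terrain.to_json(out / f"terrain_{name}.json")
    pd.concat(
        [p.samples.assign(participant_id=p.participant_id,
                          session_id=p.session_id) for p in cohort.paths]
    ).to_csv(out / "paths.csv", index=False)
    pd.concat(
        [l.events.assign(participant_id=l.participant_id,
                         session_id=l.session_id) for l in cohort.train_logs]
    ).to_csv(out / "events_training.csv", index=False)
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    report["n_participants"] = config.synth.n_participants
    report["n_segments"] = len(cohort.curves)
    report["n_excluded_segments"] = cohort.n_excluded_segments

    # ---- stage 2: curves --------------------------------------------------
    curves = cohort.curves
    if not curves:
        raise RuntimeError("simulation produced no usable segments")
    long_rows = []
    for idx, c in enumerate(curves):
        long_rows.append(pd.DataFrame({
            "curve_id": idx,
            "participant_id": c.segment.participant_id,
            "session_id": c.segment.session_id,
            "segment_index": c.segment.index,
            "grid_index": np.arange(len(c.grid)),
            "value": c.values,
        }))
    pd.concat(long_rows).to_csv(out / "curves.csv", index=False)
    cohort.curve_meta.to_csv(out / "curve_meta.csv", index=False)

    # ---- stage 3: cluster -------------------------------------------------
    basis = SplineBasis(n_basis=config.cluster_n_basis, t_max=config.t_unified)
    coeffs = coefficient_matrix(curves, basis)
    best_k, silhouette_table = select_k_silhouette(
        coeffs, list(config.k_range), seed=config.seed
    )
    silhouette_table.to_csv(out / "silhouette.csv", index=False)
    model = cluster_curves(coeffs, best_k, seed=config.seed)
    mean_ari, sd_ari = clustering_stability(
        coeffs, best_k, config.n_stability_repeats, base_seed=config.seed
    )
    tables = composition_tables(model, cohort.curve_meta)
    for name, table in tables.items():
        table.to_csv(out / f"composition_{name}.csv")
    pd.DataFrame({
        "curve_id": np.arange(len(curves)),
        "cluster": model.assignments,
    }).to_csv(out / "assignments.csv", index=False)
    grid = curves[0].grid
    pd.DataFrame(
        model.centroid_curves(basis, grid).T,
        columns=[f"cluster{k}" for k in range(1, best_k + 1)],
    ).assign(t=grid).to_csv(out / "centroid_curves.csv", index=False)
    cluster_sizes = np.bincount(model.assignments)[1:].tolist()
    report["clustering"] = {
        "selected_k": best_k,
        "silhouette": silhouette_table.set_index("n_clusters")["silhouette"].to_dict(),
        "cluster_sizes": cluster_sizes,
        "cluster_shares": [s / len(curves) for s in cluster_sizes],
        "stability_mean_ari": mean_ari,
        "stability_sd_ari": sd_ari,
    }

    # ---- stage 4: features ------------------------------------------------
    features = []
    curve_pid = pd.Series([c.segment.participant_id for c in curves])
    cov_lookup = cohort.covariates.set_index("participant_id")
    for pid, idx in curve_pid.groupby(curve_pid).groups.items():
        idx = np.asarray(idx)
        p_curves = [curves[i] for i in idx]
        covs = cov_lookup.loc[pid].to_dict()
        features.append(participant_features(
            str(pid), p_curves, model.assignments[idx], covs,
            n_clusters=best_k, cutoff=config.cutoff,
        ))
    usable = [f for f in features if f.mean_curve is not None]
    report["features"] = {
        "n_participants_with_curves": len(features),
        "n_excluded_no_low_cost": len(features) - len(usable),
    }
    pd.DataFrame([{
        "participant_id": f.participant_id,
        "removed_curve_count": f.removed_curve_count,
        "average_segment_time": f.average_segment_time,
        "n_segments": f.n_segments,
        "n_low_cost": f.n_low_cost,
        **{f"cluster{k}_proportion": v for k, v in f.cluster_proportions.items()},
    } for f in features]).to_csv(out / "participant_features.csv", index=False)

    # ---- stage 5: regress -------------------------------------------------
    outcomes_df = cohort.outcomes.set_index("participant_id")
    report["regression"] = {}
    for label in ("Y1", "Y2", "Y3"):
        y = np.array([
            outcomes_df.loc[f.participant_id, label] for f in features
        ])
        fit = fit_sofr(features, y, label,
                       n_basis=config.sofr_n_basis, lambda_=config.lambda_)
        bands = bootstrap_beta_bands(
            features, y, label, n_boot=max(config.n_boot, 100),
            seed=config.seed, n_basis=config.sofr_n_basis,
            lambda_=config.lambda_,
        )
        fit.gamma.to_csv(out / f"coefficients_{label}.csv")
        bands.to_csv(out / f"beta_bands_{label}.csv", index=False)
        report["regression"][label] = {
            "n": fit.n,
            "r_squared": fit.r_squared,
            "edf": fit.edf,
            "gamma": fit.gamma["estimate"].to_dict(),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
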