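"""Experiment orchestration: module-set comparisons, criteria-vs-performance
sweeps, dimensionality baselines, and the DB/PB regression statistics.

Each experiment trains synergy networks repeatedly (fresh seeds per
repetition), summarizes performance as the *median* final error and median
learning speed across repetitions, and pairs those medians with the DB and
PB of the module set under the training plant.  The statistics layer then
fits

    X = k1 * PB + k2 * DB + k3          (multiple regression, F-test, VIF)

and the univariate first-order regressions of error or speed on a single
criterion.  Every record carries its full seed list so any row can be
recomputed bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .criteria import evaluate_criteria
from .network import DEFAULT_N_M1, init_nonsynergy, init_synergy
from .plant import Plant, module_torques, scale_passive
from .synergy_gen import (
    CUTOFF_SINGLE,
    DATASET_ALPHA,
    DATASET_TRIALS,
    ActivationDataset,
    SynergySet,
    build_activation_dataset,
    choose_n_synergies,
    feasibility_filter,
    nmf_extract,
    sample_fs_joint,
    sample_fsfordb,
    sample_fsforpb,
)
from .training import (
    TaskSet,
    TrainConfig,
    final_error,
    fit_learning_speed,
    make_task_targets,
    train,
)

__all__ = [
    "ExperimentRecord",
    "RegressionResult",
    "run_module_comparison",
    "run_criteria_sweep",
    "run_dimensionality_baseline",
    "fit_db_pb_regression",
    "correlate",
    "records_to_frame",
    "write_records",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentRecord:
    """One module-set condition: its criteria and its median performance
    over ``n_reps`` seeded training repetitions."""

    condition: str
    db: float
    pb: float
    final_error_median: float
    speed_median: float
    n_reps: int
    seeds: tuple[int, ...]
    n_mod: int = 0
    passive_magnitude: float = float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        return d


@dataclass(frozen=True)
class RegressionResult:
    """Coefficients of X = k1 PB + k2 DB + k3 with the overall F-test and
    the variance inflation factors of the two criteria."""

    k1: float
    k2: float
    k3: float
    r_squared: float
    f_p_value: float
    vif_pb: float
    vif_db: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _train_synergy_reps(
    w_syn: np.ndarray,
    plant: Plant,
    tasks: TaskSet,
    config: TrainConfig,
    n_reps: int,
    n_m1: int,
    rep_seed_base: int,
) -> tuple[float, float, tuple[int, ...]]:
    """Median final error and median learning speed over seeded reps."""
    errors, speeds, seeds = [], [], []
    for rep in range(n_reps):
        seed = rep_seed_base + rep
        reference = init_nonsynergy(plant.n_mus, n_m1=n_m1, seed=seed)
        state = init_synergy(w_syn, plant, reference, n_m1=n_m1, seed=seed)
        cfg = dataclasses.replace(config, seed=seed)
        state, curve = train(state, plant, tasks, cfg)
        errors.append(final_error(curve, config.final_window))
        speeds.append(fit_learning_speed(curve).v)
        seeds.append(seed)
    return float(np.median(errors)), float(np.median(speeds)), tuple(seeds)


def run_module_comparison(
    plant: Plant,
    perturbations: list[tuple[float, float]],
    config: TrainConfig | None = None,
    n_reps: int = 30,
    n_m1: int = DEFAULT_N_M1,
    n_mod: int | None = None,
    vaf_threshold: float = 0.95,
) -> list[ExperimentRecord]:
    """Synergy-vs-non-synergy comparison with context-transplanted modules.

    Trains a non-synergy model on the base plant, extracts NMF modules from
    it and from each perturbed context (plant columns rotated by the stated
    degrees, passive torque rescaled to the stated magnitude -- an emulation
    of extracting synergies at a different posture), then trains synergy
    models with each module set *on the base plant* for ``n_reps`` seeded
    repetitions.  The non-synergy baseline's DB/PB use the identity synergy
    matrix.  ``n_mod`` defaults to the VAF-selected count on the base
    context.
    """
    if config is None:
        config = TrainConfig()
    tasks = make_task_targets(12, 1.0)
    records: list[ExperimentRecord] = []

    # --- non-synergy baseline (identity modules for DB/PB) -------------
    errors, speeds, seeds = [], [], []
    for rep in range(n_reps):
        seed = config.seed * 1_000 + rep
        state = init_nonsynergy(plant.n_mus, n_m1=n_m1, seed=seed)
        state, curve = train(
            state, plant, tasks, dataclasses.replace(config, seed=seed)
        )
        errors.append(final_error(curve, config.final_window))
        speeds.append(fit_learning_speed(curve).v)
        seeds.append(seed)
    ident = evaluate_criteria(module_torques(plant, np.eye(plant.n_mus)), plant.t_pl)
    records.append(
        ExperimentRecord(
            condition="nonsynergy",
            db=ident.db,
            pb=ident.pb,
            final_error_median=float(np.median(errors)),
            speed_median=float(np.median(speeds)),
            n_reps=n_reps,
            seeds=tuple(seeds),
            n_mod=plant.n_mus,
            passive_magnitude=float(np.linalg.norm(plant.t_pl)),
        )
    )

    # --- NMF modules from the base and perturbed contexts --------------
    contexts = [("base", 0.0, float(np.linalg.norm(plant.t_pl)))] + [
        (f"rot{rot:g}_tpl{mag:g}", rot, mag) for rot, mag in perturbations
    ]
    for ctx_idx, (label, rot_deg, tpl_mag) in enumerate(contexts):
        ctx_plant = _perturb_plant(plant, rot_deg, tpl_mag)
        src_seed = config.seed * 1_000 + 101 * (ctx_idx + 1)
        src_state = init_nonsynergy(ctx_plant.n_mus, n_m1=n_m1, seed=src_seed)
        src_state, src_curve = train(
            src_state,
            ctx_plant,
            tasks,
            dataclasses.replace(config, seed=src_seed),
            record_activations=True,
        )
        acts = src_curve.activations[-config.final_window :]
        k = n_mod if n_mod is not None else choose_n_synergies(acts, vaf_threshold)
        wset, _, _ = nmf_extract(acts, k, seed=src_seed)
        crit = evaluate_criteria(module_torques(plant, wset), plant.t_pl)
        err_med, spd_med, seeds = _train_synergy_reps(
            wset.w_syn, plant, tasks, config, n_reps, n_m1,
            rep_seed_base=src_seed * 10,
        )
        records.append(
            ExperimentRecord(
                condition=f"nmf_{label}",
                db=crit.db,
                pb=crit.pb,
                final_error_median=err_med,
                speed_median=spd_med,
                n_reps=n_reps,
                seeds=seeds,
                n_mod=k,
                passive_magnitude=float(np.linalg.norm(plant.t_pl)),
            )
        )
    return records


def _perturb_plant(plant: Plant, rot_deg: float, tpl_mag: float) -> Plant:
    """Context-change emulation: rotate the active torque columns and
    rescale the passive torque magnitude."""
    if rot_deg == 0.0 and tpl_mag == float(np.linalg.norm(plant.t_pl)):
        return plant
    th = np.deg2rad(rot_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rotated = Plant(
        D=R @ plant.D, t_pl=R @ plant.t_pl, seed=plant.seed, validate=False
    )
    if tpl_mag != float(np.linalg.norm(rotated.t_pl)) and np.linalg.norm(rotated.t_pl) > 0:
        rotated = scale_passive(rotated, tpl_mag)
    return rotated


def run_criteria_sweep(
    plant: Plant,
    kind: str,
    n_sets: int,
    n_mod: int = 4,
    cutoff: float = CUTOFF_SINGLE,
    config: TrainConfig | None = None,
    n_reps: int = 30,
    n_m1: int = DEFAULT_N_M1,
    dataset: ActivationDataset | None = None,
    max_draws_factor: int = 10,
) -> list[ExperimentRecord]:
    """Generate feasible module sets of one kind and measure their
    performance.

    ``kind`` is ``fsfordb`` (equal amplitudes, direction varies),
    ``fsforpb`` (regular directions, gains vary) or ``joint`` (both vary).
    Candidate sets failing the feasibility cutoff are logged with their
    DB/PB and resampled.  Returns one record per admitted set.
    """
    if kind not in {"fsfordb", "fsforpb", "joint"}:
        raise ValueError(f"unknown generator kind {kind!r}")
    if config is None:
        config = TrainConfig()
    if dataset is None:
        dataset = build_activation_dataset(plant, TrainConfig(
            alpha=DATASET_ALPHA, beta=config.beta, n_trials=DATASET_TRIALS,
            seed=config.seed, final_window=config.final_window,
        ), n_m1=n_m1)
    tasks = make_task_targets(12, 1.0)
    tpl_mag = float(np.linalg.norm(plant.t_pl))
    records: list[ExperimentRecord] = []
    n_rejected = 0
    draw = 0
    max_draws = max_draws_factor * n_sets
    while len(records) < n_sets and draw < max_draws:
        set_seed = config.seed * 100_000 + draw
        draw += 1
        if kind == "fsfordb":
            wset = sample_fsfordb(dataset, n_mod, seed=set_seed)
        elif kind == "fsforpb":
            wset = sample_fsforpb(
                dataset, n_mod, plant.t_pl, seed=set_seed, plant=plant
            )
        else:
            wset = sample_fs_joint(dataset, n_mod, seed=set_seed)
        crit = evaluate_criteria(module_torques(plant, wset), plant.t_pl)
        cfg_filter = dataclasses.replace(config, seed=set_seed)
        if not feasibility_filter(wset, plant, tasks, cutoff, cfg_filter, n_m1):
            n_rejected += 1
            logger.info(
                "rejected %s set (seed %d): DB=%.2f deg PB=%.3f Nm above "
                "cutoff %.2f Nm", kind, set_seed, crit.db, crit.pb, cutoff,
            )
            continue
        # common random numbers: every set is trained with the same block of
        # repetition seeds, so between-set performance differences are not
        # diluted by initialization noise
        err_med, spd_med, seeds = _train_synergy_reps(
            wset.w_syn, plant, tasks, config, n_reps, n_m1,
            rep_seed_base=config.seed * 1_000,
        )
        records.append(
            ExperimentRecord(
                condition=f"{kind}_{len(records):03d}",
                db=crit.db,
                pb=crit.pb,
                final_error_median=err_med,
                speed_median=spd_med,
                n_reps=n_reps,
                seeds=seeds,
                n_mod=n_mod,
                passive_magnitude=tpl_mag,
            )
        )
    if len(records) < n_sets:
        raise RuntimeError(
            f"generator exhausted: {len(records)}/{n_sets} sets admitted in "
            f"{draw} draws (acceptance rate "
            f"{(draw - n_rejected) / max(draw, 1):.2f})"
        )
    if n_rejected:
        logger.info("%d/%d candidate %s sets rejected by the feasibility "
                    "cutoff", n_rejected, draw, kind)
    return records


def run_dimensionality_baseline(
    plant: Plant,
    n_mods: list[int],
    config: TrainConfig | None = None,
    n_reps: int = 30,
    n_m1: int = DEFAULT_N_M1,
    dataset: ActivationDataset | None = None,
) -> list[ExperimentRecord]:
    """One DB ~ 0, PB = 0 module set per module count (equal-gain FSforPB
    construction), trained ``n_reps`` times each, for cross-dimensionality
    comparison of achievable performance."""
    if config is None:
        config = TrainConfig()
    if dataset is None:
        dataset = build_activation_dataset(plant, TrainConfig(
            alpha=DATASET_ALPHA, beta=config.beta, n_trials=DATASET_TRIALS,
            seed=config.seed, final_window=config.final_window,
        ), n_m1=n_m1)
    tasks = make_task_targets(12, 1.0)
    records: list[ExperimentRecord] = []
    for n_mod in n_mods:
        wset = sample_fsforpb(
            dataset, n_mod, plant.t_pl, seed=config.seed + n_mod,
            plant=plant, equal_gains=True,
        )
        crit = evaluate_criteria(module_torques(plant, wset), plant.t_pl)
        err_med, spd_med, seeds = _train_synergy_reps(
            wset.w_syn, plant, tasks, config, n_reps, n_m1,
            rep_seed_base=config.seed * 1_000,
        )
        records.append(
            ExperimentRecord(
                condition=f"baseline_nmod{n_mod}",
                db=crit.db,
                pb=crit.pb,
                final_error_median=err_med,
                speed_median=spd_med,
                n_reps=n_reps,
                seeds=seeds,
                n_mod=n_mod,
                passive_magnitude=float(np.linalg.norm(plant.t_pl)),
            )
        )
    return records


def _response(records: list[ExperimentRecord], response: str) -> np.ndarray:
    if response == "error":
        return np.array([r.final_error_median for r in records])
    if response == "speed":
        return np.array([r.speed_median for r in records])
    raise ValueError("response must be 'error' or 'speed'")


def fit_db_pb_regression(
    records: list[ExperimentRecord], response: str = "error"
) -> RegressionResult:
    """OLS of the chosen response on (PB, DB) with intercept, overall
    F-test p-value, and VIF_j = 1 / (1 - R_j^2) from regressing each
    criterion on the other."""
    if len(records) < 4:
        raise ValueError("need at least 4 records for the two-criterion fit")
    pb = np.array([r.pb for r in records])
    db = np.array([r.db for r in records])
    if np.ptp(pb) == 0 or np.ptp(db) == 0:
        raise ValueError("rank-deficient design: a criterion is constant")
    y = _response(records, response)
    X = sm.add_constant(np.column_stack([pb, db]))
    fit = sm.OLS(y, X).fit()
    r2_cross = stats.linregress(db, pb).rvalue ** 2
    vif = 1.0 / (1.0 - r2_cross) if r2_cross < 1 else float("inf")
    return RegressionResult(
        k1=float(fit.params[1]),
        k2=float(fit.params[2]),
        k3=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_p_value=float(fit.f_pvalue),
        vif_pb=vif,
        vif_db=vif,
    )


def correlate(
    records: list[ExperimentRecord], criterion: str, response: str
) -> tuple[float, float, float]:
    """Univariate first-order regression of a response on one criterion.
    Returns (r_squared, p_value, slope); the p-value is the overall F-test,
    which for a single regressor equals the slope t-test."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    if criterion == "db":
        x = np.array([r.db for r in records])
    elif criterion == "pb":
        x = np.array([r.pb for r in records])
    else:
        raise ValueError("criterion must be 'db' or 'pb'")
    if np.ptp(x) == 0:
        raise ValueError("criterion is constant across records")
    y = _response(records, response)
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)


def records_to_frame(records: list[ExperimentRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (seed lists JSON-encoded)."""
    rows = []
    for r in records:
        d = r.to_dict()
        d["seeds"] = json.dumps(d["seeds"])
        rows.append(d)
    return pd.DataFrame(rows)


def write_records(
    records: list[ExperimentRecord],
    out_dir: str | Path,
    name: str,
    manifest: dict | None = None,
) -> Path:
    """Write records as CSV plus a JSON manifest with all seeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    records_to_frame(records).to_csv(csv_path, index=False)
    meta = {
        "name": name,
        "n_records": len(records),
        "seeds": [list(r.seeds) for r in records],
    }
    if manifest:
        meta.update(manifest)
    (out_dir / f"{name}_manifest.json").write_text(json.dumps(meta, indent=2))
    return csv_path
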