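"""Isometric musculoskeletal plant: toy Hill-form muscles, the affine
activation-to-force approximation and its least-squares fitter, synthetic
plant generation, and torque computation.

The plant is a two-joint (shoulder horizontal flexion/extension, elbow
flexion/extension) isometric torque producer.  At a fixed posture each
muscle's force is affine in its activation, so the whole plant reduces to

    T = D a + t_pl,

where ``D`` (2 x N_mus, Nm per unit activation) is the active torque map --
moment arms times maximum isometric forces times active force coefficients --
and ``t_pl`` (2-vector, Nm) is the constant passive torque produced when all
activations are zero.  One ``Plant`` instance corresponds to one posture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "ToyMuscleParams",
    "AffineMuscle",
    "Plant",
    "toy_muscle_force",
    "sample_muscle_forces",
    "fit_affine_coefficients",
    "make_synthetic_plant",
    "plant_torque",
    "module_torques",
    "scale_passive",
    "save_plant",
    "load_plant",
]

# Radius (Nm) of the torque-target circle the feasibility check probes.
TARGET_RADIUS = 1.0
# Number of directions on the dense angular grid of the feasibility check.
FEASIBILITY_GRID = 120
# Residual (Nm) below which a nonnegative least-squares solve counts as exact.
FEASIBILITY_TOL = 1e-8


def _default_active_fl(l: float) -> float:
    """Unimodal active force-length curve, peak 1 at optimal length l = 1."""
    return float(np.exp(-(((l - 1.0) / 0.45) ** 2)))


def _default_passive_fl(l: float) -> float:
    """Nonnegative, monotone passive force-length curve; zero below slack
    length l = 1, exponential toe region above it."""
    return float(max(math.expm1(4.0 * (l - 1.0)), 0.0) / math.expm1(2.0))


@dataclass(frozen=True)
class ToyMuscleParams:
    """Parameters of a rigid-tendon toy muscle at a fixed posture.

    ``fiber_length`` is the normalized fiber length fixed by the posture
    (rigid-tendon convention), so force is exactly affine in activation
    unless ``quadratic_gain`` is nonzero.  The optional quadratic term exists
    to give the affine fitter a nontrivial residual to work on.
    """

    f_iso: float
    active_fl_curve: Callable[[float], float] = _default_active_fl
    passive_fl_curve: Callable[[float], float] = _default_passive_fl
    pennation_cos: float = 1.0
    fiber_length: float = 1.0
    quadratic_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.f_iso <= 0:
            raise ValueError(f"f_iso must be positive, got {self.f_iso}")
        if not 0 < self.pennation_cos <= 1:
            raise ValueError(
                f"pennation_cos must be in (0, 1], got {self.pennation_cos}"
            )


def toy_muscle_force(params: ToyMuscleParams, activation: float) -> float:
    """Force (N) of a toy muscle at the given activation.

    F = f_iso * (a * f_AL(l) + f_PL(l) + quadratic_gain * a^2) * cos(psi)

    Raises ``ValueError`` if activation lies outside [0, 1].
    """
    a = float(activation)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation must be in [0, 1], got {a}")
    l = params.fiber_length
    fl_a = params.active_fl_curve(l)
    fl_p = params.passive_fl_curve(l)
    if fl_p < 0:
        raise ValueError("passive force-length curve must be nonnegative")
    norm_force = a * fl_a + fl_p + params.quadratic_gain * a * a
    return params.f_iso * norm_force * params.pennation_cos


def sample_muscle_forces(
    params: ToyMuscleParams, n_samples: int = 20, delta: float = 0.05
) -> np.ndarray:
    """Sample (activation, force) pairs on a regular activation grid.

    Default: 20 samples at activation intervals of 0.05 starting at 0.
    Returns an (n_samples, 2) array.
    """
    activations = np.arange(n_samples) * delta
    if activations[-1] > 1.0 + 1e-12:
        raise ValueError("activation grid exceeds 1")
    forces = [toy_muscle_force(params, a) for a in activations]
    return np.column_stack([activations, forces])


@dataclass(frozen=True)
class AffineMuscle:
    """Affine activation-to-force model F = f_iso * (k_al * a + k_pl).

    ``fit_stats`` carries the regression diagnostics: mean absolute error and
    median absolute deviation of the normalized-force residuals in percent of
    f_iso, the coefficient of determination, and the F-test p-value of the
    linear fit.
    """

    f_iso: float
    k_al: float
    k_pl: float
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f_iso <= 0:
            raise ValueError("f_iso must be positive")
        if self.k_al < 0 or self.k_pl < 0:
            raise ValueError("force coefficients must be nonnegative")

    def force(self, activation: float) -> float:
        return self.f_iso * (self.k_al * activation + self.k_pl)


def fit_affine_coefficients(
    samples: Sequence[Sequence[float]] | np.ndarray, f_iso: float
) -> AffineMuscle:
    """Ordinary least squares of normalized force (force / f_iso) on activation.

    The slope is the active force coefficient k_al and the intercept the
    passive coefficient k_pl.  Requires at least two distinct activation
    values; identical activations raise a singular-design ``ValueError``.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("samples must be an (n >= 2, 2) array of (activation, force)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples contain non-finite values")
    a, f = arr[:, 0], arr[:, 1] / f_iso
    if np.ptp(a) == 0:
        raise ValueError("singular design: all activation values identical")
    res = stats.linregress(a, f)
    resid = f - (res.slope * a + res.intercept)
    fit_stats = {
        "mean_error_pct": float(np.mean(np.abs(resid)) * 100.0),
        "mad_pct": float(stats.median_abs_deviation(resid, scale="normal") * 100.0),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }
    return AffineMuscle(
        f_iso=f_iso,
        k_al=max(res.slope, 0.0),
        k_pl=max(res.intercept, 0.0),
        fit_stats=fit_stats,
    )


@dataclass(frozen=True)
class Plant:
    """Affine isometric plant: torque = D @ a + t_pl.

    On construction (unless ``validate=False``) the plant checks that every
    torque target on the 1 Nm circle is reachable with nonnegative
    activations, by solving a nonnegative least-squares feasibility problem
    on a dense angular grid.  Hand-built low-dimensional plants used for
    analytic checks may skip validation.
    """

    D: np.ndarray
    t_pl: np.ndarray
    muscle_names: tuple[str, ...] | None = None
    seed: int | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        D = np.atleast_2d(np.asarray(self.D, dtype=float))
        t_pl = np.asarray(self.t_pl, dtype=float).reshape(-1)
        if D.shape[0] != 2:
            raise ValueError(f"D must have exactly 2 rows, got shape {D.shape}")
        if t_pl.shape != (2,):
            raise ValueError("t_pl must be a length-2 vector")
        if not np.all(np.isfinite(D)) or not np.all(np.isfinite(t_pl)):
            raise ValueError("plant matrices must be finite")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "t_pl", t_pl)
        if self.muscle_names is not None:
            names = tuple(self.muscle_names)
            if len(names) != D.shape[1]:
                raise ValueError("muscle_names length must match number of columns")
            object.__setattr__(self, "muscle_names", names)
        if self.validate and not _is_feasible(D, t_pl):
            raise ValueError(
                "plant is infeasible: some unit-circle torque target is not "
                "reachable with nonnegative activations"
            )

    @property
    def n_mus(self) -> int:
        return self.D.shape[1]


def _is_feasible(
    D: np.ndarray,
    t_pl: np.ndarray,
    radius: float = TARGET_RADIUS,
    n_grid: int = FEASIBILITY_GRID,
) -> bool:
    """True if D a + t_pl = u has a nonnegative solution for every direction u
    on a dense grid of the radius-``radius`` circle."""
    angles = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    for ang in angles:
        u = radius * np.array([np.cos(ang), np.sin(ang)])
        _, resid = nnls(D, u - t_pl)
        if resid > FEASIBILITY_TOL:
            return False
    return True


def make_synthetic_plant(
    n_mus: int = 22,
    passive_magnitude: float = 0.5,
    seed: int = 0,
    max_redraws: int = 50,
) -> Plant:
    """Generate a seeded synthetic plant emulating a multi-muscle two-joint
    isometric system.

    Column torque directions are stratified over eight 45-degree sectors
    (guaranteeing agonist/antagonist coverage of all four quadrants) with
    log-normal amplitudes (median 1 Nm, sigma_log = 0.5).  The passive torque
    points in a seeded random direction with exact magnitude
    ``passive_magnitude``.  Construction redraws until the unit-circle
    feasibility invariant holds; identical seeds give identical plants.
    """
    if n_mus < 4:
        raise ValueError("n_mus must be at least 4 for planar positive span")
    if passive_magnitude < 0:
        raise ValueError("passive_magnitude must be nonnegative")
    rng = np.random.default_rng(seed)
    tpl_angle = rng.uniform(0.0, 2.0 * np.pi)
    t_pl = passive_magnitude * np.array([np.cos(tpl_angle), np.sin(tpl_angle)])
    for _ in range(max_redraws):
        sectors = np.arange(n_mus) % 8
        angles = np.deg2rad(sectors * 45.0 + rng.uniform(0.0, 45.0, size=n_mus))
        amplitudes = np.exp(rng.normal(0.0, 0.5, size=n_mus))
        D = np.vstack([np.cos(angles), np.sin(angles)]) * amplitudes
        if _is_feasible(D, t_pl):
            names = tuple(f"mus{i:02d}" for i in range(n_mus))
            return Plant(D=D, t_pl=t_pl, muscle_names=names, seed=seed)
    raise RuntimeError(
        f"could not draw a feasible plant in {max_redraws} attempts "
        f"(n_mus={n_mus}, passive_magnitude={passive_magnitude})"
    )


def plant_torque(plant: Plant, activation: np.ndarray) -> np.ndarray:
    """Joint torque (Nm) produced by an activation vector: D @ a + t_pl.

    Negative activations are a domain error -- rectification is the
    controller's job, not the plant's.
    """
    a = np.asarray(activation, dtype=float).reshape(-1)
    if a.shape[0] != plant.n_mus:
        raise ValueError(
            f"activation length {a.shape[0]} != number of muscles {plant.n_mus}"
        )
    if np.any(a < 0):
        raise ValueError("activations must be nonnegative")
    return plant.D @ a + plant.t_pl


def module_torques(plant: Plant, w_syn) -> np.ndarray:
    """Active torque of each module: column i is D @ w_syn[:, i] (Nm).

    The passive torque is excluded by definition; module torque is the active
    component only.  ``w_syn`` may be an (N_mus, N_mod) array or any object
    with a ``w_syn`` attribute.
    """
    W = np.asarray(getattr(w_syn, "w_syn", w_syn), dtype=float)
    if W.ndim != 2 or W.shape[0] != plant.n_mus:
        raise ValueError(
            f"synergy matrix must have {plant.n_mus} rows, got shape {W.shape}"
        )
    if np.any(W < 0):
        raise ValueError("synergy matrix must be nonnegative")
    return plant.D @ W


def scale_passive(plant: Plant, target_magnitude: float) -> Plant:
    """Copy of the plant with |t_pl| rescaled to ``target_magnitude``,
    direction preserved; the active map D is unchanged."""
    if target_magnitude < 0:
        raise ValueError("target_magnitude must be nonnegative")
    mag = float(np.linalg.norm(plant.t_pl))
    if mag == 0.0:
        if target_magnitude == 0.0:
            return plant
        raise ValueError("cannot rescale a zero passive torque: no direction defined")
    return replace(plant, t_pl=plant.t_pl * (target_magnitude / mag), validate=False)


def save_plant(plant: Plant, path: str | Path) -> None:
    """Write the plant as CSV (two D rows then one t_pl row) with a JSON
    sidecar carrying names and provenance."""
    path = Path(path)
    np.savetxt(path, plant.D, delimiter=",")
    with path.open("a") as fh:
        fh.write(",".join(f"{v:.18e}" for v in plant.t_pl) + "\n")
    sidecar = {
        "n_mus": plant.n_mus,
        "muscle_names": list(plant.muscle_names) if plant.muscle_names else None,
        "seed": plant.seed,
        "format": "rows: D joint 1, D joint 2, t_pl",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_plant(path: str | Path, validate: bool = True) -> Plant:
    """Load a plant written by :func:`save_plant`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().strip().splitlines() if ln.strip()]
    if len(lines) != 3:
        raise ValueError("plant CSV must have exactly 3 rows (D x2, t_pl)")
    D = np.array([[float(v) for v in lines[i].split(",")] for i in range(2)])
    t_pl = np.array([float(v) for v in lines[2].split(",")][:2])
    names = None
    seed = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = tuple(meta["muscle_names"]) if meta.get("muscle_names") else None
        seed = meta.get("seed")
    return Plant(D=D, t_pl=t_pl, muscle_names=names, seed=seed, validate=validate)
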