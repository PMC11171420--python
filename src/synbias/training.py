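"""Task definition, the error-feedback-with-decay learning rule, training
loops, final-error summary, and learning-speed estimation.

Each trial draws one target torque uniformly from the task set, runs the
forward pass, and applies one stochastic-gradient step with weight decay:

    w_inp <- w_inp - alpha * dJ/dw_inp - beta * w_inp,   J = 1/2 |tau - T|^2

The gradient flows through the plant's active torque map, the (optional)
synergy matrix, the innervation matrix and the rectifier (subgradient 1
where pre_activation > 0, else 0 -- including exactly at 0).  The per-trial
error norm |e| is recorded *before* the update, so the learning curve
reflects performance at presentation time.

The learning rate default is calibrated to the default synthetic plant
(unit-scale torque columns, 1000 M1 neurons, unit-norm innervation columns)
so that the non-synergy baseline converges over thousands of trials with a
learning speed v of a few 1e-3 per trial and a final error of a few
hundredths of a Nm; see docs/methods.md for the stability analysis.

A numba-compiled kernel drives :func:`train`; :func:`train_step` is the
plain-numpy reference implementation of a single trial, and the two are
held together by an equivalence test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

from .network import NetworkState
from .plant import Plant

__all__ = [
    "TaskSet",
    "TrainConfig",
    "LearningCurve",
    "SpeedFit",
    "TrainingDivergenceError",
    "SpeedFitError",
    "make_task_targets",
    "train_step",
    "train",
    "final_error",
    "fit_learning_speed",
]

DEFAULT_ALPHA = 3e-5
DEFAULT_BETA = 1e-4
DEFAULT_N_TRIALS = 25_000
DEFAULT_FINAL_WINDOW = 100


class TrainingDivergenceError(RuntimeError):
    """Raised when training produces a non-finite error, naming the trial."""


class SpeedFitError(RuntimeError):
    """Raised when the exponential learning-speed fit fails to converge;
    carries the best parameters found so far."""

    def __init__(self, message: str, best: "SpeedFit | None" = None) -> None:
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class TaskSet:
    """Torque targets evenly spaced on a circle of the given radius (Nm)."""

    targets: np.ndarray
    radius: float
    spacing: float

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if t.shape[1] != 2:
            raise ValueError("targets must be (n, 2)")
        object.__setattr__(self, "targets", t)

    @property
    def n_targets(self) -> int:
        return self.targets.shape[0]


def make_task_targets(n: int = 12, radius: float = 1.0) -> TaskSet:
    """n targets at angles 0, 360/n, ... degrees, all with |tau| = radius.

    The standard task is n = 12 on the 1 Nm circle (30-degree intervals);
    the dataset-building grid uses n = 120 (3-degree intervals).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    ang = np.deg2rad(np.arange(n) * 360.0 / n)
    targets = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return TaskSet(targets=targets, radius=radius, spacing=360.0 / n)


@dataclass(frozen=True)
class TrainConfig:
    """Learning hyperparameters.

    alpha: learning rate; beta: weight-decay rate; n_trials: number of
    training trials; seed: RNG seed for target draws; final_window: number
    of closing trials averaged by :func:`final_error`.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    n_trials: int = DEFAULT_N_TRIALS
    seed: int = 0
    final_window: int = DEFAULT_FINAL_WINDOW

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.n_trials < 0:
            raise ValueError("n_trials must be nonnegative")


@dataclass(frozen=True)
class LearningCurve:
    """Per-trial error norms |e_t| (Nm) and the drawn target indices.
    ``activations`` optionally holds the per-trial rectified activations
    (recorded when dataset building needs them)."""

    errors: np.ndarray
    targets_drawn: np.ndarray
    activations: np.ndarray | None = None

    def __len__(self) -> int:
        return self.errors.shape[0]


@dataclass(frozen=True)
class SpeedFit:
    """Parameters of |e_t| = gamma1 * exp(-v t) + gamma2 with the residual
    sum of squares of the fit."""

    gamma1: float
    v: float
    gamma2: float
    residual: float


@njit(cache=True)
def _train_kernel(
    w_inp, zeff, D, t_pl, targets, idx, alpha, beta, bias, errs, acts, record
):  # pragma: no cover - exercised through train()
    """In-place training loop.  Returns the trial index at which a
    non-finite error appeared, or -1 on clean completion."""
    n_trials = idx.shape[0]
    n_out, n_m1 = zeff.shape
    x = np.empty(4)
    x[2] = bias[0]
    x[3] = bias[1]
    g = np.empty(n_out)
    for t in range(n_trials):
        tau0 = targets[idx[t], 0]
        tau1 = targets[idx[t], 1]
        x[0] = tau0
        x[1] = tau1
        u = w_inp @ x
        pre = zeff @ u
        T0 = t_pl[0]
        T1 = t_pl[1]
        for i in range(n_out):
            a = pre[i] if pre[i] > 0.0 else 0.0
            T0 += D[0, i] * a
            T1 += D[1, i] * a
            if record:
                acts[t, i] = a
        e0 = tau0 - T0
        e1 = tau1 - T1
        errs[t] = np.sqrt(e0 * e0 + e1 * e1)
        if not np.isfinite(errs[t]):
            return t
        for i in range(n_out):
            if pre[i] > 0.0:
                g[i] = -(D[0, i] * e0 + D[1, i] * e1)
            else:
                g[i] = 0.0
        gw = zeff.T @ g
        for j in range(n_m1):
            gj = alpha * gw[j]
            w_inp[j, 0] -= gj * x[0] + beta * w_inp[j, 0]
            w_inp[j, 1] -= gj * x[1] + beta * w_inp[j, 1]
            w_inp[j, 2] -= gj * x[2] + beta * w_inp[j, 2]
            w_inp[j, 3] -= gj * x[3] + beta * w_inp[j, 3]
    return -1


def train_step(
    state: NetworkState, plant: Plant, target: np.ndarray, config: TrainConfig
) -> tuple[NetworkState, float]:
    """One learning trial on one target (numpy reference implementation).

    Updates ``state.w_inp`` in place and returns (state, |e|) with the error
    measured before the update.  Raises :class:`TrainingDivergenceError` on
    a non-finite gradient.
    """
    tau = np.asarray(target, dtype=float).reshape(2)
    x = np.concatenate([tau, state.bias])
    zeff = state.zeff
    pre = zeff @ (state.w_inp @ x)
    a = np.maximum(pre, 0.0)
    T = plant.D @ a + plant.t_pl
    e = tau - T
    err = float(np.linalg.norm(e))
    g = -(plant.D.T @ e) * (pre > 0.0)
    grad = np.outer(zeff.T @ g, x)
    if not np.all(np.isfinite(grad)):
        raise TrainingDivergenceError("non-finite gradient in train_step")
    state.w_inp -= config.alpha * grad + config.beta * state.w_inp
    return state, err


def train(
    state: NetworkState,
    plant: Plant,
    tasks: TaskSet,
    config: TrainConfig,
    record_activations: bool = False,
) -> tuple[NetworkState, LearningCurve]:
    """Train for ``config.n_trials`` trials, drawing one target uniformly
    per trial with ``config.seed``; seed-deterministic and bit-reproducible.

    Returns the trained state and the full learning curve.  Raises
    :class:`TrainingDivergenceError` naming the trial if the error goes
    non-finite.
    """
    if config.n_trials == 0:
        return state, LearningCurve(
            errors=np.empty(0), targets_drawn=np.empty(0, dtype=np.int64)
        )
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, tasks.n_targets, size=config.n_trials)
    errs = np.empty(config.n_trials)
    zeff = np.ascontiguousarray(state.zeff)
    n_out = zeff.shape[0]
    acts = (
        np.empty((config.n_trials, n_out))
        if record_activations
        else np.empty((1, 1))
    )
    bad = _train_kernel(
        state.w_inp,
        zeff,
        np.ascontiguousarray(plant.D),
        plant.t_pl,
        np.ascontiguousarray(tasks.targets),
        idx,
        float(config.alpha),
        float(config.beta),
        state.bias,
        errs,
        acts,
        record_activations,
    )
    if bad >= 0:
        raise TrainingDivergenceError(
            f"training diverged (non-finite error) at trial {bad}"
        )
    curve = LearningCurve(
        errors=errs,
        targets_drawn=idx,
        activations=acts if record_activations else None,
    )
    return state, curve


def final_error(curve: LearningCurve, window: int = DEFAULT_FINAL_WINDOW) -> float:
    """Arithmetic mean of the last ``window`` per-trial error norms (Nm)."""
    if len(curve) == 0:
        raise ValueError("cannot summarize an empty learning curve")
    if window > len(curve):
        raise ValueError(f"window {window} exceeds curve length {len(curve)}")
    return float(np.mean(curve.errors[-window:]))


def _exp_model(t: np.ndarray, g1: float, v: float, g2: float) -> np.ndarray:
    return g1 * np.exp(-v * t) + g2


def fit_learning_speed(
    curve: LearningCurve | np.ndarray,
    smooth_window: int | None = None,
    max_restarts: int = 5,
) -> SpeedFit:
    """Nonlinear least squares of |e_t| = gamma1 exp(-v t) + gamma2.

    Initialization: gamma2 = mean of the last decile, gamma1 = mean of the
    first decile minus gamma2, v = 10 / n_trials; all three parameters are
    constrained nonnegative.  Restarts with perturbed rate guesses on
    failure; after ``max_restarts`` failures raises :class:`SpeedFitError`
    carrying the best fit so far.  ``smooth_window`` optionally applies a
    centered moving average before fitting (off by default: the raw trial
    errors are fitted).
    """
    e = curve.errors if isinstance(curve, LearningCurve) else np.asarray(curve, float)
    if e.shape[0] < 3:
        raise ValueError("need at least 3 trials to fit a learning speed")
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        e = np.convolve(e, kernel, mode="valid")
    t = np.arange(e.shape[0], dtype=float)
    dec = max(e.shape[0] // 10, 1)
    g2_0 = float(np.mean(e[-dec:]))
    g1_0 = max(float(np.mean(e[:dec])) - g2_0, 1e-12)
    v_0 = 10.0 / e.shape[0]
    best: SpeedFit | None = None
    last_exc: Exception | None = None
    # the loss surface has shallow local minima (e.g. a huge rate fitted to
    # the first-trial transient), so always try a ladder of rate guesses and
    # keep the lowest-residual fit
    for k in range(max_restarts):
        p0 = [g1_0, v_0 * (4.0**k), g2_0]
        try:
            popt, _ = curve_fit(
                _exp_model,
                t,
                e,
                p0=p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20_000,
            )
        except RuntimeError as exc:
            last_exc = exc
            continue
        resid = float(np.sum((_exp_model(t, *popt) - e) ** 2))
        fit = SpeedFit(
            gamma1=float(popt[0]),
            v=float(popt[1]),
            gamma2=float(popt[2]),
            residual=resid,
        )
        if best is None or fit.residual < best.residual:
            best = fit
    if best is not None:
        return best
    raise SpeedFitError(
        f"learning-speed fit failed after {max_restarts} restarts: {last_exc}",
        best=None,
    )
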