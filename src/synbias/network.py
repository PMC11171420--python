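"""Feedforward controllers for isometric torque production.

Two architectures share the input convention x = (tau_1, tau_2, b_1, b_2):
the desired torque plus two constant task-irrelevant bias inputs (the bias
lets the network cancel the plant's constant passive torque).

Non-synergy model:   a = relu(Z  W_inp x)      Z:     N_mus x n_m1
Synergy model:       a = relu(W_syn Z_syn W_inp x)   Z_syn: N_mod x n_m1

W_inp (n_m1 x 4) is the only learned matrix; the innervation matrix Z (or
Z_syn) and the synergy matrix W_syn are fixed.  The M1 layer defaults to
1000 neurons.  Z columns are initialized uniformly on the unit hypersphere;
Z_syn is additionally rescaled globally so the mean torque amplitude of
M1-neuron output directions matches a reference non-synergy network, which
makes synergy/non-synergy comparisons fair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .plant import Plant, plant_torque

__all__ = [
    "NetworkState",
    "DEFAULT_N_M1",
    "DEFAULT_SIGMA_INIT",
    "DEFAULT_BIAS",
    "init_nonsynergy",
    "init_synergy",
    "make_input",
    "forward",
    "save_network",
    "load_network",
]

logger = logging.getLogger(__name__)

DEFAULT_N_M1 = 1000
DEFAULT_SIGMA_INIT = 0.01
DEFAULT_BIAS = (1.0, 1.0)


@dataclass
class NetworkState:
    """Everything the forward pass needs.

    ``z`` maps M1 to muscles (non-synergy; N_mus rows) or to modules
    (synergy; N_mod rows, in which case ``w_syn`` maps modules to muscles).
    """

    w_inp: np.ndarray
    z: np.ndarray
    bias: np.ndarray
    w_syn: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w_inp = np.asarray(self.w_inp, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float).reshape(2)
        if self.w_inp.ndim != 2 or self.w_inp.shape[1] != 4:
            raise ValueError(f"w_inp must be n_m1 x 4, got {self.w_inp.shape}")
        if self.z.shape[1] != self.w_inp.shape[0]:
            raise ValueError("z column count must equal n_m1")
        if np.all(self.bias == 0):
            raise ValueError("bias must be nonzero")
        if self.w_syn is not None:
            self.w_syn = np.asarray(self.w_syn, dtype=float)
            if self.w_syn.shape[1] != self.z.shape[0]:
                raise ValueError(
                    "w_syn must have as many columns as z has rows (N_mod)"
                )

    @property
    def n_m1(self) -> int:
        return self.w_inp.shape[0]

    @property
    def is_synergy(self) -> bool:
        return self.w_syn is not None

    @property
    def zeff(self) -> np.ndarray:
        """Effective M1-to-muscle map: Z, or W_syn @ Z_syn."""
        return self.z if self.w_syn is None else self.w_syn @ self.z

    def copy(self) -> "NetworkState":
        return NetworkState(
            w_inp=self.w_inp.copy(),
            z=self.z.copy(),
            bias=self.bias.copy(),
            w_syn=None if self.w_syn is None else self.w_syn.copy(),
        )


def _unit_columns(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """Columns i.i.d. Gaussian then normalized: uniform on the unit sphere."""
    z = rng.standard_normal((n_rows, n_cols))
    return z / np.linalg.norm(z, axis=0)


def init_nonsynergy(
    n_mus: int,
    n_m1: int = DEFAULT_N_M1,
    seed: int = 0,
    sigma_init: float = DEFAULT_SIGMA_INIT,
    bias: tuple[float, float] = DEFAULT_BIAS,
) -> NetworkState:
    """Seeded non-synergy controller: white-noise W_inp (sd ``sigma_init``)
    and innervation columns uniform on the N_mus unit sphere."""
    if n_m1 < 1:
        raise ValueError("n_m1 must be positive")
    rng = np.random.default_rng(seed)
    w_inp = rng.normal(0.0, sigma_init, size=(n_m1, 4)) if sigma_init > 0 else np.zeros((n_m1, 4))
    z = _unit_columns(rng, n_mus, n_m1)
    return NetworkState(w_inp=w_inp, z=z, bias=np.asarray(bias, dtype=float))


def init_synergy(
    w_syn: np.ndarray,
    plant: Plant,
    reference: NetworkState,
    n_m1: int = DEFAULT_N_M1,
    seed: int = 0,
    sigma_init: float = DEFAULT_SIGMA_INIT,
    bias: tuple[float, float] = DEFAULT_BIAS,
) -> NetworkState:
    """Seeded synergy controller with the fixed module matrix ``w_syn``.

    Z_syn columns start uniform on the N_mod sphere and are then globally
    rescaled so that the mean over M1 neurons j of |D W_syn z_syn[:, j]|
    equals the reference non-synergy network's mean |D z_ref[:, j]|.
    Raises if the synergy torque image is degenerate (D @ W_syn = 0).
    """
    W = np.asarray(getattr(w_syn, "w_syn", w_syn), dtype=float)
    if np.any(W < 0):
        raise ValueError("synergy matrix must be nonnegative")
    if W.shape[0] != plant.n_mus:
        raise ValueError("synergy matrix rows must match plant muscles")
    rng = np.random.default_rng(seed)
    w_inp = rng.normal(0.0, sigma_init, size=(n_m1, 4)) if sigma_init > 0 else np.zeros((n_m1, 4))
    z_syn = _unit_columns(rng, W.shape[1], n_m1)
    ref_amp = np.linalg.norm(plant.D @ reference.zeff, axis=0).mean()
    cur_amp = np.linalg.norm(plant.D @ W @ z_syn, axis=0).mean()
    if cur_amp == 0:
        raise ValueError(
            "normalization impossible: synergy torque image D @ W_syn is zero"
        )
    z_syn *= ref_amp / cur_amp
    return NetworkState(
        w_inp=w_inp, z=z_syn, bias=np.asarray(bias, dtype=float), w_syn=W
    )


def make_input(tau: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Input vector x = (tau; b)."""
    tau = np.asarray(tau, dtype=float).reshape(2)
    bias = np.asarray(bias, dtype=float).reshape(2)
    return np.concatenate([tau, bias])


def forward(
    state: NetworkState, plant: Plant, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One forward pass: returns (activation, torque, pre_activation).

    pre_activation = Zeff @ W_inp @ x; activation = max(0, pre_activation)
    (no upper clip -- activations above 1 are legal but logged); torque is
    the plant response D @ a + t_pl.
    """
    x = np.asarray(x, dtype=float).reshape(4)
    pre = state.zeff @ (state.w_inp @ x)
    a = np.maximum(pre, 0.0)
    if np.any(a > 1.0):
        logger.warning(
            "activation exceeds 1 (max %.3f); the model enforces only "
            "non-negativity",
            float(a.max()),
        )
    return a, plant_torque(plant, a), pre


def save_network(state: NetworkState, path) -> None:
    """Write a NetworkState as a JSON header plus CSV weight blocks
    (<stem>_winp.csv, <stem>_z.csv, optional <stem>_wsyn.csv)."""
    import json
    from pathlib import Path

    path = Path(path)
    stem = path.with_suffix("")
    np.savetxt(f"{stem}_winp.csv", state.w_inp, delimiter=",")
    np.savetxt(f"{stem}_z.csv", state.z, delimiter=",")
    header = {
        "n_m1": state.n_m1,
        "bias": state.bias.tolist(),
        "is_synergy": state.is_synergy,
    }
    if state.w_syn is not None:
        np.savetxt(f"{stem}_wsyn.csv", state.w_syn, delimiter=",")
    path.write_text(json.dumps(header, indent=2))


def load_network(path) -> NetworkState:
    """Load a NetworkState written by :func:`save_network`."""
    import json
    from pathlib import Path

    path = Path(path)
    stem = path.with_suffix("")
    header = json.loads(path.read_text())
    w_inp = np.loadtxt(f"{stem}_winp.csv", delimiter=",", ndmin=2)
    z = np.loadtxt(f"{stem}_z.csv", delimiter=",", ndmin=2)
    w_syn = None
    if header.get("is_synergy"):
        w_syn = np.loadtxt(f"{stem}_wsyn.csv", delimiter=",", ndmin=2)
    return NetworkState(
        w_inp=w_inp, z=z, bias=np.asarray(header["bias"]), w_syn=w_syn
    )
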