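"""Direction bias and power bias of a module set.

A module set exerts one active torque vector per module in the planar
shoulder/elbow torque space.  Because the network must cancel the constant
passive torque t_pl before it can place its output on the 1 Nm target
circle, the torques it actually has to generate lie on the *shifted* circle
|tau - t_pl| = 1, whose center is -t_pl.

Direction bias (DB, degrees) measures how irregularly the module torque
rays cover that shifted circle: each ray is intersected with the circle,
intersection points get polar angles about the circle's center, and DB is
the population standard deviation of the circular gaps between neighboring
points.  Evenly spaced points give DB = 0.

Power bias (PB, Nm) measures how uneven the module torque magnitudes are:
the population standard deviation of |T_mod_i|.  Equal amplitudes give
PB = 0.  The two criteria are independent by construction -- DB ignores
amplitudes and PB ignores directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModuleTorqueSet",
    "CriteriaResult",
    "intersect_ray_circle",
    "direction_bias",
    "power_bias",
    "evaluate_criteria",
]


@dataclass(frozen=True)
class ModuleTorqueSet:
    """Active torques of a module set: a 2 x N_mod matrix (Nm) plus a
    provenance tag (nmf | fsfordb | fsforpb | joint | identity | user)."""

    torques: np.ndarray
    source: str = "user"

    def __post_init__(self) -> None:
        T = np.atleast_2d(np.asarray(self.torques, dtype=float))
        if T.shape[0] != 2:
            raise ValueError(f"torques must be 2 x N_mod, got shape {T.shape}")
        if T.shape[1] < 2:
            raise ValueError("a module set needs at least 2 modules")
        norms = np.linalg.norm(T, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero torque column: module direction undefined")
        object.__setattr__(self, "torques", T)

    @property
    def n_mod(self) -> int:
        return self.torques.shape[1]

    @property
    def amplitudes(self) -> np.ndarray:
        return np.linalg.norm(self.torques, axis=0)


@dataclass(frozen=True)
class CriteriaResult:
    """DB (degrees) and PB (Nm) of one module set under one plant, with the
    intermediate geometry (intersection angles about the shifted-circle
    center and the circular gaps between them)."""

    db: float
    pb: float
    mean_amplitude: float
    gap_angles: tuple[float, ...] = field(default_factory=tuple)
    intersection_angles: tuple[float, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "db_deg": self.db,
            "pb_nm": self.pb,
            "mean_amplitude_nm": self.mean_amplitude,
            "gap_angles_deg": list(self.gap_angles),
            "intersection_angles_deg": list(self.intersection_angles),
        }


def intersect_ray_circle(
    direction: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Unique forward intersection of the ray {t * direction, t > 0} from the
    origin with the circle |p - center| = radius.

    Requires the origin strictly inside the circle (|center| < radius), which
    guarantees exactly one forward intersection.  Raises ``ValueError``
    otherwise (the supported geometry has |t_pl| < 1 Nm) and for a zero
    direction.
    """
    d = np.asarray(direction, dtype=float).reshape(2)
    c = np.asarray(center, dtype=float).reshape(2)
    dn = np.linalg.norm(d)
    if dn == 0:
        raise ValueError("ray direction must be nonzero")
    if np.linalg.norm(c) >= radius:
        raise ValueError(
            "unsupported geometry: the origin must lie strictly inside the "
            f"circle (|center| = {np.linalg.norm(c):.4g} >= radius = {radius:.4g})"
        )
    u = d / dn
    # |t u - c|^2 = r^2  =>  t^2 - 2 t (u.c) + |c|^2 - r^2 = 0
    uc = float(u @ c)
    disc = uc * uc - (float(c @ c) - radius * radius)
    t = uc + np.sqrt(disc)  # the unique positive root since |c| < r
    return t * u


def _circular_gaps(angles_deg: np.ndarray) -> np.ndarray:
    """Sorted circular gaps (degrees, summing to 360) between angles."""
    s = np.sort(np.mod(angles_deg, 360.0))
    gaps = np.diff(s, append=s[0] + 360.0)
    return gaps


def direction_bias(
    modules: ModuleTorqueSet | np.ndarray,
    t_pl: np.ndarray,
    radius: float = 1.0,
) -> float:
    """Direction bias (degrees) of a module set under passive torque t_pl.

    Each module torque ray is intersected with the circle of the given
    radius centered at -t_pl; intersection points get polar angles about
    that center; DB is the population standard deviation
    sqrt(mean((omega_i - mean(omega))^2)) of the circular gaps omega_i
    between neighboring points.  With t_pl = 0 this reduces to the angular
    regularity of the module directions themselves.  Duplicate directions
    are legal (gap 0).
    """
    mset = modules if isinstance(modules, ModuleTorqueSet) else ModuleTorqueSet(modules)
    t_pl = np.asarray(t_pl, dtype=float).reshape(2)
    center = -t_pl
    angles = np.empty(mset.n_mod)
    for i in range(mset.n_mod):
        p = intersect_ray_circle(mset.torques[:, i], center, radius)
        rel = p - center
        angles[i] = np.degrees(np.arctan2(rel[1], rel[0]))
    gaps = _circular_gaps(angles)
    return float(np.sqrt(np.mean((gaps - gaps.mean()) ** 2)))


def power_bias(modules: ModuleTorqueSet | np.ndarray) -> float:
    """Power bias (Nm): population standard deviation of the module torque
    amplitudes |T_mod_i| about their mean."""
    mset = modules if isinstance(modules, ModuleTorqueSet) else ModuleTorqueSet(modules)
    amp = mset.amplitudes
    return float(np.sqrt(np.mean((amp - amp.mean()) ** 2)))


def evaluate_criteria(
    modules: ModuleTorqueSet | np.ndarray,
    t_pl: np.ndarray,
    radius: float = 1.0,
) -> CriteriaResult:
    """DB and PB of a module set in one pass, retaining the intersection
    geometry for inspection."""
    mset = modules if isinstance(modules, ModuleTorqueSet) else ModuleTorqueSet(modules)
    t_pl = np.asarray(t_pl, dtype=float).reshape(2)
    center = -t_pl
    angles = np.empty(mset.n_mod)
    for i in range(mset.n_mod):
        p = intersect_ray_circle(mset.torques[:, i], center, radius)
        rel = p - center
        angles[i] = np.degrees(np.arctan2(rel[1], rel[0]))
    gaps = _circular_gaps(angles)
    db = float(np.sqrt(np.mean((gaps - gaps.mean()) ** 2)))
    amp = mset.amplitudes
    pb = float(np.sqrt(np.mean((amp - amp.mean()) ** 2)))
    return CriteriaResult(
        db=db,
        pb=pb,
        mean_amplitude=float(amp.mean()),
        gap_angles=tuple(gaps.tolist()),
        intersection_angles=tuple(np.sort(np.mod(angles, 360.0)).tolist()),
    )
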