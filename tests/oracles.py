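"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form geometry: intersections
are located by dense sampling of the circle followed by bisection root
refinement on the ray-alignment function.
"""

import numpy as np
from scipy.optimize import brentq


def dense_circle_intersection(direction, center, radius, n_samples=1_000_000):
    """Forward ray-circle intersection located by dense sampling + root
    refinement; returns the intersection point's angle (radians) about the
    circle center."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    c = np.asarray(center, float)
    phis = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    pts = c[None, :] + radius * np.column_stack([np.cos(phis), np.sin(phis)])
    # alignment: cross(d, p) vanishes where p is parallel to the ray;
    # forward side selected by dot(d, p) > 0
    cross = d[0] * pts[:, 1] - d[1] * pts[:, 0]
    dot = pts @ d
    sign = np.sign(cross)
    flips = np.nonzero((sign[:-1] * np.roll(sign, -1)[:-1] < 0))[0]

    def f(phi):
        p = c + radius * np.array([np.cos(phi), np.sin(phi)])
        return d[0] * p[1] - d[1] * p[0]

    best = None
    for i in flips:
        lo, hi = phis[i], phis[i + 1]
        if dot[i] <= 0 and dot[i + 1] <= 0:
            continue
        root = brentq(f, lo, hi, xtol=1e-14)
        p = c + radius * np.array([np.cos(root), np.sin(root)])
        if p @ d > 0:
            best = root
    assert best is not None, "no forward intersection found"
    return best


def dense_direction_bias(torques, t_pl, radius=1.0, n_samples=1_000_000):
    """DB (degrees) from dense-sampled intersections: population standard
    deviation of circular gaps between intersection angles."""
    torques = np.asarray(torques, float)
    center = -np.asarray(t_pl, float)
    angs = np.array(
        [
            dense_circle_intersection(torques[:, i], center, radius, n_samples)
            for i in range(torques.shape[1])
        ]
    )
    angs = np.degrees(np.mod(angs, 2.0 * np.pi))
    s = np.sort(angs)
    gaps = np.diff(s, append=s[0] + 360.0)
    return float(np.sqrt(np.mean((gaps - gaps.mean()) ** 2)))


def ols_normal_equations(X, y):
    """Closed-form OLS with intercept via the normal equations; returns
    (coefficients incl. intercept first, r_squared)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta, 1.0 - ss_res / ss_tot
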