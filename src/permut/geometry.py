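"""Metrics and metric-ball volumes on R^3, SO(3) and their product.

kNN entropy estimation needs, for each space, a distance and the volume of
the metric ball at a given radius:

* Euclidean d-space: V_d(r) = pi^(d/2) / Gamma(d/2 + 1) * r^d.
* SO(3) under the chordal quaternion metric
  d_quat(q1, q2) = min(||q1 - q2||, ||q1 + q2||): orientations are unit
  quaternions with antipodes identified, so the total volume is half the
  unit-3-sphere surface, pi^2. A chordal radius r corresponds to the polar
  angle alpha = 2 arcsin(r/2) on S^3, giving the closed-form cap volume
  pi (2 alpha - sin 2 alpha).
* The product R^3 x SO(3) under the composite metric
  d = sqrt((xi d_eucl)^2 + d_quat^2), with the scaling factor xi (nm^-1)
  rendering the Euclidean term unitless. Its ball volume has no closed form
  and is evaluated by quadrature over SO(3) shells, cached on a radius grid
  with monotone cubic interpolation.

The uniform-orientation entropy under this convention is ln(pi^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import gammaln

SQRT2 = math.sqrt(2.0)
SO3_TOTAL_VOLUME = math.pi**2


@dataclass
class CompositeMetricParams:
    """Scaling factor xi (nm^-1) of the composite translational-rotational
    metric. Typical distances in R^3 and SO(3) should be of the same
    magnitude; 10 nm^-1 is appropriate for liquid water and results are
    insensitive to factor-of-3 changes."""

    xi: float = 10.0

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")


def ball_volume_euclidean(d: int, r) -> np.ndarray:
    """Volume of the Euclidean d-ball of radius r."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    r = np.asarray(r, dtype=float)
    log_unit = (d / 2.0) * math.log(math.pi) - gammaln(d / 2.0 + 1.0)
    with np.errstate(divide="ignore"):
        return np.exp(log_unit) * r**d


def log_ball_volume_euclidean(d: int, r) -> np.ndarray:
    """ln of the Euclidean d-ball volume (stable for small radii)."""
    r = np.asarray(r, dtype=float)
    log_unit = (d / 2.0) * math.log(math.pi) - gammaln(d / 2.0 + 1.0)
    with np.errstate(divide="ignore"):
        return log_unit + d * np.log(r)


def _check_unit(q: np.ndarray, tol: float = 1e-9) -> None:
    norms = np.linalg.norm(np.atleast_2d(q), axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("quaternions must be unit norm")


def quat_distance(q1, q2) -> np.ndarray:
    """Chordal metric on orientations: min(||q1 - q2||, ||q1 + q2||).

    Respects the double cover (q and -q are the same orientation); values
    lie in [0, sqrt(2)].
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    _check_unit(q1)
    _check_unit(q2)
    dot = np.abs(np.sum(q1 * q2, axis=-1))
    return np.sqrt(np.maximum(2.0 - 2.0 * np.clip(dot, -1.0, 1.0), 0.0))


def composite_distance(x1, q1, x2, q2, params: CompositeMetricParams | None = None):
    """Distance on R^3 x SO(3): sqrt((xi |x1-x2|)^2 + d_quat(q1,q2)^2)."""
    if params is None:
        params = CompositeMetricParams()
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    de = np.linalg.norm(x1 - x2, axis=-1)
    dq = quat_distance(q1, q2)
    return np.sqrt((params.xi * de) ** 2 + dq**2)


def ball_volume_so3(r) -> np.ndarray:
    """SO(3) ball volume under d_quat, normalized to total volume pi^2."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    rc = np.clip(r, 0.0, SQRT2)
    alpha = 2.0 * np.arcsin(rc / 2.0)
    return math.pi * (2.0 * alpha - np.sin(2.0 * alpha))


def so3_shell_area(s) -> np.ndarray:
    """d/ds of ball_volume_so3: area of the SO(3) sphere of chordal radius s."""
    s = np.asarray(s, dtype=float)
    alpha = 2.0 * np.arcsin(np.clip(s, 0.0, SQRT2) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        area = 8.0 * math.pi * np.sin(alpha) ** 2 / np.sqrt(np.maximum(4.0 - s**2, 0.0))
    return np.where(s >= SQRT2, 0.0, area)


def _composite_volume_quad(r: np.ndarray, xi: float, order: int = 96) -> np.ndarray:
    """Composite ball volume by Gauss-Legendre quadrature over SO(3) shells:

    Vol(r) = int_0^min(r, sqrt2) A_so3(s) * V_3(sqrt(r^2 - s^2)) / xi^3 ds
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    nodes, weights = np.polynomial.legendre.leggauss(order)
    upper = np.minimum(r, SQRT2)
    # map nodes from [-1, 1] to [0, upper] per radius
    s = 0.5 * upper[:, None] * (nodes[None, :] + 1.0)
    w = 0.5 * upper[:, None] * weights[None, :]
    resid = np.sqrt(np.maximum(r[:, None] ** 2 - s**2, 0.0))
    integrand = so3_shell_area(s) * (4.0 * math.pi / 3.0) * (resid / xi) ** 3
    return np.sum(w * integrand, axis=1)


@dataclass
class VolumeTable:
    """Precomputed log-volume vs log-radius with monotone cubic interpolation.

    Below the grid the locally-flat 6-D limit V = (pi^3/6) r^6 / xi^3 is
    exact to interpolation accuracy and is used directly.
    """

    space: str
    xi: float
    log_r: np.ndarray
    log_v: np.ndarray

    def __post_init__(self) -> None:
        self._interp = PchipInterpolator(self.log_r, self.log_v, extrapolate=False)

    def log_volume(self, r) -> np.ndarray:
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out = np.empty_like(r)
        with np.errstate(divide="ignore"):
            logr = np.log(r)
        below = logr < self.log_r[0]
        above = logr > self.log_r[-1]
        mid = ~(below | above)
        out[mid] = self._interp(logr[mid])
        # small-r: flat 6-D product space
        out[below] = (
            3.0 * math.log(math.pi) - math.log(6.0) + 6.0 * logr[below]
            - 3.0 * math.log(self.xi)
        )
        if np.any(above):  # SO(3) saturated: pi^2 * euclidean shell
            ra = r[above]
            out[above] = np.log(
                _composite_volume_quad(ra, self.xi)
            )
        return out

    def volume(self, r) -> np.ndarray:
        return np.exp(self.log_volume(r))


_TABLE_CACHE: dict = {}


def composite_volume_table(
    params: CompositeMetricParams | None = None,
    r_min: float = 1e-4,
    r_max: float = 1e3,
    n_grid: int = 4096,
) -> VolumeTable:
    """Build (and memoize per xi) the composite-ball volume table."""
    if params is None:
        params = CompositeMetricParams()
    key = (round(params.xi, 12), r_min, r_max, n_grid)
    if key not in _TABLE_CACHE:
        r = np.geomspace(r_min, r_max, n_grid)
        v = _composite_volume_quad(r, params.xi)
        _TABLE_CACHE[key] = VolumeTable(
            space="composite", xi=params.xi, log_r=np.log(r), log_v=np.log(v)
        )
    return _TABLE_CACHE[key]


def ball_volume_composite(r, params: CompositeMetricParams | None = None) -> np.ndarray:
    """Composite-metric ball volume (nm^3 x SO(3) measure), via the table."""
    if params is None:
        params = CompositeMetricParams()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    scalar = r.ndim == 0
    out = np.where(
        np.atleast_1d(r) == 0.0, 0.0, composite_volume_table(params).volume(np.atleast_1d(r))
    )
    return float(out[0]) if scalar else out
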