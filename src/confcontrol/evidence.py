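"""Ideal-observer decision evidence from von Mises direction distributions.

A trial presents a stream of dot directions drawn from a (possibly
time-varying) von Mises distribution.  The observer's objective evidence for
a left vs right choice on each display frame is the log probability that the
generating mean direction lies to the left of the decision axis ``theta0``,
obtained by fitting a von Mises distribution to the directions currently on
screen and integrating its density over the left half-circle.

All directions are in radians, wrapped to ``[0, 2*pi)``.  The canonical
decision axis is downward vertical, ``theta0 = pi/2``; "left" corresponds to
directions in ``[theta0 - pi, theta0]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

TWO_PI = 2.0 * np.pi

#: display refresh rate (Hz) that paces both the stimulus and integration
FRAME_RATE = 120.0
#: seconds per frame
DT = 1.0 / FRAME_RATE
#: frames in a 2 s stimulus
N_FRAMES = 240
#: canonical decision-axis angle (downward vertical)
THETA0 = np.pi / 2.0
#: cap on the ML concentration estimate (all-identical directions otherwise
#: give an infinite kappa)
KAPPA_CAP = 500.0
#: probabilities are clipped to [eps, 1-eps] before taking logs
P_CLIP = 1e-12
#: default grid points per half-circle for numerical integration
DEFAULT_GRID = 4096


class InvalidParameterError(ValueError):
    """Raised when a distribution parameter is out of its valid range."""


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction ``mu`` (radians) and concentration ``kappa`` (>= 0)."""

    mu: float
    kappa: float

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.kappa):
            raise InvalidParameterError("mu and kappa must be finite")
        if self.kappa < 0:
            raise InvalidParameterError(f"kappa must be >= 0, got {self.kappa}")
        object.__setattr__(self, "mu", float(np.mod(self.mu, TWO_PI)))


@dataclass
class EvidenceTrace:
    """Frame-wise decision evidence for one stimulus.

    Attributes
    ----------
    nu_left, nu_right:
        Per-frame log probability (<= 0) that the generating direction is
        left / right of the decision axis.
    circ_var:
        Per-frame circular variance ``1 - I1(k)/I0(k)`` of the fitted
        distribution, in [0, 1]; used to scale internal noise.
    dt:
        Seconds per frame.
    theta0:
        Decision-axis angle in radians.
    """

    nu_left: np.ndarray
    nu_right: np.ndarray
    circ_var: np.ndarray
    dt: float = DT
    theta0: float = THETA0
    stimulus_id: str | None = None
    condition_id: str | None = None
    side: str | None = None  # correct answer: "left" | "right"

    def __post_init__(self):
        self.nu_left = np.asarray(self.nu_left, dtype=float)
        self.nu_right = np.asarray(self.nu_right, dtype=float)
        self.circ_var = np.asarray(self.circ_var, dtype=float)
        if not (self.nu_left.shape == self.nu_right.shape == self.circ_var.shape):
            raise ValueError("evidence arrays must share one shape")
        if np.any(self.nu_left > 0) or np.any(self.nu_right > 0):
            raise ValueError("log probabilities must be <= 0")
        if np.any((self.circ_var < 0) | (self.circ_var > 1)):
            raise ValueError("circular variance must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.nu_left.shape[0]


def von_mises_pdf(theta, params: VonMisesParams):
    """Von Mises probability density at angle(s) ``theta`` (1/radian).

    Uses the exponentially scaled Bessel function so that large
    concentrations do not overflow.
    """
    theta = np.asarray(theta, dtype=float)
    return np.exp(params.kappa * (np.cos(theta - params.mu) - 1.0)) / (
        TWO_PI * special.i0e(params.kappa)
    )


def circular_variance(kappa):
    """Circular variance ``1 - I1(kappa)/I0(kappa)`` of a von Mises law.

    Decreases monotonically from 1 (uniform, kappa=0) towards 0 as the
    distribution concentrates.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0) or not np.all(np.isfinite(kappa)):
        raise InvalidParameterError("kappa must be finite and >= 0")
    out = 1.0 - special.i1e(kappa) / special.i0e(kappa)
    return float(out) if out.ndim == 0 else out


def _prob_left_grid(mu, kappa, theta0, n_grid):
    """Vectorised trapezoid estimate of the left-half-circle probability.

    The normalisation constant cancels between numerator and denominator, so
    the integrand is the unnormalised density ``exp(kappa*(cos(.-mu)-1))``
    (shifted by ``-kappa`` in the exponent for overflow safety).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    grid = np.linspace(theta0 - np.pi, theta0 + np.pi, 2 * n_grid + 1)
    f = np.exp(kappa[:, None] * (np.cos(grid[None, :] - mu[:, None]) - 1.0))
    num = np.trapezoid(f[:, : n_grid + 1], grid[: n_grid + 1], axis=1)
    den = np.trapezoid(f, grid, axis=1)
    return num / den


def prob_left(params: VonMisesParams, theta0: float = THETA0,
              n_grid: int = DEFAULT_GRID) -> float:
    """Probability that the mean direction lies left of the decision axis.

    Numerically integrates the fitted density over ``[theta0 - pi, theta0]``
    and normalises by the integral over the full circle.
    """
    if not np.isfinite(theta0):
        raise InvalidParameterError("theta0 must be finite")
    p = float(_prob_left_grid(params.mu, params.kappa, theta0, n_grid)[0])
    return min(max(p, P_CLIP), 1.0 - P_CLIP)


def log_evidence(p_left):
    """Map a left-probability to the pair of log-evidence samples.

    Returns ``(nu_left, nu_right) = (log p, log(1 - p))`` after clipping
    ``p`` into ``[P_CLIP, 1 - P_CLIP]``; the right side is the binary
    complement of the left.
    """
    p = np.asarray(p_left, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p_left must lie in [0, 1]")
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    return np.log(p), np.log1p(-p)


def kappa_from_resultant(rbar):
    """ML concentration from a mean resultant length.

    Standard truncated-series approximation of the inverse of
    ``A(kappa) = I1(kappa)/I0(kappa)`` (Best & Fisher), capped at
    ``KAPPA_CAP`` for degenerate samples.
    """
    r = np.atleast_1d(np.asarray(rbar, dtype=float))
    k = np.empty_like(r)
    lo = r < 0.53
    mid = (r >= 0.53) & (r < 0.85)
    hi = r >= 0.85
    k[lo] = 2 * r[lo] + r[lo] ** 3 + 5 * r[lo] ** 5 / 6
    k[mid] = -0.4 + 1.39 * r[mid] + 0.43 / (1 - r[mid])
    denom = r[hi] ** 3 - 4 * r[hi] ** 2 + 3 * r[hi]
    with np.errstate(divide="ignore"):
        k[hi] = np.where(denom > 0, 1.0 / np.maximum(denom, 1e-300), np.inf)
    return np.minimum(np.maximum(k, 0.0), KAPPA_CAP)


def estimate_von_mises(directions) -> VonMisesParams:
    """Fit a von Mises distribution to a sample of directions.

    ``mu`` is the circular mean; ``kappa`` the ML concentration implied by
    the mean resultant length (see :func:`kappa_from_resultant`).
    """
    d = np.asarray(directions, dtype=float).ravel()
    if d.size < 2:
        raise InvalidParameterError("need at least 2 directions")
    c, s = np.cos(d).mean(), np.sin(d).mean()
    mu = np.mod(np.arctan2(s, c), TWO_PI)
    rbar = np.hypot(c, s)
    return VonMisesParams(mu=mu, kappa=float(kappa_from_resultant(rbar)[0]))


def compute_evidence_trace(stimulus, theta0: float = THETA0,
                           n_grid: int = DEFAULT_GRID) -> EvidenceTrace:
    """Frame-wise ideal-observer evidence for a dot stimulus.

    Each frame's von Mises parameters are estimated from all dots visible on
    that frame, then converted to left/right log evidence and circular
    variance.  Stimuli generated on the upward axis are first rotated into
    the canonical downward frame.
    """
    dirs = np.asarray(stimulus.frame_directions, dtype=float)
    if getattr(stimulus, "axis", "down") == "up":
        dirs = np.mod(dirs - np.pi, TWO_PI)
    c = np.cos(dirs).mean(axis=1)
    s = np.sin(dirs).mean(axis=1)
    mu = np.mod(np.arctan2(s, c), TWO_PI)
    rbar = np.hypot(c, s)
    kappa = kappa_from_resultant(rbar)
    p = _prob_left_grid(mu, kappa, theta0, n_grid)
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    nu_l, nu_r = np.log(p), np.log1p(-p)
    return EvidenceTrace(
        nu_left=nu_l, nu_right=nu_r, circ_var=circular_variance(kappa),
        dt=1.0 / getattr(stimulus, "frame_rate", FRAME_RATE), theta0=theta0,
        condition_id=getattr(stimulus, "condition_id", None),
        side=getattr(stimulus, "side", None),
    )
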