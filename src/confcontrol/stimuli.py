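"""Dynamic dot-direction stimuli under the nine evidence-quality conditions.

The quality of the directional evidence is set by two schedule arrays on the
120 Hz frame grid: ``delta``, the mean offset of the generating distribution
from the decision axis (degrees), and ``kappa``, its concentration.  Both
may change during the first second of the 2 s stimulus and are constant
afterwards.  Nine conditions combine increasing, decreasing, or stable mean
offset with increasing, decreasing, or stable concentration:

- two ramps of the mean (``ramp-up-mean``, ``ramp-down-mean``),
- two ramps of the concentration (``ramp-up-kappa``, ``ramp-down-kappa``),
- three stable levels (``stable-low``, ``stable-moderate``, ``stable-high``),
- two opposed schedules of moderate net quality (``opposed-A``: mean up while
  concentration down; ``opposed-B``: the reverse).

The numeric anchors (low/moderate/high delta and kappa) are configuration
values; the defaults below were calibrated once on pilot simulations to span
accuracies from roughly 0.65 to 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence import FRAME_RATE, N_FRAMES, THETA0, TWO_PI

#: frames in the dynamic first second
RAMP_FRAMES = int(FRAME_RATE)  # 120

CONDITION_IDS = (
    "ramp-up-mean",
    "ramp-down-mean",
    "ramp-up-kappa",
    "ramp-down-kappa",
    "stable-low",
    "stable-moderate",
    "stable-high",
    "opposed-A",
    "opposed-B",
)


class ConfigError(ValueError):
    """Raised when a condition configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class ConditionConfig:
    """Anchor values defining the nine schedules.

    ``delta_*`` are mean offsets from the decision axis in degrees,
    ``kappa_*`` von Mises concentrations.  Low/moderate/high refer to
    evidence strength, so ``kappa_low`` is the *smallest* concentration
    (widest spread).
    """

    delta_low: float = 1.5
    delta_moderate: float = 3.0
    delta_high: float = 5.0
    kappa_low: float = 1.0
    kappa_moderate: float = 2.0
    kappa_high: float = 4.0

    def __post_init__(self):
        vals = (self.delta_low, self.delta_moderate, self.delta_high,
                self.kappa_low, self.kappa_moderate, self.kappa_high)
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ConfigError("all six anchors must be finite numbers")
        if min(self.kappa_low, self.kappa_moderate, self.kappa_high) < 0:
            raise ConfigError("kappa anchors must be >= 0")


@dataclass
class ConditionSchedule:
    """Per-frame ``delta`` (degrees) and ``kappa`` schedules for one condition."""

    condition_id: str
    delta: np.ndarray
    kappa: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.delta.shape != (N_FRAMES,) or self.kappa.shape != (N_FRAMES,):
            raise ConfigError(f"schedules must have length {N_FRAMES}")
        if np.any(self.kappa < 0):
            raise ConfigError("kappa must be >= 0 everywhere")
        for arr in (self.delta, self.kappa):
            if not np.allclose(arr[RAMP_FRAMES:], arr[RAMP_FRAMES]):
                raise ConfigError("schedules must be constant after 1 s")


def _ramp(start: float, stop: float) -> np.ndarray:
    """Linear change over the first second, constant thereafter."""
    out = np.empty(N_FRAMES)
    out[:RAMP_FRAMES] = np.linspace(start, stop, RAMP_FRAMES)
    out[RAMP_FRAMES:] = stop
    return out


def _flat(value: float) -> np.ndarray:
    return np.full(N_FRAMES, float(value))


def make_condition_set(config: ConditionConfig | None = None):
    """Build the nine condition schedules from anchor values.

    Returns a dict keyed by condition id.
    """
    cfg = config if config is not None else ConditionConfig()
    d_lo, d_md, d_hi = cfg.delta_low, cfg.delta_moderate, cfg.delta_high
    k_lo, k_md, k_hi = cfg.kappa_low, cfg.kappa_moderate, cfg.kappa_high
    spec = {
        "ramp-up-mean": (_ramp(d_lo, d_hi), _flat(k_md)),
        "ramp-down-mean": (_ramp(d_hi, d_lo), _flat(k_md)),
        "ramp-up-kappa": (_flat(d_md), _ramp(k_lo, k_hi)),
        "ramp-down-kappa": (_flat(d_md), _ramp(k_hi, k_lo)),
        "stable-low": (_flat(d_lo), _flat(k_lo)),
        "stable-moderate": (_flat(d_md), _flat(k_md)),
        "stable-high": (_flat(d_hi), _flat(k_hi)),
        "opposed-A": (_ramp(d_lo, d_hi), _ramp(k_hi, k_lo)),
        "opposed-B": (_ramp(d_hi, d_lo), _ramp(k_lo, k_hi)),
    }
    return {
        cid: ConditionSchedule(cid, delta, kappa)
        for cid, (delta, kappa) in spec.items()
    }


@dataclass
class DirectionStimulus:
    """One sampled dot stimulus.

    ``frame_directions`` holds the direction (radians, canonical frame) of
    every dot on every frame.  Dots live in 10 staggered cohorts; one cohort
    (``replacement_fraction`` of the dots) is redrawn each frame from the
    schedule's distribution at that frame, and each dot keeps its direction
    for its whole lifetime.
    """

    frame_directions: np.ndarray  # (n_frames, n_dots)
    condition_id: str
    side: str  # correct answer: "left" | "right"
    n_dots: int = 100
    frame_rate: float = FRAME_RATE
    lifetime_frames: int = 10
    replacement_fraction: float = 0.1
    axis: str = "down"
    seed: int | None = None


def sample_dot_directions(schedule: ConditionSchedule, side: str = "left",
                          n_dots: int = 100, seed=None,
                          axis: str = "down") -> DirectionStimulus:
    """Sample a dot stimulus from a condition schedule.

    The generating mean on frame ``f`` is ``theta0 -/+ delta[f]`` (in
    radians) for a left/right stimulus.  Cohort ``k`` is refreshed on frames
    ``f`` with ``f % 10 == k`` so that exactly 10% of the dots are replaced
    per frame.
    """
    if side not in ("left", "right"):
        raise ConfigError("side must be 'left' or 'right'")
    n_cohorts = 10
    if n_dots % n_cohorts:
        raise ConfigError(f"n_dots must be divisible by {n_cohorts}")
    per = n_dots // n_cohorts
    sign = -1.0 if side == "left" else 1.0
    mu = THETA0 + sign * np.deg2rad(schedule.delta)
    rng = np.random.default_rng(seed)
    # one fresh draw block per (frame, cohort-refresh); plus initial cohorts
    init = rng.vonmises(mu[0], schedule.kappa[0], size=(n_cohorts, per))
    refresh = rng.vonmises(mu[:, None], schedule.kappa[:, None],
                           size=(N_FRAMES, per))
    current = init.copy()
    frames = np.empty((N_FRAMES, n_dots))
    for f in range(N_FRAMES):
        if f > 0:
            current[f % n_cohorts] = refresh[f]
        frames[f] = current.ravel()
    return DirectionStimulus(
        frame_directions=np.mod(frames, TWO_PI), condition_id=schedule.condition_id,
        side=side, n_dots=n_dots, axis=axis, seed=seed,
    )
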