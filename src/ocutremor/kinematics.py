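"""Gaze kinematics: velocities, inter-velocity angles, and the direction-reversal statistic.

Gaze positions sampled on a uniform millisecond grid are turned into planar
velocities by a one-step forward difference.  Three velocity variants feed the
downstream frequency analysis:

``raw``
    v(t) = (x(t+tau) - x(t)) / tau, tau the sampling step.
``unit``
    the raw velocity divided by its Euclidean norm, retaining only direction.
``fixational``
    the raw velocity restricted to sample pairs whose both endpoints are
    labelled as fixations, where microtremor lives.

The direction-reversal statistic Pr_{phi,k}(tau) is the probability that the
angle between the velocity at time t and at time t+tau falls in the narrow
band A_k = [(1-1/k)*pi, pi], i.e. that gaze has (nearly) inverted its
direction over the lag.  For an oscillatory gaze component this probability
peaks at half the oscillation period, which is how the microtremor period is
read off the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

FIX = "FIX"
SACC = "SACC"
BLINK = "BLINK"
VALID_LABELS = frozenset({FIX, SACC, BLINK})


@dataclass
class GazeRecording:
    """Uniformly sampled gaze positions with per-sample event labels.

    Parameters
    ----------
    t : array of float
        Sample times in milliseconds, strictly increasing with constant step.
    x, y : array of float
        Gaze position (degrees of visual angle, or pixels before conversion).
        May be NaN on BLINK samples only.
    labels : array of str
        Per-sample event label, one of ``FIX``, ``SACC``, ``BLINK``.
    participant_id : str
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.labels) == n):
            raise ValueError("t, x, y and labels must have equal length")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("t must be strictly increasing with a constant step")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")
        nonblink = self.labels != BLINK
        if np.any(~np.isfinite(self.x[nonblink])) or np.any(~np.isfinite(self.y[nonblink])):
            raise ValueError("non-finite positions outside BLINK spans")

    @property
    def sampling_interval(self) -> float:
        """Sampling step tau in milliseconds."""
        if len(self.t) < 2:
            raise ValueError("need at least 2 samples to define a sampling interval")
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class VelocitySeries:
    """Planar gaze velocity with a per-sample validity mask.

    ``variant`` is one of ``raw``, ``unit`` or ``fixational``; invalid samples
    (blink-adjacent, zero-norm for the unit variant, non-fixational for the
    fixational variant) carry NaN components and ``valid=False``.
    """

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    variant: str = "raw"
    participant_id: str = ""

    def __len__(self) -> int:
        return len(self.t)

    def component(self, name: str) -> np.ndarray:
        if name == "vx":
            return self.vx
        if name == "vy":
            return self.vy
        raise KeyError(name)


@dataclass
class ReversalCurve:
    """Pr_{phi,k}(tau): probability of direction reversal per lag.

    ``pr`` is NaN at lags where fewer than ``n_min`` valid velocity pairs were
    available; ``n_pairs`` records the pair count per lag.
    """

    k: int
    tau_grid: np.ndarray
    pr: np.ndarray
    n_pairs: np.ndarray
    participant_id: str = ""
    variant: str = "raw"
    n_min: int = field(default=1, repr=False)


def compute_velocity(rec: GazeRecording) -> VelocitySeries:
    """One-step forward-difference velocity v(t) = (pos(t+tau) - pos(t)) / tau.

    The returned series has length n-1; samples whose either endpoint is a
    BLINK sample are invalid.
    """
    if len(rec) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    tau = rec.sampling_interval
    vx = np.diff(rec.x) / tau
    vy = np.diff(rec.y) / tau
    blink = rec.labels == BLINK
    valid = ~(blink[:-1] | blink[1:]) & np.isfinite(vx) & np.isfinite(vy)
    vx = np.where(valid, vx, np.nan)
    vy = np.where(valid, vy, np.nan)
    return VelocitySeries(rec.t[:-1], vx, vy, valid, "raw", rec.participant_id)


def unit_velocity(v: VelocitySeries) -> VelocitySeries:
    """Normalise each velocity sample to unit Euclidean norm.

    Zero-norm samples have no direction and are marked invalid.
    """
    if v.variant != "raw":
        raise ValueError("unit_velocity expects the raw variant")
    norm = np.hypot(v.vx, v.vy)
    valid = v.valid & (norm > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(valid, v.vx / norm, np.nan)
        uy = np.where(valid, v.vy / norm, np.nan)
    return VelocitySeries(v.t, ux, uy, valid, "unit", v.participant_id)


def fixational_velocity(rec: GazeRecording) -> VelocitySeries:
    """Velocity restricted to sample pairs with both endpoints labelled FIX."""
    v = compute_velocity(rec)
    fix = rec.labels == FIX
    valid = v.valid & fix[:-1] & fix[1:]
    if not valid.any():
        warnings.warn(
            f"no fixational velocity samples for participant {rec.participant_id!r}",
            stacklevel=2,
        )
    vx = np.where(valid, v.vx, np.nan)
    vy = np.where(valid, v.vy, np.nan)
    return VelocitySeries(v.t, vx, vy, valid, "fixational", rec.participant_id)


def angle_between(v_a, v_b) -> float:
    """Angle phi in [0, pi] between two planar velocity vectors.

    arccos of the cosine similarity; the cosine is clipped to [-1, 1] to
    absorb floating-point overshoot.  Raises for zero vectors, whose direction
    is undefined.
    """
    a = np.asarray(v_a, dtype=float)
    b = np.asarray(v_b, dtype=float)
    na = np.hypot(a[0], a[1])
    nb = np.hypot(b[0], b[1])
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero velocity vector")
    c = np.clip((a[0] * b[0] + a[1] * b[1]) / (na * nb), -1.0, 1.0)
    return float(np.arccos(c))


def _pairwise_angles(v: VelocitySeries, lag_samples: int) -> tuple[np.ndarray, int]:
    """Angles phi(t, t+lag) over all valid velocity pairs at one lag."""
    vx0, vy0 = v.vx[:-lag_samples], v.vy[:-lag_samples]
    vx1, vy1 = v.vx[lag_samples:], v.vy[lag_samples:]
    ok = v.valid[:-lag_samples] & v.valid[lag_samples:]
    n0 = np.hypot(vx0, vy0)
    n1 = np.hypot(vx1, vy1)
    ok = ok & (n0 > 0) & (n1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (vx0 * vx1 + vy0 * vy1) / (n0 * n1)
    phi = np.arccos(np.clip(cos[ok], -1.0, 1.0))
    return phi, int(ok.sum())


def reversal_probability(
    v: VelocitySeries,
    k: int,
    tau_grid,
    n_min: int = 1,
) -> ReversalCurve:
    """Pr_{phi,k}(tau): fraction of valid pairs with phi(t, t+tau) in A_k.

    A_k = [(1-1/k)*pi, pi] has angular measure pi/k; under isotropic
    independent directions the probability is exactly 1/k, which serves as the
    null reference.  Lags must be positive multiples of the sampling step.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tau_grid = np.asarray(tau_grid, dtype=float)
    step = float(v.t[1] - v.t[0]) if len(v.t) >= 2 else 1.0
    pr = np.full(tau_grid.shape, np.nan)
    n_pairs = np.zeros(tau_grid.shape, dtype=int)
    lo = (1.0 - 1.0 / k) * np.pi
    for i, tau in enumerate(tau_grid):
        m = tau / step
        if tau <= 0 or abs(m - round(m)) > 1e-9:
            raise ValueError(f"lag {tau} ms is not a positive multiple of the step {step} ms")
        m = int(round(m))
        if m >= len(v):
            continue
        phi, n = _pairwise_angles(v, m)
        n_pairs[i] = n
        if n >= n_min:
            pr[i] = np.mean(phi >= lo)
    return ReversalCurve(k, tau_grid, pr, n_pairs, v.participant_id, v.variant, n_min)


def reversal_peak(curve: ReversalCurve) -> tuple[float, float]:
    """Lag (ms) and value of the maximum of Pr_{phi,k}(tau); ties -> smallest lag."""
    if np.all(np.isnan(curve.pr)):
        raise ValueError("reversal curve has no non-missing entries")
    i = int(np.nanargmax(curve.pr))  # nanargmax returns the first maximum
    return float(curve.tau_grid[i]), float(curve.pr[i])


def period_to_frequency(period_bounds) -> tuple[float, float]:
    """Convert a period interval [lo, hi] in ms to a frequency interval in Hz.

    f = 1000/period applied to each bound; the order swaps, so a [6, 8] ms
    reversal period maps to the [125, 166.7] Hz band.
    """
    lo, hi = float(period_bounds[0]), float(period_bounds[1])
    if lo <= 0 or hi <= 0:
        raise ValueError("period bounds must be positive")
    if lo > hi:
        raise ValueError("period bounds must satisfy lower <= upper")
    return 1000.0 / hi, 1000.0 / lo
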