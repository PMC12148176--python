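"""Synthetic gaze and trial-response generator.

Emulates the statistical structure of a two-target flicker-detection session
recorded at 1 kHz: gaze alternates between two targets 19 degrees apart,
fixations of a few hundred milliseconds separated by ~60 ms saccades.  Within
fixations the gaze position is the sum of

* ocular drift — a 2-D random walk whose displacement variance grows as
  ``drift_diffusion * t`` (deg^2/s),
* microtremor — a small-amplitude oscillation at ``tremor_freq`` in the
  70-150 Hz band; circular by default (the velocity direction then rotates
  uniformly, so the direction-reversal statistic peaks at half the tremor
  period), optionally linear along a random axis.  The oscillator carries
  phase diffusion (``tremor_phase_jitter``, rad per sqrt-ms), giving the
  tremor the finite spectral linewidth of a physiological rhythm rather
  than the infinite coherence of a mathematical sinusoid; without it the
  reversal statistic would keep re-peaking at every odd half-period,
* white measurement noise of standard deviation ``noise_sd``.

Occasional microsaccades (small, SACC-labelled jumps inside fixations) and
blinks (BLINK-labelled spans with missing positions) complete the event
taxonomy.  Ground-truth FIX/SACC/BLINK labels are attached to every sample,
standing in for an eye-tracker's event detector.

Each synthetic participant also carries a latent critical flicker fusion
threshold (CFFT) tied to their tremor frequency by a configurable linear
link; trial responses are drawn from a chance-floored logistic detection
model around that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import BLINK, FIX, SACC, GazeRecording
from .psychophysics import TrialResponse

DEFAULT_TREMOR_BAND = (70.0, 150.0)

#: Default tremor -> CFFT link: cfft = slope * tremor_freq + intercept + N(0, noise_sd).
#: Maps the 70-150 Hz tremor band onto CFFTs spanning roughly 30-85 Hz, so that
#: nearly the whole cohort resolves 30 Hz flicker and about half resolve 60 Hz
#: after the guessing floor; the group passing the criterion at 120 Hz is then
#: mostly guess-level, the price of a linear link on a uniform band.
DEFAULT_LINK = {"slope": 0.7, "intercept": -19.0, "noise_sd": 5.0}


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent per-participant parameters of the generative model."""

    participant_id: str
    tremor_freq: float  # Hz
    tremor_amp: float = 0.01  # deg of visual angle
    drift_diffusion: float = 0.01  # deg^2/s
    cfft: float = 60.0  # Hz
    detection_slope: float = 0.1  # 1/Hz

    def __post_init__(self) -> None:
        if self.tremor_amp <= 0:
            raise ValueError("tremor_amp must be > 0")
        if self.drift_diffusion < 0:
            raise ValueError("drift_diffusion must be >= 0")
        if self.cfft <= 0:
            raise ValueError("cfft must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Session geometry, timing and noise of the synthetic recording."""

    sampling_interval: float = 1.0  # ms
    duration: float = 30.0  # s
    target_separation: float = 19.0  # deg
    target_size: float = 1.4  # deg
    fixation_mean_duration: float = 600.0  # ms
    saccade_duration: float = 60.0  # ms
    microsaccade_rate: float = 1.0  # 1/s
    microsaccade_amp: float = 0.25  # deg
    microsaccade_duration: float = 10.0  # ms
    noise_sd: float = 0.002  # deg
    blink_rate: float = 0.0  # 1/s
    blink_duration: float = 100.0  # ms
    tremor_waveform: str = "circular"  # or "linear"
    tremor_phase_jitter: float = 0.3  # rad per sqrt(ms): oscillator linewidth
    seed: int = 0
    flicker_frequencies: tuple[float, ...] = (30.0, 60.0, 120.0)
    trials_per_frequency: int = 3

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in ("microsaccade_rate", "blink_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tremor_waveform not in ("circular", "linear"):
            raise ValueError("tremor_waveform must be 'circular' or 'linear'")

    @property
    def n_samples(self) -> int:
        n = self.duration * 1000.0 / self.sampling_interval
        if abs(n - round(n)) > 1e-6:
            raise ValueError("sampling_interval must divide the duration evenly")
        return int(round(n))


def sample_profiles(
    n_participants: int,
    config: SimulationConfig,
    link_params: dict | None = None,
    tremor_band: tuple[float, float] = DEFAULT_TREMOR_BAND,
    tremor_amp: float = 0.01,
    drift_diffusion: float = 0.01,
    detection_slope: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[ParticipantProfile]:
    """Draw participant profiles with tremor frequencies uniform on the band.

    The latent CFFT follows the linear link
    ``cfft = slope * tremor_freq + intercept + N(0, noise_sd)``, truncated
    below at 1 Hz.  ``link_params`` overrides :data:`DEFAULT_LINK` keys.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    lo, hi = tremor_band
    if lo > hi:
        raise ValueError(f"invalid tremor band [{lo}, {hi}]")
    link = {**DEFAULT_LINK, **(link_params or {})}
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profiles = []
    for i in range(n_participants):
        f_tremor = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        eps = float(rng.normal(0.0, link["noise_sd"])) if link["noise_sd"] > 0 else 0.0
        cfft = max(1.0, link["slope"] * f_tremor + link["intercept"] + eps)
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i:03d}",
                tremor_freq=f_tremor,
                tremor_amp=tremor_amp,
                drift_diffusion=drift_diffusion,
                cfft=cfft,
                detection_slope=detection_slope,
            )
        )
    return profiles


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0->1 ramp of length n (saccade position profile)."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, n)))


def simulate_recording(
    profile: ParticipantProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GazeRecording:
    """Generate one gaze recording for a participant.

    Gaze alternates between targets at x = +/- separation/2 (y = 0) with
    exponentially distributed fixation durations; within each fixation the
    position superposes drift, tremor and measurement noise as described in
    the module docstring.  Event labels carry the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt_ms = config.sampling_interval
    dt_s = dt_ms / 1000.0
    n = config.n_samples
    if config.duration * 1000.0 < config.fixation_mean_duration:
        raise ValueError("duration shorter than one mean fixation")

    x = np.empty(n)
    y = np.empty(n)
    labels = np.full(n, FIX, dtype=object)
    half = config.target_separation / 2.0
    side = int(rng.integers(0, 2))  # 0 -> left, 1 -> right

    min_fix = max(3, int(round(100.0 / dt_ms)))
    n_sacc = max(2, int(round(config.saccade_duration / dt_ms)))
    omega = 2.0 * math.pi * profile.tremor_freq  # rad/s
    lin_axis = rng.uniform(0.0, 2.0 * math.pi)

    i = 0
    cur = np.array([(half if side else -half), 0.0])
    while i < n:
        # --- fixation span ---
        n_fix = int(round(rng.exponential(config.fixation_mean_duration) / dt_ms))
        n_fix = min(max(n_fix, min_fix), n - i)
        t_loc = np.arange(n_fix) * dt_s
        steps = rng.normal(0.0, math.sqrt(profile.drift_diffusion * dt_s), size=(n_fix, 2))
        drift = np.cumsum(steps, axis=0)
        phase0 = rng.uniform(0.0, 2.0 * math.pi)
        phase = phase0 + omega * t_loc
        if config.tremor_phase_jitter > 0:
            jitter = rng.normal(
                0.0, config.tremor_phase_jitter * math.sqrt(dt_ms), size=n_fix
            )
            jitter[0] = 0.0
            phase = phase + np.cumsum(jitter)
        if config.tremor_waveform == "circular":
            trem_x = profile.tremor_amp * np.cos(phase)
            trem_y = profile.tremor_amp * np.sin(phase)
        else:
            carrier = profile.tremor_amp * np.cos(phase)
            trem_x = carrier * math.cos(lin_axis)
            trem_y = carrier * math.sin(lin_axis)
        seg_x = cur[0] + drift[:, 0] + trem_x
        seg_y = cur[1] + drift[:, 1] + trem_y

        # microsaccades: short SACC-labelled jumps inside the fixation
        n_ms = rng.poisson(config.microsaccade_rate * n_fix * dt_s)
        n_ms_len = max(2, int(round(config.microsaccade_duration / dt_ms)))
        for _ in range(n_ms):
            if n_fix - n_ms_len <= min_fix // 2 + 1:
                break
            start = int(rng.integers(min_fix // 2, n_fix - n_ms_len))
            amp = rng.uniform(0.3, 1.0) * config.microsaccade_amp
            ang = rng.uniform(0.0, 2.0 * math.pi)
            ramp = _raised_cosine(n_ms_len)
            dx, dy = amp * math.cos(ang), amp * math.sin(ang)
            seg_x[start:start + n_ms_len] += dx * ramp
            seg_y[start:start + n_ms_len] += dy * ramp
            seg_x[start + n_ms_len:] += dx
            seg_y[start + n_ms_len:] += dy
            labels[i + start:i + start + n_ms_len] = SACC

        x[i:i + n_fix] = seg_x
        y[i:i + n_fix] = seg_y
        cur = np.array([seg_x[-1], seg_y[-1]])
        i += n_fix
        if i >= n:
            break

        # --- saccade to the other target ---
        side = 1 - side
        tgt = np.array([(half if side else -half), 0.0])
        tgt = tgt + rng.normal(0.0, 0.05 * config.target_size, size=2)  # landing error
        m = min(n_sacc, n - i)
        ramp = _raised_cosine(m)
        x[i:i + m] = cur[0] + (tgt[0] - cur[0]) * ramp
        y[i:i + m] = cur[1] + (tgt[1] - cur[1]) * ramp
        labels[i:i + m] = SACC
        cur = np.array([x[i + m - 1], y[i + m - 1]])
        i += m

    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=n)
        y += rng.normal(0.0, config.noise_sd, size=n)

    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * config.duration)
        blen = max(1, int(round(config.blink_duration / dt_ms)))
        for _ in range(n_blinks):
            start = int(rng.integers(0, max(1, n - blen)))
            x[start:start + blen] = np.nan
            y[start:start + blen] = np.nan
            labels[start:start + blen] = BLINK

    t = np.arange(n) * dt_ms
    return GazeRecording(t, x, y, labels, profile.participant_id)


def detection_probability(profile: ParticipantProfile, f: float, chance: float = 1.0 / 3.0) -> float:
    """Per-trial probability of a correct answer at flicker frequency f.

    ``chance + (1 - chance) * logistic(detection_slope * (cfft - f))``:
    far below threshold the participant truly sees the flicker; far above,
    answers fall to the 1/3 guessing floor (left / right / not sure).
    """
    z = profile.detection_slope * (profile.cfft - f)
    return chance + (1.0 - chance) / (1.0 + math.exp(-z))


def simulate_trials(
    profile: ParticipantProfile,
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[TrialResponse]:
    """Draw the forced-choice responses for one participant.

    Per trial at frequency f the answer is correct with
    :func:`detection_probability`; otherwise the wrong side or "not_sure"
    is chosen uniformly.  The flickering side is randomised per trial.
    """
    if not config.flicker_frequencies:
        raise ValueError("flicker_frequencies must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for f in config.flicker_frequencies:
        p = detection_probability(profile, f)
        for _ in range(config.trials_per_frequency):
            true_side = "left" if rng.random() < 0.5 else "right"
            if rng.random() < p:
                answer = true_side
            else:
                wrong = "right" if true_side == "left" else "left"
                answer = wrong if rng.random() < 0.5 else "not_sure"
            out.append(TrialResponse(profile.participant_id, float(f), true_side, answer))
    return out


def simulate_cohort(
    n_participants: int,
    config: SimulationConfig,
    link_params: dict | None = None,
    **profile_kwargs,
) -> tuple[list[ParticipantProfile], list[GazeRecording], list[TrialResponse]]:
    """Profiles, recordings and trial responses for a whole cohort.

    One child generator per participant keeps recordings reproducible and
    independent of cohort size.
    """
    root = np.random.default_rng(config.seed)
    profiles = sample_profiles(
        n_participants, config, link_params, rng=root, **profile_kwargs
    )
    recordings, trials = [], []
    for prof in profiles:
        child = np.random.default_rng(root.integers(0, 2**31))
        recordings.append(simulate_recording(prof, config, rng=child))
        trials.extend(simulate_trials(prof, config, rng=child))
    return profiles, recordings, trials
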