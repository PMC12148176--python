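"""Flicker-detection psychophysics: trial scoring, group labels and chance level.

Each participant answers 9 forced-choice trials (3 at each flicker frequency
30, 60 and 120 Hz): which of two crosses flickered — left, right, or "not
sure".  A participant is said to detect flicker at frequency f when at least
2 of the 3 trials at f are answered correctly.  Under random guessing with
success probability 1/3 the criterion is met with probability 7/27, the
chance level against which group sizes are judged.

Participants detecting at f form the group P>f, the rest P<f; the fraction
P>f per frequency decays with f, and fitting exp(-f/f_l) to the decay gives
the frequency tolerance f_l of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

ANSWERS = ("left", "right", "not_sure")


@dataclass(frozen=True)
class TrialResponse:
    """One forced-choice trial: which side flickered and what was answered."""

    participant_id: str
    flicker_freq: float
    true_side: str
    answer: str

    def __post_init__(self) -> None:
        if self.true_side not in ("left", "right"):
            raise ValueError(f"true_side must be left/right, got {self.true_side!r}")
        if self.answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}, got {self.answer!r}")

    @property
    def correct(self) -> bool:
        return self.answer == self.true_side


@dataclass
class DetectionLabels:
    """Per-participant detection outcomes and P>f / P<f group membership."""

    detected_at: dict[str, dict[float, bool]] = field(default_factory=dict)

    @property
    def participants(self) -> list[str]:
        return sorted(self.detected_at)

    @property
    def frequencies(self) -> list[float]:
        freqs: set[float] = set()
        for d in self.detected_at.values():
            freqs.update(d)
        return sorted(freqs)

    def group(self, threshold_freq: float) -> dict[str, bool]:
        """True for members of P>threshold (detected), False for P<threshold."""
        return {p: d[threshold_freq] for p, d in self.detected_at.items()}


class IncompleteProtocolError(ValueError):
    """A participant is missing trials for some frequency."""


def label_detection(
    trials: list[TrialResponse],
    trials_per_frequency: int = 3,
    min_correct: int = 2,
) -> DetectionLabels:
    """Apply the 2-of-3 correctness criterion per participant and frequency.

    "Not sure" counts as incorrect.  Raises :class:`IncompleteProtocolError`
    naming the participant if any (participant, frequency) cell does not hold
    exactly ``trials_per_frequency`` responses.
    """
    counts: dict[tuple[str, float], list[bool]] = {}
    for tr in trials:
        counts.setdefault((tr.participant_id, tr.flicker_freq), []).append(tr.correct)
    participants = sorted({p for p, _ in counts})
    freqs = sorted({f for _, f in counts})
    labels = DetectionLabels()
    for p in participants:
        row: dict[float, bool] = {}
        for f in freqs:
            got = counts.get((p, f), [])
            if len(got) != trials_per_frequency:
                raise IncompleteProtocolError(
                    f"participant {p!r} has {len(got)} trials at {f} Hz, "
                    f"expected {trials_per_frequency}"
                )
            row[f] = sum(got) >= min_correct
        labels.detected_at[p] = row
    return labels


def chance_probability(n_trials: int, p_success: float, min_successes: int) -> float:
    """Exact binomial tail P(X >= min_successes) with X ~ Bin(n_trials, p_success).

    With 3 trials, success probability 1/3 and a 2-of-3 criterion this is
    7/27 — the probability of passing the detection criterion by guessing.
    """
    if not 0 <= p_success <= 1:
        raise ValueError("p_success must be in [0, 1]")
    if not 0 <= min_successes <= n_trials:
        raise ValueError("min_successes must be in [0, n_trials]")
    return float(stats.binom.sf(min_successes - 1, n_trials, p_success))


def detection_fractions(labels: DetectionLabels) -> dict[float, float]:
    """Fraction of participants in P>f at each flicker frequency f."""
    participants = labels.participants
    if not participants:
        raise ValueError("no participants")
    n = len(participants)
    return {
        f: sum(labels.detected_at[p][f] for p in participants) / n
        for f in labels.frequencies
    }


def fit_frequency_tolerance(fractions: dict[float, float]) -> tuple[float, np.ndarray]:
    """Fit P(f) = exp(-f / f_l) to the detection fractions; return (f_l, residuals).

    Unweighted nonlinear least squares.  f_l (Hz) is the frequency scale over
    which the cohort loses the ability to resolve flicker.  All-ones input is
    degenerate (any large f_l fits) and rejected; a single point (f, p) with
    p < 1 reduces to the closed form -f / ln(p).
    """
    pts = [(f, p) for f, p in sorted(fractions.items()) if 0 < p <= 1]
    if not pts:
        raise ValueError("need >= 1 frequency with a fraction in (0, 1]")
    f = np.array([q[0] for q in pts], dtype=float)
    p = np.array([q[1] for q in pts], dtype=float)
    if np.all(p == 1.0):
        raise ValueError("all fractions equal 1: frequency tolerance unidentifiable")
    if len(pts) == 1:
        f_l = -f[0] / np.log(p[0])
        return float(f_l), np.zeros(1)
    # closed-form single-point start keeps the solver away from the flat region
    i = int(np.argmin(np.abs(p - 0.5)))
    f0 = -f[i] / np.log(p[i]) if p[i] < 1 else 100.0
    (f_l,), _ = optimize.curve_fit(lambda x, fl: np.exp(-x / fl), f, p, p0=[f0])
    residuals = p - np.exp(-f / f_l)
    return float(f_l), residuals
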