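"""Normalized power spectra of velocity components and their cumulative curves.

The discriminating feature between participants who do and do not resolve
fast flicker is the cumulative power spectrum

    C_X(f') = integral_0^f' S_X(f~) df~,

where S_X is the power spectrum of a velocity component X, normalized so the
total spectral mass over (0, f_nyq] equals one (f_nyq = 500 Hz at 1 kHz
sampling).  C_X(f') is then the fraction of velocity variance carried by
frequencies at or below f'.

Velocity series carry validity masks (blinks, non-fixational samples), so a
single FFT over the whole series is undefined.  Spectra are instead computed
per contiguous valid segment — mean-subtracted, optionally Hann-tapered,
|FFT|^2 on the one-sided grid — and averaged across segments with
segment-length weights after interpolation to a common 0.5 Hz grid
(Welch-style averaging with maximal, gap-respecting segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import VelocitySeries

NYQUIST_DEFAULT = 500.0
GRID_STEP_DEFAULT = 0.5


class InsufficientDataError(ValueError):
    """No valid segment long enough to estimate a spectrum."""

    def __init__(self, msg: str, segment_lengths: list[int] | None = None):
        super().__init__(msg)
        self.segment_lengths = segment_lengths or []


@dataclass
class SpectrumSummary:
    """Normalized one-sided power spectrum on a common frequency grid.

    ``power`` is spectral mass per bin (sums to 1 over the grid, DC excluded);
    ``cumulative`` its running sum, reaching 1 at the Nyquist frequency.
    """

    freqs: np.ndarray
    power: np.ndarray
    cumulative: np.ndarray
    variable: str = ""
    participant_id: str = ""

    @property
    def f_nyq(self) -> float:
        return float(self.freqs[-1])


def valid_segments(values: np.ndarray, valid: np.ndarray, min_length: int = 1) -> list[np.ndarray]:
    """Contiguous runs of valid samples, at least ``min_length`` long."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    out = []
    for chunk in np.split(idx, breaks + 1):
        if chunk.size >= min_length:
            out.append(values[chunk[0]:chunk[-1] + 1])
    return out


def power_spectrum(
    series: VelocitySeries,
    component: str = "vy",
    min_segment: int = 256,
    grid_step: float = GRID_STEP_DEFAULT,
    window: str | None = None,
) -> SpectrumSummary:
    """Normalized power spectrum of one velocity component.

    Per contiguous valid segment of length >= ``min_segment``: subtract the
    segment mean, apply the optional taper (``window="hann"``), take
    |FFT|^2 on the one-sided frequency grid.  Segment spectra are
    interpolated (as densities) onto the common ``grid_step`` grid over
    [0, f_nyq], averaged with segment-length weights, converted back to mass
    per bin and normalized to unit total.  The DC bin is excluded.

    Raises
    ------
    InsufficientDataError
        If no segment reaches ``min_segment`` samples, or the signal carries
        no non-DC power (e.g. a constant); carries the segment-length
        histogram for diagnostics.
    """
    values = series.component(component)
    dt_ms = float(series.t[1] - series.t[0]) if len(series) >= 2 else 1.0
    dt_s = dt_ms / 1000.0
    f_nyq = 0.5 / dt_s

    all_lengths = [len(s) for s in valid_segments(values, series.valid, 1)]
    segments = valid_segments(values, series.valid, min_segment)
    if not segments:
        raise InsufficientDataError(
            f"no valid segment of length >= {min_segment}", all_lengths
        )

    grid = np.arange(0.0, f_nyq + grid_step / 2, grid_step)
    density_acc = np.zeros_like(grid)
    weight_acc = 0.0
    for seg in segments:
        seg = seg - seg.mean()
        if window == "hann":
            seg = seg * np.hanning(len(seg))
        elif window is not None:
            raise ValueError(f"unknown window {window!r}")
        spec = np.abs(np.fft.rfft(seg)) ** 2
        freqs = np.fft.rfftfreq(len(seg), d=dt_s)
        spec[0] = 0.0  # DC excluded
        total = spec.sum()
        if total <= 0:
            continue
        df = freqs[1] - freqs[0]
        density = spec / total / df  # unit-mass spectral density
        density_acc += len(seg) * np.interp(grid, freqs, density)
        weight_acc += len(seg)
    if weight_acc == 0:
        raise InsufficientDataError(
            "all long-enough segments carry no non-DC power", all_lengths
        )
    density = density_acc / weight_acc
    power = density * grid_step
    power[0] = 0.0
    total = power.sum()
    if total <= 0:
        raise InsufficientDataError("zero total spectral mass", all_lengths)
    power = power / total
    return SpectrumSummary(
        freqs=grid,
        power=power,
        cumulative=np.cumsum(power),
        variable=f"{component}_{series.variant}",
        participant_id=series.participant_id,
    )


def cumulative_spectrum(summary: SpectrumSummary, f_prime: float) -> float:
    """C_X(f'): fraction of spectral mass at or below f'.

    Linear interpolation of the cumulative curve between grid points;
    C_X(0) = 0 (DC excluded) and C_X(f_nyq) = 1 by normalization.
    """
    if not 0.0 <= f_prime <= summary.f_nyq:
        raise ValueError(f"f_prime must lie in [0, {summary.f_nyq}]")
    if f_prime == 0.0:
        return 0.0
    return float(np.interp(f_prime, summary.freqs, summary.cumulative))
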