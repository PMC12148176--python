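"""Empirical mode decomposition and Hilbert-Huang instantaneous frequency.

EMD adaptively splits a signal into intrinsic mode functions (IMFs), ordered
from high to low frequency.  One IMF is extracted by *sifting*: cubic-spline
envelopes are drawn through the local maxima and minima (with mirror
extension of the outermost extrema to tame end swings), their mean is
subtracted, and the step repeats until the candidate is envelope-symmetric —
operationally, until the normalized squared change between consecutive sifts
drops below ``sd_threshold`` and the IMF criterion (extrema and
zero-crossing counts differing by at most one) holds.  Extraction stops when
the residual is monotone or has fewer than three extrema.

Each IMF S(t) then yields the analytic signal Z(t) = S(t) + j*H{S(t)}
(H the Hilbert transform), whose magnitude is the instantaneous amplitude
a(t), whose unwrapped argument is the instantaneous phase theta(t), and
whose phase derivative omega(t) = d theta/dt gives the instantaneous
frequency (IF) in Hz after division by 2*pi.  The empirical distribution of
the IF over time, binned at 0.5 Hz on [0, 500], is the feature carried into
the group statistics:  cdf_{X,Y}(f) = integral_0^f rho_{X,Y}(f~) df~ for
velocity variable X and IMF Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert as _hilbert

SD_THRESHOLD_DEFAULT = 0.2
MAX_SIFTINGS_DEFAULT = 100


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus count once."""
    dx = np.diff(x)
    s = np.sign(dx)
    nz = s != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    # propagate the last nonzero slope sign across plateaus
    pos = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(pos, out=pos)
    sf = s[pos]
    ds = np.diff(sf)
    imax = np.flatnonzero(ds < 0) + 1
    imin = np.flatnonzero(ds > 0) + 1
    return imax, imin


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def _mirrored_spline(n: int, idx: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through (idx, val), mirror-extended at both ends."""
    k = min(2, len(idx))
    t_pre = -idx[:k][::-1].astype(float)
    v_pre = val[:k][::-1]
    t_post = 2.0 * (n - 1) - idx[-k:][::-1].astype(float)
    v_post = val[-k:][::-1]
    t = np.concatenate([t_pre, idx.astype(float), t_post])
    v = np.concatenate([v_pre, val, v_post])
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    if len(t) < 2:
        return np.full(n, v[0])
    return CubicSpline(t, v)(np.arange(n))


@dataclass
class ImfSet:
    """IMFs S_1..S_m (high to low frequency) plus the residual trend."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_variable: str = ""
    sift_report: list[dict] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for s in self.imfs:
            out += s
        return out


def imf_defect(imf: np.ndarray) -> int:
    """|#extrema - #zero-crossings| — at most 1 for a proper IMF."""
    imax, imin = _extrema_indices(imf)
    return abs((len(imax) + len(imin)) - _zero_crossings(imf))


def decompose(
    signal: np.ndarray,
    max_imfs: int = 10,
    sd_threshold: float = SD_THRESHOLD_DEFAULT,
    max_siftings: int = MAX_SIFTINGS_DEFAULT,
    source_variable: str = "",
) -> ImfSet:
    """Decompose a finite signal into IMFs by sifting.

    A constant or monotone signal yields zero IMFs with the signal as
    residual.  Signals shorter than 16 samples are rejected — there is no
    room for envelope construction.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < 16:
        raise ValueError("signal too short for EMD (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite (pass a valid segment)")

    residual = x.copy()
    imfs: list[np.ndarray] = []
    report: list[dict] = []
    for _ in range(max_imfs):
        imax, imin = _extrema_indices(residual)
        if len(imax) + len(imin) < 3:
            break
        h = residual.copy()
        stop_reason = "max_siftings"
        for it in range(1, max_siftings + 1):
            imax, imin = _extrema_indices(h)
            if len(imax) < 2 or len(imin) < 2:
                stop_reason = "too_few_extrema"
                break
            upper = _mirrored_spline(len(h), imax, h[imax])
            lower = _mirrored_spline(len(h), imin, h[imin])
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2) / denom) if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold and imf_defect(h) <= 1:
                stop_reason = "sd_and_defect"
                break
        if stop_reason == "too_few_extrema" and imf_defect(h) > 1:
            # not an oscillatory mode; it belongs to the residual trend
            break
        imfs.append(h)
        report.append({"iterations": it, "stop_reason": stop_reason})
        residual = residual - h
    return ImfSet(imfs, residual, source_variable, report)


@dataclass
class HilbertAnalysis:
    """Instantaneous amplitude, phase and frequency of one IMF.

    ``interior`` flags the samples away from the edges (the first and last
    ``boundary_frac`` of the series), where the discrete Hilbert transform
    is trustworthy.
    """

    ia: np.ndarray
    ip: np.ndarray
    inst_freq: np.ndarray
    interior: np.ndarray
    imf_index: int = 0
    dt_ms: float = 1.0


def hilbert_analysis(
    imf: np.ndarray,
    dt_ms: float = 1.0,
    imf_index: int = 0,
    boundary_frac: float = 0.05,
) -> HilbertAnalysis:
    """Analytic-signal analysis of an IMF.

    IA is |Z(t)|; IP the unwrapped argument of Z(t); IF the centred
    difference of the IP divided by 2*pi*dt (forward/backward at the ends),
    in Hz.  An all-zero IMF has no defined phase and is rejected.
    """
    x = np.asarray(imf, dtype=float)
    if np.allclose(x, 0.0):
        raise ValueError("all-zero IMF: instantaneous phase undefined")
    z = _hilbert(x)
    ia = np.abs(z)
    ip = np.unwrap(np.angle(z))
    dt_s = dt_ms / 1000.0
    inst_freq = np.gradient(ip, dt_s) / (2.0 * np.pi)
    n = len(x)
    b = max(1, int(round(boundary_frac * n)))
    interior = np.zeros(n, dtype=bool)
    interior[b:n - b] = True
    return HilbertAnalysis(ia, ip, inst_freq, interior, imf_index, dt_ms)


@dataclass
class IfDistribution:
    """Histogram distribution of instantaneous frequency for one IMF.

    ``edges`` are the bin edges on [0, f_max]; ``density`` integrates to one
    over the range; ``cdf`` is evaluated at the bin edges (cdf[0] = 0,
    cdf[-1] = 1).  ``n_negative`` counts excluded negative-IF samples.
    """

    edges: np.ndarray
    density: np.ndarray
    cdf: np.ndarray
    variable: str = ""
    imf_index: int = 0
    n_negative: int = 0
    n_samples: int = 0


def if_distribution_from_samples(
    samples: np.ndarray,
    bin_width: float = 0.5,
    f_max: float = 500.0,
    min_samples: int = 8,
    variable: str = "",
    imf_index: int = 0,
) -> IfDistribution:
    """Build an IF distribution from raw IF samples (possibly pooled across
    several valid segments of one recording)."""
    vals = np.asarray(samples, dtype=float)
    if vals.size < min_samples:
        raise ValueError(f"too few interior samples ({vals.size} < {min_samples})")
    n_negative = int(np.sum(vals < 0))
    vals = np.clip(vals[vals >= 0], 0.0, f_max - 1e-12)
    if vals.size == 0:
        raise ValueError("all interior IF samples negative")
    edges = np.arange(0.0, f_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    density = counts / counts.sum() / bin_width
    cdf = np.concatenate([[0.0], np.cumsum(counts) / counts.sum()])
    return IfDistribution(edges, density, cdf, variable, imf_index, n_negative, vals.size)


def if_distribution(
    h: HilbertAnalysis,
    bin_width: float = 0.5,
    f_max: float = 500.0,
    min_samples: int = 8,
    variable: str = "",
) -> IfDistribution:
    """Empirical IF distribution over interior samples, 0.5 Hz bins on [0, 500].

    Negative IF values (non-IMF-like local behaviour) are excluded from the
    histogram and counted; values above ``f_max`` land in the last bin.
    """
    return if_distribution_from_samples(
        h.inst_freq[h.interior], bin_width, f_max, min_samples, variable, h.imf_index
    )


def cdf_at(dist: IfDistribution, f: float) -> float:
    """cdf_{X,Y}(f): linear interpolation of the IF cdf between bin edges."""
    if not 0.0 <= f <= dist.edges[-1]:
        raise ValueError(f"f must lie in [0, {dist.edges[-1]}]")
    return float(np.interp(f, dist.edges, dist.cdf))
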