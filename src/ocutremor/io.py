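"""Tabular file formats, run configuration and screen-geometry conversions.

All interchange is plain delimited text (comma, UTF-8, "." decimal):

* gaze tables — columns ``time_ms, x, y, label, participant_id``; positions
  may be blank only on BLINK rows,
* trial tables — columns ``participant_id, flicker_freq, true_side, answer``,
* feature tables — tidy ``participant, family, freq, value``,
* run configuration — YAML.

Analysis is monocular (one position pair per sample).  Pixel-space inputs
convert to degrees of visual angle through the screen geometry in the run
configuration; the visual angle of a stimulus of size s (cm) viewed at
distance d (m) is atan(s / (100 d)) in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import atan, degrees as _degrees
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import BLINK, VALID_LABELS, GazeRecording
from .psychophysics import TrialResponse


def visual_angle(size_cm: float, distance_m: float) -> float:
    """Visual angle in degrees of a stimulus of ``size_cm`` at ``distance_m``.

    A 2.5 cm cross at 1 m subtends 1.4 degrees; two targets 35 cm apart at
    1 m are 19 degrees apart.  Rounding is the caller's concern.
    """
    if size_cm < 0:
        raise ValueError("size must be >= 0")
    if distance_m <= 0:
        raise ValueError("distance must be > 0")
    return _degrees(atan(size_cm / (100.0 * distance_m)))


def pixels_to_degrees(px: np.ndarray, px_per_cm: float, distance_m: float) -> np.ndarray:
    """Convert screen-referenced pixel offsets to degrees of visual angle."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be > 0")
    return np.degrees(np.arctan(np.asarray(px, float) / px_per_cm / (100.0 * distance_m)))


@dataclass
class RunConfig:
    """Everything a pipeline run reads; no stage holds hidden constants."""

    seed: int = 0
    out_dir: str = "run_output"
    n_participants: int = 81
    duration: float = 30.0  # s per recording
    sampling_interval: float = 1.0  # ms
    # screen geometry (pixel-input conversions and simulated target layout)
    viewing_distance_m: float = 1.0
    target_size_cm: float = 2.5
    target_separation_cm: float = 35.0
    screen_px: tuple[int, int] = (1920, 1080)
    # analysis settings
    reversal_k: tuple[int, ...] = (2, 4, 8)
    reversal_lags_ms: tuple[float, ...] = tuple(float(t) for t in range(1, 11))
    spectrum_min_segment: int = 256
    spectrum_grid_step: float = 0.5
    emd_max_imfs: int = 6
    emd_sd_threshold: float = 0.2
    n_imfs_analyzed: int = 3
    thresholds: tuple[float, ...] = (60.0, 120.0)
    classifier_grid: dict = field(default_factory=dict)
    link_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("screen_px", "reversal_k", "reversal_lags_ms", "thresholds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


class GazeTableError(ValueError):
    """Malformed gaze table; the message names the first offending line."""


def read_gaze_table(path: str | Path) -> GazeRecording:
    """Read and validate a gaze CSV into a :class:`GazeRecording`.

    Checks: uniform time grid, legal labels, positions present except on
    BLINK rows.  Error messages carry 1-based file line numbers (the header
    is line 1).
    """
    df = pd.read_csv(path, dtype={"label": str, "participant_id": str})
    required = {"time_ms", "x", "y", "label", "participant_id"}
    missing = required - set(df.columns)
    if missing:
        raise GazeTableError(f"{path}: missing columns {sorted(missing)}")
    lines = df.index.to_numpy() + 2  # header occupies line 1

    bad_label = ~df["label"].isin(sorted(VALID_LABELS))
    if bad_label.any():
        i = int(np.flatnonzero(bad_label)[0])
        raise GazeTableError(
            f"{path}, line {lines[i]}: unknown label {df['label'].iloc[i]!r}"
        )
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) >= 2:
        steps = np.diff(t)
        off = ~np.isclose(steps, steps[0], rtol=0, atol=1e-9) | (steps <= 0)
        if off.any():
            i = int(np.flatnonzero(off)[0]) + 1
            raise GazeTableError(
                f"{path}, line {lines[i]}: non-uniform time step "
                f"({steps[i - 1]} ms vs {steps[0]} ms)"
            )
    nonblink = (df["label"] != BLINK).to_numpy()
    for col in ("x", "y"):
        blank = df[col].isna().to_numpy() & nonblink
        if blank.any():
            i = int(np.flatnonzero(blank)[0])
            raise GazeTableError(
                f"{path}, line {lines[i]}: blank {col} on a "
                f"{df['label'].iloc[i]} row"
            )
    pid = str(df["participant_id"].iloc[0]) if len(df) else ""
    return GazeRecording(
        t,
        df["x"].to_numpy(dtype=float),
        df["y"].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=object),
        pid,
    )


def write_gaze_table(rec: GazeRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_ms": rec.t,
            "x": rec.x,
            "y": rec.y,
            "label": rec.labels,
            "participant_id": rec.participant_id,
        }
    ).to_csv(path, index=False)


def read_trial_table(path: str | Path) -> list[TrialResponse]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return [
        TrialResponse(
            str(r.participant_id), float(r.flicker_freq), str(r.true_side), str(r.answer)
        )
        for r in df.itertuples()
    ]


def write_trial_table(trials: list[TrialResponse], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "flicker_freq": [t.flicker_freq for t in trials],
            "true_side": [t.true_side for t in trials],
            "answer": [t.answer for t in trials],
        }
    ).to_csv(path, index=False)
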