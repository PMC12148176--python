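"""End-to-end pipeline: simulate -> features -> labels -> statistics -> classifier.

Feature extraction turns one gaze recording into the 16 cumulative feature
curves used downstream: the cumulative power spectrum ``C_{var}`` of each of
the four velocity variables (vx/vy, unit/fixational), and the instantaneous-
frequency cdf ``cdf_{var}_Sk`` of IMFs S1-S3 of each variable.  EMD and
spectra are computed per contiguous valid segment; IF samples are pooled
across segments of a recording before binning.

:func:`run_pipeline` drives the whole analysis from a :class:`~.io.RunConfig`
and writes every intermediate table plus a run manifest (seed, config hash,
library versions, per-stage outputs) so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import COMPONENT_FAMILIES, CfftTreeModel, assemble_features
from .emd import decompose, hilbert_analysis, if_distribution_from_samples
from .group_stats import GroupSeparation, ParticipantFeatureCurve
from .io import RunConfig, write_gaze_table, write_trial_table
from .kinematics import (
    GazeRecording,
    compute_velocity,
    fixational_velocity,
    reversal_peak,
    reversal_probability,
    unit_velocity,
)
from .psychophysics import label_detection
from .spectral import InsufficientDataError, power_spectrum, valid_segments
from .synthetic import SimulationConfig, simulate_cohort


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def velocity_variables(rec: GazeRecording) -> dict[str, tuple]:
    """The four analysis variables as (series, component) pairs."""
    v_unit = unit_velocity(compute_velocity(rec))
    v_fix = fixational_velocity(rec)
    return {
        "vx_unit": (v_unit, "vx"),
        "vy_unit": (v_unit, "vy"),
        "vx_fix": (v_fix, "vx"),
        "vy_fix": (v_fix, "vy"),
    }


def extract_feature_curves(
    rec: GazeRecording,
    min_segment: int = 256,
    grid_step: float = 0.5,
    max_imfs: int = 6,
    n_imfs_analyzed: int = 3,
    include_emd: bool = True,
) -> dict[str, ParticipantFeatureCurve]:
    """All cumulative feature curves of one recording, keyed by family name.

    Families whose inputs are insufficient (e.g. no valid fixational segment
    long enough) are silently absent from the result; callers decide whether
    a missing family is an error.
    """
    curves: dict[str, ParticipantFeatureCurve] = {}
    for var, (series, comp) in velocity_variables(rec).items():
        try:
            spec = power_spectrum(series, comp, min_segment=min_segment, grid_step=grid_step)
        except InsufficientDataError:
            continue
        curves[f"C_{var}"] = ParticipantFeatureCurve(
            rec.participant_id, f"C_{var}", spec.freqs, spec.cumulative
        )
        if not include_emd:
            continue
        dt_ms = rec.sampling_interval
        pooled: dict[int, list[np.ndarray]] = {i: [] for i in range(n_imfs_analyzed)}
        for seg in valid_segments(series.component(comp), series.valid, min_segment):
            imf_set = decompose(seg, max_imfs=max_imfs, source_variable=var)
            for i, imf in enumerate(imf_set.imfs[:n_imfs_analyzed]):
                try:
                    h = hilbert_analysis(imf, dt_ms=dt_ms, imf_index=i)
                except ValueError:
                    continue
                pooled[i].append(h.inst_freq[h.interior])
        for i in range(n_imfs_analyzed):
            if not pooled[i]:
                continue
            samples = np.concatenate(pooled[i])
            try:
                dist = if_distribution_from_samples(
                    samples, bin_width=grid_step, variable=var, imf_index=i
                )
            except ValueError:
                continue
            fam = f"cdf_{var}_S{i + 1}"
            curves[fam] = ParticipantFeatureCurve(
                rec.participant_id, fam, dist.edges, dist.cdf
            )
    return curves


def reversal_table(
    rec: GazeRecording,
    k_values: tuple[int, ...] = (2, 4, 8),
    lags_ms: tuple[float, ...] = tuple(float(t) for t in range(1, 11)),
) -> pd.DataFrame:
    """Tidy direction-reversal curves of one recording (fixational velocity)."""
    v = fixational_velocity(rec)
    rows = []
    for k in k_values:
        curve = reversal_probability(v, k, lags_ms)
        for tau, pr, n in zip(curve.tau_grid, curve.pr, curve.n_pairs):
            rows.append(
                {"participant": rec.participant_id, "k": k, "tau_ms": tau,
                 "pr": pr, "n_pairs": n}
            )
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artifacts under ``config.out_dir``.

    Stages: simulate, reversal, features, psychophysics, group_stats,
    classify.  Returns the manifest (also written as ``manifest.json``).
    Any stage failure raises :class:`PipelineError` naming the stage, after
    writing the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import scipy
    import sklearn

    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "versions": {
            "ocutremor": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "stages": {},
    }

    def _fail(stage: str, exc: Exception):
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, manifest, exc) from exc

    # --- simulate ---
    stage = "simulate"
    try:
        sim = SimulationConfig(
            sampling_interval=config.sampling_interval,
            duration=config.duration,
            seed=config.seed,
        )
        profiles, recordings, trials = simulate_cohort(
            config.n_participants, sim, link_params=config.link_params or None
        )
        gaze_dir = out / "gaze"
        gaze_dir.mkdir(exist_ok=True)
        files = []
        for rec in recordings:
            p = gaze_dir / f"{rec.participant_id}.csv"
            write_gaze_table(rec, p)
            files.append(str(p))
        write_trial_table(trials, out / "trials.csv")
        pd.DataFrame([asdict(p) for p in profiles]).to_csv(
            out / "profiles.csv", index=False
        )
        manifest["stages"][stage] = files + [str(out / "trials.csv"), str(out / "profiles.csv")]
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail(stage, exc)

    # --- reversal statistic ---
    stage = "reversal"
    try:
        tables = [
            reversal_table(rec, config.reversal_k, config.reversal_lags_ms)
            for rec in recordings
        ]
        rev = pd.concat(tables, ignore_index=True)
        rev.to_csv(out / "reversal_curves.csv", index=False)
        peaks = []
        for rec, tab in zip(recordings, tables):
            v = fixational_velocity(rec)
            for k in config.reversal_k:
                curve = reversal_probability(v, k, config.reversal_lags_ms)
                tau_max, pr_max = reversal_peak(curve)
                peaks.append(
                    {"participant": rec.participant_id, "k": k,
                     "tau_max_ms": tau_max, "pr_max": pr_max}
                )
        pd.DataFrame(peaks).to_csv(out / "reversal_peaks.csv", index=False)
        manifest["stages"][stage] = [
            str(out / "reversal_curves.csv"), str(out / "reversal_peaks.csv")
        ]
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- features ---
    stage = "features"
    try:
        all_curves: dict[str, list[ParticipantFeatureCurve]] = {}
        rows = []
        for rec in recordings:
            curves = extract_feature_curves(
                rec,
                min_segment=config.spectrum_min_segment,
                grid_step=config.spectrum_grid_step,
                max_imfs=config.emd_max_imfs,
                n_imfs_analyzed=config.n_imfs_analyzed,
            )
            for fam, c in curves.items():
                all_curves.setdefault(fam, []).append(c)
                rows.append(
                    pd.DataFrame(
                        {"participant": c.participant_id, "family": fam,
                         "freq": c.freqs, "value": c.values}
                    )
                )
        feat = pd.concat(rows, ignore_index=True)
        feat.to_csv(out / "feature_curves.csv", index=False)
        manifest["stages"][stage] = [str(out / "feature_curves.csv")]
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- psychophysics ---
    stage = "psychophysics"
    try:
        labels = label_detection(trials)
        lab_rows = [
            {"participant": p, **{f"detected_{f:g}Hz": d[f] for f in sorted(d)}}
            for p, d in labels.detected_at.items()
        ]
        pd.DataFrame(lab_rows).to_csv(out / "detection_labels.csv", index=False)
        manifest["stages"][stage] = [str(out / "detection_labels.csv")]
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- group statistics (Table-1 analogue) ---
    stage = "group_stats"
    try:
        complete = {
            fam: cs for fam, cs in all_curves.items()
            if len(cs) == len(recordings)
        }
        model = GroupSeparation(complete, labels, config.thresholds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sep = model.fit()
        sep._partial_table().to_csv(out / "group_separation.csv", index=False)
        manifest["stages"][stage] = [str(out / "group_separation.csv")]
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --- classification (Table-2 analogue) ---
    stage = "classify"
    try:
        files = []
        for th in config.thresholds:
            per_th = {
                fam: sep[(fam, th)] for fam in COMPONENT_FAMILIES if fam in complete
            }
            matrix = assemble_features(per_th, complete, labels, tuple(per_th))
            grid = {k: tuple(v) for k, v in config.classifier_grid.items()} or None
            clf = CfftTreeModel(matrix, param_grid=grid)
            res = clf.fit(seed=config.seed)
            p_json = out / f"classifier_{th:g}Hz.json"
            p_txt = out / f"classifier_{th:g}Hz.txt"
            p_json.write_text(res.report.to_json())
            p_txt.write_text(res.summary() + "\n")
            files += [str(p_json), str(p_txt)]
        manifest["stages"][stage] = files
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
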