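"""End-to-end session pipeline.

Convenience drivers that chain the simulator, behavior segmentation, trace
processing, tuning analyses, and the encoding model the way the analysis
scripts and recovery tests consume them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior, encoder, simulate, traces, tuning


@dataclass
class SessionData:
    """One simulated session plus everything derived from it."""

    config: simulate.SessionConfig
    timeline: pd.DataFrame
    truth: simulate.SyntheticGroundTruth
    trace_set: simulate.RoiTraceSet
    pupil_raw: simulate.PupilRaw
    labeling: behavior.EpochLabeling
    laps: pd.DataFrame
    pupil: pd.DataFrame           # cleaned channels
    norm_dff: np.ndarray          # merged, corrected, normalized axon trace
    peaks: traces.PeakSet
    merge_groups: list[list[int]]


def simulate_session(condition: str, seed: int,
                     n_rois: int = 3, **config_kwargs) -> tuple:
    """Generate one full synthetic session (behavior, traces, pupil)."""
    cfg = simulate.SessionConfig(condition=condition, rng_seed=seed,
                                 **config_kwargs)
    timeline, truth = simulate.generate_behavior(cfg)
    trace_set = simulate.generate_axon_traces(
        timeline, truth, n_rois=n_rois, seed=seed + 1,
        frame_rate_hz=cfg.frame_rate_hz)
    pupil_raw, blink_frames = simulate.generate_pupil(
        timeline, seed=seed + 2, frame_rate_hz=cfg.frame_rate_hz)
    truth.blink_frames = blink_frames
    return cfg, timeline, truth, trace_set, pupil_raw


def process_session(cfg: simulate.SessionConfig, timeline: pd.DataFrame,
                    truth: simulate.SyntheticGroundTruth,
                    trace_set: simulate.RoiTraceSet,
                    pupil_raw: simulate.PupilRaw) -> SessionData:
    """Run segmentation and trace processing on a simulated session."""
    rate = cfg.frame_rate_hz
    velocity = timeline["velocity_cm_s"].to_numpy()
    teleport = timeline["is_teleport"].to_numpy()

    labeling = behavior.label_frames(velocity, rate, teleport=teleport)
    laps = behavior.split_traversals(timeline["position_cm"].to_numpy(),
                                     teleport, frame_rate=rate,
                                     track_length=cfg.track_length_cm)
    pupil = behavior.pupil_preprocess(pupil_raw.area, pupil_raw.x_pos,
                                      pupil_raw.y_pos, pupil_raw.blink_area,
                                      frame_rate=rate)

    n_rois = trace_set.green_raw.shape[0]
    dff = np.vstack([
        traces.compute_dff(
            traces.correct_channels(trace_set.green_raw[r],
                                    trace_set.red_raw[r]), rate)
        for r in range(n_rois)])
    groups, merged = traces.merge_correlated_rois(dff, rate, seed=cfg.rng_seed)
    # the most active merged trace is the session's putative single axon
    axon = merged[int(np.argmax(merged.std(axis=1)))]
    norm = traces.normalize_per_day(axon)
    peaks = traces.detect_peaks(norm, rate)

    return SessionData(config=cfg, timeline=timeline, truth=truth,
                       trace_set=trace_set, pupil_raw=pupil_raw,
                       labeling=labeling, laps=laps, pupil=pupil,
                       norm_dff=norm, peaks=peaks, merge_groups=groups)


def run_session(condition: str, seed: int, n_rois: int = 3,
                **config_kwargs) -> SessionData:
    """Simulate and process one session."""
    parts = simulate_session(condition, seed, n_rois=n_rois, **config_kwargs)
    return process_session(*parts)


def encode_session(data: SessionData,
                   config: encoder.FitConfig | None = None) -> dict:
    """Fit and score the encoding model for one processed session."""
    features = encoder.build_features(data.timeline, data.labeling,
                                      data.pupil, data.config.frame_rate_hz)
    result = encoder.run_encoding_session(features, data.norm_dff,
                                          data.laps, config)
    result["features"] = features
    return result
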