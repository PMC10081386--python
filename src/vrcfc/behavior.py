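"""Behavioral-state segmentation and fear-behavior statistics.

Frames are partitioned into five states from the signed forward velocity:

* ``freeze``    — |velocity| < 0.001 cm/s sustained for >= 12 frames (~0.75 s)
* ``run``       — velocity > 0.001 cm/s sustained for >= 2 frames
* ``backtrack`` — velocity < -0.001 cm/s sustained for >= 2 frames
* ``discarded`` — sub-criterion stretches of any of the above
* ``teleport``  — virtual-reality teleport pause; terminates any open epoch

Threshold comparisons are strict; a frame exactly at +-0.001 cm/s counts as
neither freezing nor locomotion and ends up discarded.  Epochs are half-open
frame intervals ``[start, end)``, numbered 1..n in time order; ``epoch_id``
0 means the frame belongs to no epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

log = logging.getLogger(__name__)

FREEZE = "freeze"
RUN = "run"
BACKTRACK = "backtrack"
DISCARDED = "discarded"
TELEPORT = "teleport"
UNLABELED = "unlabeled"

VELOCITY_THRESH_CM_S = 0.001
MIN_FREEZE_FRAMES = 12
MIN_RUN_FRAMES = 2


@dataclass
class EpochLabeling:
    """Per-frame state labels plus the epoch table."""

    state: np.ndarray            # per-frame state string
    epoch_id: np.ndarray         # per-frame epoch ordinal, 0 = none
    epoch_table: pd.DataFrame    # epoch_id, state, start_frame, end_frame, duration_s
    frame_rate_hz: float

    def epochs(self, state: str) -> pd.DataFrame:
        return self.epoch_table[self.epoch_table["state"] == state]


@dataclass
class FreezeSummary:
    pct_time_freezing: float
    n_freezes: int
    freeze_lengths_s: list[float]
    mean_freeze_len_s: float
    median_freeze_len_s: float


@dataclass
class DiscriminationResult:
    di: float
    pct_shocked: float
    pct_control: float


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open (start, end) pairs."""
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _segments(n: int, teleport: np.ndarray | None) -> list[tuple[int, int]]:
    """Contiguous non-teleport stretches; epochs never span a teleport."""
    if teleport is None:
        return [(0, n)] if n else []
    return _maximal_runs(~np.asarray(teleport, dtype=bool))


def _finalize(labeling: EpochLabeling) -> EpochLabeling:
    """Renumber epochs 1..n in time order and rebuild the frame epoch_id."""
    tab = labeling.epoch_table.sort_values("start_frame").reset_index(drop=True)
    tab["epoch_id"] = np.arange(1, len(tab) + 1)
    epoch_id = np.zeros(len(labeling.state), dtype=int)
    for row in tab.itertuples():
        epoch_id[row.start_frame:row.end_frame] = row.epoch_id
    labeling.epoch_table = tab
    labeling.epoch_id = epoch_id
    return labeling


def _empty_labeling(n: int, frame_rate: float,
                    teleport: np.ndarray | None) -> EpochLabeling:
    state = np.full(n, UNLABELED, dtype=object)
    if teleport is not None:
        state[np.asarray(teleport, dtype=bool)] = TELEPORT
    table = pd.DataFrame(columns=["epoch_id", "state", "start_frame",
                                  "end_frame", "duration_s"])
    return EpochLabeling(state=state, epoch_id=np.zeros(n, dtype=int),
                         epoch_table=table, frame_rate_hz=frame_rate)


def _add_epochs(labeling: EpochLabeling, runs: list[tuple[int, int]],
                state: str, min_frames: int) -> None:
    """Label maximal runs: long enough -> epoch of ``state``, else discarded."""
    rows = []
    for a, b in runs:
        if b - a >= min_frames:
            labeling.state[a:b] = state
            rows.append((0, state, a, b, (b - a) / labeling.frame_rate_hz))
        else:
            labeling.state[a:b] = DISCARDED
    if rows:
        new = pd.DataFrame(rows, columns=["epoch_id", "state", "start_frame",
                                          "end_frame", "duration_s"])
        labeling.epoch_table = (pd.concat([labeling.epoch_table, new])
                                if len(labeling.epoch_table) else new)


def segment_freezing(velocity: np.ndarray, frame_rate: float,
                     thresh: float = VELOCITY_THRESH_CM_S,
                     min_frames: int = MIN_FREEZE_FRAMES,
                     teleport: np.ndarray | None = None) -> EpochLabeling:
    """Label freezing epochs: |velocity| < thresh for >= ``min_frames``.

    Sub-threshold stretches shorter than ``min_frames`` are discarded.
    Remaining frames stay unlabeled for :func:`segment_running`.
    """
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity trace contains non-finite values")
    labeling = _empty_labeling(len(v), frame_rate, teleport)
    for a, b in _segments(len(v), teleport):
        runs = [(a + s, a + e) for s, e in _maximal_runs(np.abs(v[a:b]) < thresh)]
        _add_epochs(labeling, runs, FREEZE, min_frames)
    return _finalize(labeling)


def segment_running(velocity: np.ndarray, labeling: EpochLabeling,
                    thresh: float = VELOCITY_THRESH_CM_S,
                    min_frames: int = MIN_RUN_FRAMES) -> EpochLabeling:
    """Fill running epochs (velocity > thresh for >= 2 frames) into a
    labeling produced by :func:`segment_freezing`."""
    v = np.asarray(velocity, dtype=float)
    open_mask = labeling.state == UNLABELED
    runs = _maximal_runs((v > thresh) & open_mask)
    _add_epochs(labeling, runs, RUN, min_frames)
    # above-threshold singletons orphaned next to freezes/teleports
    labeling.state[(labeling.state == UNLABELED) & (v > thresh)] = DISCARDED
    return _finalize(labeling)


def detect_backtracking(velocity: np.ndarray, labeling: EpochLabeling | None = None,
                        thresh: float = VELOCITY_THRESH_CM_S,
                        min_frames: int = MIN_RUN_FRAMES) -> np.ndarray:
    """Flag backward-movement frames: velocity < -thresh sustained >= 2 frames.

    If a labeling is given, qualifying runs become ``backtrack`` epochs and
    shorter ones are discarded (mirror of the running rule).
    """
    v = np.asarray(velocity, dtype=float)
    mask = v < -thresh
    flags = np.zeros(len(v), dtype=bool)
    if labeling is not None:
        mask = mask & (labeling.state == UNLABELED)
    runs = _maximal_runs(mask)
    for a, b in runs:
        if b - a >= min_frames:
            flags[a:b] = True
    if labeling is not None:
        _add_epochs(labeling, runs, BACKTRACK, min_frames)
        _finalize(labeling)
    return flags


def backtrack_fraction_by_traversal(flags: np.ndarray, laps: pd.DataFrame,
                                    first_n: int = 1) -> tuple[float, float]:
    """Fraction of lap frames spent backtracking in the first ``first_n``
    traversals versus all later traversals.

    How many early laps count as "first" is exposed because backward
    escape attempts concentrate at context entry.
    """
    flags = np.asarray(flags, dtype=bool)

    def frac(sel: pd.DataFrame) -> float:
        total = int((sel.end_frame - sel.start_frame).sum())
        if total == 0:
            return float("nan")
        hits = sum(int(flags[r.start_frame:r.end_frame].sum())
                   for r in sel.itertuples())
        return hits / total

    return frac(laps.iloc[:first_n]), frac(laps.iloc[first_n:])


def total_displacement(velocity: np.ndarray, frame_rate: float) -> float:
    """Total distance traversed (cm): sum of |velocity| x frame interval."""
    return float(np.sum(np.abs(np.asarray(velocity, dtype=float)))
                 / frame_rate)


def label_frames(velocity: np.ndarray, frame_rate: float,
                 teleport: np.ndarray | None = None,
                 thresh: float = VELOCITY_THRESH_CM_S,
                 min_freeze_frames: int = MIN_FREEZE_FRAMES,
                 min_run_frames: int = MIN_RUN_FRAMES) -> EpochLabeling:
    """Full segmentation: freeze, then run, then backtrack; leftovers are
    discarded.  Returns a labeling whose states partition every frame."""
    labeling = segment_freezing(velocity, frame_rate, thresh,
                                min_freeze_frames, teleport)
    segment_running(velocity, labeling, thresh, min_run_frames)
    detect_backtracking(velocity, labeling, thresh, min_run_frames)
    labeling.state[labeling.state == UNLABELED] = DISCARDED
    return labeling


def freeze_summary(labeling: EpochLabeling) -> FreezeSummary:
    """Percent time freezing and the freeze-length distribution.

    The denominator counts freeze, run, and backtrack frames only; discarded
    and teleport frames are excluded as un-analyzable.
    """
    state = labeling.state
    n_freeze = int(np.sum(state == FREEZE))
    denom = n_freeze + int(np.sum(state == RUN)) + int(np.sum(state == BACKTRACK))
    if denom == 0:
        raise ValueError("no analyzable (freeze/run/backtrack) frames")
    lengths = labeling.epochs(FREEZE)["duration_s"].tolist()
    return FreezeSummary(
        pct_time_freezing=100.0 * n_freeze / denom,
        n_freezes=len(lengths),
        freeze_lengths_s=lengths,
        mean_freeze_len_s=float(np.mean(lengths)) if lengths else float("nan"),
        median_freeze_len_s=float(np.median(lengths)) if lengths else float("nan"),
    )


def percent_increase(new: float, old: float) -> float:
    """Percent increase of ``new`` over ``old``: 100 * (new - old) / old."""
    if old == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new - old) / old


def discrimination_index(pct_shocked: float, pct_control: float
                         ) -> DiscriminationResult:
    """Context-discrimination index (s - c) / (s + c), in [-1, 1]."""
    if pct_shocked < 0 or pct_control < 0:
        raise ValueError("freezing percentages must be non-negative")
    total = pct_shocked + pct_control
    if total == 0:
        raise ValueError("discrimination index undefined when both are zero")
    return DiscriminationResult(di=(pct_shocked - pct_control) / total,
                                pct_shocked=pct_shocked,
                                pct_control=pct_control)


def shock_aligned_velocity(velocity: np.ndarray, shock_onsets: np.ndarray,
                           frame_rate: float, pre_s: float = 2.0,
                           post_s: float = 4.0) -> dict:
    """Align velocity snippets to shock onsets; mean and 95% CI per offset.

    Onsets too close to the session edge for a full window are dropped
    (logged).  Returns offsets (s), the snippet matrix, the mean trace, and
    normal-theory 95% confidence bounds.
    """
    v = np.asarray(velocity, dtype=float)
    pre = int(round(pre_s * frame_rate))
    post = int(round(post_s * frame_rate))
    snippets = []
    for onset in np.asarray(shock_onsets, dtype=int):
        if onset - pre < 0 or onset + post > len(v):
            log.info("dropping shock at frame %d: window exceeds session", onset)
            continue
        snippets.append(v[onset - pre:onset + post])
    mat = (np.vstack(snippets) if snippets
           else np.empty((0, pre + post)))
    mean = mat.mean(axis=0) if len(mat) else np.full(pre + post, np.nan)
    sem = (mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
           if len(mat) > 1 else np.zeros(pre + post))
    return {
        "offsets_s": (np.arange(-pre, post)) / frame_rate,
        "matrix": mat,
        "mean": mean,
        "ci_low": mean - 1.96 * sem,
        "ci_high": mean + 1.96 * sem,
    }


def split_traversals(position: np.ndarray, teleport_flags: np.ndarray,
                     frame_rate: float | None = None,
                     track_length: float = 200.0) -> pd.DataFrame:
    """Split the session into track traversals (laps).

    Laps are delimited by teleport pauses (and, defensively, by any raw
    position wrap from the track end back to the start).  Teleport frames
    belong to no lap.  Returns lap_id, start_frame, end_frame (half-open)
    and, when ``frame_rate`` is given, per-lap traversal time in seconds.
    """
    pos = np.asarray(position, dtype=float)
    tp = np.asarray(teleport_flags, dtype=bool)
    rows = []
    for a, b in _maximal_runs(~tp):
        # split further at downward position jumps (wrap without teleport)
        breaks = [a]
        seg = pos[a:b]
        jump = np.flatnonzero(np.diff(seg) < -track_length / 2)
        breaks += [a + int(j) + 1 for j in jump]
        breaks.append(b)
        for s, e in zip(breaks[:-1], breaks[1:]):
            if e > s:
                rows.append((s, e))
    laps = pd.DataFrame(rows, columns=["start_frame", "end_frame"])
    laps.insert(0, "lap_id", np.arange(len(laps)))
    if frame_rate is not None:
        laps["traversal_time_s"] = (laps.end_frame - laps.start_frame) / frame_rate
    return laps


def pupil_preprocess(area: np.ndarray, x_pos: np.ndarray, y_pos: np.ndarray,
                     blink_area: np.ndarray, frame_rate: float,
                     target_rate: float | None = None,
                     window: int = 9, polyorder: int = 3,
                     blink_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Clean raw pupil channels.

    Frames whose blink area falls below ``mean - 2*SD`` of the blink-area
    series are treated as blinks (a precomputed ``blink_mask`` may override
    the rule): removed and linearly interpolated across.  Channels are then
    resampled to ``target_rate`` (default: unchanged) and smoothed with a
    Savitzky-Golay polynomial filter.
    """
    area = np.asarray(area, dtype=float)
    x_pos = np.asarray(x_pos, dtype=float)
    y_pos = np.asarray(y_pos, dtype=float)
    blink = np.asarray(blink_area, dtype=float)
    if not (len(area) == len(x_pos) == len(y_pos) == len(blink)):
        raise ValueError("pupil channels must have equal length")
    n = len(area)
    blinked = (np.asarray(blink_mask, dtype=bool) if blink_mask is not None
               else blink < blink.mean() - 2.0 * blink.std())
    if blinked.all():
        raise ValueError("every frame classified as a blink")

    t = np.arange(n) / frame_rate
    good = ~blinked
    target_rate = target_rate or frame_rate
    n_out = int(round(n / frame_rate * target_rate))
    t_out = np.arange(n_out) / target_rate

    out = {}
    for name, ch in (("area", area), ("x_pos", x_pos), ("y_pos", y_pos)):
        interp = np.interp(t, t[good], ch[good])     # fill blink gaps
        resampled = np.interp(t_out, t, interp)
        win = min(window if window % 2 else window + 1, n_out - (n_out + 1) % 2)
        out[name] = (savgol_filter(resampled, win, polyorder)
                     if win > polyorder else resampled)
    out["time_s"] = t_out
    return pd.DataFrame(out)
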