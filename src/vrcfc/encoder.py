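"""Boosted-trees encoding model of axonal activity.

Builds the per-frame behavioral feature table (freeze/run sawtooths,
velocity offsets, acceleration, interval counters, track location, pupil),
fits an XGBoost regression-tree ensemble to predict the normalized axon
trace, scores it with r² = 1 − u/v on held-out laps, estimates chance by
shuffling the trace across traversals, and reports grouped gain importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .behavior import EpochLabeling, FREEZE, RUN, BACKTRACK

log = logging.getLogger(__name__)

#: Feature -> interpretation-group mapping used for grouped gain reporting.
#: Acceleration is derived from velocity and reported with the velocity group.
FEATURE_GROUPS: dict[str, list[str]] = {
    "freezing": ["freeze", "is_freezing", "freeze_remaining", "is_postfreeze",
                 "freeze_progress", "freeze_elapsed"],
    "velocities": ["recorded_velocity", "velocity_back_15", "velocity_back_8",
                   "velocity_forward_8", "velocity_forward_15", "acceleration"],
    "running": ["is_running", "running_progress", "running_remaining",
                "is_backtracking", "running_elapsed"],
    "interval": ["interval_elapsed", "interval_remaining", "interval_progress"],
    "location": ["location"],
    "pupil": ["pupil_area", "pupil_x", "pupil_y"],
}

FEATURE_COLUMNS = [f for group in FEATURE_GROUPS.values() for f in group]


@dataclass
class FitConfig:
    """Model hyperparameters and evaluation settings."""

    gamma: float = 1.0
    learning_rate: float = 0.01
    n_estimators: int = 1000
    base_score: float = 1.0
    early_stopping_rounds: int = 5
    seed: int = 42
    train_fraction: float = 0.8
    eval_fraction: float = 0.1      # tail of the training laps for early stop
    n_null_shuffles: int = 20
    #: ensemble size for shuffle-null refits; kept at full capacity because
    #: early stopping terminates signal-free fits within a few rounds anyway
    null_n_estimators: int = 1000

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ModelScore:
    u: float    # residual sum of squares
    v: float    # total sum of squares
    r2: float


@dataclass
class GainReport:
    per_feature: dict[str, float]
    group_gain: dict[str, float]
    group_fraction: dict[str, float]


def _sawtooths(n: int, table: pd.DataFrame, prefix: str,
               out: dict[str, np.ndarray]) -> None:
    """elapsed / remaining / progress counters for one epoch state."""
    elapsed = np.zeros(n)
    remaining = np.zeros(n)
    progress = np.zeros(n)
    for row in table.itertuples():
        length = row.end_frame - row.start_frame
        idx = np.arange(length)
        elapsed[row.start_frame:row.end_frame] = idx
        remaining[row.start_frame:row.end_frame] = length - 1 - idx
        progress[row.start_frame:row.end_frame] = idx / max(length - 1, 1)
    out[f"{prefix}_elapsed"] = elapsed
    out[f"{prefix}_remaining"] = remaining
    out[f"{prefix}_progress"] = progress


def _edge_fill(shifted: np.ndarray, velocity: np.ndarray, lo: int, hi: int,
               leading: bool, n_ref: int = 15) -> None:
    """Fill missing edge frames with the mean of the nearest valid frames."""
    ref = velocity[:n_ref] if leading else velocity[-n_ref:]
    shifted[lo:hi] = float(ref.mean())


def build_features(timeline: pd.DataFrame, labeling: EpochLabeling,
                   pupil: pd.DataFrame, frame_rate: float,
                   postfreeze_window_s: float = 1.0) -> pd.DataFrame:
    """Assemble the per-frame behavioral predictor table.

    All frames (including teleports) get a row; lap-restricted frame
    selection happens at split time.  Velocity offsets shift the recorded
    velocity by ±8 and ±15 frames (~0.5 s and ~1 s), with missing edge
    frames filled from the mean of the nearest 15 recorded frames.
    """
    n = len(timeline)
    if len(pupil) != n or len(labeling.state) != n:
        raise ValueError("timeline, labeling, and pupil must share a frame base")
    v = timeline["velocity_cm_s"].to_numpy(dtype=float)
    out: dict[str, np.ndarray] = {}

    freeze_tab = labeling.epochs(FREEZE)
    run_tab = labeling.epochs(RUN)
    out["is_freezing"] = (labeling.state == FREEZE).astype(float)
    out["is_running"] = (labeling.state == RUN).astype(float)
    out["is_backtracking"] = (labeling.state == BACKTRACK).astype(float)

    # 'freeze': ordinal of the freeze epoch a frame belongs to, else 0
    freeze_ordinal = np.zeros(n)
    for k, row in enumerate(freeze_tab.itertuples(), start=1):
        freeze_ordinal[row.start_frame:row.end_frame] = k
    out["freeze"] = freeze_ordinal

    _sawtooths(n, freeze_tab, "freeze", out)
    _sawtooths(n, run_tab, "running", out)

    # interval counters: freeze and run sawtooths concatenated, resetting at
    # every state switch
    interval_tab = pd.concat([freeze_tab, run_tab]).sort_values("start_frame")
    _sawtooths(n, interval_tab, "interval", out)

    post = np.zeros(n)
    w = int(round(postfreeze_window_s * frame_rate))
    for row in freeze_tab.itertuples():
        post[row.end_frame:min(row.end_frame + w, n)] = 1.0
    out["is_postfreeze"] = post

    out["recorded_velocity"] = v
    for name, shift in (("velocity_back_15", 15), ("velocity_back_8", 8),
                        ("velocity_forward_8", -8), ("velocity_forward_15", -15)):
        s = np.roll(v, shift)
        if shift > 0:
            _edge_fill(s, v, 0, shift, leading=True)
        else:
            _edge_fill(s, v, n + shift, n, leading=False)
        out[name] = s
    out["acceleration"] = np.diff(v, prepend=v[0]) * frame_rate

    out["location"] = np.floor(timeline["position_cm"].to_numpy(dtype=float))
    out["pupil_area"] = pupil["area"].to_numpy(dtype=float)
    out["pupil_x"] = pupil["x_pos"].to_numpy(dtype=float)
    out["pupil_y"] = pupil["y_pos"].to_numpy(dtype=float)

    return pd.DataFrame(out)[FEATURE_COLUMNS]


def split_by_traversal(laps: pd.DataFrame, train_fraction: float = 0.8,
                       seed: int = 42) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole laps to train or test (no lap straddles the split)."""
    lap_ids = laps["lap_id"].to_numpy()
    if len(lap_ids) < 5:
        raise ValueError("need at least 5 laps for an 80/20 split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(lap_ids)
    n_train = int(round(train_fraction * len(lap_ids)))
    n_train = min(max(n_train, 1), len(lap_ids) - 1)
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def lap_frames(laps: pd.DataFrame, lap_ids: np.ndarray) -> np.ndarray:
    """Frame indices belonging to the given laps (teleports excluded)."""
    sel = laps[laps.lap_id.isin(lap_ids)]
    return np.concatenate([np.arange(r.start_frame, r.end_frame)
                           for r in sel.itertuples()]) if len(sel) else np.array([], int)


def score_r2(y_true: np.ndarray, y_pred: np.ndarray) -> ModelScore:
    """r² = 1 − u/v with u the residual and v the total sum of squares.

    A perfect prediction scores exactly 1.0; scores can be negative.  A
    constant target (v = 0) leaves r² undefined and raises.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    u = float(((yt - yp) ** 2).sum())
    v = float(((yt - yt.mean()) ** 2).sum())
    if v == 0:
        raise ValueError("total sum of squares is zero; r² undefined")
    return ModelScore(u=u, v=v, r2=1.0 - u / v)


def fit_encoding_model(X_train: pd.DataFrame, y_train: np.ndarray,
                       config: FitConfig | None = None,
                       eval_set: tuple[pd.DataFrame, np.ndarray] | None = None
                       ) -> xgb.XGBRegressor:
    """Fit the gradient-boosted-trees regressor with the configured
    hyperparameters; early stopping monitors ``eval_set`` when given."""
    config = config or FitConfig()
    if np.ptp(np.asarray(y_train, dtype=float)) == 0:
        log.warning("constant training target; model will predict a constant")
    model = xgb.XGBRegressor(
        gamma=config.gamma, learning_rate=config.learning_rate,
        n_estimators=config.n_estimators, base_score=config.base_score,
        early_stopping_rounds=(config.early_stopping_rounds
                               if eval_set is not None else None),
        random_state=config.seed, tree_method="hist", n_jobs=1)
    model.fit(X_train, y_train,
              eval_set=[eval_set] if eval_set is not None else None,
              verbose=False)
    return model


def run_encoding_session(features: pd.DataFrame, target: np.ndarray,
                         laps: pd.DataFrame, config: FitConfig | None = None
                         ) -> dict:
    """Split by traversal, fit, and score one session.

    The last ``eval_fraction`` of the training laps is held out for early
    stopping.  Returns the fitted model, train/test lap ids, and the test
    :class:`ModelScore`.
    """
    config = config or FitConfig()
    target = np.asarray(target, dtype=float)
    train_ids, test_ids = split_by_traversal(laps, config.train_fraction,
                                             config.seed)
    n_eval = max(int(round(config.eval_fraction * len(train_ids))), 1)
    fit_ids, eval_ids = train_ids[:-n_eval], train_ids[-n_eval:]
    fi = lap_frames(laps, fit_ids)
    ei = lap_frames(laps, eval_ids)
    ti = lap_frames(laps, test_ids)
    model = fit_encoding_model(features.iloc[fi], target[fi], config,
                               eval_set=(features.iloc[ei], target[ei]))
    pred = model.predict(features.iloc[ti])
    score = score_r2(target[ti], pred)
    return {"model": model, "train_lap_ids": train_ids,
            "test_lap_ids": test_ids, "test_frames": ti,
            "prediction": pred, "score": score}


def shuffle_null(features: pd.DataFrame, target: np.ndarray,
                 laps: pd.DataFrame, config: FitConfig | None = None,
                 n_shuffles: int | None = None, seed: int | None = None
                 ) -> np.ndarray:
    """Chance-level r² distribution from traversal-shuffled activity.

    Lap-blocks of the target trace are permuted across lap slots (each
    permuted block linearly resampled to the slot length), the model is
    refitted at the reduced ``null_n_estimators``, and the test r² recorded.
    """
    config = config or FitConfig()
    n_shuffles = n_shuffles if n_shuffles is not None else config.n_null_shuffles
    rng = np.random.default_rng(config.seed if seed is None else seed)
    target = np.asarray(target, dtype=float)
    blocks = [target[r.start_frame:r.end_frame] for r in laps.itertuples()]
    null_cfg = FitConfig(**{**config.__dict__,
                            "n_estimators": config.null_n_estimators})
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(blocks))
        shuffled = target.copy()
        for slot, src in zip(laps.itertuples(), perm):
            blk = blocks[src]
            length = slot.end_frame - slot.start_frame
            resampled = np.interp(np.linspace(0, 1, length),
                                  np.linspace(0, 1, len(blk)), blk)
            shuffled[slot.start_frame:slot.end_frame] = resampled
        out[s] = run_encoding_session(features, shuffled, laps,
                                      null_cfg)["score"].r2
    return out


def grouped_gain_from_dict(per_feature: dict[str, float],
                           grouping: dict[str, list[str]] | None = None
                           ) -> GainReport:
    """Map per-feature gains onto interpretation groups.

    Group gain is the mean of member gains (absent features count 0);
    fractions are normalized to sum to 1.  A feature not covered by the
    grouping raises, forcing explicit assignment.
    """
    grouping = grouping or FEATURE_GROUPS
    covered = {f for members in grouping.values() for f in members}
    missing = set(per_feature) - covered
    if missing:
        raise KeyError(f"features missing from the grouping: {sorted(missing)}")
    group_gain = {g: float(np.mean([per_feature.get(f, 0.0) for f in members]))
                  for g, members in grouping.items()}
    total = sum(group_gain.values())
    frac = {g: (val / total if total > 0 else 0.0)
            for g, val in group_gain.items()}
    return GainReport(per_feature=dict(per_feature), group_gain=group_gain,
                      group_fraction=frac)


def grouped_gain(model: xgb.XGBRegressor,
                 grouping: dict[str, list[str]] | None = None) -> GainReport:
    """Grouped gain importance of a fitted model."""
    raw = model.get_booster().get_score(importance_type="gain")
    return grouped_gain_from_dict(raw, grouping)
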