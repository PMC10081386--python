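"""Synthetic VR contextual-fear sessions with ground truth.

Generates the three data streams the downstream pipeline consumes —
a per-frame behavioral timeline, two-channel (GCaMP/mRuby-like) axonal
fluorescence traces, and raw pupil scalars — together with the generative
truth (epoch boundaries, transient times, tuning condition, shared artifact)
needed for recovery tests.

The behavioral model is a run/freeze renewal process: epoch durations are
drawn from condition-specific log-normal distributions whose means set the
long-run freeze fraction.  Position integrates velocity along a 200 cm
virtual track; completing a traversal triggers a 1.5 s teleport pause back
to the track start.  Shock-day sessions insert six 1 s tail shocks with
inter-shock gaps uniform in 20-26 s, each provoking a brief sprint
(velocity roughly quadrupling) during and just after the shock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

# Per-frame state codes used by the generator (the analysis package has its
# own labeling; these describe generative truth only).
RUN, FREEZE, TELEPORT = 0, 1, 2

#: Condition-specific generative parameters.
#: freeze_mean_s     mean freeze-epoch duration (s, log-normal mean)
#: freeze_frac       target long-run fraction of time frozen
#: backtrack_per_min expected backward-movement bouts per minute of running
#: tuning            "untuned" or "freeze_tuned" axonal event statistics
CONDITION_PARAMS: dict[str, dict] = {
    "pre_shock": dict(freeze_mean_s=2.5, freeze_frac=0.17, backtrack_per_min=0.0,
                      tuning="untuned"),
    "shock_day": dict(freeze_mean_s=2.5, freeze_frac=0.15, backtrack_per_min=0.0,
                      tuning="untuned"),
    "post_shock_shocked": dict(freeze_mean_s=5.5, freeze_frac=0.475,
                               backtrack_per_min=0.3, tuning="freeze_tuned"),
    "post_shock_control": dict(freeze_mean_s=4.2, freeze_frac=0.27,
                               backtrack_per_min=0.15, tuning="freeze_tuned"),
    "nr_inhibited": dict(freeze_mean_s=21.1, freeze_frac=0.775,
                         backtrack_per_min=0.3, tuning="freeze_tuned"),
}

LOGNORM_SIGMA = 0.6  # shape of epoch-length distributions (all conditions)


@dataclass
class SessionConfig:
    """Parameters of one simulated context exposure."""

    condition: str = "post_shock_shocked"
    frame_rate_hz: float = 15.49
    track_length_cm: float = 200.0
    session_duration_s: float = 322.0
    teleport_pause_s: float = 1.5
    #: list of (onset_s, duration_s); None = auto (day-0 schedule for
    #: condition "shock_day", empty otherwise)
    shock_schedule: list[tuple[float, float]] | None = None
    rng_seed: int = 0

    # locomotion
    run_speed_cm_s: float = 15.0      # session-mean running speed
    run_speed_jitter: float = 2.0     # across-session SD of that mean
    sprint_factor: float = 4.0        # velocity multiple during shocks
    sprint_hold_s: float = 1.0        # sprint persists this long post-shock
    sprint_relax_s: float = 0.5       # exponential relaxation time constant
    backtrack_speed_cm_s: float = 3.0

    # shock schedule defaults (day 0)
    n_shocks: int = 6
    shock_duration_s: float = 1.0
    shock_gap_range_s: tuple[float, float] = (20.0, 26.0)
    first_shock_s: float = 120.0

    @property
    def n_frames(self) -> int:
        return int(round(self.session_duration_s * self.frame_rate_hz))

    def __post_init__(self):
        if self.condition not in CONDITION_PARAMS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.frame_rate_hz <= 0 or self.session_duration_s <= 0:
            raise ValueError("frame rate and duration must be positive")


@dataclass
class WithinFreezeProfile:
    """Ramp-plateau-fall modulation of axonal event rate within a freeze.

    Rate ramps from ``floor`` to 1 over the first ``ramp_frac`` of the epoch,
    stays at ``plateau_level``, and falls back toward ``fall_floor`` over the
    final ``fall_frac``.
    """

    ramp_frac: float = 0.2
    plateau_level: float = 1.0
    fall_frac: float = 0.1
    floor: float = 0.2
    fall_floor: float = 0.3

    def __call__(self, progress: np.ndarray) -> np.ndarray:
        p = np.asarray(progress, dtype=float)
        out = np.full(p.shape, self.plateau_level)
        ramp = p < self.ramp_frac
        out[ramp] = self.floor + (self.plateau_level - self.floor) * (
            p[ramp] / self.ramp_frac
        )
        fall = p > 1.0 - self.fall_frac
        out[fall] = self.plateau_level - (self.plateau_level - self.fall_floor) * (
            (p[fall] - (1.0 - self.fall_frac)) / self.fall_frac
        )
        return out


@dataclass
class SyntheticGroundTruth:
    """Generative truth for one session."""

    true_freeze_epochs: list[tuple[int, int]]   # half-open [start, end)
    true_run_epochs: list[tuple[int, int]]
    backtrack_frames: np.ndarray
    tuning: str                                  # "untuned" | "freeze_tuned"
    artifact_trace: np.ndarray                   # shared motion component, SD 1
    within_freeze_profile: WithinFreezeProfile
    transient_times: list[np.ndarray] = field(default_factory=list)
    blink_frames: np.ndarray | None = None


@dataclass
class PupilRaw:
    """Raw pupil scalars, one value per imaging frame."""

    area: np.ndarray
    x_pos: np.ndarray
    y_pos: np.ndarray
    blink_area: np.ndarray


@dataclass
class RoiTraceSet:
    """Raw two-channel fluorescence, shape (n_rois, n_frames)."""

    green_raw: np.ndarray
    red_raw: np.ndarray
    frame_rate_hz: float


def default_shock_schedule(cfg: SessionConfig,
                           rng: np.random.Generator) -> list[tuple[float, float]]:
    """Day-0 schedule: n shocks of fixed duration, gaps uniform in the
    configured range, starting at ``first_shock_s``."""
    onsets = [cfg.first_shock_s]
    lo, hi = cfg.shock_gap_range_s
    for _ in range(cfg.n_shocks - 1):
        onsets.append(onsets[-1] + rng.uniform(lo, hi))
    sched = [(t, cfg.shock_duration_s) for t in onsets]
    if onsets[-1] + cfg.shock_duration_s > cfg.session_duration_s:
        raise ValueError(
            "session too short to fit the shock schedule "
            f"(last shock ends at {onsets[-1] + cfg.shock_duration_s:.1f} s, "
            f"session is {cfg.session_duration_s} s)")
    return sched


def _epoch_sampler(mean_s: float, min_frames: int, rate: float,
                   rng: np.random.Generator):
    """Draw log-normal epoch lengths (frames), clipped to a minimum."""
    mu = np.log(mean_s) - LOGNORM_SIGMA ** 2 / 2.0

    def draw() -> int:
        dur_s = float(rng.lognormal(mu, LOGNORM_SIGMA))
        return max(int(round(dur_s * rate)), min_frames)

    return draw


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open (start, end)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def generate_behavior(config: SessionConfig
                      ) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate the per-frame behavioral timeline of one session.

    Returns the timeline table (frame, time_s, position_cm, velocity_cm_s,
    context, is_teleport, is_shock) and the generative truth.
    """
    rng = np.random.default_rng(config.rng_seed)
    rate = config.frame_rate_hz
    dt = 1.0 / rate
    n = config.n_frames
    params = CONDITION_PARAMS[config.condition]

    # shock schedule
    if config.shock_schedule is not None:
        schedule = list(config.shock_schedule)
    elif config.condition == "shock_day":
        schedule = default_shock_schedule(config, rng)
    else:
        schedule = []
    for onset, dur in schedule:
        if onset < 0 or onset + dur > config.session_duration_s:
            raise ValueError(f"shock at {onset} s falls outside the session")

    is_shock = np.zeros(n, dtype=bool)
    sprint_mult = np.ones(n)
    for onset, dur in schedule:
        a = int(round(onset * rate))
        b = min(int(round((onset + dur + config.sprint_hold_s) * rate)), n)
        is_shock[a:min(int(round((onset + dur) * rate)), n)] = True
        sprint_mult[a:b] = config.sprint_factor
        # exponential relaxation back to baseline
        relax = np.arange(b, min(b + int(round(4 * config.sprint_relax_s * rate)), n))
        if relax.size:
            sprint_mult[relax] = np.maximum(
                sprint_mult[relax],
                1.0 + (config.sprint_factor - 1.0)
                * np.exp(-(relax - b) * dt / config.sprint_relax_s))

    # condition-specific epoch samplers
    f_mean = params["freeze_mean_s"]
    frac = params["freeze_frac"]
    r_mean = f_mean * (1.0 - frac) / frac
    draw_freeze = _epoch_sampler(f_mean, 13, rate, rng)
    draw_run = _epoch_sampler(r_mean, 4, rate, rng)

    # smooth running-speed process (AR-filtered noise around a session mean)
    base_speed = float(np.clip(rng.normal(config.run_speed_cm_s,
                                          config.run_speed_jitter), 8.0, 25.0))
    speed = base_speed + gaussian_filter1d(rng.normal(0.0, 3.0, n), sigma=rate)
    speed = np.clip(speed, 2.0, None)

    state = np.empty(n, dtype=np.int8)
    velocity = np.zeros(n)
    position = np.zeros(n)
    teleport_frames = int(round(config.teleport_pause_s * rate))

    cur_state = RUN
    frames_left = draw_run()
    teleport_left = 0
    backtrack_left = 0
    bt_marks = np.zeros(n, dtype=bool)
    # backward-movement bouts arrive at ``backtrack_per_min`` per minute of
    # running; each bout lasts 0.3-1.2 s at a fixed backward speed
    p_bt = params["backtrack_per_min"] * dt / 60.0
    pos = 0.0
    sprinting = sprint_mult > 1.0
    for i in range(n):
        if teleport_left > 0:
            state[i] = TELEPORT
            velocity[i] = 0.0
            position[i] = 0.0
            teleport_left -= 1
            continue
        if sprinting[i]:
            # shock-evoked sprint overrides the renewal process
            state[i] = RUN
            velocity[i] = speed[i] * sprint_mult[i]
            backtrack_left = 0
        else:
            if frames_left == 0:
                cur_state = FREEZE if cur_state == RUN else RUN
                frames_left = draw_freeze() if cur_state == FREEZE else draw_run()
            state[i] = cur_state
            frames_left -= 1
            if cur_state == RUN:
                if backtrack_left == 0 and p_bt > 0 and rng.random() < p_bt:
                    backtrack_left = max(
                        int(round(rng.uniform(0.3, 1.2) * rate)), 2)
                if backtrack_left > 0:
                    velocity[i] = -config.backtrack_speed_cm_s
                    bt_marks[i] = True
                    backtrack_left -= 1
                else:
                    velocity[i] = speed[i]
            else:
                velocity[i] = 0.0
                backtrack_left = 0
        pos = max(pos + velocity[i] * dt, 0.0)
        if pos >= config.track_length_cm:
            # traversal complete: clamp this frame, then teleport to the start
            position[i] = config.track_length_cm
            pos = 0.0
            teleport_left = teleport_frames
        else:
            position[i] = pos
    backtrack_frames = np.flatnonzero(bt_marks)

    # shared motion-artifact component: slow noise plus velocity coupling
    slow = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma=0.5 * rate)
    vmod = gaussian_filter1d(np.abs(velocity), sigma=0.5 * rate)
    vmod = (vmod - vmod.mean()) / (vmod.std() + 1e-12)
    artifact = 0.7 * slow / (slow.std() + 1e-12) + 0.3 * vmod
    artifact /= artifact.std() + 1e-12

    truth = SyntheticGroundTruth(
        true_freeze_epochs=_runs_of(state == FREEZE),
        true_run_epochs=_runs_of(state == RUN),
        backtrack_frames=backtrack_frames,
        tuning=params["tuning"],
        artifact_trace=artifact,
        within_freeze_profile=WithinFreezeProfile(),
    )

    timeline = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": np.arange(n) * dt,
        "position_cm": position,
        "velocity_cm_s": velocity,
        "context": config.condition,
        "is_teleport": state == TELEPORT,
        "is_shock": is_shock,
    })
    return timeline, truth


# ---------------------------------------------------------------------------
# axonal fluorescence

def gcamp_kernel(frame_rate_hz: float, rise_s: float = 0.18,
                 decay_s: float = 1.6, length_s: float = 8.0) -> np.ndarray:
    """Double-exponential calcium-transient kernel, peak-normalized to 1."""
    t = np.arange(0.0, length_s, 1.0 / frame_rate_hz)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def _event_rate_per_frame(truth: SyntheticGroundTruth, n: int, rate: float,
                          rate_in_hz: float, rate_out_hz: float,
                          untuned_rate_hz: float) -> np.ndarray:
    """Per-frame transient rate (Hz) implied by the tuning condition."""
    if truth.tuning == "untuned":
        return np.full(n, untuned_rate_hz)
    lam = np.full(n, rate_out_hz)
    profile = truth.within_freeze_profile
    for start, end in truth.true_freeze_epochs:
        length = end - start
        progress = (np.arange(length) + 0.5) / length
        lam[start:end] = rate_in_hz * profile(progress)
    return lam


def generate_axon_traces(timeline: pd.DataFrame, truth: SyntheticGroundTruth,
                         n_rois: int = 3, noise_sd: float = 0.04,
                         artifact_gain: float = 0.15, seed: int = 0, *,
                         frame_rate_hz: float = 15.49,
                         rate_in_hz: float = 3.0, rate_out_hz: float = 0.05,
                         untuned_rate_hz: float = 0.15,
                         amp_mean: float = 0.35, amp_sigma: float = 0.35,
                         green_baseline: float = 100.0,
                         red_baseline: float = 80.0,
                         roi_sources: list[int] | None = None) -> RoiTraceSet:
    """Simulate green (activity + artifact) and red (artifact-only) traces.

    All ROIs assigned to the same source share one transient train (they are
    segments of one axon); ROI-specific Gaussian noise is added on top.
    Traces are in raw-fluorescence units: ``baseline * (1 + dff-like signal)``,
    so downstream Δf/f recovers the transient train.

    ``truth.transient_times`` is filled with the per-ROI event frames.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(timeline)
    if roi_sources is None:
        roi_sources = [0] * n_rois
    if len(roi_sources) != n_rois:
        raise ValueError("roi_sources must have one entry per ROI")

    lam = _event_rate_per_frame(truth, n, frame_rate_hz, rate_in_hz,
                                rate_out_hz, untuned_rate_hz)
    kernel = gcamp_kernel(frame_rate_hz)
    mu = np.log(amp_mean) - amp_sigma ** 2 / 2.0

    signals, events_by_source = {}, {}
    for src in sorted(set(roi_sources)):
        event_mask = rng.random(n) < lam / frame_rate_hz
        amps = np.zeros(n)
        amps[event_mask] = rng.lognormal(mu, amp_sigma, int(event_mask.sum()))
        signals[src] = np.convolve(amps, kernel)[:n]
        events_by_source[src] = np.flatnonzero(event_mask)

    artifact = truth.artifact_trace
    green = np.empty((n_rois, n))
    red = np.empty((n_rois, n))
    truth.transient_times = []
    for r, src in enumerate(roi_sources):
        g_noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        r_noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        green[r] = green_baseline * (
            1.0 + signals[src] + artifact_gain * artifact + g_noise)
        red[r] = red_baseline * (1.0 + artifact_gain * artifact + r_noise)
        truth.transient_times.append(events_by_source[src])

    return RoiTraceSet(green_raw=green, red_raw=red,
                       frame_rate_hz=frame_rate_hz)


# ---------------------------------------------------------------------------
# pupil

def generate_pupil(timeline: pd.DataFrame, blink_rate_hz: float = 0.05,
                   seed: int = 0, *, frame_rate_hz: float = 15.49
                   ) -> tuple[PupilRaw, np.ndarray]:
    """Smooth latent pupil signals with injected blink frames.

    Returns the raw pupil record and the injected blink-frame indices.
    Blink frames drop ``blink_area`` to zero (well below mean - 2 SD of the
    resulting blink-area series) and corrupt the pupil channels, emulating
    lid closure.
    """
    if blink_rate_hz < 0:
        raise ValueError("blink_rate_hz must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(timeline)
    smooth = lambda sd, sigma_s: gaussian_filter1d(  # noqa: E731
        rng.normal(0.0, sd, n), sigma=sigma_s * frame_rate_hz)
    area = 50.0 + smooth(8.0, 2.0)
    x = smooth(4.0, 1.0)
    y = smooth(4.0, 1.0)
    # bounded (uniform) noise keeps the no-blink baseline within 2 SD of its
    # mean, so the removal rule fires only on injected blinks
    blink_area = 10.0 + rng.uniform(-1.5, 1.5, n)

    blink_frames: list[int] = []
    n_blinks = rng.poisson(blink_rate_hz * n / frame_rate_hz)
    for _ in range(n_blinks):
        start = int(rng.integers(0, n))
        length = int(rng.integers(2, 5))
        for i in range(start, min(start + length, n)):
            blink_frames.append(i)
    blink_frames = np.unique(np.array(blink_frames, dtype=int))
    if blink_frames.size:
        blink_area[blink_frames] = 0.0
        area[blink_frames] = 2.0   # lid occludes the pupil
        x[blink_frames] += rng.normal(0.0, 5.0, blink_frames.size)
        y[blink_frames] += rng.normal(0.0, 5.0, blink_frames.size)

    return PupilRaw(area=area, x_pos=x, y_pos=y, blink_area=blink_area), blink_frames


# ---------------------------------------------------------------------------
# session bundles (delimited text + JSON sidecar)

def write_bundle(out_dir, timeline: pd.DataFrame, truth: SyntheticGroundTruth,
                 traces: RoiTraceSet, pupil: PupilRaw) -> None:
    """Write one session to ``out_dir`` as CSV tables plus a truth sidecar."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timeline.to_csv(out / "behavior.csv", index=False)

    cols = {}
    for r in range(traces.green_raw.shape[0]):
        cols[f"green_roi_{r}"] = traces.green_raw[r]
        cols[f"red_roi_{r}"] = traces.red_raw[r]
    pd.DataFrame(cols).to_csv(out / "traces.csv", index=False)
    pd.DataFrame({"area": pupil.area, "x_pos": pupil.x_pos,
                  "y_pos": pupil.y_pos, "blink_area": pupil.blink_area
                  }).to_csv(out / "pupil.csv", index=False)

    sidecar = {
        "true_freeze_epochs": [list(e) for e in truth.true_freeze_epochs],
        "true_run_epochs": [list(e) for e in truth.true_run_epochs],
        "backtrack_frames": truth.backtrack_frames.tolist(),
        "tuning": truth.tuning,
        "artifact_trace": truth.artifact_trace.tolist(),
        "within_freeze_profile": asdict(truth.within_freeze_profile),
        "transient_times": [t.tolist() for t in truth.transient_times],
        "blink_frames": (truth.blink_frames.tolist()
                         if truth.blink_frames is not None else None),
        "frame_rate_hz": traces.frame_rate_hz,
    }
    (out / "truth.json").write_text(json.dumps(sidecar))


def read_bundle(in_dir):
    """Read a session bundle written by :func:`write_bundle`."""
    from pathlib import Path
    src = Path(in_dir)
    timeline = pd.read_csv(src / "behavior.csv")
    tr = pd.read_csv(src / "traces.csv")
    n_rois = sum(c.startswith("green_roi_") for c in tr.columns)
    side = json.loads((src / "truth.json").read_text())
    traces = RoiTraceSet(
        green_raw=np.stack([tr[f"green_roi_{r}"].to_numpy()
                            for r in range(n_rois)]),
        red_raw=np.stack([tr[f"red_roi_{r}"].to_numpy()
                          for r in range(n_rois)]),
        frame_rate_hz=side["frame_rate_hz"])
    pp = pd.read_csv(src / "pupil.csv")
    pupil = PupilRaw(area=pp["area"].to_numpy(), x_pos=pp["x_pos"].to_numpy(),
                     y_pos=pp["y_pos"].to_numpy(),
                     blink_area=pp["blink_area"].to_numpy())
    truth = SyntheticGroundTruth(
        true_freeze_epochs=[tuple(e) for e in side["true_freeze_epochs"]],
        true_run_epochs=[tuple(e) for e in side["true_run_epochs"]],
        backtrack_frames=np.array(side["backtrack_frames"], dtype=int),
        tuning=side["tuning"],
        artifact_trace=np.array(side["artifact_trace"]),
        within_freeze_profile=WithinFreezeProfile(**side["within_freeze_profile"]),
        transient_times=[np.array(t, dtype=int) for t in side["transient_times"]],
        blink_frames=(np.array(side["blink_frames"], dtype=int)
                      if side["blink_frames"] is not None else None))
    return timeline, truth, traces, pupil
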