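"""Freeze-vs-run tuning of axonal activity.

State-conditioned peak statistics, length-binned freeze→run transition
alignment, within-epoch progress profiles, and robust (Huber / MAD-scaled)
fits of peak amplitude against epoch length or progress.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behavior import EpochLabeling, FREEZE, RUN
from .traces import PeakSet

log = logging.getLogger(__name__)

DEFAULT_LENGTH_BINS_S = [(1.0, 2.0), (2.0, 3.0), (3.0, 4.0),
                         (4.0, 5.0), (5.0, 6.0), (6.0, 7.0)]


@dataclass
class StateActivitySummary:
    mean_norm_peak_freeze: float       # NaN when no freeze epoch has a peak
    mean_norm_peak_run: float
    per_epoch_means: pd.DataFrame      # epoch_id, state, mean_peak, n_peaks


@dataclass
class TransitionAlignment:
    length_bin: tuple[float, float] | None
    aligned_matrix: np.ndarray         # epochs x offset frames
    offsets_s: np.ndarray
    transition_col: int                # column index of the freeze->run frame
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


@dataclass
class ProgressProfile:
    bin_means: np.ndarray              # length n_bins
    epoch_state: str
    n_epochs: int


@dataclass
class RobustFitResult:
    coefficients: np.ndarray           # intercept, slope[, quadratic]
    scale: float                       # standardized-MAD residual scale
    r2: float
    q: float                           # Huber objective sum rho(e_i / s)
    n_iter: int
    converged: bool


def peaks_to_epochs(peaks: PeakSet, labeling: EpochLabeling) -> pd.DataFrame:
    """Assign each peak to the epoch containing its frame (epoch_id 0 =
    outside any epoch)."""
    eid = labeling.epoch_id[peaks.frames]
    state = labeling.state[peaks.frames]
    return pd.DataFrame({"frame": peaks.frames, "height": peaks.heights,
                         "epoch_id": eid, "state": state})


def state_peak_means(peaks: PeakSet, labeling: EpochLabeling
                     ) -> StateActivitySummary:
    """Mean normalized peak Δf/f per epoch, then per state across epochs.

    Only epochs containing at least one peak contribute; a state with no
    peak-bearing epochs gets a NaN mean (flagged undefined, not zero).
    """
    assigned = peaks_to_epochs(peaks, labeling)
    assigned = assigned[assigned.epoch_id > 0]
    per_epoch = (assigned.groupby(["epoch_id", "state"])["height"]
                 .agg(mean_peak="mean", n_peaks="size").reset_index())

    def state_mean(state: str) -> float:
        vals = per_epoch.loc[per_epoch.state == state, "mean_peak"]
        return float(vals.mean()) if len(vals) else float("nan")

    return StateActivitySummary(mean_norm_peak_freeze=state_mean(FREEZE),
                                mean_norm_peak_run=state_mean(RUN),
                                per_epoch_means=per_epoch)


def declares_freeze_tuning(peaks: PeakSet, labeling: EpochLabeling,
                           alpha: float = 0.05) -> bool:
    """Declare an axon freeze-tuned when per-epoch mean peak heights are
    significantly higher in freezing than in running epochs (one-sided
    Welch t-test at ``alpha``)."""
    from scipy import stats

    per_epoch = state_peak_means(peaks, labeling).per_epoch_means
    f = per_epoch.loc[per_epoch.state == FREEZE, "mean_peak"]
    r = per_epoch.loc[per_epoch.state == RUN, "mean_peak"]
    if len(f) < 2 or len(r) < 2:
        return False
    res = stats.ttest_ind(f, r, equal_var=False, alternative="greater")
    return bool(res.pvalue < alpha)


def bin_epochs_by_length(labeling: EpochLabeling,
                         bins_s: list[tuple[float, float]] | None = None,
                         state: str = FREEZE) -> dict[tuple[float, float], pd.DataFrame]:
    """Group epochs into half-open duration bins; epochs longer than the
    last bin edge (default 7 s) are excluded."""
    bins_s = bins_s if bins_s is not None else DEFAULT_LENGTH_BINS_S
    epochs = labeling.epochs(state)
    out = {}
    for lo, hi in bins_s:
        sel = epochs[(epochs.duration_s >= lo) & (epochs.duration_s < hi)]
        out[(lo, hi)] = sel.reset_index(drop=True)
    return out


def align_to_transition(norm_dff: np.ndarray, epochs: pd.DataFrame,
                        labeling: EpochLabeling, pre_window_s: float,
                        post_window_s: float = 2.0,
                        length_bin: tuple[float, float] | None = None
                        ) -> TransitionAlignment:
    """Align activity snippets to each epoch's freeze→run transition.

    The transition is the epoch's end frame (first frame of the following
    run epoch); only epochs immediately followed by a run epoch are used.
    Snippets exceeding the session bounds are dropped with a log record.
    """
    trace = np.asarray(norm_dff, dtype=float)
    rate = labeling.frame_rate_hz
    pre = int(round(pre_window_s * rate))
    post = int(round(post_window_s * rate))
    rows = []
    for row in epochs.itertuples():
        t = int(row.end_frame)
        if t >= len(labeling.state) or labeling.state[t] != RUN:
            continue
        if t - pre < 0 or t + post > len(trace):
            log.info("dropping epoch ending at frame %d: window out of bounds", t)
            continue
        rows.append(trace[t - pre:t + post])
    mat = np.vstack(rows) if rows else np.empty((0, pre + post))
    mean = mat.mean(axis=0) if len(mat) else np.full(pre + post, np.nan)
    sem = (mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
           if len(mat) > 1 else np.zeros(pre + post))
    return TransitionAlignment(length_bin=length_bin, aligned_matrix=mat,
                               offsets_s=np.arange(-pre, post) / rate,
                               transition_col=pre, mean=mean,
                               ci_low=mean - 1.96 * sem,
                               ci_high=mean + 1.96 * sem)


def progress_profile(peaks: PeakSet, labeling: EpochLabeling,
                     n_bins: int = 5, state: str = FREEZE,
                     zero_fill: bool = True) -> ProgressProfile:
    """Mean normalized peak Δf/f in even progress bins across epochs.

    Each epoch (>= ``n_bins`` frames) is divided into ``n_bins`` even bins by
    fractional position; each bin's within-epoch mean peak height is taken,
    then averaged across epochs.  With ``zero_fill`` (default) a bin with no
    peak contributes 0 — peaks carry the activity, absence is baseline;
    otherwise empty bins are skipped.
    """
    epochs = labeling.epochs(state)
    assigned = peaks_to_epochs(peaks, labeling)
    per_epoch_bins = []
    for row in epochs.itertuples():
        length = row.end_frame - row.start_frame
        if length < n_bins:
            log.info("skipping %s epoch %d: shorter than %d frames",
                     state, row.epoch_id, n_bins)
            continue
        in_epoch = assigned[assigned.epoch_id == row.epoch_id]
        progress = (in_epoch.frame - row.start_frame) / length
        bin_idx = np.minimum((progress * n_bins).astype(int), n_bins - 1)
        means = np.full(n_bins, 0.0 if zero_fill else np.nan)
        for b in range(n_bins):
            h = in_epoch.height[bin_idx == b]
            if len(h):
                means[b] = float(h.mean())
        per_epoch_bins.append(means)
    if per_epoch_bins:
        stack = np.vstack(per_epoch_bins)
        bin_means = (stack.mean(axis=0) if zero_fill
                     else np.nanmean(stack, axis=0))
    else:
        bin_means = np.full(n_bins, np.nan)
    return ProgressProfile(bin_means=bin_means, epoch_state=state,
                           n_epochs=len(per_epoch_bins))


def robust_fit(x: np.ndarray, y: np.ndarray, degree: int = 1,
               tol: float = 1e-8, maxiter: int = 50) -> RobustFitResult:
    """Huber M-estimate of a polynomial fit via IRLS.

    Residual scale is the standardized median absolute deviation; iteration
    runs to coefficient convergence.  With no outliers the Huber estimate
    coincides with ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    X = np.vander(x, degree + 1, increasing=True)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT())
    res = model.fit(conv="coefs", tol=tol, maxiter=maxiter,
                    scale_est="mad", update_scale=True)
    fitted = X @ res.params
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    scale = float(res.scale)
    rho = sm.robust.norms.HuberT().rho(resid / scale) if scale > 0 else resid * np.nan
    n_iter = len(res.fit_history["params"])
    converged = n_iter < maxiter
    if not converged:
        raise RuntimeError(
            f"robust fit did not converge in {maxiter} iterations; "
            f"coefficient trace: {res.fit_history['params']}")
    return RobustFitResult(coefficients=np.asarray(res.params), scale=scale,
                           r2=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
                           q=float(np.sum(rho)), n_iter=n_iter,
                           converged=converged)


def robust_fit_peak_vs_length(max_peak_per_freeze: np.ndarray,
                              lengths_s: np.ndarray,
                              degree: int = 1) -> RobustFitResult:
    """Robust fit of per-freeze maximum peak height against freeze length."""
    return robust_fit(np.asarray(lengths_s, dtype=float),
                      np.asarray(max_peak_per_freeze, dtype=float), degree)


def max_peak_vs_progress(peaks: PeakSet, labeling: EpochLabeling,
                         state: str = FREEZE
                         ) -> tuple[pd.DataFrame, RobustFitResult | None]:
    """Per-epoch (progress of tallest peak, height) pairs plus a robust
    linear fit of height against progress (None with < 3 epochs)."""
    assigned = peaks_to_epochs(peaks, labeling)
    epochs = labeling.epochs(state)
    rows = []
    for row in epochs.itertuples():
        in_epoch = assigned[assigned.epoch_id == row.epoch_id]
        if not len(in_epoch):
            continue
        best = in_epoch.loc[in_epoch.height.idxmax()]
        length = row.end_frame - row.start_frame
        rows.append((row.epoch_id,
                     float((best.frame - row.start_frame) / max(length - 1, 1)),
                     float(best.height)))
    pairs = pd.DataFrame(rows, columns=["epoch_id", "progress", "height"])
    fit = (robust_fit(pairs.progress.to_numpy(), pairs.height.to_numpy())
           if len(pairs) >= 3 else None)
    return pairs, fit
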