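"""Two-channel ROI trace processing.

Pipeline for converting raw green (activity) / red (structural) fluorescence
into artifact-corrected, baseline-normalized Δf/f with detected peaks:

1. Savitzky-Golay smooth both channels.
2. Demean and orthogonalize: subtract the red channel's projection
   Cov(g, r) / Cov(r, r) * r from the green channel, leaving a trace with
   exactly zero sample covariance with the red channel (removes shared
   motion artifacts).
3. Δf/f against a rolling low-percentile baseline.
4. Merge ROIs whose pairwise covariance exceeds the 99th percentile of a
   circular-shift shuffle null (segments of one axon), replacing each merged
   group with its first principal component.
5. Rescale per day to the 99th percentile of activity and detect peaks
   (height >= 0.1, prominence >= 0.1, separation >= 0.5 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks, savgol_filter
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Detected transient peaks on a normalized Δf/f trace."""

    frames: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)


def smooth_channel(trace: np.ndarray, window: int = 9,
                   polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (window in frames, must exceed the order)."""
    return savgol_filter(np.asarray(trace, dtype=float), window, polyorder)


def orthogonalize(green: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Project the red channel out of the green channel in variance space.

    Both inputs are demeaned; the output is
    ``g - Cov(g, r) / Cov(r, r) * r``, which has zero sample covariance with
    the red channel.  A constant red channel makes the projection degenerate;
    the demeaned green channel is returned unchanged with a warning.
    """
    g = np.asarray(green, dtype=float)
    r = np.asarray(red, dtype=float)
    if g.shape != r.shape:
        raise ValueError("green and red traces must have equal length")
    g = g - g.mean()
    r = r - r.mean()
    var_r = float(r @ r)
    if var_r <= 1e-12 * len(r):
        log.warning("red channel has (near-)zero variance; skipping projection")
        return g
    return g - (float(g @ r) / var_r) * r


def correct_channels(green_raw: np.ndarray, red_raw: np.ndarray,
                     window: int = 9, polyorder: int = 3) -> np.ndarray:
    """Smooth, demean, orthogonalize; restore the green mean so a Δf/f
    baseline can still be computed on the corrected trace."""
    g = smooth_channel(green_raw, window, polyorder)
    r = smooth_channel(red_raw, window, polyorder)
    return orthogonalize(g, r) + g.mean()


def compute_dff(raw: np.ndarray, frame_rate: float, window_s: float = 30.0,
                baseline_percentile: float = 8.0) -> np.ndarray:
    """Δf/f = (f - F0) / F0 with F0 a rolling low-percentile baseline.

    The baseline window is ``window_s`` seconds; a non-positive F0 anywhere
    signals corrupt input scaling and raises.
    """
    f = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("trace contains non-finite values")
    size = max(int(round(window_s * frame_rate)), 1)
    f0 = percentile_filter(f, baseline_percentile, size=size, mode="nearest")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; input scaling looks corrupt")
    return (f - f0) / f0


def normalize_per_day(dff: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Rescale so the day's ``percentile``-th Δf/f value maps to 1.

    Values above 1 are permitted; invariant under positive rescaling of the
    raw fluorescence.
    """
    d = np.asarray(dff, dtype=float)
    p = float(np.percentile(d, percentile))
    if p <= 0:
        raise ValueError("normalization percentile of Δf/f is <= 0")
    return d / p


def detect_peaks(norm_dff: np.ndarray, frame_rate: float,
                 min_height: float = 0.1, min_distance_s: float = 0.5,
                 min_prominence: float = 0.1) -> PeakSet:
    """Peaks with height >= 0.1, prominence >= 0.1, separation >= 0.5 s.

    Where the separation constraint conflicts, the taller peak wins.
    """
    trace = np.asarray(norm_dff, dtype=float)
    distance = max(int(round(min_distance_s * frame_rate)), 1)
    frames, props = find_peaks(trace, height=min_height, distance=distance,
                               prominence=min_prominence)
    return PeakSet(frames=frames, heights=props["peak_heights"],
                   prominences=props["prominences"])


def activity_criterion(peaks: PeakSet, min_peaks: int = 2,
                       min_height: float = 0.1) -> bool:
    """Session-inclusion rule: at least two peaks reaching 0.1 Δf/f."""
    return int(np.sum(peaks.heights >= min_height)) >= min_peaks


# ---------------------------------------------------------------------------
# ROI merging

def _pairwise_cov(traces: np.ndarray) -> np.ndarray:
    x = traces - traces.mean(axis=1, keepdims=True)
    return x @ x.T / (traces.shape[1] - 1)


def merge_correlated_rois(dff: np.ndarray, frame_rate: float,
                          n_shuffles: int = 500, percentile: float = 99.0,
                          min_shift_s: float = 1.0,
                          seed: int | np.random.Generator = 0
                          ) -> tuple[list[list[int]], np.ndarray]:
    """Merge ROIs with above-chance pairwise covariance.

    The null distribution comes from circularly time-shifting each ROI by a
    random offset (>= ``min_shift_s`` from zero, preserving autocorrelation)
    ``n_shuffles`` times.  ROI pairs whose observed covariance exceeds the
    ``percentile``-th percentile of their own null are linked; connected
    components form merge groups.  Each multi-ROI group is replaced by the
    first principal component of its members, sign-aligned so the mean
    loading is positive and rescaled to the members' mean variance (and mean
    offset), so merged traces stay on the Δf/f scale.

    Returns ``(groups, merged)`` where ``groups`` partitions ROI indices and
    ``merged`` has one trace per group.
    """
    x = np.atleast_2d(np.asarray(dff, dtype=float))
    n_rois, n = x.shape
    if n_rois == 1:
        return [[0]], x.copy()
    if n_shuffles < 100:
        log.warning("n_shuffles=%d gives a coarse shuffle null", n_shuffles)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    obs = _pairwise_cov(x)
    min_shift = max(int(round(min_shift_s * frame_rate)), 1)
    null = np.empty((n_shuffles, n_rois, n_rois))
    centered = x - x.mean(axis=1, keepdims=True)
    for s in range(n_shuffles):
        shifts = rng.integers(min_shift, n - min_shift, size=n_rois)
        rolled = np.empty_like(centered)
        for r in range(n_rois):
            rolled[r] = np.roll(centered[r], int(shifts[r]))
        null[s] = rolled @ rolled.T / (n - 1)
    thresh = np.percentile(null, percentile, axis=0)

    # union-find over significant pairs
    parent = list(range(n_rois))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_rois):
        for j in range(i + 1, n_rois):
            if obs[i, j] > thresh[i, j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n_rois):
        groups.setdefault(find(i), []).append(i)
    group_list = sorted(groups.values(), key=lambda g: g[0])

    merged = np.empty((len(group_list), n))
    for k, members in enumerate(group_list):
        if len(members) == 1:
            merged[k] = x[members[0]]
            continue
        sub = x[members]                       # (m, n)
        pca = PCA(n_components=1)
        scores = pca.fit_transform(sub.T)[:, 0]
        if pca.components_[0].mean() < 0:      # PC sign is arbitrary
            scores = -scores
        target_sd = float(np.sqrt(sub.var(axis=1, ddof=1).mean()))
        scores *= target_sd / (scores.std(ddof=1) + 1e-12)
        merged[k] = scores + sub.mean()
    return group_list, merged
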