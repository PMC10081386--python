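"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the implementation's code paths: plain python
scans and greedy enumeration only.
"""

import numpy as np


def scan_maximal_runs(values, predicate, min_len):
    """Enumerate maximal runs of frames satisfying ``predicate`` by a plain
    left-to-right scan; return half-open (start, end) pairs of runs with at
    least ``min_len`` frames."""
    runs, start = [], None
    for i, v in enumerate(values):
        if predicate(v):
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(values) - start >= min_len:
        runs.append((start, len(values)))
    return runs


def freeze_epochs_bruteforce(velocity, thresh=0.001, min_frames=12):
    return scan_maximal_runs(velocity, lambda v: abs(v) < thresh, min_frames)


def run_epochs_bruteforce(velocity, thresh=0.001, min_frames=2):
    return scan_maximal_runs(velocity, lambda v: v > thresh, min_frames)


def _prominence(trace, peak):
    """Topographic prominence of a strict local maximum, by definition."""
    h = trace[peak]
    left_min = h
    for i in range(peak - 1, -1, -1):
        if trace[i] > h:
            break
        left_min = min(left_min, trace[i])
    right_min = h
    for i in range(peak + 1, len(trace)):
        if trace[i] > h:
            break
        right_min = min(right_min, trace[i])
    return h - max(left_min, right_min)


def peaks_bruteforce(trace, min_height=0.1, min_distance=8, min_prominence=0.1):
    """Admissible peak set by greedy enumeration.

    Strict local maxima passing the height floor are ranked by height
    (earlier wins ties); the minimum-distance constraint is enforced
    greedily from the tallest down; survivors are filtered by prominence.
    """
    trace = np.asarray(trace, dtype=float)
    candidates = [i for i in range(1, len(trace) - 1)
                  if trace[i - 1] < trace[i] > trace[i + 1]
                  and trace[i] >= min_height]
    order = sorted(candidates, key=lambda i: (-trace[i], i))
    kept = []
    removed = set()
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in candidates:
            if j != i and abs(j - i) < min_distance:
                removed.add(j)
    return sorted(i for i in kept if _prominence(trace, i) >= min_prominence)
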