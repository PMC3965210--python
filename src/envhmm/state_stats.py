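"""Temporal summary statistics of hard state paths.

All statistics treat the (virtual) sample before each segment as "no
state", so a run that starts a subject block counts as an entry into its
state.  Durations are converted to seconds with the path's sampling rate.

Definitions (per state k, path u of length T samples):

* fractional occupancy: (1/T) sum_t (u_t == k)
* number of occurrences: count of entries into k
* mean life time: dwell samples / occurrences
* mean interval length: (T - dwell samples) / occurrences

The interval formula divides the total time *not* in the state by the
number of visits; the literal mean gap between consecutive visits is the
separately named :func:`mean_gap_length`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import StatePath
from .windows import window_params, windowed_mean

__all__ = [
    "number_of_occurrences",
    "fractional_occupancy",
    "mean_life_time",
    "mean_interval_length",
    "mean_gap_length",
    "summary_table",
    "FOTimeCourse",
    "fo_timecourse",
    "fo_correlation_matrix",
    "transition_probability_matrix",
]


def _check_state(path: StatePath, k: int):
    if not 0 <= k < path.n_states:
        raise ValueError(f"state {k} outside 0..{path.n_states - 1}")


def _entries(path: StatePath, k: int) -> int:
    on = path.states == k
    prev = np.empty_like(on)
    prev[0] = False
    prev[1:] = on[:-1]
    starts = np.concatenate([[0], path.segment_boundaries[:-1]])
    prev[starts] = False  # sample before a segment start is "not k"
    return int(np.sum(on & ~prev))


def number_of_occurrences(path: StatePath, k: int) -> int:
    """Number of entries into state k (segment-initial runs count)."""
    _check_state(path, k)
    return _entries(path, k)


def fractional_occupancy(path: StatePath) -> np.ndarray:
    """Fraction of samples spent in each state; sums to 1."""
    return np.bincount(path.states, minlength=path.n_states) / path.n_samples


def mean_life_time(path: StatePath, k: int) -> float:
    """Average visit duration in seconds; NaN if the state never occurs."""
    _check_state(path, k)
    occ = _entries(path, k)
    if occ == 0:
        return float("nan")
    dwell = int(np.sum(path.states == k))
    return dwell / occ / path.sampling_rate


def mean_interval_length(path: StatePath, k: int) -> float:
    """(T - dwell samples) / occurrences, in seconds; NaN if never visited."""
    _check_state(path, k)
    occ = _entries(path, k)
    if occ == 0:
        return float("nan")
    dwell = int(np.sum(path.states == k))
    return (path.n_samples - dwell) / occ / path.sampling_rate


def mean_gap_length(path: StatePath, k: int) -> float:
    """Literal mean gap (s) between consecutive visits, within segments.

    NaN when the state is visited fewer than twice in every segment.
    """
    _check_state(path, k)
    gaps = []
    for start, stop in path.segments():
        on = path.states[start:stop] == k
        idx = np.flatnonzero(on)
        if idx.size == 0:
            continue
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for a, b in zip(runs[:-1], runs[1:]):
            gaps.append(b[0] - a[-1] - 1)
    if not gaps:
        return float("nan")
    return float(np.mean(gaps)) / path.sampling_rate


def summary_table(path: StatePath) -> pd.DataFrame:
    """Tidy per-state table of the four summary statistics."""
    fo = fractional_occupancy(path)
    rows = []
    for k in range(path.n_states):
        rows.append(
            {
                "state": k,
                "fractional_occupancy": fo[k],
                "mean_life_time_s": mean_life_time(path, k),
                "mean_interval_length_s": mean_interval_length(path, k),
                "number_of_occurrences": number_of_occurrences(path, k),
            }
        )
    return pd.DataFrame(rows)


class FOTimeCourse:
    """Within-window fractional occupancies (windows x K; rows sum to 1)."""

    def __init__(self, occupancies: np.ndarray, window_s: float, overlap_fraction: float,
                 sampling_rate: float, step_samples: int, width_samples: int):
        self.occupancies = occupancies
        self.window_s = window_s
        self.overlap_fraction = overlap_fraction
        self.sampling_rate = sampling_rate
        self.step_samples = step_samples
        self.width_samples = width_samples

    @property
    def n_windows(self) -> int:
        return self.occupancies.shape[0]


def fo_timecourse(path: StatePath, window_s: float = 10.0, overlap_fraction: float = 0.75) -> FOTimeCourse:
    """Fractional occupancy of each state within sliding windows.

    Default 10-s windows with 75% overlap.  Trailing partial windows are
    dropped.
    """
    width, step = window_params(path.sampling_rate, window_s, overlap_fraction)
    ind = path.indicators().T  # (K, T)
    occ = windowed_mean(ind, width, step).T  # (windows, K)
    return FOTimeCourse(occ, window_s, overlap_fraction, path.sampling_rate, step, width)


def fo_correlation_matrix(fo_tc: FOTimeCourse) -> np.ndarray:
    """Pearson correlation between the per-state occupancy time courses."""
    return np.corrcoef(fo_tc.occupancies, rowvar=False)


def transition_probability_matrix(model_or_path, mask_diagonal: bool = False) -> np.ndarray:
    """K x K transition probabilities.

    From an :class:`~envhmm.hmm.HMMModel`: the posterior expected transition
    matrix.  From a :class:`StatePath`: empirical within-segment transition
    frequencies (rows of states that are never left are NaN).  With
    ``mask_diagonal`` the diagonal is set to NaN without renormalizing.
    """
    if isinstance(model_or_path, StatePath):
        path = model_or_path
        K = path.n_states
        counts = np.zeros((K, K))
        for start, stop in path.segments():
            seg = path.states[start:stop]
            np.add.at(counts, (seg[:-1], seg[1:]), 1.0)
        rows = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            A = counts / rows
    else:
        A = model_or_path.expected_transition_matrix()
    if mask_diagonal:
        A = A.copy()
        np.fill_diagonal(A, np.nan)
    return A
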