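"""Sliding-window primitives shared by every windowed operation.

All windowed quantities in the package (envelope downsampling, fractional-
occupancy time courses, sliding-window correlations, the window-width sweep)
are built on the same two functions so that their window boundaries are
identical by construction: windows start at ``j * step`` and cover
``width`` samples; trailing windows that would run past the end of the
series are dropped.
"""

from __future__ import annotations

import numpy as np

__all__ = ["window_params", "window_starts", "windowed_mean", "windowed_correlation"]


def window_params(sampling_rate: float, window_s: float, overlap_fraction: float) -> tuple[int, int]:
    """Convert a window length (s) and overlap fraction into (width, step) in samples."""
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    width = int(round(window_s * sampling_rate))
    if width < 1:
        raise ValueError(
            f"window of {window_s} s is shorter than one sample at {sampling_rate} Hz"
        )
    step = int(round(width * (1.0 - overlap_fraction)))
    if step < 1:
        raise ValueError("window step is shorter than one sample; reduce the overlap")
    return width, step


def window_starts(n_samples: int, width: int, step: int) -> np.ndarray:
    """Start indices of all complete windows."""
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1 sample")
    if n_samples < width:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, n_samples - width + 1, step, dtype=np.int64)


def windowed_mean(x: np.ndarray, width: int, step: int) -> np.ndarray:
    """Mean of ``x`` within each complete window, along the last axis.

    Uses a cumulative sum, so the cost is independent of the window width.
    """
    x = np.asarray(x, dtype=np.float64)
    starts = window_starts(x.shape[-1], width, step)
    c = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    return (c[..., starts + width] - c[..., starts]) / width


def windowed_correlation(a: np.ndarray, b: np.ndarray, width: int, step: int) -> np.ndarray:
    """Pearson correlation of two equal-length series within each window.

    Windows in which either series is constant yield NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    # centering globally improves the conditioning of the cumulative sums
    # and leaves every window's correlation unchanged
    a = a - a.mean()
    b = b - b.mean()
    ma = windowed_mean(a, width, step)
    mb = windowed_mean(b, width, step)
    maa = windowed_mean(a * a, width, step)
    mbb = windowed_mean(b * b, width, step)
    mab = windowed_mean(a * b, width, step)
    va = maa - ma**2
    vb = mbb - mb**2
    cov = mab - ma * mb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(va * vb)
    r[(va <= 0) | (vb <= 0)] = np.nan
    return r
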