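"""Timescale analyses of state dynamics.

Two questions about the discovered states' temporal scale are answered
here.  First, over what window width does a state's fractional occupancy
best predict the envelope at its most-correlated voxel?  Fast-switching
states peak at sub-second windows; if the envelopes are first low-passed
below 0.5 Hz the peak moves to windows around a second, confirming that
the short widths reflect genuine fast dynamics rather than an analysis
artifact.  Second, how does sliding-window envelope correlation between
two regions relate to the fraction of each window spent in a state that
couples them?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EnvelopeDataset, StatePath
from .envelope import lowpass
from .spatial_maps import PartialCorrelationMap
from .windows import window_params, windowed_correlation, windowed_mean

__all__ = [
    "WindowSweepResult",
    "representative_voxel",
    "fo_window_sweep",
    "default_sweep_widths",
    "lowpass_envelopes",
    "add_bandlimited_noise",
    "sliding_envelope_correlation",
    "compare_fo_envcorr",
]


@dataclass
class WindowSweepResult:
    """Correlation between width-specific FO regressors and an envelope."""

    widths_s: np.ndarray
    correlations: np.ndarray

    @property
    def argmax_width_s(self) -> float:
        return float(self.widths_s[np.nanargmax(self.correlations)])


def representative_voxel(pmap: PartialCorrelationMap, k: int) -> int:
    """Voxel with the largest partial correlation for state k (ties -> lowest)."""
    row = pmap.coefficients[k]
    if np.all(np.isnan(row)):
        raise ValueError(f"state {k} has no defined coefficients")
    return int(np.nanargmax(row))


def default_sweep_widths(min_s: float = 0.1, max_s: float = 8.0, n: int = 20) -> np.ndarray:
    """Logarithmic grid of window widths (s)."""
    return np.geomspace(min_s, max_s, n)


def fo_window_sweep(path: StatePath, k: int, envelope_voxel_ts, widths_s=None) -> WindowSweepResult:
    """Correlation of a state's windowed occupancy with a voxel envelope.

    For each width the state-k indicator is averaged in sliding windows
    with a step of one sample, so the regressor shares the envelope's time
    base; the envelope sample at each window's center is the regressand.
    Both are z-scored and the Pearson correlation recorded.
    """
    env = np.asarray(envelope_voxel_ts, dtype=np.float64)
    if env.size != path.n_samples:
        raise ValueError("envelope and path must have equal length")
    widths_s = default_sweep_widths() if widths_s is None else np.asarray(widths_s, float)
    if np.any(np.diff(widths_s) <= 0):
        raise ValueError("widths must be strictly increasing")
    if widths_s[-1] > path.n_samples / path.sampling_rate:
        raise ValueError("largest width exceeds the recording length")
    ind = (path.states == k).astype(np.float64)
    corrs = np.empty(widths_s.size)
    for i, w_s in enumerate(widths_s):
        width = int(round(w_s * path.sampling_rate))
        if width < 1:
            raise ValueError(f"width {w_s} s is shorter than one sample")
        reg = windowed_mean(ind, width, 1)
        target = env[(width - 1) // 2 : (width - 1) // 2 + reg.size]
        if reg.std() == 0 or target.std() == 0:
            corrs[i] = np.nan
            continue
        corrs[i] = np.corrcoef(reg, target)[0, 1]
    return WindowSweepResult(widths_s=widths_s, correlations=corrs)


def lowpass_envelopes(dataset: EnvelopeDataset, cutoff_hz: float) -> EnvelopeDataset:
    """Zero-phase low-pass of every voxel's envelope."""
    return EnvelopeDataset(
        lowpass(dataset.data, dataset.sampling_rate, cutoff_hz),
        dataset.sampling_rate,
        voxel_coords=dataset.voxel_coords,
        segment_boundaries=dataset.segment_boundaries,
    )


def add_bandlimited_noise(dataset: EnvelopeDataset, cutoff_hz: float, noise_sd: float, seed) -> EnvelopeDataset:
    """Add seeded Gaussian noise low-passed at ``cutoff_hz``.

    The noise is rescaled per voxel *after* filtering so its standard
    deviation is exactly ``noise_sd``; its spectral content mimics that of
    the envelopes themselves (non-independent neighboring samples).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return dataset
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(dataset.data.shape)
    noise = lowpass(noise, dataset.sampling_rate, cutoff_hz)
    noise *= noise_sd / noise.std(axis=1, keepdims=True)
    return EnvelopeDataset(
        dataset.data + noise,
        dataset.sampling_rate,
        voxel_coords=dataset.voxel_coords,
        segment_boundaries=dataset.segment_boundaries,
    )


def sliding_envelope_correlation(ts_a, ts_b, sampling_rate: float, window_s: float = 10.0,
                                 overlap_fraction: float = 0.75) -> np.ndarray:
    """Pearson correlation of two envelopes within sliding windows."""
    width, step = window_params(sampling_rate, window_s, overlap_fraction)
    return windowed_correlation(np.asarray(ts_a, float), np.asarray(ts_b, float), width, step)


def compare_fo_envcorr(fo_tc_for_state: np.ndarray, envcorr_tc: np.ndarray) -> float:
    """Correlation between window-level occupancy and envelope-correlation series.

    Both series must come from identical window and overlap settings.
    """
    a = np.asarray(fo_tc_for_state, dtype=np.float64)
    b = np.asarray(envcorr_tc, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("the two window-level series must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
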