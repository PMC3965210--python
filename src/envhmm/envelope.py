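"""Band-limited amplitude envelopes: filtering, Hilbert transform,
windowed downsampling, spatial smoothing, and group concatenation.

The canonical preparation order, matching the processing chain the HMM
expects, is: band-pass the sensor or source data (default 4-30 Hz), take
the magnitude of the Hilbert transform, average within sliding windows
(default 100 ms windows, 75% overlap: 200 Hz -> 40 Hz), smooth spatially
(default FWHM 9.4 mm), then demean each voxel per subject, divide by the
subject's global (pooled over voxels) standard deviation, and concatenate
subjects in time.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.signal

from .containers import EnvelopeDataset
from .windows import window_params, windowed_mean

__all__ = [
    "bandpass",
    "lowpass",
    "hilbert_envelope",
    "window_downsample",
    "spatial_smooth",
    "normalize_and_concatenate",
    "prepare_envelopes",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_FILTER_ORDER = 4  # Butterworth order; doubled in effect by filtfilt


def _check_band(edges, sampling_rate):
    nyq = sampling_rate / 2.0
    for e in edges:
        if not 0 < e < nyq:
            raise ValueError(
                f"band edge {e} Hz must lie strictly between 0 and Nyquist ({nyq} Hz)"
            )


def bandpass(ts, sampling_rate: float, low_hz: float, high_hz: float, order: int = DEFAULT_FILTER_ORDER):
    """Zero-phase Butterworth band-pass along the last axis."""
    if low_hz >= high_hz:
        raise ValueError("low_hz must be below high_hz")
    _check_band((low_hz, high_hz), sampling_rate)
    sos = scipy.signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos"
    )
    return scipy.signal.sosfiltfilt(sos, np.asarray(ts, dtype=np.float64), axis=-1)


def lowpass(ts, sampling_rate: float, cutoff_hz: float, order: int = DEFAULT_FILTER_ORDER):
    """Zero-phase Butterworth low-pass along the last axis."""
    _check_band((cutoff_hz,), sampling_rate)
    sos = scipy.signal.butter(order, cutoff_hz, btype="lowpass", fs=sampling_rate, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(ts, dtype=np.float64), axis=-1)


def hilbert_envelope(ts):
    """Pointwise magnitude of the analytic signal, along the last axis."""
    ts = np.asarray(ts, dtype=np.float64)
    if not np.all(np.isfinite(ts)):
        raise ValueError("input contains non-finite values")
    return np.abs(scipy.signal.hilbert(ts, axis=-1))


def window_downsample(envelope, sampling_rate: float, window_s: float = 0.1, overlap_fraction: float = 0.75):
    """Average within sliding windows, reducing the sampling rate.

    With the defaults (100 ms windows, 75% overlap) a 200 Hz envelope is
    reduced to 40 Hz.  Incomplete trailing windows are dropped.  Returns
    ``(downsampled, new_rate)``.
    """
    width, step = window_params(sampling_rate, window_s, overlap_fraction)
    out = windowed_mean(np.asarray(envelope, dtype=np.float64), width, step)
    return out, sampling_rate / step


def spatial_smooth(dataset: EnvelopeDataset, fwhm_mm: float) -> EnvelopeDataset:
    """Gaussian-weighted average over voxels, sigma = FWHM / (2 sqrt(2 ln 2)).

    Weights are normalized to sum to 1 for each target voxel, so a
    spatially uniform field is unchanged.  ``fwhm_mm = 0`` is the identity.
    """
    if dataset.voxel_coords is None:
        raise ValueError("spatial smoothing requires voxel coordinates")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return dataset
    sigma = fwhm_mm * FWHM_TO_SIGMA
    coords = dataset.voxel_coords
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    W = np.exp(-d2 / (2.0 * sigma**2))
    W /= W.sum(axis=1, keepdims=True)
    return EnvelopeDataset(
        W @ dataset.data,
        dataset.sampling_rate,
        voxel_coords=coords,
        segment_boundaries=dataset.segment_boundaries,
    )


def normalize_and_concatenate(datasets) -> EnvelopeDataset:
    """Demean each voxel and scale by the global SD, per subject, then concatenate.

    Each subject's block has every voxel demeaned, and all voxels divided
    by the square root of the subject's pooled (over all voxels) variance,
    so each block ends up with per-voxel mean 0 and pooled variance 1.
    Segment boundaries record the cumulative subject lengths.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    V = datasets[0].n_voxels
    rate = datasets[0].sampling_rate
    coords = datasets[0].voxel_coords
    blocks, lengths = [], []
    for ds in datasets:
        if ds.n_voxels != V or ds.sampling_rate != rate:
            raise ValueError("all subjects must share voxel count and sampling rate")
        X = ds.data - ds.data.mean(axis=1, keepdims=True)
        global_var = np.mean(X**2)
        if global_var <= 0:
            raise ValueError("subject block has zero global variance")
        blocks.append(X / np.sqrt(global_var))
        lengths.append(ds.n_samples)
    return EnvelopeDataset(
        np.concatenate(blocks, axis=1),
        rate,
        voxel_coords=coords,
        segment_boundaries=np.cumsum(lengths),
    )


def prepare_envelopes(
    subject_data,
    sampling_rate: float,
    low_hz: float = 4.0,
    high_hz: float = 30.0,
    window_s: float = 0.1,
    overlap_fraction: float = 0.75,
    fwhm_mm: float = 9.4,
    voxel_coords=None,
    already_bandlimited: bool = False,
) -> EnvelopeDataset:
    """Full envelope pipeline over per-subject (V, T) source time courses.

    Order: band-pass -> Hilbert envelope -> windowed downsampling ->
    spatial smoothing -> per-subject normalization -> concatenation.
    """
    logger.info(
        "envelope pipeline: bandpass %.3g-%.3g Hz -> hilbert -> downsample "
        "(%.3g s windows, %.0f%% overlap) -> smooth (FWHM %.3g mm) -> normalize/concatenate",
        low_hz, high_hz, window_s, overlap_fraction * 100, fwhm_mm,
    )
    prepared = []
    for X in subject_data:
        X = np.asarray(X, dtype=np.float64)
        if not already_bandlimited:
            X = bandpass(X, sampling_rate, low_hz, high_hz)
        env = hilbert_envelope(X)
        env, new_rate = window_downsample(env, sampling_rate, window_s, overlap_fraction)
        ds = EnvelopeDataset(env, new_rate, voxel_coords=voxel_coords)
        if fwhm_mm > 0 and voxel_coords is not None:
            ds = spatial_smooth(ds, fwhm_mm)
        prepared.append(ds)
    return normalize_and_concatenate(prepared)
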