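"""Shared data containers for the envelope-HMM pipeline.

Two containers travel between nearly every stage: the voxels-by-time
amplitude-envelope matrix and the hard state path produced by Viterbi
decoding (or by a simulator).  Both carry a sampling rate and the
per-subject segment boundaries so that downstream code can treat the
group-concatenated recording as a set of independent chains.

Conventions
-----------
* States are 0-based integers ``0..K-1``.
* ``segment_boundaries`` is the ordered array of *end* indices of each
  subject block, so a single-subject recording of length ``T`` has
  boundaries ``[T]`` and three equal subjects have ``[T, 2T, 3T]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = ["StatePath", "EnvelopeDataset", "as_segment_boundaries", "segments"]


def as_segment_boundaries(boundaries, n_samples: int) -> np.ndarray:
    """Validate and canonicalize segment boundaries.

    ``boundaries`` may be None (one segment covering everything) or a
    strictly increasing sequence of end indices whose last entry equals
    ``n_samples``.
    """
    if boundaries is None:
        return np.array([n_samples], dtype=np.int64)
    b = np.asarray(boundaries, dtype=np.int64)
    if b.ndim != 1 or b.size == 0:
        raise ValueError("segment boundaries must be a non-empty 1-D sequence")
    if np.any(np.diff(b) <= 0) or b[0] <= 0:
        raise ValueError("segment boundaries must be strictly increasing and positive")
    if b[-1] != n_samples:
        raise ValueError(
            f"last segment boundary ({b[-1]}) must equal the number of samples ({n_samples})"
        )
    return b


def segments(boundaries: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (start, stop) index pairs for each segment."""
    start = 0
    for stop in boundaries:
        yield int(start), int(stop)
        start = stop


@dataclass
class StatePath:
    """Hard state assignment per sample.

    Attributes
    ----------
    states : (T,) int array of 0-based state labels.
    sampling_rate : samples per second of the state sequence.
    segment_boundaries : end indices of each subject block.
    n_states : number of states K (labels may not all occur).
    """

    states: np.ndarray
    sampling_rate: float
    segment_boundaries: np.ndarray = None
    n_states: int = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("state path must be a non-empty 1-D sequence")
        if self.states.min() < 0:
            raise ValueError("state labels must be non-negative")
        if self.n_states is None:
            self.n_states = int(self.states.max()) + 1
        elif self.states.max() >= self.n_states:
            raise ValueError("state label exceeds n_states - 1")
        self.segment_boundaries = as_segment_boundaries(
            self.segment_boundaries, self.states.size
        )

    @property
    def n_samples(self) -> int:
        return self.states.size

    def segments(self) -> Iterator[tuple[int, int]]:
        return segments(self.segment_boundaries)

    def indicators(self) -> np.ndarray:
        """(T, K) 0/1 indicator matrix of the path."""
        return np.eye(self.n_states)[self.states]


@dataclass
class EnvelopeDataset:
    """Voxels-by-time amplitude envelopes with spatial and temporal metadata.

    ``data`` is (V, T) and non-negative before normalization (z-scored
    group data may be negative; ``require_nonnegative`` is therefore a
    construction-time option, not an invariant of the class).
    """

    data: np.ndarray
    sampling_rate: float
    voxel_coords: np.ndarray = None
    segment_boundaries: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("envelope data must be a 2-D (voxels x time) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("envelope data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.float64)
            if self.voxel_coords.shape != (self.data.shape[0], 3):
                raise ValueError("voxel_coords must be (V, 3)")
        self.segment_boundaries = as_segment_boundaries(
            self.segment_boundaries, self.data.shape[1]
        )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def segments(self) -> Iterator[tuple[int, int]]:
        return segments(self.segment_boundaries)
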