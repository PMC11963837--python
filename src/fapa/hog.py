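"""Per-frame HOG descriptors and the scalar frame-difference (Diff) series.

Every downstream paralysis decision consumes Diff(x): the distance between
the HOG vector of frame 1 and that of frame x of the same session. A
larger Diff means more facial movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.feature import hog as _skimage_hog

from fapa.video_io import FrameStack

__all__ = [
    "HOGParams",
    "HOGSeries",
    "DiffSeries",
    "compute_hog",
    "hog_series",
    "hog_diff_series",
    "session_summary",
    "normalize_sessions",
]


@dataclass(frozen=True)
class HOGParams:
    """Descriptor parameters: 8 orientation bins over 32-px cells, one cell
    per block, with power-law (gamma) intensity compression applied first."""

    orientations: int = 8
    cell_size: int = 32
    cells_per_block: int = 1
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.orientations < 1 or self.cell_size < 1 or self.cells_per_block < 1:
            raise ValueError("HOG parameters must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def vector_length(self, height: int, width: int) -> int:
        """Descriptor length for an H x W zone."""
        cr = height // self.cell_size
        cc = width // self.cell_size
        b = self.cells_per_block
        if cr < b or cc < b:
            raise ValueError(
                f"frame {height}x{width} smaller than one {self.cell_size}-px block"
            )
        return (cr - b + 1) * (cc - b + 1) * b * b * self.orientations


@dataclass
class HOGSeries:
    """Per-frame HOG vectors for one zone of one session."""

    vectors: np.ndarray  # (n_frames, L)
    params: HOGParams
    zone: str = "whole"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (frames x features)")
        if (self.vectors < -1e-12).any():
            raise ValueError("HOG entries must be non-negative")

    @property
    def frame_count(self) -> int:
        return self.vectors.shape[0]


@dataclass
class DiffSeries:
    """Scalar distance of each frame's HOG from frame 1; Diff(1) = 0."""

    values: np.ndarray
    zone: str = "whole"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("Diff series must be a non-empty 1-D array")
        if abs(self.values[0]) > 1e-12:
            raise ValueError("Diff(1) must be 0")
        if (self.values < -1e-12).any():
            raise ValueError("Diff values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


def compute_hog(frame: np.ndarray, params: HOGParams = HOGParams()) -> np.ndarray:
    """HOG descriptor of one grayscale frame.

    Gamma compression (``I -> I**gamma``) is applied first; gradients are
    binned into unsigned orientations (0-180 deg) per cell, L2-normalized
    per block, and flattened row-major. Zero-gradient cells stay zero.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("compute_hog expects a 2-D grayscale frame")
    h, w = frame.shape
    expected = params.vector_length(h, w)  # raises if frame < one cell
    compressed = np.power(np.clip(frame, 0.0, None), params.gamma)
    vec = _skimage_hog(
        compressed,
        orientations=params.orientations,
        pixels_per_cell=(params.cell_size, params.cell_size),
        cells_per_block=(params.cells_per_block, params.cells_per_block),
        block_norm="L2",
        transform_sqrt=False,
        feature_vector=True,
    )
    assert vec.shape == (expected,)
    return vec


def hog_series(
    stack: FrameStack | np.ndarray,
    params: HOGParams = HOGParams(),
    zone: str = "whole",
    session_id: str = "",
) -> HOGSeries:
    """Compute :func:`compute_hog` for every frame of a stack."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    vectors = np.stack([compute_hog(f, params) for f in frames])
    return HOGSeries(vectors=vectors, params=params, zone=zone, session_id=session_id)


def hog_diff_series(series: HOGSeries, metric: str = "l2") -> DiffSeries:
    """Reduce a HOG series to the scalar Diff series.

    Diff(x) is the norm of ``vector_1 - vector_x`` (Euclidean by default;
    ``metric="l1"`` selects the absolute-sum norm). Diff(1) is exactly 0.
    """
    delta = series.vectors - series.vectors[0]
    if metric == "l2":
        values = np.linalg.norm(delta, axis=1)
    elif metric == "l1":
        values = np.abs(delta).sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    values[0] = 0.0
    return DiffSeries(values=values, zone=series.zone, session_id=series.session_id)


def session_summary(diff: DiffSeries | Sequence[float]) -> float:
    """Session-level movement scalar: the mean of the Diff values."""
    values = diff.values if isinstance(diff, DiffSeries) else np.asarray(diff, float)
    if len(values) < 1:
        raise ValueError("empty Diff series")
    return float(values.mean())


def normalize_sessions(values: Sequence[float], method: str = "minmax") -> np.ndarray:
    """Normalize a mouse's per-session summaries across sessions.

    ``minmax`` (default) maps onto [0, 1]; ``zscore`` standardizes to zero
    mean / unit sd. All-equal input has no spread to normalize and raises.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 sessions to normalize")
    if np.allclose(v, v[0]):
        raise ValueError("degenerate normalization: all session values equal")
    if method == "minmax":
        return (v - v.min()) / (v.max() - v.min())
    if method == "zscore":
        return (v - v.mean()) / v.std(ddof=1)
    raise ValueError(f"unknown normalization method {method!r}")
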