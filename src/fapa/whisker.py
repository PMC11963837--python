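"""Painted-whisker tracking and kinematics.

The marker is segmented by color, cleaned morphologically, and reduced to
an angle about the whiskerpad insertion point. Accumulated per-frame
angles form a continuous signal that is rebased so the session minimum is
0 deg; cycles are delimited minimum-to-minimum (protraction = rising
phase, retraction = falling phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy import ndimage

from fapa.video_io import FrameStack

__all__ = [
    "WhiskerTrace",
    "MovementCycle",
    "AmplitudeClasses",
    "segment_marker",
    "clean_mask",
    "whisker_angle",
    "build_trace",
    "detect_change_point",
    "detect_cycles",
    "classify_amplitudes",
    "cycle_auc",
    "movement_spectrogram",
    "NO_CHANGE",
    "MissingMarkerError",
    "TrackingFailureError",
]

#: Sentinel returned by :func:`detect_change_point` for motionless traces.
NO_CHANGE = -1

#: Longest run of marker-less frames bridged by linear interpolation.
MAX_INTERP_RUN = 5


class MissingMarkerError(RuntimeError):
    """The marker was not found in a frame (empty mask)."""


class TrackingFailureError(RuntimeError):
    """Too many frames without a detectable marker."""


@dataclass
class WhiskerTrace:
    """Per-frame whisker angle signal.

    When ``rebased`` the session minimum is exactly 0 deg.
    """

    angles: np.ndarray
    fps: float
    insertion_point: Tuple[float, float] = (0.0, 0.0)
    rebased: bool = False

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1 or len(self.angles) < 2:
            raise ValueError("angles must be a 1-D signal of length >= 2")
        if not np.isfinite(self.angles).all():
            raise ValueError("angles must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.rebased and abs(float(self.angles.min())) > 1e-9:
            raise ValueError("rebased trace must have minimum exactly 0")

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.angles)) / self.fps

    def rebase(self) -> "WhiskerTrace":
        """Shift the signal so the session minimum is 0 deg."""
        shifted = self.angles - self.angles.min()
        shifted[np.argmin(self.angles)] = 0.0  # exact zero at the minimum
        return WhiskerTrace(angles=shifted, fps=self.fps,
                            insertion_point=self.insertion_point, rebased=True)


@dataclass(frozen=True)
class MovementCycle:
    """One minimum-to-minimum whisker movement cycle."""

    start_index: int
    min_index: int
    max_index: int
    end_index: int
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.start_index <= self.min_index <= self.end_index):
            raise ValueError("cycle indices out of order")
        if self.amplitude < 0:
            raise ValueError("cycle amplitude must be >= 0")

    @property
    def protraction_span(self) -> Tuple[int, int]:
        """Frame interval of the forward (rising) sweep: minimum -> maximum."""
        return (self.min_index, self.max_index)

    @property
    def retraction_span(self) -> Tuple[int, int]:
        """Frame interval of the backward (falling) sweep: maximum -> end."""
        return (self.max_index, self.end_index)


@dataclass
class AmplitudeClasses:
    """Long/short amplitude partition about the mean-amplitude threshold."""

    threshold: float
    long_count: int
    short_count: int

    @property
    def proportions(self) -> Tuple[float, float]:
        total = self.long_count + self.short_count
        return (self.long_count / total, self.short_count / total)


def segment_marker(frame: np.ndarray, color_ref: Sequence[float],
                   tolerance: float) -> np.ndarray:
    """Binarize a frame: True where the pixel matches the painted color.

    Color distance is the per-channel Chebyshev (max-abs) distance; a pixel
    is kept when that distance is <= ``tolerance``. Grayscale frames are
    matched against the mean of ``color_ref``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    frame = np.asarray(frame, dtype=float)
    ref = np.asarray(color_ref, dtype=float)
    if frame.ndim == 2:
        dist = np.abs(frame - ref.mean())
    else:
        dist = np.abs(frame[..., :3] - ref[:3]).max(axis=-1)
    return dist <= tolerance


def clean_mask(mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Remove stray pixels farther than ``radius`` from the main marker blob.

    Pixels within ``radius`` of each other are grouped (dilation-based
    linkage); only the group with the largest pixel count survives. An
    all-false mask is returned unchanged with a warning.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("clean_mask called on an empty mask", stacklevel=2)
        return mask.copy()
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    disk = (yy ** 2 + xx ** 2) <= radius ** 2
    linked = ndimage.binary_dilation(mask, structure=disk)
    labels, n = ndimage.label(linked)
    if n == 1:
        return mask.copy()
    counts = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(counts)) + 1
    return mask & (labels == keep)


def whisker_angle(mask: np.ndarray, insertion: Tuple[float, float]) -> float:
    """Angle (degrees) of the marker centroid about the insertion point.

    Measured counterclockwise from the +x (rightward) axis; rows grow
    downward, so a centroid above the insertion reads +90 deg.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MissingMarkerError("empty mask: whisker marker not found")
    rows, cols = np.nonzero(mask)
    c_row, c_col = rows.mean(), cols.mean()
    ins_row, ins_col = insertion
    return float(np.degrees(np.arctan2(ins_row - c_row, c_col - ins_col)))


def build_trace(
    stack: FrameStack | np.ndarray,
    color_ref: Sequence[float],
    tolerance: float,
    insertion: Tuple[float, float],
    fps: float | None = None,
    clean_radius: int = 5,
) -> WhiskerTrace:
    """Track the marker across a session and return the rebased angle trace.

    Frames where the marker is missing are bridged by linear interpolation
    for runs of up to 5 frames; longer gaps or >50% missing frames abort
    with :class:`TrackingFailureError`.
    """
    if isinstance(stack, FrameStack):
        frames = stack.frames
        fps = stack.fps
    else:
        frames = np.asarray(stack)
        if fps is None:
            raise ValueError("fps required when passing a bare frame array")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to build a trace")

    angles = np.full(len(frames), np.nan)
    for i, frame in enumerate(frames):
        raw = segment_marker(frame, color_ref, tolerance)
        if raw.any():
            mask = clean_mask(raw, radius=clean_radius)
            angles[i] = whisker_angle(mask, insertion)

    missing = np.isnan(angles)
    if missing.mean() > 0.5:
        raise TrackingFailureError(
            f"marker missing in {missing.sum()}/{len(angles)} frames (>50%)"
        )
    if missing.any():
        runs = _nan_run_lengths(missing)
        if runs.max(initial=0) > MAX_INTERP_RUN:
            raise TrackingFailureError(
                f"marker missing for a run of {runs.max()} frames (> {MAX_INTERP_RUN})"
            )
        idx = np.arange(len(angles))
        angles[missing] = np.interp(idx[missing], idx[~missing], angles[~missing])

    trace = WhiskerTrace(angles=angles, fps=float(fps), insertion_point=tuple(insertion))
    return trace.rebase()


def _nan_run_lengths(missing: np.ndarray) -> np.ndarray:
    lengths = []
    run = 0
    for m in missing:
        if m:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return np.asarray(lengths, dtype=int)


def detect_change_point(trace: WhiskerTrace | np.ndarray,
                        penalty: float | None = None) -> int:
    """Single mean-shift changepoint of the angle signal.

    Splits the signal at the index k that maximizes
    ``C(A) - [C(A1) + C(A2)]`` where C is the sum of squared residuals
    about each segment's mean; the split is accepted only when the
    improvement exceeds ``penalty``. Returns :data:`NO_CHANGE` when no
    split clears the penalty (motionless trace).

    ``penalty`` defaults to 5x the trace variance.
    """
    x = trace.angles if isinstance(trace, WhiskerTrace) else np.asarray(trace, float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples for changepoint detection")
    if penalty is None:
        penalty = 5.0 * float(np.var(x))

    # segment SSE via prefix sums: C = sum(x^2) - (sum x)^2 / n
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(i: int, j: int) -> float:  # cost of x[i:j]
        m = j - i
        return (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / m

    total = sse(0, n)
    best_k, best_gain = NO_CHANGE, -np.inf
    for k in range(1, n):
        gain = total - (sse(0, k) + sse(k, n))
        if gain > best_gain:
            best_gain, best_k = gain, k
    if best_gain > penalty:
        return best_k
    return NO_CHANGE


def _local_minima(x: np.ndarray) -> List[int]:
    """Strict local minima, plateau ties resolved at the plateau midpoint."""
    n = len(x)
    minima: List[int] = []
    i = 1
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                minima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return minima


def detect_cycles(
    trace: WhiskerTrace,
    smooth_s: float = 0.0,
    min_prominence: float = 0.0,
) -> List[MovementCycle]:
    """Delimit movement cycles between consecutive signal minima.

    Cycles tile the trace minimum-to-minimum; amplitude is the max minus
    min angle within the cycle. Fewer than two minima (flat or paralyzed
    trace) yields an empty list.

    For noisy traces, ``smooth_s`` applies a Savitzky-Golay filter (cubic,
    window of that many seconds) before minima detection and
    ``min_prominence`` (degrees) discards shallow noise-induced minima;
    amplitudes are then measured on the smoothed signal. The defaults
    reproduce the exact strict-minima behavior on raw angles.
    """
    x = trace.angles
    if len(x) < 3:
        raise ValueError("trace too short for cycle detection")
    if smooth_s > 0:
        w = max(5, int(round(smooth_s * trace.fps)) | 1)
        if w < len(x):
            x = sps.savgol_filter(x, w, polyorder=3)
    if min_prominence > 0:
        minima = list(sps.find_peaks(-x, prominence=min_prominence)[0])
    else:
        minima = _local_minima(x)
    cycles: List[MovementCycle] = []
    for a, b in zip(minima[:-1], minima[1:]):
        seg = x[a:b + 1]
        lo, hi = float(seg.min()), float(seg.max())
        cycles.append(
            MovementCycle(
                start_index=a,
                min_index=a + int(np.argmin(seg)),
                max_index=a + int(np.argmax(seg)),
                end_index=b,
                amplitude=hi - lo,
            )
        )
    return cycles


def classify_amplitudes(
    cycles: Sequence[MovementCycle],
    fps: float | None = None,
    window_s: float | None = None,
    window_start_s: float = 0.0,
) -> AmplitudeClasses:
    """Split cycles into long/short about the mean-amplitude threshold.

    The threshold is the mean amplitude of the cycles that start inside
    the evaluation window (all cycles when ``window_s`` is None). A cycle
    is long when its amplitude is strictly above the threshold; ties are
    short.
    """
    if not cycles:
        raise ValueError("cannot classify amplitudes of an empty cycle list")
    if window_s is not None:
        if fps is None:
            raise ValueError("fps required when windowing by seconds")
        lo = window_start_s * fps
        hi = (window_start_s + window_s) * fps
        in_win = [c for c in cycles if lo <= c.start_index < hi]
        ref = in_win if in_win else list(cycles)
    else:
        ref = list(cycles)
    threshold = float(np.mean([c.amplitude for c in ref]))
    long_count = sum(1 for c in cycles if c.amplitude > threshold)
    return AmplitudeClasses(
        threshold=threshold,
        long_count=long_count,
        short_count=len(cycles) - long_count,
    )


def cycle_auc(trace: WhiskerTrace, cycle: MovementCycle) -> float:
    """Trapezoidal area under the angle curve over one cycle (deg * s)."""
    if not (0 <= cycle.start_index < cycle.end_index < len(trace.angles)):
        raise ValueError("cycle indices outside trace")
    seg = trace.angles[cycle.start_index:cycle.end_index + 1]
    return float(np.trapezoid(seg, dx=1.0 / trace.fps))


def cycle_frequency(cycle: MovementCycle, fps: float) -> float:
    """Cycle rate in Hz implied by the cycle duration (each cycle = 1 beat)."""
    duration = (cycle.end_index - cycle.start_index) / fps
    if duration <= 0:
        raise ValueError("degenerate cycle duration")
    return 1.0 / duration


def movement_spectrogram(
    trace: WhiskerTrace,
    window_s: float = 0.5,
    overlap: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier power of the angle signal.

    Hann window of ``window_s`` seconds with fractional ``overlap``;
    returns ``(times, frequencies, power)`` with frequencies spanning 0 to
    fps/2.
    """
    nperseg = int(round(window_s * trace.fps))
    if nperseg < 2 or len(trace.angles) < nperseg:
        raise ValueError("trace shorter than one spectrogram window")
    freqs, times, power = sps.spectrogram(
        trace.angles,
        fs=trace.fps,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="spectrum",
        mode="psd",
    )
    return times, freqs, power
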