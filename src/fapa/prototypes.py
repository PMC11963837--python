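"""Facial-expression prototypes and similarity traces.

A basal prototype is the mean HOG of 250 resting frames; an emotional
prototype is the mean HOG of the 10 stimulation frames least correlated
with the basal prototype. Per-frame Pearson correlation with a prototype
tracks expression over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from fapa.hog import HOGParams, HOGSeries

__all__ = [
    "Prototype",
    "SimilarityTrace",
    "basal_prototype",
    "similarity_trace",
    "emotional_prototype",
    "expression_onset_report",
    "expression_window_indices",
]

STIMULUS_LABELS = {"sucrose": "pleasure", "quinine": "disgust", "water": "neutral"}


@dataclass
class Prototype:
    """Averaged HOG template for one facial state."""

    vector: np.ndarray
    label: str
    n_source_frames: int
    params: HOGParams = HOGParams()

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if self.n_source_frames < 1:
            raise ValueError("prototype needs at least one source frame")


@dataclass
class SimilarityTrace:
    """Per-frame Pearson correlation against a prototype."""

    r: np.ndarray
    fps: float
    event_time: float | None = None
    prototype_label: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.r)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.r)) / self.fps


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt((du ** 2).sum() * (dv ** 2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((du * dv).sum() / denom, -1.0, 1.0))


def basal_prototype(hogs: HOGSeries, n: int = 250) -> Prototype:
    """Mean of the first ``n`` pre-stimulation HOG vectors."""
    if hogs.frame_count < n:
        raise ValueError(
            f"basal prototype needs {n} frames, only {hogs.frame_count} available"
        )
    return Prototype(vector=hogs.vectors[:n].mean(axis=0), label="basal",
                     n_source_frames=n, params=hogs.params)


def similarity_trace(
    hogs: HOGSeries,
    proto: Prototype,
    fps: float = 30.0,
    event_time: float | None = None,
) -> SimilarityTrace:
    """Pearson r of every frame's HOG vector against the prototype vector.

    Frames with a constant HOG vector have undefined correlation and are
    emitted as NaN with a warning.
    """
    if hogs.vectors.shape[1] != proto.vector.shape[0]:
        raise ValueError("HOG vector length does not match prototype")
    if np.allclose(proto.vector, proto.vector[0]):
        raise ValueError("prototype vector is constant; correlation undefined")
    r = np.array([_pearson(v, proto.vector) for v in hogs.vectors])
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        warnings.warn(f"{n_bad} constant frame vector(s); r undefined there",
                      stacklevel=2)
    return SimilarityTrace(r=r, fps=fps, event_time=event_time,
                           prototype_label=proto.label)


def emotional_prototype(
    hogs_stim: HOGSeries,
    basal: Prototype,
    k: int = 10,
    stimulus: str = "sucrose",
) -> Prototype:
    """Mean HOG of the k stimulation frames least correlated with basal.

    Ties in correlation are broken toward the earlier frame. The label
    follows the stimulus: sucrose -> pleasure, quinine -> disgust,
    water -> neutral.
    """
    if hogs_stim.frame_count < k:
        raise ValueError(
            f"need >= {k} stimulation frames, got {hogs_stim.frame_count}"
        )
    label = STIMULUS_LABELS.get(stimulus, stimulus)
    r = np.array([_pearson(v, basal.vector) for v in hogs_stim.vectors])
    r = np.where(np.isnan(r), np.inf, r)  # constant frames never selected
    order = np.argsort(r, kind="stable")  # stable sort = earlier-frame tie-break
    chosen = np.sort(order[:k])
    return Prototype(vector=hogs_stim.vectors[chosen].mean(axis=0), label=label,
                     n_source_frames=k, params=hogs_stim.params)


def expression_window_indices(
    n_frames: int,
    fps: float,
    event_time: float,
    pre_s: float = 5.0,
    post_s: float = 5.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Frame indices of the pre- and post-stimulus analysis windows.

    The pre window covers ``[event - pre_s, event)`` and the post window
    ``[event, event + post_s)``; both are clipped to the session bounds.
    """
    event_idx = int(round(event_time * fps))
    pre_lo = max(event_idx - int(round(pre_s * fps)), 0)
    post_hi = min(event_idx + int(round(post_s * fps)), n_frames)
    pre = np.arange(pre_lo, min(event_idx, n_frames))
    post = np.arange(max(event_idx, 0), post_hi)
    return pre, post


def expression_onset_report(
    trace: SimilarityTrace,
    window_s: float = 10.0,
) -> Dict[str, float]:
    """Mean similarity before vs after the stimulus event.

    Uses symmetric ``window_s / 2`` second windows on each side of
    ``event_time``; windows extending past the trace are truncated (the
    report flags this).
    """
    if trace.event_time is None:
        raise ValueError("trace has no event_time")
    half = window_s / 2.0
    pre_idx, post_idx = expression_window_indices(
        len(trace), trace.fps, trace.event_time, pre_s=half, post_s=half
    )
    full_len = int(round(half * trace.fps))
    truncated = len(pre_idx) < full_len or len(post_idx) < full_len
    if truncated:
        warnings.warn("onset window truncated at trace bounds", stacklevel=2)
    pre = float(np.nanmean(trace.r[pre_idx])) if len(pre_idx) else np.nan
    post = float(np.nanmean(trace.r[post_idx])) if len(post_idx) else np.nan
    return {
        "pre_mean_r": pre,
        "post_mean_r": post,
        "difference": post - pre,
        "truncated": bool(truncated),
    }
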