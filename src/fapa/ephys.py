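"""Spike-train correlates of facial movement: PSTHs, baseline z-scores, and
cross-covariance between firing and behavioral traces."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "SpikeTrain",
    "PSTH",
    "ZTrace",
    "psth",
    "zscore_psth",
    "cross_covariance",
    "covariance_correlation",
]


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) of one unit."""

    spike_times: np.ndarray
    unit_id: str = ""
    recording_duration: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.isnan(self.spike_times).any():
            raise ValueError("spike times contain NaN")
        if (np.diff(self.spike_times) < 0).any():
            raise ValueError("spike times must be sorted ascending")
        if self.recording_duration is None:
            self.recording_duration = float(self.spike_times[-1]) if len(self.spike_times) else 0.0
        if len(self.spike_times) and (
            self.spike_times[0] < 0 or self.spike_times[-1] > self.recording_duration + 1e-9
        ):
            raise ValueError("spike times outside [0, recording_duration]")


@dataclass
class PSTH:
    """Event-aligned firing rate per bin, averaged over events."""

    rates: np.ndarray  # spikes/s per bin
    bin_centers: np.ndarray  # seconds relative to event
    n_events: int
    bin_width: float = 0.1
    window: Tuple[float, float] = (10.0, 10.0)  # (pre_s, post_s)

    @property
    def counts(self) -> np.ndarray:
        """Mean spike count per bin (rate x bin width)."""
        return self.rates * self.bin_width


@dataclass
class ZTrace:
    """PSTH standardized against its 10-s pre-event baseline."""

    z: np.ndarray
    bin_centers: np.ndarray
    baseline_mean: float
    baseline_sd: float

    def clipped(self, lo: float = -2.0, hi: float = 2.0) -> np.ndarray:
        """Display-clipped copy of the z trace; raw values stay intact."""
        return np.clip(self.z, lo, hi)


def psth(
    train: SpikeTrain,
    events: Sequence[float],
    pre_s: float = 10.0,
    post_s: float = 10.0,
    bin_s: float = 0.1,
) -> PSTH:
    """Peristimulus time histogram in 100-ms bins (by default).

    Events whose window falls outside the recording are dropped with a
    warning; if none remain an error is raised.
    """
    events = np.asarray(events, dtype=float)
    if len(events) < 1:
        raise ValueError("need at least one event")
    duration = train.recording_duration
    keep = (events - pre_s >= -1e-9) & (events + post_s <= duration + 1e-9)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} event(s) whose window exceeds the recording",
            stacklevel=2,
        )
    events = events[keep]
    if len(events) == 0:
        raise ValueError("all events dropped: windows exceed recording bounds")

    n_bins = int(round((pre_s + post_s) / bin_s))
    edges = -pre_s + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for ev in events:
        rel = train.spike_times - ev
        counts += np.histogram(rel, bins=edges)[0]
    rates = counts / (len(events) * bin_s)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return PSTH(rates=rates, bin_centers=centers, n_events=len(events),
                bin_width=bin_s, window=(pre_s, post_s))


def zscore_psth(p: PSTH, baseline_s: float = 10.0) -> ZTrace:
    """Standardize a PSTH by its pre-event baseline bins.

    The baseline mean and sd come from the ``baseline_s`` seconds of bins
    immediately before the event (bin centers in ``[-baseline_s, 0)``).
    """
    base = (p.bin_centers >= -baseline_s) & (p.bin_centers < 0)
    n_base = int(base.sum())
    if n_base * p.bin_width < baseline_s - 1e-9:
        raise ValueError(
            f"pre-event window holds only {n_base * p.bin_width:.1f} s of the "
            f"{baseline_s:.1f} s baseline"
        )
    m = float(p.rates[base].mean())
    sd = float(p.rates[base].std(ddof=1))
    if sd == 0:
        raise ValueError("zero baseline sd; use a longer or more variable baseline")
    return ZTrace(z=(p.rates - m) / sd, bin_centers=p.bin_centers,
                  baseline_mean=m, baseline_sd=sd)


def cross_covariance(
    x: Sequence[float],
    y: Sequence[float],
    max_lag: int,
    normalize: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean-removed cross-covariance of two equally sampled series.

    Returns ``(lags, values)`` for lags in ``[-max_lag, max_lag]``
    samples. ``values[lag]`` correlates ``x[t]`` with ``y[t + lag]``, so a
    positive peak lag means x leads y. When ``normalize`` (default) the
    values are scaled by the zero-lag autocovariance product's square
    root: identical signals give exactly 1 at lag 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    if n <= max_lag:
        raise ValueError("series shorter than max_lag")
    dx = x - x.mean()
    dy = y - y.mean()
    if np.allclose(dx, 0) or np.allclose(dy, 0):
        raise ValueError("constant series: cross-covariance undefined")
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            values[i] = (dx[: n - lag] * dy[lag:]).sum() / n
        else:
            values[i] = (dx[-lag:] * dy[: n + lag]).sum() / n
    if normalize:
        scale = np.sqrt((dx ** 2).sum() / n * (dy ** 2).sum() / n)
        values = values / scale
    return lags, values


def covariance_correlation(cc_expression: Sequence[float],
                           cc_movement: Sequence[float]) -> float:
    """Pearson r across lags between two cross-covariance traces."""
    a = np.asarray(cc_expression, dtype=float)
    b = np.asarray(cc_movement, dtype=float)
    if a.shape != b.shape:
        raise ValueError("cross-covariance traces differ in length")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0:
        raise ValueError("constant cross-covariance trace")
    return float(np.clip((da * db).sum() / denom, -1.0, 1.0))
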