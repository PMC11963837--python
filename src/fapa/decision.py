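"""Threshold construction, the ten paralysis decision models, the per-frame
movement rule, session verdicts, and system scoring (decision percentage,
d-prime).

Semantics of the binary flags: a zone is flagged "low" (1) when its
movement summary is strictly below the threshold; ties are not low. A
session is declared paralyzed when the fraction of no-movement frames is
strictly above 90%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "ThresholdSet",
    "ModelSpec",
    "ParalysisVerdict",
    "PerformanceReport",
    "MODEL_SPECS",
    "group_threshold",
    "individual_threshold",
    "two_session_threshold",
    "low_flags",
    "apply_model",
    "frame_movement",
    "frame_movement_series",
    "session_verdict",
    "decision_percentage",
    "d_prime",
]

STILLNESS_CUTOFF = 0.90  # strict: paralyzed iff stillness_fraction > 0.90


def _as_zone_map(values) -> Dict[str, float]:
    if isinstance(values, Mapping):
        return {str(k): float(v) for k, v in values.items()}
    return {"Total": float(values)}


@dataclass
class ThresholdSet:
    """Per-zone movement thresholds plus provenance of how they were built."""

    thresholds: Dict[str, float]
    mode: str
    normalized: bool = False

    def __post_init__(self) -> None:
        for zone, t in self.thresholds.items():
            if t < 0:
                raise ValueError(f"threshold for zone {zone} is negative: {t}")
        if self.mode not in {"group_mean_plus_std", "individual_mean", "two_session_mean"}:
            raise ValueError(f"unknown threshold mode {self.mode!r}")

    def __getitem__(self, zone: str) -> float:
        return self.thresholds[zone]


@dataclass(frozen=True)
class ModelSpec:
    """One of the ten decision models.

    ``combinator`` is "or" (any used zone low) or "and" (all used zones
    low); ``scope`` names the threshold flavor: group (G), normalized group
    (GN), or individual (I). Model 10 works on the whole-face summary.
    """

    model_id: int
    zones: tuple
    combinator: str
    scope: str


#: The ten printed decision models, keyed by id.
MODEL_SPECS: Dict[int, ModelSpec] = {
    1: ModelSpec(1, ("A", "M"), "or", "individual"),
    2: ModelSpec(2, ("A", "M"), "and", "group_normalized"),
    3: ModelSpec(3, ("A", "M"), "and", "individual"),
    4: ModelSpec(4, ("A", "M"), "or", "group"),
    5: ModelSpec(5, ("A", "M"), "and", "group"),
    6: ModelSpec(6, ("A", "M", "P"), "or", "individual"),
    7: ModelSpec(7, ("A", "M", "P"), "and", "individual"),
    8: ModelSpec(8, ("A", "M", "P"), "or", "group"),
    9: ModelSpec(9, ("A", "M", "P"), "and", "group"),
    10: ModelSpec(10, ("Total",), "and", "group"),
}

#: Recommended default: AND of normalized anterior + middle zone flags.
DEFAULT_MODEL_ID = 2


@dataclass
class ParalysisVerdict:
    """Binary paralysis decision with its supporting flags."""

    level: str  # frame | session | timeline
    paralyzed: bool
    flags: Dict[str, int] = field(default_factory=dict)
    stillness_fraction: float | None = None

    @property
    def verdict(self) -> str:
        return "paralyzed" if self.paralyzed else "not_paralyzed"


@dataclass
class PerformanceReport:
    """System-level scoring of paralysis detection."""

    decision_percentage: float
    hit_rate: float
    fa_rate: float
    d_prime: float


def group_threshold(session_summaries, normalized: bool = False) -> ThresholdSet:
    """Group threshold: mean of per-session summaries plus their sample sd.

    Accepts a mapping zone -> sequence of session summaries, or a bare
    sequence (treated as zone "Total"). Requires >= 2 sessions.
    """
    if not isinstance(session_summaries, Mapping):
        session_summaries = {"Total": session_summaries}
    thresholds = {}
    for zone, vals in session_summaries.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"zone {zone}: need >= 2 sessions for a group threshold")
        thresholds[zone] = float(v.mean() + v.std(ddof=1))
    return ThresholdSet(thresholds=thresholds, mode="group_mean_plus_std",
                        normalized=normalized)


def individual_threshold(session_summaries, normalized: bool = False) -> ThresholdSet:
    """Individual threshold: plain mean of one mouse's session summaries."""
    if not isinstance(session_summaries, Mapping):
        session_summaries = {"Total": session_summaries}
    thresholds = {}
    for zone, vals in session_summaries.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 1:
            raise ValueError(f"zone {zone}: need >= 1 session")
        thresholds[zone] = float(v.mean())
    return ThresholdSet(thresholds=thresholds, mode="individual_mean",
                        normalized=normalized)


def two_session_threshold(diff_baseline, diff_paralyzed,
                          normalized: bool = False) -> ThresholdSet:
    """Two-assessment threshold: midpoint of baseline and paralyzed summaries.

    The paralyzed assessment is conventionally the 24 h post-injury
    session. Accepts per-zone mappings or bare scalars.
    """
    base = _as_zone_map(diff_baseline)
    para = _as_zone_map(diff_paralyzed)
    if set(base) != set(para):
        raise ValueError(f"zone mismatch: {set(base)} vs {set(para)}")
    thresholds = {}
    for zone in base:
        if base[zone] < 0 or para[zone] < 0:
            raise ValueError("Diff summaries must be >= 0")
        thresholds[zone] = (base[zone] + para[zone]) / 2.0
    return ThresholdSet(thresholds=thresholds, mode="two_session_mean",
                        normalized=normalized)


def low_flags(session_values, thresholds: ThresholdSet) -> Dict[str, int]:
    """Binary low-movement flags: 1 iff value is strictly below threshold."""
    values = _as_zone_map(session_values)
    if set(values) - set(thresholds.thresholds):
        missing = set(values) - set(thresholds.thresholds)
        raise ValueError(f"no threshold for zones {missing}")
    return {zone: int(values[zone] < thresholds[zone]) for zone in values}


def apply_model(model_id: int, flags: Mapping[str, int]) -> ParalysisVerdict:
    """Evaluate one decision model on the per-zone low-movement flags.

    OR models declare paralysis when any used zone is low; AND models when
    every used zone is low (the flag sum equals the zone count).
    """
    try:
        spec = MODEL_SPECS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id}; valid ids are 1-10") from None
    missing = [z for z in spec.zones if z not in flags]
    if missing:
        raise ValueError(f"model {model_id} needs flags for zones {missing}")
    bits = [int(flags[z]) for z in spec.zones]
    paralyzed = any(bits) if spec.combinator == "or" else sum(bits) == len(bits)
    return ParalysisVerdict(level="session", paralyzed=paralyzed,
                            flags={z: int(flags[z]) for z in spec.zones})


def frame_movement(flag_a: int, flag_m: int) -> bool:
    """Per-frame movement rule: movement iff the flag sum is < 2."""
    return (int(flag_a) + int(flag_m)) < 2


def frame_movement_series(
    diff_a: Sequence[float],
    diff_m: Sequence[float],
    thresholds: ThresholdSet,
) -> np.ndarray:
    """Apply the per-frame movement rule along paired zone Diff series.

    Per-frame Diff values are compared against the session thresholds for
    zones A and M; returns a boolean movement array.
    """
    a = np.asarray(diff_a, dtype=float)
    m = np.asarray(diff_m, dtype=float)
    if a.shape != m.shape:
        raise ValueError("zone Diff series lengths differ")
    low_a = a < thresholds["A"]
    low_m = m < thresholds["M"]
    return (low_a.astype(int) + low_m.astype(int)) < 2


def session_verdict(frame_movements: Sequence[bool]) -> ParalysisVerdict:
    """Session verdict: paralyzed iff stillness fraction strictly > 90%."""
    moves = np.asarray(frame_movements, dtype=bool)
    if len(moves) < 1:
        raise ValueError("need at least one frame")
    stillness = float((~moves).mean())
    return ParalysisVerdict(
        level="session",
        paralyzed=stillness > STILLNESS_CUTOFF,
        stillness_fraction=stillness,
    )


def decision_percentage(verdicts: Sequence[bool], ground_truth: Sequence[bool]) -> float:
    """Percent of truly-paralyzed days on which the system flags paralysis."""
    v = np.asarray(verdicts, dtype=bool)
    t = np.asarray(ground_truth, dtype=bool)
    if v.shape != t.shape:
        raise ValueError("verdict and truth sequences differ in length")
    n_true = int(t.sum())
    if n_true == 0:
        raise ValueError("decision percentage undefined: no truly paralyzed days")
    return 100.0 * int((v & t).sum()) / n_true


def d_prime(hit_rate: float, fa_rate: float, n_trials: int | None = None) -> float:
    """Signal-detection sensitivity: z(hit) - z(false alarm).

    Extreme rates (0 or 1) are corrected by the 1/(2N) rule, which
    requires ``n_trials``.
    """
    rates = []
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
        if r in (0.0, 1.0):
            if n_trials is None or n_trials < 1:
                raise ValueError("extreme rate needs n_trials >= 1 for 1/(2N) correction")
            r = 1.0 / (2 * n_trials) if r == 0.0 else 1.0 - 1.0 / (2 * n_trials)
        rates.append(r)
    return float(norm.ppf(rates[0]) - norm.ppf(rates[1]))


def score_timeline(
    verdicts: Sequence[bool],
    ground_truth: Sequence[bool],
) -> PerformanceReport:
    """Full performance report over a day-by-day timeline."""
    v = np.asarray(verdicts, dtype=bool)
    t = np.asarray(ground_truth, dtype=bool)
    if v.shape != t.shape:
        raise ValueError("verdict and truth sequences differ in length")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    hit = int((v & t).sum()) / n_pos if n_pos else 0.0
    fa = int((v & ~t).sum()) / n_neg if n_neg else 0.0
    n = max(n_pos, n_neg, 1)
    return PerformanceReport(
        decision_percentage=decision_percentage(v, t) if n_pos else float("nan"),
        hit_rate=hit,
        fa_rate=fa,
        d_prime=d_prime(hit, fa, n_trials=n),
    )
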