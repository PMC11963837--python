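"""Seeded synthetic fixtures: face videos with zone-wise programmable
motion, whisker traces with paralysis schedules, and motion-coupled spike
trains.

Every generator is deterministic given its seed and returns enough ground
truth to score the downstream analysis without any animal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from fapa.ephys import SpikeTrain
from fapa.video_io import FrameStack, LandmarkSet, ZoneConfig
from fapa.whisker import WhiskerTrace

__all__ = [
    "MotionSchedule",
    "WhiskerSimParams",
    "make_schedule",
    "session_names",
    "simulate_whisker_trace",
    "render_face_video",
    "simulate_timeline",
    "timeline_diff_summaries",
    "simulate_spikes",
]

N_SESSIONS = 23  # baseline; 0.5 h; 6 h; 24 h; days 2-20
ZONE_ORDER = ("A", "M", "P")
CRUSH_RAMP_SESSIONS = 3  # linear return to full motion over this many sessions


def session_names() -> List[str]:
    """Names of the 23 evaluation sessions in timeline order."""
    return ["day-1_baseline", "0.5h", "6h", "24h"] + [f"day{d}" for d in range(2, 21)]


@dataclass
class MotionSchedule:
    """Per-session motion amplitude multipliers for the three face zones.

    ``multipliers`` has shape (23, 3) in zone order A, M, P. The baseline
    session always has multiplier 1; the posterior zone never loses motion.
    """

    multipliers: np.ndarray
    injury_model: str
    recovery_session: int | None = None

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if self.multipliers.shape != (N_SESSIONS, len(ZONE_ORDER)):
            raise ValueError(
                f"multipliers must be ({N_SESSIONS}, {len(ZONE_ORDER)})"
            )
        if (self.multipliers < 0).any():
            raise ValueError("multipliers must be >= 0")
        if not np.allclose(self.multipliers[0], 1.0):
            raise ValueError("baseline session multiplier must be 1")

    @property
    def n_sessions(self) -> int:
        return self.multipliers.shape[0]

    @property
    def paralysis_labels(self) -> np.ndarray:
        """Ground-truth per-session paralysis labels."""
        labels = np.zeros(self.n_sessions, dtype=bool)
        if self.injury_model == "transection":
            labels[1:] = True
        elif self.injury_model == "crush":
            end = self.recovery_session if self.recovery_session is not None else self.n_sessions
            labels[1:end] = True
        return labels


@dataclass
class WhiskerSimParams:
    """Parameters of the sinusoidal whisker-sweep generator."""

    frequency_hz: float = 8.0
    amplitude_deg: float = 30.0
    noise_sd_deg: float = 0.0
    fps: float = 120.0
    duration_s: float = 2.0
    multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency_hz >= self.fps / 2:
            raise ValueError("frequency must be below Nyquist (fps/2)")
        if self.amplitude_deg < 0 or self.noise_sd_deg < 0 or self.multiplier < 0:
            raise ValueError("amplitude, noise, and multiplier must be >= 0")


def make_schedule(
    injury_model: str,
    recovery_session: int | None = None,
    residual: float = 0.0,
) -> MotionSchedule:
    """Build the standard 23-session motion schedule for one injury model.

    ``transection`` zeroes anterior/middle motion (down to ``residual``)
    from the first post-injury session onward with no recovery; ``crush``
    does the same until ``recovery_session`` (default: the day-12 session,
    index 14) and then ramps linearly back to 1 over 3 sessions; ``sham``
    keeps full motion throughout. The posterior zone always keeps full
    motion.
    """
    if injury_model not in {"transection", "crush", "sham"}:
        raise ValueError(f"unknown injury model {injury_model!r}")
    mult = np.ones((N_SESSIONS, 3))
    if injury_model == "transection":
        mult[1:, 0] = residual
        mult[1:, 1] = residual
    elif injury_model == "crush":
        if recovery_session is None:
            recovery_session = 14  # day 12 in the standard timeline
        if not 2 <= recovery_session < N_SESSIONS:
            raise ValueError("recovery_session must lie within the timeline")
        for s in range(1, N_SESSIONS):
            if s < recovery_session:
                level = residual
            else:
                ramp = (s - recovery_session + 1) / CRUSH_RAMP_SESSIONS
                level = min(1.0, max(ramp, residual))
            mult[s, 0] = level
            mult[s, 1] = level
    return MotionSchedule(multipliers=mult, injury_model=injury_model,
                          recovery_session=recovery_session if injury_model == "crush" else None)


def simulate_whisker_trace(params: WhiskerSimParams) -> Tuple[WhiskerTrace, Dict]:
    """Sinusoidal whisker sweep with optional Gaussian angle noise.

    angle(t) = amplitude * multiplier * (0.5 + 0.5 sin(2 pi f t)) + noise,
    rebased so the session minimum is 0. Ground truth records the
    programmed cycle count, amplitude, and frequency.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fps))
    t = np.arange(n) / params.fps
    amp = params.amplitude_deg * params.multiplier
    angles = amp * (0.5 + 0.5 * np.sin(2 * np.pi * params.frequency_hz * t))
    if params.noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, params.noise_sd_deg, n)
    trace = WhiskerTrace(angles=angles, fps=params.fps).rebase()
    truth = {
        "n_cycles": params.frequency_hz * params.duration_s,
        "amplitude_deg": amp,
        "frequency_hz": params.frequency_hz,
        "seed": params.seed,
        "noise_sd_deg": params.noise_sd_deg,
    }
    return trace, truth


def _zone_config(size: int) -> ZoneConfig:
    third = size // 3
    return ZoneConfig(zones={
        "A": (0, size, 0, third),
        "M": (0, size, third, 2 * third),
        "P": (0, size, 2 * third, size),
    })


def _landmarks(size: int) -> LandmarkSet:
    third = size // 3
    # eyes in the middle zone, nose points in the anterior zone
    return LandmarkSet(
        eye_1=(size * 0.25, third + third * 0.4),
        eye_2=(size * 0.25 + 8, third + third * 0.6),
        nose_1=(size * 0.55, third * 0.3),
        nose_2=(size * 0.7, third * 0.5),
    )


def _smooth_walk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth random walk in the plane, normalized to unit peak radius."""
    steps = rng.normal(0.0, 1.0, size=(n, 2))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    walk = ndimage.gaussian_filter1d(walk, sigma=3.0, axis=0)
    peak = np.abs(walk).max()
    if peak > 0:
        walk = walk / peak
    return walk


def render_face_video(
    schedule: MotionSchedule,
    session: int,
    size: int = 96,
    fps: float = 30.0,
    duration_s: float = 120.0,
    seed: int = 0,
    max_shift: float = 6.0,
) -> Tuple[FrameStack, Dict]:
    """Face-like textured video whose three zones move with scheduled gain.

    Each zone holds a fixed band-limited noise texture that is displaced
    per frame along a smooth random walk scaled by the zone's session
    multiplier (sub-pixel shifts, wrap-around padding). Four bright
    landmark dots (two "eye", two "nose") are stamped at fixed
    coordinates. Texture is tied to ``seed``; the walk is tied to
    ``(seed, session)`` so sessions differ but the face does not.
    """
    if size < 96:
        raise ValueError("size must be >= 96 so each zone holds a full HOG cell")
    if not 0 <= session < schedule.n_sessions:
        raise ValueError(f"session {session} outside schedule")
    n = int(round(duration_s * fps))
    zones = _zone_config(size)
    tex_rng = np.random.default_rng(seed)
    walk_rng = np.random.default_rng((seed, session))

    textures = {}
    for label, (r0, r1, c0, c1) in zones.zones.items():
        raw = tex_rng.uniform(size=(r1 - r0, c1 - c0))
        tex = ndimage.gaussian_filter(raw, sigma=2.0, mode="wrap")
        tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
        textures[label] = 0.1 + 0.8 * tex

    mult = dict(zip(ZONE_ORDER, schedule.multipliers[session]))
    walks = {label: _smooth_walk(walk_rng, n) for label in ZONE_ORDER}

    frames = np.empty((n, size, size))
    for i in range(n):
        frame = np.empty((size, size))
        for label, (r0, r1, c0, c1) in zones.zones.items():
            amp = mult[label] * max_shift
            if amp == 0 or i == 0:
                patch = textures[label]
            else:
                shift = walks[label][i] * amp
                patch = ndimage.shift(textures[label], shift, order=1, mode="wrap")
            frame[r0:r1, c0:c1] = patch
        frames[i] = frame

    marks = _landmarks(size)
    for r, c in marks.as_array():
        ri, ci = int(r), int(c)
        frames[:, ri:ri + 2, ci:ci + 2] = 1.0

    stack = FrameStack(frames=np.clip(frames, 0.0, 1.0), fps=fps,
                       source_id=f"synthetic:{schedule.injury_model}:s{session}")
    truth = {
        "zones": zones,
        "landmarks": marks,
        "multipliers": mult,
        "max_shift": max_shift,
        "seed": seed,
        "session": session,
    }
    return stack, truth


def simulate_timeline(
    injury_model: str,
    seed: int = 0,
    recovery_session: int | None = None,
    residual: float = 0.0,
) -> Tuple[MotionSchedule, np.ndarray]:
    """Standard 23-session schedule plus ground-truth paralysis labels."""
    schedule = make_schedule(injury_model, recovery_session=recovery_session,
                             residual=residual)
    return schedule, schedule.paralysis_labels


def timeline_diff_summaries(
    schedule: MotionSchedule,
    seed: int = 0,
    size: int = 96,
    fps: float = 10.0,
    duration_s: float = 5.0,
    max_shift: float = 6.0,
    keep_frame_diffs: bool = False,
):
    """Render every session of a timeline and run the HOG-Diff pipeline.

    Returns ``(summaries, frame_diffs)``: per-session per-zone mean Diff
    values (dict zone -> length-23 array) and, when requested, the raw
    per-frame Diff series per session and zone. Defaults are scaled down
    from the full 2-min 30-fps protocol to keep test runtimes short; the
    construction is identical at full scale.
    """
    from fapa.hog import HOGParams, hog_diff_series, hog_series, session_summary
    from fapa.video_io import crop_zone_stack

    params = HOGParams()
    summaries: Dict[str, List[float]] = {z: [] for z in ZONE_ORDER}
    frame_diffs: List[Dict[str, np.ndarray]] = []
    for s in range(schedule.n_sessions):
        stack, truth = render_face_video(schedule, s, size=size, fps=fps,
                                         duration_s=duration_s, seed=seed,
                                         max_shift=max_shift)
        crops = crop_zone_stack(stack, truth["zones"])
        per_zone: Dict[str, np.ndarray] = {}
        for zone in ZONE_ORDER:
            diffs = hog_diff_series(hog_series(crops[zone], params, zone=zone))
            summaries[zone].append(session_summary(diffs))
            if keep_frame_diffs:
                per_zone[zone] = diffs.values
        if keep_frame_diffs:
            frame_diffs.append(per_zone)
    out = {z: np.asarray(v) for z, v in summaries.items()}
    return (out, frame_diffs) if keep_frame_diffs else (out, None)


def render_whisker_frames(
    angles_deg: Sequence[float],
    size: int = 64,
    insertion: Tuple[float, float] | None = None,
    arm: float = 20.0,
    marker_half: int = 2,
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Grayscale frames with a painted-marker blob at each programmed angle.

    The square marker (intensity 1 on a black background) is centered
    ``arm`` pixels from the insertion point at the requested angle
    (counterclockwise from the +x axis, rows growing downward). Returns
    ``(frames, insertion)``; the centroid-derived angle of each frame
    matches the programmed one up to pixel quantization.
    """
    if insertion is None:
        insertion = (size * 0.75, size * 0.25)
    ins_row, ins_col = insertion
    n = len(angles_deg)
    frames = np.zeros((n, size, size))
    for i, ang in enumerate(np.asarray(angles_deg, dtype=float)):
        rad = np.radians(ang)
        row = ins_row - arm * np.sin(rad)
        col = ins_col + arm * np.cos(rad)
        r0 = int(round(row)) - marker_half
        c0 = int(round(col)) - marker_half
        side = 2 * marker_half + 1
        if r0 < 0 or c0 < 0 or r0 + side > size or c0 + side > size:
            raise ValueError(f"marker at angle {ang} deg leaves the {size}px frame")
        frames[i, r0:r0 + side, c0:c0 + side] = 1.0
    return frames, insertion


def simulate_spikes(
    rate_base: float,
    motion_trace: Sequence[float],
    gain: float,
    lag_s: float,
    duration_s: float,
    seed: int = 0,
    motion_fps: float = 30.0,
    unit_id: str = "sim",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes: rate(t) = base + gain * motion(t - lag).

    Motion is linearly interpolated on its own clock and treated as 0
    outside its support. A negative instantaneous rate anywhere is an
    error.
    """
    motion = np.asarray(motion_trace, dtype=float)
    dt = 1.0 / motion_fps
    t = np.arange(int(round(duration_s * motion_fps))) * dt
    motion_t = np.arange(len(motion)) * dt
    shifted = np.interp(t - lag_s, motion_t, motion, left=0.0, right=0.0)
    rate = rate_base + gain * shifted
    if (rate < 0).any():
        raise ValueError("negative instantaneous firing rate; reduce |gain|")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * dt)
    times = np.repeat(t, counts) + rng.uniform(0.0, dt, int(counts.sum()))
    times.sort()
    times = times[times <= duration_s]
    return SpikeTrain(spike_times=times, unit_id=unit_id,
                      recording_duration=duration_s)
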