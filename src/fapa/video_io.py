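"""Frame extraction, landmark-based alignment, and face-zone cropping.

Conventions: pixel coordinates are 0-based ``(row, col)`` with the origin
at the top-left; zone rectangles are half-open intervals
``[row_start, row_end) x [col_start, col_end)``; intensities live in
``[0, 1]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from skimage.transform import AffineTransform, SimilarityTransform, warp

__all__ = [
    "FrameStack",
    "LandmarkSet",
    "ZoneConfig",
    "extract_frames",
    "estimate_alignment",
    "align_frames",
    "crop_zones",
    "DecodeError",
    "EmptyInputError",
]

#: ITU-R BT.601 luminance weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

ZONE_LABELS = ("A", "M", "P")


class DecodeError(RuntimeError):
    """Raised when a video file cannot be decoded."""


class EmptyInputError(ValueError):
    """Raised when a frame directory contains no readable images."""


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an image to float grayscale in [0, 1] (BT.601 luminance)."""
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3] @ LUMA_WEIGHTS
    frame = frame.astype(float)
    if frame.size and frame.max() > 1.0:
        frame = frame / 255.0
    return np.clip(frame, 0.0, 1.0)


@dataclass
class FrameStack:
    """Ordered grayscale frames with a common geometry and frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with values in [0, 1].
    fps
        Acquisition rate in frames per second (> 0).
    source_id
        Free-text provenance tag.
    """

    frames: np.ndarray
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n, height, width); got shape {self.frames.shape}"
            )
        if len(self.frames) < 1:
            raise ValueError("FrameStack requires at least one frame")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1]; range [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def timestamps(self) -> np.ndarray:
        """Frame times in seconds, ``index / fps``."""
        return np.arange(len(self.frames)) / self.fps


@dataclass(frozen=True)
class LandmarkSet:
    """Four anatomical reference points, two on the eye and two on the nose.

    Each point is a ``(row, col)`` pixel coordinate.
    """

    eye_1: Tuple[float, float]
    eye_2: Tuple[float, float]
    nose_1: Tuple[float, float]
    nose_2: Tuple[float, float]

    def as_array(self) -> np.ndarray:
        """Points as a (4, 2) array of (row, col), fixed label order."""
        return np.array([self.eye_1, self.eye_2, self.nose_1, self.nose_2], dtype=float)

    def validate(self, shape: Tuple[int, int]) -> None:
        pts = self.as_array()
        h, w = shape
        if (pts[:, 0] < 0).any() or (pts[:, 0] >= h).any() \
                or (pts[:, 1] < 0).any() or (pts[:, 1] >= w).any():
            raise ValueError(f"landmarks outside {h}x{w} frame bounds: {pts.tolist()}")
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("landmark points must be pairwise distinct")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "LandmarkSet":
        return cls(
            eye_1=tuple(mapping["eye_1"]),
            eye_2=tuple(mapping["eye_2"]),
            nose_1=tuple(mapping["nose_1"]),
            nose_2=tuple(mapping["nose_2"]),
        )


@dataclass(frozen=True)
class ZoneConfig:
    """Anterior / middle / posterior crop rectangles.

    Each zone is ``(row_start, row_end, col_start, col_end)``, half-open.
    """

    zones: Mapping[str, Tuple[int, int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.zones) != set(ZONE_LABELS):
            raise ValueError(f"zone labels must be exactly {set(ZONE_LABELS)}, got {set(self.zones)}")
        for label, (r0, r1, c0, c1) in self.zones.items():
            if not (r0 < r1 and c0 < c1):
                raise ValueError(f"zone {label} rectangle {r0, r1, c0, c1} is empty")
            if r0 < 0 or c0 < 0:
                raise ValueError(f"zone {label} has negative start")

    def validate(self, shape: Tuple[int, int]) -> None:
        h, w = shape
        for label, (r0, r1, c0, c1) in self.zones.items():
            if r1 > h or c1 > w:
                raise ValueError(f"zone {label} {r0, r1, c0, c1} exceeds {h}x{w} frame")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[int]]) -> "ZoneConfig":
        return cls(zones={k: tuple(int(x) for x in v) for k, v in mapping.items()})


def _read_image_dir(path: Path) -> list:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not files:
        raise EmptyInputError(f"no image files found in {path}")
    return [iio.imread(f) for f in files]


def _read_video(path: Path) -> list:
    import imageio.v3 as iio

    try:
        return list(iio.imiter(path))
    except Exception as exc:  # noqa: BLE001 - backend errors vary
        raise DecodeError(f"could not decode video {path}: {exc}") from exc


def extract_frames(video_path: os.PathLike | str, fps_override: float | None = None) -> FrameStack:
    """Read a video file or a lexically ordered image directory as a FrameStack.

    Parameters
    ----------
    video_path
        Path to an MP4/AVI file or to a directory of PNG/TIFF frames.
    fps_override
        Frame rate to stamp on the output; required for directories if the
        default of 30 fps is wrong, optional for videos with metadata.
    """
    path = Path(video_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        raw = _read_image_dir(path)
        fps = fps_override if fps_override is not None else 30.0
    else:
        raw = _read_video(path)
        if not raw:
            raise DecodeError(f"video {path} decoded to zero frames")
        fps = fps_override
        if fps is None:
            try:
                import imageio.v3 as iio

                meta = iio.immeta(path)
                fps = float(meta.get("fps", 30.0))
            except Exception:  # noqa: BLE001
                fps = 30.0
    frames = np.stack([to_grayscale(f) for f in raw])
    return FrameStack(frames=frames, fps=float(fps), source_id=str(path))


def _points_xy(landmarks: LandmarkSet) -> np.ndarray:
    # skimage transforms operate on (x, y) = (col, row)
    return landmarks.as_array()[:, ::-1]


def estimate_alignment(
    landmarks: LandmarkSet,
    reference: LandmarkSet,
    family: str = "similarity",
):
    """Least-squares transform mapping ``landmarks`` onto ``reference``.

    Returns a skimage transform (SimilarityTransform by default; pass
    ``family="affine"`` for a full affine fit). The similarity fit is the
    closed-form Procrustes/Umeyama solution: rotation + translation +
    uniform scale.
    """
    src = _points_xy(landmarks)
    dst = _points_xy(reference)
    # coincident (or near-coincident) landmarks cannot anchor a transform
    for pts, name in ((src, "landmarks"), (dst, "reference")):
        spread = np.linalg.norm(pts - pts.mean(axis=0), axis=1).max()
        if spread < 1e-6:
            raise ValueError(f"degenerate {name}: points are coincident")
    if family == "similarity":
        cls = SimilarityTransform
    elif family == "affine":
        cls = AffineTransform
    else:
        raise ValueError(f"unknown transform family {family!r}")
    if hasattr(cls, "from_estimate"):
        tform = cls.from_estimate(src, dst)
        ok = bool(tform)
    else:  # scikit-image < 0.26
        tform = cls()
        ok = tform.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise ValueError("degenerate landmark configuration: transform is singular")
    return tform


def alignment_parameters(tform) -> Dict[str, float]:
    """Human-readable parameters of a similarity transform.

    ``rotation_deg`` is the counterclockwise angle in conventional (x up)
    terms applied in image (x right, y down) coordinates; ``translation``
    is reported as ``(row, col)``.
    """
    return {
        "rotation_deg": float(np.degrees(tform.rotation)),
        "scale": float(tform.scale),
        "translation_row": float(tform.translation[1]),
        "translation_col": float(tform.translation[0]),
    }


def align_frames(
    stack: FrameStack,
    landmarks: LandmarkSet,
    reference: LandmarkSet,
    family: str = "similarity",
    output_shape: Tuple[int, int] | None = None,
    order: int = 1,
) -> FrameStack:
    """Warp every frame so that ``landmarks`` land on ``reference``.

    One transform is estimated for the whole stack (per-session alignment);
    call per frame with single-frame stacks for per-frame mode. Out-of-field
    pixels are filled with 0. ``order=1`` is bilinear; ``order=0`` selects
    nearest-neighbor resampling.
    """
    landmarks.validate(stack.shape)
    tform = estimate_alignment(landmarks, reference, family=family)
    shape = output_shape if output_shape is not None else stack.shape
    warped = np.stack(
        [
            warp(f, tform.inverse, output_shape=shape, order=order,
                 mode="constant", cval=0.0, preserve_range=True)
            for f in stack.frames
        ]
    )
    return FrameStack(frames=np.clip(warped, 0.0, 1.0), fps=stack.fps,
                      source_id=stack.source_id)


def crop_zones(frame: np.ndarray, zones: ZoneConfig) -> Dict[str, np.ndarray]:
    """Cut a frame into the anterior/middle/posterior sub-arrays."""
    frame = np.asarray(frame)
    zones.validate(frame.shape[:2])
    return {
        label: frame[r0:r1, c0:c1]
        for label, (r0, r1, c0, c1) in zones.zones.items()
    }


def crop_zone_stack(stack: FrameStack, zones: ZoneConfig) -> Dict[str, FrameStack]:
    """Apply :func:`crop_zones` to every frame of a stack."""
    zones.validate(stack.shape)
    out: Dict[str, FrameStack] = {}
    for label, (r0, r1, c0, c1) in zones.zones.items():
        out[label] = FrameStack(
            frames=stack.frames[:, r0:r1, c0:c1],
            fps=stack.fps,
            source_id=f"{stack.source_id}[{label}]",
        )
    return out
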