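"""Video decoding and preprocessing for motion-energy triage.

Recordings are represented as grayscale tensors with intensities in [0, 1].
Two preprocessing steps precede the variation filters: removal of leading
frames (the camera prints a time stamp on the first frame and the light is
unstable while it starts up) and spatio-temporal average pooling, which
suppresses detector noise and small vegetation/water flicker while preserving
the motion of a large, slow animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VideoTensor",
    "PreprocessConfig",
    "DecodeError",
    "DegenerateVideoError",
    "load_video",
    "drop_leading_frames",
    "downsample",
    "apply_timestamp_mask",
    "preprocess",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


class DecodeError(RuntimeError):
    """A video file or frame directory could not be decoded."""


class DegenerateVideoError(ValueError):
    """An operation would leave a video with no frames."""


@dataclass(frozen=True)
class VideoTensor:
    """A grayscale video as a float array of shape (t, height, width).

    Intensities lie in [0, 1].  ``frame_period`` is the time between
    consecutive frames in seconds; ``duration_s`` is therefore
    ``frame_period * n_frames``.
    """

    frames: np.ndarray
    frame_period: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, y, x); got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise DegenerateVideoError(f"empty video tensor: shape {arr.shape}")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.frame_period * self.n_frames


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Defaults follow the standard pipeline: drop the first two frames, then
    average-pool by 5 along x and y and by 10 along t.  ``timestamp_mask``,
    if given, is a pixel rectangle (x0, y0, x1, y1), 0-based half-open, whose
    content is replaced by the frame's spatial mean before filtering, for
    cameras that overlay a stamp on every frame.
    """

    drop_leading_frames: int = 2
    pool_x: int = 5
    pool_y: int = 5
    pool_t: int = 10
    grayscale_mode: str = "mean"  # "mean" (mean of channels) or "luma"
    timestamp_mask: Optional[tuple[int, int, int, int]] = None
    reduction: str = "mean_minus_min"
    normalize_per_pixel: bool = False

    def __post_init__(self) -> None:
        if self.drop_leading_frames < 0:
            raise ValueError("drop_leading_frames must be non-negative")
        if min(self.pool_x, self.pool_y, self.pool_t) < 1:
            raise ValueError("pooling factors must be >= 1")
        if self.grayscale_mode not in ("mean", "luma"):
            raise ValueError("grayscale_mode must be 'mean' or 'luma'")


def _to_grayscale(frame: np.ndarray, mode: str) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3:
        rgb = frame[..., :3].astype(np.float64)
        if mode == "luma":
            return rgb @ np.array([0.2126, 0.7152, 0.0722])
        return rgb.mean(axis=-1)
    raise DecodeError(f"cannot interpret frame of shape {frame.shape}")


def _rescale(frames: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        return frames / float(np.iinfo(dtype).max)
    # float input: assume already on [0,1] unless it clearly is not
    top = frames.max(initial=0.0)
    if top > 1.0:
        return frames / 255.0
    return frames


def load_video(
    path: str | Path,
    grayscale_mode: str = "mean",
    frame_period: Optional[float] = None,
) -> VideoTensor:
    """Decode a video file or an ordered image-sequence directory.

    A directory is read as one frame per image file in lexicographic order.
    A single file is decoded with imageio (multi-frame TIFF/GIF natively; AVI
    and other containers only when an ffmpeg-capable plugin is installed).
    Multi-channel frames are collapsed to one channel by ``grayscale_mode``
    and intensities are rescaled to [0, 1].

    ``frame_period`` overrides the container's frame rate; when the container
    carries none, it defaults to 1 s per frame.
    """
    path = Path(path)
    import imageio.v3 as iio

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise DecodeError(f"no image frames found in directory {path}")
        raw = []
        for f in files:
            try:
                raw.append(iio.imread(f))
            except Exception as exc:  # pragma: no cover - backend specific
                raise DecodeError(f"could not decode frame {f}: {exc}") from exc
        shapes = {r.shape for r in raw}
        if len(shapes) != 1:
            raise DecodeError(f"inconsistent frame shapes in {path}: {shapes}")
        stack = np.stack(raw)
    else:
        if not path.exists():
            raise DecodeError(f"no such file: {path}")
        try:
            stack = np.asarray(iio.imread(path, index=None))
        except Exception as exc:
            raise DecodeError(f"could not decode video {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 3 and stack.shape[-1] in (3, 4) and stack.shape[0] > 4:
            # a single RGB(A) image: one frame
            stack = stack[None]
        if frame_period is None:
            try:
                meta = iio.immeta(path)
                fps = meta.get("fps")
                if fps:
                    frame_period = 1.0 / float(fps)
            except Exception:
                pass

    if stack.shape[0] == 0:
        raise DecodeError(f"video {path} contains zero frames")

    dtype = stack.dtype
    gray = np.stack([_to_grayscale(f, grayscale_mode) for f in stack])
    gray = _rescale(gray, dtype)
    return VideoTensor(
        frames=np.clip(gray, 0.0, 1.0),
        frame_period=frame_period if frame_period is not None else 1.0,
        source_id=path.name,
    )


def drop_leading_frames(v: VideoTensor, n: int) -> VideoTensor:
    """Remove the first ``n`` frames (time stamp / startup instability)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= v.n_frames:
        raise DegenerateVideoError(
            f"cannot drop {n} frames from a {v.n_frames}-frame video"
        )
    if n == 0:
        return v
    return replace(v, frames=v.frames[n:])


def _pool_axis(arr: np.ndarray, factor: int, axis: int) -> np.ndarray:
    """Average-pool one axis by ``factor``; a trailing partial block is
    averaged over its actual size."""
    if factor == 1:
        return arr
    n = arr.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(arr, starts, axis=axis)
    sizes = np.minimum(starts + factor, n) - starts
    shape = [1] * arr.ndim
    shape[axis] = len(starts)
    return sums / sizes.reshape(shape)


def downsample(v: VideoTensor, cfg: PreprocessConfig) -> VideoTensor:
    """Spatio-temporal average pooling by (pool_x, pool_y, pool_t).

    Output cell (k, j, i) is the arithmetic mean of the input block
    [k*pool_t, (k+1)*pool_t) x [j*pool_y, (j+1)*pool_y) x [i*pool_x,
    (i+1)*pool_x); trailing partial blocks are averaged over their actual
    size, so no end-of-clip motion is discarded.  The frame period grows by
    pool_t.
    """
    out = _pool_axis(v.frames, cfg.pool_t, axis=0)
    out = _pool_axis(out, cfg.pool_y, axis=1)
    out = _pool_axis(out, cfg.pool_x, axis=2)
    return replace(v, frames=out, frame_period=v.frame_period * cfg.pool_t)


def apply_timestamp_mask(
    v: VideoTensor, rect: tuple[int, int, int, int]
) -> VideoTensor:
    """Replace a pixel rectangle (x0, y0, x1, y1; 0-based, half-open) with the
    per-frame spatial mean, neutralising a burnt-in stamp overlay."""
    x0, y0, x1, y1 = rect
    if not (0 <= x0 < x1 <= v.width and 0 <= y0 < y1 <= v.height):
        raise ValueError(f"mask rectangle {rect} outside frame {v.width}x{v.height}")
    frames = v.frames.copy()
    frames[:, y0:y1, x0:x1] = frames.mean(axis=(1, 2))[:, None, None]
    return replace(v, frames=frames)


def preprocess(v: VideoTensor, cfg: PreprocessConfig) -> VideoTensor:
    """Full preprocessing chain: optional stamp mask, leading-frame removal,
    then average pooling."""
    if cfg.timestamp_mask is not None:
        v = apply_timestamp_mask(v, cfg.timestamp_mask)
    v = drop_leading_frames(v, cfg.drop_leading_frames)
    return downsample(v, cfg)
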