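"""Frame-variation filters and the scalar D statistic.

Both filters reduce a video to a per-time-step "motion energy" series d(t):

* Filter 1 measures each frame's squared distance from the time-averaged
  frame: d(t) = sum over pixels of (A(x,y,t) - mean_t A(x,y,t))^2.
* Filter 2 measures the squared distance between consecutive frames:
  d(t) = sum over pixels of (A(x,y,t+1) - A(x,y,t))^2.

The discrimination score is D = mean(d) - min(d).  Subtracting the per-video
minimum removes the baseline variation of the environment (rippling water or
moving vegetation raises every d(t), a passing animal raises only some), so
recordings from dynamic and static scenes become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import DegenerateVideoError, PreprocessConfig, VideoTensor, preprocess

__all__ = [
    "FrameVariationSeries",
    "DStatistic",
    "METHODS",
    "REDUCTIONS",
    "frame_variation_filter1",
    "frame_variation_filter2",
    "frame_variation",
    "d_statistic",
    "compute_d",
]

METHODS = ("filter1", "filter2")
REDUCTIONS = ("mean_minus_min", "max_minus_min", "sum_minus_n_min")


@dataclass(frozen=True)
class FrameVariationSeries:
    """The motion-energy series d(t) of one recording under one filter."""

    values: np.ndarray
    method: str
    source_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("d(t) must be a non-empty 1-D sequence")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class DStatistic:
    """The scalar pixel-variation score of one recording."""

    value: float
    method: str
    source_id: str = ""


def _pixel_sums(sq: np.ndarray) -> np.ndarray:
    # sum squared deviations over the spatial axes in float64; numpy's
    # pairwise summation keeps the accumulation error well below the 1e-9
    # relative tolerance the brute-force oracle is compared at
    return sq.reshape(sq.shape[0], -1).sum(axis=1)


def frame_variation_filter1(v: VideoTensor) -> FrameVariationSeries:
    """d(t): squared distance of each frame to the time-averaged frame."""
    mean_frame = v.frames.mean(axis=0)
    d = _pixel_sums((v.frames - mean_frame) ** 2)
    return FrameVariationSeries(values=d, method="filter1", source_id=v.source_id)


def frame_variation_filter2(v: VideoTensor) -> FrameVariationSeries:
    """d(t): squared distance between consecutive frames (T-1 values)."""
    if v.n_frames < 2:
        raise DegenerateVideoError("filter2 needs at least 2 frames")
    d = _pixel_sums(np.diff(v.frames, axis=0) ** 2)
    return FrameVariationSeries(values=d, method="filter2", source_id=v.source_id)


_FILTERS = {"filter1": frame_variation_filter1, "filter2": frame_variation_filter2}


def frame_variation(v: VideoTensor, method: str) -> FrameVariationSeries:
    """Dispatch to filter1 or filter2 by name."""
    try:
        return _FILTERS[method](v)
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def d_statistic(
    s: FrameVariationSeries, reduction: str = "mean_minus_min"
) -> DStatistic:
    """Reduce d(t) to the scalar D.

    The default reduction is mean(d) - min(d): the minimum is the per-video
    baseline, and dividing by the series length makes D insensitive to clip
    duration.  Alternatives (max - min, sum - n*min) are kept behind the
    ``reduction`` switch.
    """
    d = s.values
    if reduction == "mean_minus_min":
        value = float(d.mean() - d.min())
    elif reduction == "max_minus_min":
        value = float(d.max() - d.min())
    elif reduction == "sum_minus_n_min":
        value = float(d.sum() - d.size * d.min())
    else:
        raise ValueError(f"unknown reduction {reduction!r}; expected {REDUCTIONS}")
    # clamp the tiny negative round-off a subtraction of near-equal sums can leave
    return DStatistic(value=max(value, 0.0), method=s.method, source_id=s.source_id)


def compute_d(
    v: VideoTensor, method: str, cfg: PreprocessConfig | None = None
) -> DStatistic:
    """Full pipeline: mask/drop/downsample, filter, reduce to D.

    With ``cfg.normalize_per_pixel`` the squared distances are divided by the
    pooled pixel count, making D comparable across frame resolutions.
    """
    cfg = cfg or PreprocessConfig()
    proc = preprocess(v, cfg)
    series = frame_variation(proc, method)
    if cfg.normalize_per_pixel:
        series = FrameVariationSeries(
            values=series.values / (proc.height * proc.width),
            method=series.method,
            source_id=series.source_id,
        )
    return d_statistic(series, cfg.reduction)
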