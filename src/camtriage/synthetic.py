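"""Synthetic inputs at two levels of realism.

``generate_scene`` builds whole videos for end-to-end filter tests: a static
noisy background (infrared night footage), optionally a water-like rippling
region (the "wet" condition), and optionally a large, slow, translating
bright rectangle standing in for the animal.  The filters are shape-agnostic,
so a rectangle exercises them as well as an animal silhouette would.

``generate_population`` skips the video stage and draws per-recording D
values directly from right-skewed (log-normal) class distributions, which is
what the classification, ROC and bootstrap stages consume.  Presets encode
the ordering the method relies on: targets score higher than non-targets on
average, and wet backgrounds push the non-target distribution up, shrinking
the separation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classification import LabeledRecording
from .video_io import VideoTensor

__all__ = [
    "SceneConfig",
    "PopulationConfig",
    "generate_scene",
    "generate_population",
    "DRY_POPULATION",
    "WET_POPULATION",
]

# minimum object width (as a fraction of frame width) for a scene to count as
# a target recording: a beaver-sized animal fills a substantial part of the
# frame, small rodents and birds do not
TARGET_SIZE_FRACTION = 0.15


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic clip.

    Defaults produce a desk-scale clip (96x64, 60 frames) so that full
    end-to-end suites stay fast; field-scale 720x480 is just a config away.
    """

    width: int = 96
    height: int = 64
    n_frames: int = 60
    background: str = "dry"  # "dry" or "wet"
    background_noise_sd: float = 0.02
    wet_ripple_amplitude: float = 0.06
    wet_region_fraction: float = 0.4
    object_present: bool = False
    object_size_fraction: float = 0.25
    object_speed: float = 1.0  # pixels per frame
    object_contrast: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in ("dry", "wet"):
            raise ValueError("background must be 'dry' or 'wet'")
        if self.background == "dry" and self.wet_ripple_amplitude != 0.0:
            object.__setattr__(self, "wet_ripple_amplitude", 0.0)
        if not 0 < self.object_size_fraction <= 1:
            raise ValueError("object_size_fraction must be in (0, 1]")
        if not 0 <= self.wet_region_fraction <= 1:
            raise ValueError("wet_region_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PopulationConfig:
    """Log-scale parameters of the two D-value class distributions.

    Class sizes default to the field-study composition: 1043 target and 948
    non-target recordings (553 empty plus 395 of other species).
    """

    n_target: int = 1043
    n_nontarget: int = 948
    target_log_mean: float = 1.0
    target_log_sd: float = 0.6
    nontarget_log_mean: float = -0.8
    nontarget_log_sd: float = 0.6
    condition: str = "dry"
    seed: int = 0


#: presets differing only in how dynamic the empty background is: wet scenes
#: raise the non-target D distribution toward the targets' (harder problem)
DRY_POPULATION = PopulationConfig(condition="dry")
WET_POPULATION = PopulationConfig(
    condition="wet", nontarget_log_mean=0.2, nontarget_log_sd=0.7
)


def generate_scene(cfg: SceneConfig) -> tuple[VideoTensor, str]:
    """Render one clip; returns (video, label).

    The background is mid-gray plus i.i.d. Gaussian pixel noise.  Wet scenes
    add a temporally drifting sinusoidal ripple field over the bottom
    ``wet_region_fraction`` of the frame.  If present, the object is a bright
    rectangle ``object_size_fraction`` of the frame wide (half as tall)
    translating left to right at ``object_speed``, wrapping at the edge.
    The label is "target" only when the object is at least beaver-sized
    (width fraction >= 0.15).  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_frames)

    frames = np.full((cfg.n_frames, cfg.height, cfg.width), 0.5)
    if cfg.background_noise_sd > 0:
        frames += rng.normal(0.0, cfg.background_noise_sd, size=frames.shape)

    if cfg.background == "wet" and cfg.wet_region_fraction > 0:
        y0 = int(round(cfg.height * (1 - cfg.wet_region_fraction)))
        x = np.arange(cfg.width)
        phase = rng.uniform(0, 2 * np.pi)
        # travelling wave: spatial wavelength ~12 px, drifting ~0.8 rad/frame
        ripple = cfg.wet_ripple_amplitude * np.sin(
            2 * np.pi * x[None, None, :] / 12.0 + 0.8 * t[:, None, None] + phase
        )
        frames[:, y0:, :] += ripple

    if cfg.object_present:
        obj_w = max(1, int(round(cfg.object_size_fraction * cfg.width)))
        obj_h = max(1, obj_w // 2)
        y_top = (cfg.height - obj_h) // 2
        x_start = rng.integers(0, cfg.width)
        for k in range(cfg.n_frames):
            x_left = int(x_start + cfg.object_speed * k) % cfg.width
            cols = (x_left + np.arange(obj_w)) % cfg.width  # wraps around
            frames[k, y_top : y_top + obj_h, cols] += cfg.object_contrast

    video = VideoTensor(
        frames=np.clip(frames, 0.0, 1.0),
        frame_period=1.0,
        source_id=f"scene-{cfg.seed}",
    )
    label = (
        "target"
        if cfg.object_present and cfg.object_size_fraction >= TARGET_SIZE_FRACTION
        else "non-target"
    )
    return video, label


def generate_population(
    cfg: PopulationConfig = DRY_POPULATION, methods: tuple[str, ...] = ("filter1",)
) -> list[LabeledRecording]:
    """Draw a labeled population of D values (15 s clips, sequential ids).

    The same draw is attached under every requested method name, so the
    population can feed either filter's downstream analysis.
    """
    if cfg.n_target < 1 or cfg.n_nontarget < 1:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    d_target = rng.lognormal(cfg.target_log_mean, cfg.target_log_sd, cfg.n_target)
    d_non = rng.lognormal(
        cfg.nontarget_log_mean, cfg.nontarget_log_sd, cfg.n_nontarget
    )
    recordings = []
    for i, d in enumerate(d_target):
        recordings.append(
            LabeledRecording(
                source_id=f"rec{i:05d}",
                d_values={m: float(d) for m in methods},
                label="target",
                condition=cfg.condition,
            )
        )
    for j, d in enumerate(d_non):
        recordings.append(
            LabeledRecording(
                source_id=f"rec{cfg.n_target + j:05d}",
                d_values={m: float(d) for m in methods},
                label="non-target",
                condition=cfg.condition,
            )
        )
    return recordings
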