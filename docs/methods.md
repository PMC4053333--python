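# Methods

## Model and assumptions

`camtriage` assumes the study species is large relative to everything else
that moves in the frame, and moves slowly enough to survive temporal
averaging. Under that assumption the total pixel variation of a clip — not
its spatial pattern — separates clips worth watching from clips that are
not. No shape, texture or species recognition is attempted; the method
cannot distinguish the study species from another animal of similar size,
and it is explicitly a pre-screening step, not a classifier of species.

A recording is a grayscale intensity tensor A(x, y, t) on [0, 1]
(`VideoTensor`, stored as a float64 array indexed (t, y, x)). Infrared night
footage is effectively monochrome; when a decoder delivers three channels
they are collapsed by the mean of channels (default) or Rec.-709 luma.
Intensities are normalised to [0, 1] from the container's bit depth, so D
values are scale-consistent across 8- and 16-bit sources.

## Preprocessing

1. **Leading-frame removal** (default 2): the first frame carries the
   camera's burnt-in time stamp and the first two show start-up light
   instability; both would register as spurious motion. The count is
   configurable; an optional rectangular mask additionally replaces a
   continuously printed stamp region with the frame's spatial mean.
   Frames are dropped *before* pooling, matching the order of the two
   manipulations in the processing pipeline.
2. **Spatio-temporal average pooling** (defaults 5×5 in space, 10 in time):
   suppresses detector noise, vegetation flutter and water reflections.
   A non-divisible tail block is averaged over its actual size rather than
   discarded, so end-of-clip motion still counts; output extents are
   ceil(extent/factor). Pooling by (1, 1, 1) is the identity, and when every
   extent divides its factor the global mean is conserved exactly.

## The filters and the D statistic

Filter 1 scores each frame by its squared Euclidean distance to the
time-averaged frame; Filter 2 scores each frame transition by the squared
distance between consecutive frames (one fewer value). Both series are
non-negative, invariant under global additive intensity shifts, and scale
quadratically when intensities are scaled — properties the test suite
checks against naive triple-loop implementations (relative error ≤ 1e-9;
float64 pairwise summation keeps accumulation error far below that).

The reduction to a scalar is `D = mean(d) − min(d)`. The minimum is the
per-video baseline: a uniformly dynamic background (rippling water) raises
every d(t) and is subtracted away, while an animal crossing part of the clip
raises only some d(t) and survives. Normalising by the series length (mean,
not sum) makes D insensitive to clip duration. Two alternative reductions
(`max_minus_min`, `sum_minus_n_min`) sit behind a config switch because the
reduction is the one genuinely open design choice in the pipeline; the
default is the least length-sensitive of the three. Sums over pixels are
deliberately *not* divided by pixel count — thresholds are dataset-relative,
so a fixed normalisation would be absorbed by the threshold — but a
per-pixel normalisation flag exists for cross-resolution comparisons.

Degenerate inputs: Filter 2 requires at least two (pooled) frames;
a constant video gives D = 0 under both filters; tiny negative round-off
from the mean−min subtraction is clamped to 0.

## Classification, ROC and the operating point

The positive class is the **non-target** recording: discarding empty footage
is the success being counted. TP-rate = discarded non-target / all
non-target; FP-rate = discarded target / all target.

* **Tie-break:** discard iff D < threshold, strictly. A tie is kept for
  inspection — the conservative direction, since the asymmetric cost is
  losing target footage.
* **Candidate thresholds** are midpoints between consecutive distinct D
  values plus sentinels below the minimum and above the maximum, so every
  achievable confusion matrix appears exactly once and achieved rates are
  stable to infinitesimal threshold perturbation. Both rates are
  non-decreasing in the threshold and the sentinels pin the curve to (0, 0)
  and (1, 1).
* **Operating point:** the largest candidate threshold whose FP-rate is ≤
  the tolerated loss (maximise discarding subject to the cap), not the
  threshold nearest the cap. If even the smallest non-trivial threshold
  overshoots, the below-minimum sentinel is returned with rates (0, 0).
* **Time savings** = (number discarded) × clip duration / 60: every
  discarded recording, correctly or not, skips inspection. Reported rounded
  to the nearest minute; full precision internally.
* Dry/wet/complete analyses are the same operations on condition-filtered
  recording lists.

## Bootstrap

At a threshold fixed in advance, each replicate draws `subsample` (default
500) recordings with replacement ("resampled" is read as the standard
with-replacement bootstrap) and recomputes the FP-rate; 1000 replicates by
default. A replicate whose resample contains no target recording leaves the
rate undefined and is skipped and counted (`n_reps_skipped`) — at realistic
class balances the probability is negligible. Summaries: mean, sample
standard deviation (n−1), and empirical 2.5/97.5 percentiles with linear
interpolation. The generator is numpy's seeded PCG64 and the seed is
recorded in the summary, so results are bit-for-bit reproducible. The
replicate distribution provably follows a two-stage binomial construction
(targets drawn ~ Binomial(n_sub, target fraction); discards ~ Binomial(drawn
targets, empirical FP-rate)), which the suite verifies by a one-sample
Kolmogorov–Smirnov test against the exact mixture CDF.

## Synthetic data

Two generators provide the study conditions at desk scale.

**Scenes** (`generate_scene`): mid-gray background + i.i.d. Gaussian pixel
noise (sd 0.02, the scale of sensor noise after 8-bit quantisation); "wet"
scenes add a travelling sinusoidal ripple (amplitude 0.06, wavelength 12 px,
drift 0.8 rad/frame) over the bottom 40% of the frame; the optional object
is a bright rectangle (contrast 0.3, a quarter of the frame wide) translating
at 1 px/frame — large and slow, like the animal the method targets. A scene
is labeled "target" only when the object is at least 15% of the frame wide.
The default size is 96×64×60 so full end-to-end suites run in seconds;
field-scale 720×480 is a config change. What this does *not* emulate:
animal-shaped silhouettes, lighting drift, rain, compression artefacts, or
triggered-exposure jitter. Passing tests therefore demonstrate the
pipeline's mechanics and ordering properties (object > no object,
wet > dry), not field-accurate detection rates.

**Populations** (`generate_population`): per-recording D values drawn from
log-normal class distributions — non-negative and right-skewed, as D
empirically is. Class sizes default to the field-survey composition (1043
target, 948 non-target 15 s recordings). Presets encode only ordering
constraints, not fitted parameters: targets score higher than non-targets on
average (log-means 1.0 vs −0.8, log-sd 0.6), and the wet preset raises the
non-target log-mean to 0.2 (sd 0.7), shrinking the separation the way
dynamic water does. Real D distributions were not available to calibrate
against, so absolute TP-rates on synthetic populations say nothing about any
particular field dataset; ordering claims (dry easier than wet) are claims
about these presets.

## Numerical and interface choices

* Tables are CSV (UTF-8, header row, ISO-8601 datetimes), columns
  `filename, datetime, location, camera, condition, label, d_filter1,
  d_filter2`; D values are written with 17 significant digits so a written
  table reads back loss-free.
* Frame rate is read from the container when available, else defaults to
  1 s/frame; no computation assumes a specific fps (D's default reduction is
  per-frame, not per-second).
* CLI exit codes: 0 success, 1 usage/data error, 2 partial per-file
  failures. Every command logs its effective configuration.
* Problem sizes in the test suite (16×16×12 oracle tensors, 200-recording
  ROC sweeps, 50 scene pairs, 10 000-replicate KS checks) were chosen as the
  smallest at which each property is sharply testable.

## Known limitations

* A stationary animal generates little variation and is indistinguishable
  from an empty scene; the method bounds the *expected* loss via the FP
  tolerance, it does not protect any individual recording.
* AVI decoding requires an ffmpeg-capable imageio plugin at run time; frame
  directories and multi-frame TIFF/GIF are decoded natively.
* Thresholds are dataset-relative. A threshold chosen on one survey
  transfers to another only if camera placement, scene dynamics and species
  mix are comparable; the bootstrap quantifies sampling noise, not domain
  shift.
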