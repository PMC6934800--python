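# Methods

## Scope and model

`behavtrack` implements two classical pipelines for single-animal behavioral
video, both operating on a lazily decoded stream of grayscale frames
(cropping, frame-range restriction and optional downsampling applied on the
fly, one frame in memory at a time):

1. **Location tracking.** Each frame is compared to a *reference frame* — an
   image of the arena without the animal — and the animal's position is the
   intensity-weighted center of mass (COM) of the thresholded difference
   image. Per-frame Euclidean steps give distance traveled; polygonal ROIs
   are scored from COM membership; a two-point calibration converts pixels
   to physical units.
2. **Freezing detection.** Motion on frame *t* is the count of pixels whose
   Gaussian-filtered grayscale change from frame *t−1* strictly exceeds a
   motion threshold MT. Freezing is any maximal run of frames with motion
   strictly below a freezing threshold FT lasting at least a minimum
   duration (supplied in seconds and converted via fps, nearest integer,
   floor 1).

## Location pipeline details

**Reference frame.** `reference_sample_n` frame indices (default 100) are
drawn uniformly without replacement, seeded by `rng_seed` (recorded in the
result's provenance), and the pixel-wise median across the sampled frames is
taken. Provided the animal occupies any given pixel in fewer than half of
the sampled frames, the median is exactly the background. An empty-arena
video can be supplied instead; batch runs always regenerate the reference
from each video itself.

For videos with appreciable sensor noise, the *sampling error* of the median
matters: with integer pixel data, an even sample size yields half-integer
medians and a ~100-frame sample leaves a percent-level tail of pixels one
gray level off the true background, which is exactly the band the percentile
threshold must separate. The validation scenes with amplitude-5 noise
therefore use an odd sample of 151–201 frames, which makes the median
recover the integer background essentially everywhere. This is an analysis
choice worth making on any noisy video; the default of 100 is kept for
compatibility with common practice.

**Difference modes.** `absolute` (|frame − reference|) tracks regardless of
contrast polarity; `animal_lighter` / `animal_darker` clip one sign and can
be more reliable when the polarity is known.

**Window weighting, then thresholding.** When enabled, difference values
outside a `window_size × window_size` square centered on the pixel nearest
the previous COM are multiplied by (1 − ω); the window is clipped at frame
edges and not applied on the first analyzed frame (no prior position).
Thresholding follows: the cutoff is the `loc_thresh`-th percentile (linear
interpolation between order statistics) of the *weighted* difference image,
and only values strictly above it survive, retaining their magnitudes (a
binarize option exists, off by default). The order matters: because the
cutoff is relative to the frame's own distribution, down-weighting an
interfering object pushes its values below the cutoff, removing it from the
COM entirely rather than merely shrinking its pull to a fraction (1 − ω) of
its lever arm — the latter would leave a ω = 0.9 rescue an order of
magnitude short. For the same reason the relative cutoff makes tracking
invariant to global illumination rescaling. With ω < 1 the window recovers
("snaps back") if the animal escapes it, since outside values are damped,
not erased.

The percentile should be chosen so that the surviving pixel count is
comparable to the animal's image area: with the default 99 on a
320 × 240 frame ≈ 770 pixels survive, about the size of a mouse at typical
magnifications. The interference validation scene uses 99.5 on a 120 × 200
frame (≈ 120 survivors versus a disk of ≈ 113 pixels) for the same reason.

**COM and degenerate frames.** COM is (Σv·x/Σv, Σv·y/Σv) over surviving
values, sub-pixel. An all-zero difference image (empty arena, extreme
thresholds) falls back to the prior position — frame center on the first
frame — with a logged warning rather than failing a batch.

**Coordinates and conventions.** 0-based, x = column, y = row; crop regions
and frame/bin ranges are half-open; distance on frame 0 is 0 by convention
(and is booked to the bin containing frame 0, so tiling bins sum exactly to
the session total).

## Freezing pipeline details

Frames are smoothed with a Gaussian filter (σ = 1 px by default, reflect
boundaries; σ = 0 disables smoothing). MT is calibrated from a short
empty-arena recording made under the same settings: all filtered
frame-to-frame absolute differences are pooled and the suggestion is
2 × the 99.99th percentile of that null distribution. The percentile is
computed on *filtered* differences so calibration and measurement share one
pipeline. Motion uses strict `> MT`; freezing candidates use strict `< FT`;
frame 0 has motion 0 (no prior frame) and may join a freezing run. Freezing
is written to CSVs as 0/100 so that bin means are percentages directly.

## Synthetic scenes and what they do (not) show

The generator renders a disk (4× supersampled anti-aliasing, so the mask
centroid matches the nominal center to < 0.1 px) over a uniform or graded
background, with optional bounded uniform *integer* noise in [−a, a], an
optional interfering blob on scheduled frames, and scripted freeze epochs
(the disk stops exactly at the position of the preceding frame, so
frame-to-frame change vanishes on precisely the scripted frames). Rendering
is a pure function of (spec, seed).

Bounded integer noise is deliberate: the percentile cutoff lands on the
discrete noise maximum and strict survival removes it entirely, so
thresholds can be placed analytically above the noise floor. An interfering
blob is given positional jitter across appearances, as a hand re-entering a
scene does — a blob fixed on exactly half the frames would occupy its pixels
at the 50% median breakdown point, which no transient real-world intruder
does. Validation trajectories reflect off arena walls ("billiard" paths)
with per-frame displacement exactly equal to the nominal speed, spreading
per-pixel occlusion to a few percent; the one-row shuttle used for the ROI
scene is noise-free for the same reason (concentrated occlusion plus noise
would bias the median along the traveled row).

What passing these scenes does *not* show: robustness to shadows, fur
texture, lens distortion, compression artifacts, non-stationary lighting,
or multi-animal scenes. The disk is rigid; a stretching, rearing animal
moves its COM in ways no fixture here exercises.

## Validation problem sizes

Tracking accuracy and reference recovery use 300-frame 200 × 400 scenes
(noise-free and amplitude-5); distance fidelity uses 50 repetitions of a
fixed 400-px path on 201-frame 120 × 260 scenes; interference uses 60-frame
120 × 200 scenes with the blob on the last 30; freezing uses 300 frames at
30 fps with scripted epochs covering 123 frames (41%), a 50-frame
calibration clip, FT = 60 between the frozen (≈ 0) and moving (≈ 200+)
motion distributions, and a 0.5 s minimum duration. These sizes keep the
whole validation suite under a minute on one core while leaving wide margins
to every asserted bound.

## Known limitations

* No decoder for proprietary containers is bundled; multipage TIFF is the
  lossless native format, anything else requires an imageio plugin.
* Rectangular crops only; polygonal masking is out of scope.
* Single animal, COM only: no pose, heading, or interaction measures.
* The median reference assumes a static arena; slow drift in lighting or
  arena contents degrades both pipelines.
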