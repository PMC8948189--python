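# Methods

This note records the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Protocol language and configuration

Recipes are one command per line, `VERB: argument`, `#` comments,
case-insensitive verbs. The six verbs (PORT, PUMP, TEMP, IMAG, HOLD,
WAIT) cover reagent selection, volume exchange, stage temperature,
imaging, timed incubation, and cross-flowcell synchronization. The
configuration file is INI-style with `[experiment]`, `[reagents]`,
`[rois]`, and `[imaging]` sections. Hard limits come from the hardware
being modeled: valve ports 1–24, at most 18 reagents on the onboard
chiller per flowcell, stage temperature 15–60 °C. ROI boxes are
slide-frame millimetres, origin at the slide corner nearest the fluidic
inlet, x across the short axis, y along the scan axis, half-open
`[min, max)`; the usable capture area is fixed at 22 × 60 mm.
Antibody reagents may be cycle-suffixed (`primary_3`) and fall back to
the unsuffixed port-map entry, so each cycle can draw from its own port.

The generated 4i recipe encodes the standard cycle: 1 h blocking, 2 h
primary, 2 h secondary, exchange into imaging buffer and image, then
k × 10 min elution incubations with k = 4 for mouse and 5 for human
tissue — the counts needed for complete antibody removal on each tissue
type. PUMP volumes in recipes are the total volume drawn through the
flowcell (the pump's per-barrel accounting is internal to the
instrument model).

## Virtual instrument

A cooperative discrete-event simulation. Each flowcell runs its program
strictly in order; sim-time advances by each command's duration:

* **PUMP** — `volume / flow_rate`; volumes above one full stroke
  (8 barrels × 250 µL, barrels joined 1–4/5–8 onto the central stage
  outlets, so 2 mL per stroke) are split into `ceil(v / 2000 µL)`
  strokes, each logged.
* **TEMP** — first-order exponential approach with time constant
  τ = 20 s (default, configurable) and a ±0.5 °C "reached" tolerance:
  ramp time `τ · ln(|ΔT| / 0.5)`. The hardware publishes only measured
  traces, not a plant model; first-order dynamics with a 20 s constant
  reproduce their qualitative shape.
* **HOLD** — the stated minutes.
* **IMAG** — tiles × z-planes × (scan length / 50 µm s⁻¹ + 5 s
  overhead) summed over configured ROIs. The scan speed is an effective
  throughput constant, not a servo model.
* **WAIT v** — blocks until the *other* flowcell starts a command with
  verb `v`; the waiter resumes at exactly that start time. If no future
  command of the other flowcell carries the verb (or both flowcells
  wait), a deadlock error reports both program counters — preferable to
  guessing a semantics the language does not define.

IMAG is a mutually exclusive resource (one optical head), so imaging on
one flowcell pushes the other's IMAG start past its completion.
Reagent bookkeeping is exact: cumulative per-reagent use equals the sum
of PUMP volumes addressed to it, which the tests assert.

**TDI image formation.** The line-scan camera integrates each sample
line over 128 detector lines: output =
`clip(Poisson(128·s) + dark(group) + N(0, σ_r), 0, 4095)` with per-line
signal `s`, eight per-readout-group dark levels (2048 pixels in 8
groups of 256), and readout noise σ_r = 3 DN added once per pixel —
hence the ×128 signal advantage at ×1 readout noise. With noise
disabled the output is exactly `128·s + dark`, which the tests check.

## Imaging and autofocus

Tiles advance across the ROI in x by `fov_width − overlap`
(FOV width 769 µm), `ceil(width / step)` tiles, first origin at the ROI
corner. Sharpness is the JPEG-compressed byte count of a frame — cheap,
monotone in fine detail, and encoder-dependent, so the encoder is
pinned: fixed 12→8-bit shift (>>4), quality 75, no chroma subsampling.
A quadratic fitted to the top half of the score-vs-objective-position
profile gives the per-FOV optimum (closed-form argmax, constrained to
the scanned interval); flat or boundary-peaked profiles are flagged "no
focus found". The ROI optimum is the **median** of per-FOV optima,
which tolerates up to ⌊(n−1)/2⌋ FOVs landing on empty glass.

Candidate FOVs are ranked by interquartile-range contrast of the survey
image under the footprint and selected greedily subject to a pairwise
separation of at least one FOV width — the ranking notion of "distance"
was genuinely open; pairwise separation was chosen because it prevents
the stacked FOVs from clustering on one bright structure. n = 5 FOVs
for the full routines, 3 for partial. Partial routines restrict
candidates to the center x-tile (intended for ROIs larger than
~5 × 5 mm, where the center tile almost surely contains tissue);
`*_once` routines reuse the cycle-1 optimum from a per-ROI cache so
objective positions stay comparable across cycles. Contrast threshold:
5 DN of IQR; below it the routine raises and suggests manual mode,
which delegates frame choice to an injected callback.

## Raw-image correction

**Dark offsets.** Each camera's eight readout groups register different
mean dark values `d_px[g]`; the offset `mean_g(d_px) − d_px[g]` is
added per group (then clipped to the 12-bit range). Offsets sum to zero
per camera by construction; correction preserves within-group contrasts
exactly and is idempotent up to integer rounding. The estimator accepts
any frames presented as dark — dedicated dark frames or background
regions — since the two differ only in what the caller supplies.

**Chromatic registration** is integer-pixel rigid translation from
bead-derived shifts supplied as configuration; shifted-in borders are
zero-filled and masked, and masks propagate downstream.

**Cycle registration** uses subpixel phase cross-correlation
(upsampling ×10) of each cycle's 610 nm image against the pre-stain
autofluorescence reference, restricted to a central square window of
2.3 mm² (side √area converted at the 769 µm / 2048 px pitch) to bound
computation. The reported `(dy, dx)` is the cycle's displacement
relative to the reference; applying the negative translation aligns all
channels of that cycle. A confidence check — Pearson correlation of
the reference with the aligned window, threshold 0.2 — flags
registrations on structureless input and falls back to (0, 0).

## Spectral unmixing

Background is subtracted first: either a global level equal to the
intensity mode + 1 SD (mouse-style images with flat background) or a
registered pre-stain autofluorescence image (human-style images), both
clipped at zero.

The **blind estimator** evaluates `I(D_j − x·D_i ; D_i)` at 41 evenly
spaced `x ∈ [0, 2]`. Mutual information is the plug-in estimate from a
64 × 64 equal-width joint histogram. Two numerical choices matter and
were fixed after direct measurement on phantoms:

* The residual is **not** clipped at zero inside the minimization.
  Over-subtracted (negative) pixels carry exactly the source-correlated
  structure that penalizes too-large `x`; clipping them flattens `I(x)`
  into a plateau past the true coefficient and biases the estimate
  upward by up to several tenths. Clipping applies only when the final
  unmixed image is produced.
* The refinement is a parabola through the **three** points bracketing
  the grid minimum — a parabolic interpolation that can move the
  estimate at most half a grid step (0.025). Wider fit windows drag the
  argmin around whenever `I(x)` is asymmetric about its minimum, which
  it typically is.

A monotone `I(x)` over the grid returns the boundary value with a
warning. The strategy is deliberately non-iterative (single pass over
the grid, no alternating updates).

The **linear estimator** is the weighted least-squares through-origin
slope of target versus source reference intensities with weights
`w = D_i`: `x_l = Σ D_i²·D_j / Σ D_i³`. It is exact on noiseless
proportional images.

Diagnostics: per-pixel channel proportions for singleplex stains
(pixels above background in the fluorophore's primary channel, each
divided by its sum across channels) and Pearson correlation at 10,000
randomly sampled above-background pixels, seeded. Only the adjacent
pairs with appreciable spillover (558→610 and 687→740 nm) are estimated
by default; an all-pairs mode is available by calling the estimator on
any pair.

## Synthetic phantoms

The generator emulates the artifacts the pipeline corrects, with ground
truth retained: per-channel textures (Gaussian-blob nuclei fields,
random-walk filaments, annular myelin profiles) at tissue-like coverage
of roughly 10–20 % stained area; a channel × channel mixing matrix with
unit diagonal; additive background and structured autofluorescence;
per-readout-group dark levels; rigid chromatic and inter-cycle shifts;
defocus stacks whose Gaussian blur grows linearly away from a planted
focus plane; and stain/elute cycle series with configurable decay and
an alternating two-marker mode. Noise follows the camera model —
Poisson shot noise plus 3 DN Gaussian read noise — under which SNR 10
corresponds to a 100 DN signal and bright pixels do better; a flat
Gaussian `noise_sd` is also available. Output is quantized to 12-bit
and bit-reproducible for a fixed seed.

What the phantoms do **not** emulate: real tissue morphology and
texture statistics, spatially varying illumination, wavelength-
dependent PSFs, nonlinear fluorophore photophysics (bleaching,
saturation), or non-rigid tissue deformation across cycles. Passing
tests therefore demonstrate algorithmic correctness under the stated
artifact models, not end-to-end performance on real sections.

## Analysis

12-bit data is rescaled to 16-bit by a ×16 shift (4095 → 65520) by
default, with a full-range 65535/4095 option — both monotone; the
choice is pinned in the call. Histogram adjustment (linear windowing or
gamma) maps to [0, 1] for display only and should use one parameter set
per antibody per experiment. Region histograms sample 10⁶ pixels per
annotated region (with replacement when the region is smaller), bin
`log2(intensity)` (zeros clamped to intensity 1) over [0, 16] in 256
bins, and are seeded. Tissue-domain maps come from k-means (k-means++
initialization, fixed seed, 10 restarts) on per-pixel channel vectors
after downsampling to 25 % linear resolution to smooth pixel-scale
registration defects; defaults k = 7, per-image clustering.

## Problem sizes

Test and acceptance runs use phantom sizes chosen to keep the full
suite in seconds while leaving each estimator well-conditioned:
256 × 256 phantoms for leakage recovery and cycle registration,
15-plane stacks on 96 × 96 scenes for autofocus, 2048-wide synthetic
dark frames, and a 256 × 256 14-channel phantom (64 × 64 after
downsampling) for the clustering stage. Estimator accuracy improves
with pixel count, so these sizes are conservative relative to full
2048-wide tiles.

## Known limitations

* The scheduler models command durations, not hardware latencies or
  failures; TEMP assumes symmetric heating/cooling dynamics.
* Leakage is a single scalar per ordered channel pair; simultaneous
  multi-source unmixing into one channel is out of scope, as is an
  iterative mutual-information descent.
* The blind estimator needs the two channels' own structures to be
  spatially independent; markers that genuinely colocalize violate its
  core assumption and bias `x` upward.
* Chromatic correction is integer-pixel and rigid; no affine or
  non-rigid registration, no flat-field illumination correction.
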