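# Methods

This note documents the models, the numerical choices behind them, and
what the synthetic experiments do and do not establish.

## Kernelized correlation filter tracker

The tracker learns, from a single feature patch `x`, a ridge regression
over all cyclic shifts of `x` toward an ideal Gaussian response. The
circulant structure diagonalizes the kernel matrix in the Fourier domain,
so training is `α̂ = ŷ / (k̂^{xx} + λ)` element-wise and detection is one
FFT per frame. The Gaussian kernel map is computed as
`exp(−max(0, ‖x‖² + ‖x'‖² − 2·F⁻¹(Σ_c x̂_c* ⊙ x̂'_c)) / σ²)`; the clip at
zero only removes round-off negatives, so the map equals the explicit
cyclic-shift evaluation `exp(−‖x − P_s x'‖²/σ²)` to ~1e-15.

Assumptions: a single target whose scale does not change (the ROI box is
fixed for the whole track), approximately periodic patch statistics (the
Hann taper enforces this), and appearance that changes slowly relative to
the model interpolation rate.

### Features

The search window is `padding` (default 2.5) times the target box, cropped
with edge replication and converted to luma grayscale. Features are
unsigned gradient-orientation histograms (9 bins over [0°, 180°), hard
assignment, gradient-magnitude votes) over 4×4-pixel cells. The whole grid
is L2-normalized **as one block** rather than per cell: per-cell
normalization raises weak, static background texture to the same energy as
the instrument's edges, and on scenes with a fixed camera the background
then anchors the correlation peak at zero shift until the track is lost.
Whole-patch normalization preserves the relative edge strength and removes
only global contrast. This choice was made after observing exactly that
failure mode on rendered scenes with static textured backgrounds.

### Defaults and units

| parameter | default | units / meaning |
|---|---|---|
| `padding` | 2.5 | search window / target box ratio |
| `cell_size` | 4 | px per HOG cell; also the localization granularity |
| `n_orientations` | 9 | unsigned bins |
| `sigma_kernel` | 0.5 | kernel bandwidth in normalized feature units; the raw σ is `0.5·√(numel)` so the kernel's argument is a per-element mean distance |
| `sigma_target_factor` | 10 | ideal-response σ = √(grid area)/10 cells |
| `lambda_reg` | 1e-4 | ridge regularizer |
| `interp_factor` | 0.02 | per-frame model interpolation (0 freezes frame-1 model) |
| `detect_iterations` | 2 | detect/move repetitions per frame |

Peak localization is at integer cell resolution (no sub-cell refinement),
so a single detection is quantized to `cell_size` pixels. Running the
detect-and-move step up to twice per frame removes the systematic lag this
quantization causes on targets moving several pixels per frame; it changes
nothing for slow targets because the second detection returns zero
displacement. Ties at the response maximum break to the first cell in
row-major order. Coordinates are 0-based, x rightward, y downward, ROI
given as `(x_min, y_min, w, h)`; centers are clamped to the frame. The
model is learned on the first frame and linearly interpolated every frame;
re-seeding the ROI (the CLI's `--reseed frame:x,y,w,h`) retrains from
scratch at that frame, standing in for manual correction.

Degenerate inputs: an ROI narrower than 8 px is rejected; a uniform patch
yields an all-zero feature grid (the global normalization guards against
0/0); a zero-feature patch with λ = 0 makes the spectral denominator
vanish off the DC bin and the solve raises instead of regularizing
silently.

## Motion features

All derivatives are forward finite differences on the uniform 1/fps grid:
`v_n = ‖Δp_n‖/Δt`, `a_n = Δv_n/Δt`, `MJ_n = ‖Δ³p_n‖/Δt³`. Speed and jerk
are vector magnitudes (non-negative); acceleration is the scalar rate of
change of speed, and it enters the classifier channel as `|a|` so all
derived channels are magnitudes. The six channels `[x, y, t, v, a, MJ]`
are aligned by truncating the first k samples of the lower-order channels
to the valid range of the third difference (a length-n trajectory gives a
length n−3 series), keeping one rectangular array per trial. Units stay in
pixels and seconds — no metric calibration is attempted. The time channel
is absolute seconds from trial start.

The dispersion index `S = (1/n) Σ (x_i−x̄)² + (y_i−ȳ)²` is translation
invariant; `d`, `v`, `MJ` are additionally rotation invariant since they
are norms of differenced coordinates.

## Residual network

The classifier is the standard time-series ResNet: one stem convolution
(kernel 7), three residual blocks of three same-padded 1-D convolutions
(kernels 8/5/3) with batch normalization and ReLU, default widths
64/128/128 with a 1×1 projection (plus batch norm) on the shortcut when
widths change, global average pooling and a softmax head. Same padding
realizes `out = ceil(in/stride)` with the asymmetric left/right split
`total = (out−1)·stride + kernel − in`, left = `total // 2`.

Training: Adam at learning rate 1e-3, batch size 24, up to 100 epochs,
categorical cross-entropy, no early stopping, no pre-training, no label
smoothing. Per-channel z-score standardization uses training-fold
statistics only and is frozen into the fitted model. Forward, backward and
the optimizer are plain NumPy; compute is float32 by default (float64
available via `dtype` for verification), and runs are bit-reproducible
given the seed since parameter initialization and batch shuffling are the
only random elements.

Trial-level prediction is a majority vote over the trial's window
predictions with ties broken toward the lower label code (novice <
intermediate < expert). Windows default to 90 samples (3 s at 30 Hz) with
stride 30, so even the shortest plausible trials (≥ 5 s) yield windows.

LOSO protocol: fold i trains on all trials except trial i of every subject
and tests on those held-out trials, so train and test never share a trial;
the whole 5-fold procedure repeats over seeded runs (default 5) whose
seeds fan out from the master seed via `SeedSequence`. A two-class mode
removes the intermediate class entirely and recodes experts as 1.
Precision/recall with empty denominators report 0 and set an `undefined`
flag rather than NaN.

## Synthetic cohort generator

Each trial is a chain of minimum-jerk segments — the quintic
`p(τ) = p0 + (p1−p0)(10τ³ − 15τ⁴ + 6τ⁵)` that minimizes integrated squared
jerk, the standard model of smooth reaching — between via-points placed
uniformly in the frame at a class-dependent rate, plus Gaussian tremor
low-pass filtered (4th-order Butterworth, zero-phase) to 8 Hz, the upper
end of physiological hand tremor, with standard deviation
`tremor_amplitude × jerk_scale` pixels.

Class profiles encode the emulated cohort: trial durations are truncated
normals (≥ 5 s) with novice 172.5 ± 58.3 s, intermediate 90.8 ± 15.1 s,
expert 83 ± 13.3 s at 30 Hz; novices take the most convoluted paths
(via-point rate 1.0/s, tremor 3.0 px, jerk scale 2.0), intermediates sit
between (0.7/s, 1.5 px, 1.4), experts are smoothest (0.5/s, 0.8 px, 1.0).
Rates and amplitudes were chosen once as plausible magnitudes that
reproduce the qualitative ordering — novice trajectories longest and most
complex, expert smoothest — and are deliberately well separated in the
default profiles. Every subject carries a lognormal multiplicative random
effect (sd 0.1) on duration, via-point rate and tremor amplitude so trials
within a subject are correlated.

The **overlap profiles** model the known hard case where intermediates and
experts are kinematically similar: the intermediate's smoothness
parameters move next to the expert's (tremor 0.95 px, jerk scale 1.05)
and both classes' subject effects widen to sd 0.3, so the two
distributions genuinely overlap while novices stay distinct. On this
cohort the three-class problem is measurably harder than the two-class
(novice vs expert) problem, mirroring the accuracy gap between class
counts that motivates reporting both.

What the generator does **not** emulate: real endoscopic appearance
(tissue, specularities, occlusion by instruments), camera motion, gesture
structure within a trial, or the label noise of self-proclaimed skill. A
perfect score on the synthetic cohort therefore demonstrates the
correctness and discriminative capacity of the pipeline, not expected
accuracy on clinical video.

Rendered scenes are a static seeded texture (sd 0.05) with an anti-aliased
bright disc (radius 6 px, intensity 0.9) and per-frame photometric noise
(sd 0.02) — enough structure that the tracker must discriminate the target
from a non-trivial background, while keeping pixel-exact ground truth.

## Problem sizes for verification runs

The test suite and `scripts/acceptance.py` run the LOSO experiments at
reduced network width and epoch counts — width 16 (default-cohort run,
5 epochs, 2 runs) and width 8 (overlap cohort, 5 epochs, 5 seeded runs of
both class counts) — because the synthetic classes are separable enough
that wider networks and longer schedules only add compute. Library
defaults remain the full-size configuration (widths 64/128/128, 100
epochs, 5 runs). Tracking checks use 200-frame sequences at up to
5 px/frame.

## Known limitations

- No scale or rotation adaptation; a tip that grows or shrinks in view
  will erode the model.
- Integer-cell localization bounds single-frame precision by the HOG cell
  size; the iterated detection mitigates lag but not quantization.
- Occlusion handling is limited to what the interpolated model absorbs;
  there is no re-detection, only manual re-seeding.
- The NumPy network trains on CPU only and is sized for small cohorts, not
  for large-scale video corpora.
- Velocity curvature and gesture segmentation are out of scope.
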