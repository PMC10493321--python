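# Methods

## The problem

Motor-imagery (MI) and motor-execution (ME) decoding from EEG asks whether
a short multichannel recording can be classified by the movement a subject
performed or imagined. Single-domain features (a band power, a correlation
matrix) discard most of what distinguishes such states; this package keeps
three complementary views of inter-channel dependence — temporal, spectral
and phase — and lets a small 3D convolutional network learn from their
joint structure.

## Pipeline

1. **Band-pass** to 8–30 Hz (alpha + beta rhythms, the bands modulated by
   motor tasks). A 4th-order Butterworth is applied forward–backward
   (`sosfiltfilt`), giving zero phase distortion; this matters because the
   phase-locking feature downstream is computed from the filtered signal's
   instantaneous phase. The filter is applied to the whole trial *before*
   windowing so filter transients do not contaminate every window edge.
2. **Sliding windows**: each trial is cut into windows of `window_s` = 2 s
   at `step_s` = 0.25 s (`floor((T − window)/step) + 1` windows; 9 for a
   4-s trial, 5 for a 3-s trial). Overlapping windows both track the
   non-stationary dynamics and multiply the training sample count.
3. **Connectivity features** per window, per channel pair:
   - *PCC* — Pearson correlation, computed as the mean product of z-scored
     signals, `r = (1/N) Σ x̃(t) ỹ(t)` ∈ [−1, 1]. The z-scoring is what
     makes the plain mean-product formula a correlation.
   - *COH* — magnitude-squared coherence
     `|S_xy(f)|² / (S_xx(f) S_yy(f))`, estimated by Welch averaging (Hann
     taper, sub-window = ¼ of the segment, 50 % overlap) and averaged over
     the 8–30 Hz bins to a scalar ∈ [0, 1]. A single full-length
     periodogram would give coherence ≡ 1; averaging is what makes the
     estimate informative. Sub-band (α or β) reductions are available via
     the `band` argument.
   - *PLV* — phase-locking value `|⟨e^{iΔφ(t)}⟩|` ∈ [0, 1], with Δφ the
     difference of analytic-signal (Hilbert) phases and ⟨·⟩ the time
     average within the window; 10 % of samples are trimmed from each end
     before averaging to drop analytic-signal edge bias.

   The matrix builder computes all pairs from shared per-channel
   spectra/phases; tests assert algebraic identity with the pairwise
   definitions.
4. **3D stacking**: the three C×C matrices of one window form a C×C×3
   voxel (fixed slice order PCC, COH, PLV). In the default `per_segment`
   mode every voxel is one classifier sample; `stacked` mode concatenates
   a trial's voxels depth-wise into one C×C×3N sample. Both satisfy the
   classifier's kernel arithmetic; per-segment is the default because the
   windowing is motivated as data augmentation.
5. **Classifier**: two 3D convolutions — 3×3×3 with 50 maps, then a kernel
   equal to the first layer's entire output volume `(C−2)×(C−2)×(N−2)`
   with 100 maps — so the pre-classifier representation is exactly
   100-dimensional; a single softmax layer maps it to class probabilities.
   Valid padding and unit stride throughout (the kernel formula only holds
   under those). ReLU activations; Adam with learning rate 1e-4, batch
   size 16, 100 epochs; cross-entropy loss. The network is implemented
   directly on numpy (im2col convolution, hand-written backpropagation,
   in-place Adam); at these sizes a framework would add nothing.
6. **Cross-validation**: 10-fold at the *trial* level — all windows of a
   trial share a fold. Window-level splitting would place near-duplicate
   overlapping windows on both sides of the split and inflate accuracy; it
   is available behind `split_unit="segment"` only for comparison with
   protocols that split after windowing.
7. **Brain-network analysis**: each channel pair's observed feature is
   compared against a null of 200 phase-randomized surrogates (Fourier
   magnitudes kept exactly, positive-frequency phases replaced by iid
   uniform draws, conjugate symmetry enforced; both channels randomized
   independently). Edges survive iff the one-sided empirical p-value
   `(1 + #{null ≥ obs}) / (1 + n_surrogates)` ≤ α = 0.05; the +1
   correction means p is never exactly 0 and α = 0 always yields an empty
   graph. No multiple-comparison correction by default (Bonferroni and
   Benjamini–Hochberg are available via `correction=`). Surviving graphs
   are summarized by edge count, total weight, per-node strength, triangle
   count and exhaustive simple-cycle counts — the structural features that
   separate strongly from weakly connected subjects.

## Synthetic ground truth

The generator produces multichannel band-limited signals whose
connectivity is known by construction, so every stage has an oracle:

- A **coupled pair** (i, j, f, κ, w) shares a carrier at frequency f;
  channel j's carrier is offset by a phase δ redrawn every `block_s`
  (default 0.25 s) from a von Mises(0, κ) distribution. The population PLV
  is the von Mises mean resultant length **I₁(κ)/I₀(κ)** — an analytic
  recovery target (0 at κ=0, 0.446 at 1, 0.698 at 2, 0.893 at 5, →1 as
  κ→∞). The mixing weight w injects a shared Gaussian source into both
  channels, so expected correlation rises monotonically with w.
- The carrier phase performs a shared random walk giving it a finite
  spectral linewidth (`carrier_linewidth_hz`, default 3 Hz). Real EEG
  rhythms are narrowband noise, not pure tones; the walk is shared by both
  channels of a pair, so it cancels in the phase difference and leaves the
  Bessel-ratio oracle intact, while making phase-randomized surrogates
  behave correctly (the surrogate of a pure tone is still a tone, whose
  within-window PLV against another tone is trivially ≈ 1).
- **Noise** is white Gaussian per channel (`noise_sd`); a 1/f option
  exists (`pink_noise=True`) but the white default keeps null
  distributions simple. Output is a pure function of (spec, seed).

What the generator does *not* emulate: volume conduction and common
reference (which induce zero-lag correlations between all real EEG
channels), 1/f background by default, artifacts (eye blinks, EMG), and
electrode geometry. Passing tests therefore demonstrate the pipeline's
statistical correctness — not that real recordings will reach any
particular accuracy.

## Study conditions used in tests and the acceptance script

- **Coupling recovery**: 2 channels, 200-s recordings, noise sd 0.25,
  κ ∈ {0, 1, 2, 5, 1000}, 20 seeds per κ; tolerance ±0.05. The long
  duration keeps the κ = 0 finite-sample floor (≈ 0.89/√n_blocks ≈ 0.03
  at 800 blocks) below the tolerance.
- **Separability**: 8 channels, 4-s trials at 160 Hz, 30 trials/class;
  class 0 couples channels (0, 1), class 1 couples (2, 3), both κ = 1000,
  w = 0.5, noise sd 1.0; full training protocol; expectation ≥ 90 % mean
  CV accuracy, and chance (∈ [0.35, 0.65]) when both classes share a spec.
- **Step ablation**: same two-class task at 10 trials/class, steps
  {0.5, 0.25, 0.125} s, 2 repeats, 5 folds, 30 epochs — sized so the sweep
  runs in about a minute while still rerunning the full pipeline per step.
- **Surrogate calibration**: 500 white-noise edges, 200 surrogates each,
  PCC; survival at α = 0.05 must not exceed α + 2 binomial SE.

## Numerical choices and degenerate inputs

- Fractional window/step sample counts are rounded to the nearest sample
  (0.25 s × 160 Hz is exact; other rates must not crash).
- Constant channels raise on PCC (zero variance), all-zero channels raise
  on phase extraction (undefined phase); bands with no frequency bins at
  the given length/rate raise rather than returning an empty average.
- Connectivity matrices are forced exactly symmetric with unit diagonal;
  PCC is clipped to [−1, 1] and COH/PLV to [0, 1] against rounding.
- The second conv layer's weights scale as 50·(C−2)²·(N−2)·100; for C = 64
  with many stacked windows this is deliberately *not* materialized when
  only the architecture arithmetic is needed (`ModelConfig` exposes the
  shapes analytically).
- Determinism: weight init, batch shuffling, fold assignment, trial seeds
  and surrogate draws all derive from explicit integer seeds; identical
  (inputs, seed) reproduce results bit-for-bit.

## Known limitations

- Training accuracies on real EDF recordings depend on preprocessing
  (artifact removal is accepted from upstream, not performed here) and on
  the CV split convention; window-level splits inflate accuracy and are
  off by default.
- The coherence estimator on 2-s windows averages ~7 sub-windows, so its
  null bias is ≈ 1/7; comparisons across window lengths should use the
  same estimator settings.
- Surrogate pruning tests each edge marginally; with ~2000 edges at
  α = 0.05 roughly 100 false edges are expected unless a correction is
  enabled.
- ANOVA in the ablation harness assumes independent accuracy estimates
  per repeat; repeats share nothing but could be extended to more seeds
  for tighter inference.
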