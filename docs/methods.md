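# Methods

`radarleak` studies how much demographic information (sex, age group) leaks
from contactless radar recordings of cardiac activity. Because the clinical
radar dataset such analyses are normally run on cannot be redistributed, the
package ships a physics-based simulator that generates labeled cohorts with
the statistical structure the analysis assumes, and every downstream stage
is exercised against that simulator.

## Signal model and simulator

A continuous-wave quadrature radar observes chest displacement d(t) through
the two-way phase Φ(t) = 4π·d(t)/λ. The default carrier wavelength is
λ = 12.4 mm (a 24 GHz radar, typical for six-port vital-sign sensors); it is
a parameter, not a claim about any particular instrument. The receiver
outputs

    i(t) = dc_i + A_i·cos(Φ + Φ₀) + n_i(t)
    q(t) = dc_q + A_q·sin(Φ + Φ₀ + φ_e) + n_q(t)

where the DC offsets, amplitude imbalance (A_i, A_q) and quadrature phase
error φ_e distort the ideal unit circle into a translated, rotated ellipse.

Chest displacement is a sum of three components:

* **Respiration** — a sinusoid of amplitude ~4 mm (subject-specific,
  2–8 mm) whose instantaneous rate wanders by ~5 % with a ~10 s correlation
  time (an AR(1) modulation). Calm breathing is narrowband; a white-noise
  phase walk would scatter respiration energy across the cardiac band,
  which is not what resting recordings look like.
* **Cardiac motion** — a Gaussian bump per heartbeat, FWHM 0.20 s by
  default, amplitude ~0.35 mm. Chest-surface cardiac motion is mechanically
  smooth; sharper templates put much of their harmonic energy above the
  3.5 Hz isolation band and no band-limited isolation stage could then
  recover them. Inter-beat intervals are Gaussian with mean 60/HR and a
  beat-to-beat sd mapped from heart-rate variability (sd_ibi = 60·HRV/HR²).
* **Residual body-motion noise** — white, sd 0.01 mm by default.

Class structure: the sex label shifts heart rate (±effect/2 pooled sd of
8 bpm around 72), pulse width and pulse amplitude; the age-group label
shifts heart-rate variability (pooled sd 0.8 bpm around 3). The separation
is `effect_size` pooled standard deviations, so `effect_size = 0` makes the
classes exchangeable by construction — the null condition used to verify
that the pipeline reports chance-level accuracy when there is nothing to
find.

## Demodulation

Recordings are cut into non-overlapping 10 s windows. Within a window the
I/Q cloud is fit with a direct least-squares conic constrained to an
ellipse (scikit-image's estimator); the affine de-distortion (translate by
the center, rotate by the tilt, rescale the axes) is orientation-preserving,
so for noiseless data the compensated angle equals the true phase plus a
constant *exactly* — there is no sign ambiguity. Displacement follows from
the unwrapped `atan2` angle scaled by λ/4π, anchored to zero at the first
sample (the additive constant is unobservable).

## Cardiac isolation

The maximal-overlap discrete wavelet transform (MODWT) is implemented
directly (circular filtering with filters upsampled by 2^(j−1) per level;
adjoint reconstruction). It is a tight frame, so the multiresolution
analysis is exactly additive, energy-preserving in the coefficient domain,
and circularly shift-equivariant — all asserted in tests at 1e−8.

Numerical choices that matter, found by measuring leakage of a 4 mm
respiration carrier into the 0.3 mm cardiac band:

* **Working rate 200 Hz** (polyphase resampling) so the cardiac band sits
  at shallow decomposition levels (6–8) instead of 9–11 at 2 kHz.
  Resampling uses *line* padding: zero padding would turn the large edge
  values of the respiration carrier into step transients.
* **Wavelet `sym8`** (least-asymmetric, order 8), depth J = 8. Order 4
  leaves ~5 % in-band roll-off leakage; order 8 brings it to ~1 %.
* **Boundary handling.** A 10 s window rarely holds an integer number of
  breathing cycles, so treating it as circular creates a wrap-around
  discontinuity that injects broadband energy into every detail level
  (phase-dependent, up to 10 % of the carrier — dwarfing the cardiac
  component). `isolate_cardiac` therefore (a) subtracts a least-squares
  narrowband respiration model before the transform (fundamental below
  0.5 Hz found by scanning candidate frequencies against residual energy,
  plus harmonics below 0.8 Hz and a linear trend — the cardiac band is
  untouched), and (b) pads with an odd (point-symmetric) reflection, which
  keeps value and slope continuous at the edges, before the circular
  transform, cropping the center afterwards. After both, carrier leakage is
  ~10⁻⁴ of its RMS.
* **Level selection.** A detail level with nominal passband
  [fs/2^(j+1), fs/2^j] is selected when at least half of that passband lies
  inside the requested band (default 0.5–3.5 Hz ⇒ levels {6, 7, 8} at
  200 Hz). Pure overlap would also pick level 5, whose band only grazes
  3.5 Hz.

With these choices the isolated signal correlates with the ground-truth
cardiac displacement at 0.97 on the standard test mixture and 0.87–0.97
across full simulate→demodulate→isolate chains.

## Scalograms

Each 10 s cardiac signal is cut into overlapping 4 s frames with 0.5 s
stride (13 per full window). Frames are rendered as the magnitude of an
analytic Morlet CWT on 200 log-spaced frequencies over 0.3–20 Hz, the time
axis block-averaged from 800 samples to 200 columns, and the image min–max
normalized to [0, 1] (a constant frame maps to zeros). Images are stored as
8-bit grayscale PNG; the classifier replicates the single channel to three
at load time. Reduced profiles (e.g. 32×32) exist for desk-scale
experiments and tests; the rendering rule is identical.

## Networks

No GPU framework is assumed: the package carries a small NumPy layer stack
(`radarleak.nn`) with im2col convolutions, transposed convolutions, batch
normalization, max/adaptive-average pooling, dropout, exact manual
backpropagation, and Adam/RMSprop. Everything is float64 and deterministic
under a fixed seed in single-threaded execution.

**Generator.** Latent vector (dim 100) concatenated with a one-hot label
(102 channels at 1×1) through five transposed-convolution stages
102→256→128→64→32→16 with kernel/stride (3,2),(3,2),(5,3),(3,3),(3,2),
batch norm + ReLU on stages 1–4 and tanh on stage 5. Traced from 1×1 this
backbone ends at 139×139×16, which cannot equal a 200×200 single-channel
image; a 1×1 projection convolution, a tanh mapped affinely onto [0, 1] and
a deterministic bilinear resize to the working image size complete the
output head. The resize is implemented as two precomputed interpolation
matrices, so its adjoint (needed for backprop) is exact.

**Critic.** Two strided convolutions 1→128→256 (kernel 4, stride 2) with
batch norm + LeakyReLU, adaptive average pooling to a 2×2 grid — making the
flattened feature width exactly 1024 for *any* input size — label
concatenation (1024+2), then linear 1026→64 (LeakyReLU, dropout 0.5) and
64→1 with no final activation.

**Frame classifier.** Five convolution stages with kernel sizes 5, 3, 13,
5, 2 (stride 1, no padding), each followed by batch norm, ReLU and max
pooling (2×2 after stages 1–4, 3×3 after stage 5), channels
3→32→64→128→256→512. The spatial trace at 200×200 is
200→98→48→18→7→2, so the flatten width is 512·2·2 = 2048. The head is
1024→256→64→1 with ReLU and dropout 0.5, trained with Adam (lr 0.001) and
binary cross-entropy on the sigmoid of the scalar output. Channel counts
and pooling sizes are free design parameters fixed to honor the 2048
constraint; alternatives satisfying the same constraints would be equally
valid.

## WGAN-GP training

Five critic updates (RMSprop, lr 6.7e−6) per generator update (Adam,
lr 8e−5); batch 32; 151 epochs; gradient penalty λ = 10 on samples
interpolated uniformly per-sample between real and generated batches. The
penalty *value* λ·mean((‖∇_x̂ D(x̂)‖−1)²) is computed with an exact backward
pass to the input. Its *parameter* gradient is accumulated by a central
finite-difference Hessian-vector product: with per-sample coefficients
c_b = 2λ(‖g_b‖−1)/B and unit directions û_b, two ordinary backward passes
at x̂ ± h·(c⊙û)/max|c| (h = 1e−4) reproduce ∇_θ P without any second-order
machinery. The whole batch is perturbed jointly, so the estimate remains
exact under the batch coupling that batch normalization introduces; batch
statistics updates are frozen and dropout masks replayed across the passes
so the differenced function is smooth. The step size sits below the typical
spacing of LeakyReLU activation boundaries; agreement with direct
differentiation of the penalty is verified in tests at 2 % relative.

Desk-scale profiles (image 32–64, a few epochs, small batches) keep test
runs at seconds-to-minutes; the default configuration carries the
full-scale settings. Adversarial dynamics at desk scale are oscillatory, so
the smoke check that the trained critic scores real above generated samples
is made at a fixed seed with a critic learning rate (1e−3) large enough to
act within a few epochs.

## Evaluation conventions

* **Voting.** Frame probabilities are thresholded at 0.5 (boundary → class
  1); a window's label is the majority of its 13 frames, ties broken by the
  mean probability. For independent per-frame correctness p > 0.5, window
  accuracy follows the binomial tail Σ_{i≥7} C(13,i)p^i(1−p)^{13−i}, which
  the implementation matches in a 10,000-window simulation.
* **Metrics.** All window-level, macro-averaged over the two classes. FAR
  and FRR are defined as the complements of macro precision and macro
  recall — FAR = 100 − precision, FRR = 100 − recall — i.e. a macro false
  discovery rate and macro miss rate, not the textbook FP/(FP+TN) and
  FN/(FN+TP). This is deliberate and load-bearing: it is the only
  convention under which published result tables of this analysis close
  exactly, and the identity FAR + precision = 100 is asserted on every
  report. F1 is the macro average of per-class F1 (not the harmonic mean of
  macro precision and recall).
* **Splits.** Always subject-wise: an 80/20 stratified holdout and
  leave-one-out over the held-out subjects. Leakage guards raise if any
  held-out subject's scalogram reaches a GAN or classifier training set;
  generated scalograms carry a `synthetic` provenance tag and no subject
  identity.
* **Welch's t-test** compares repeated-run accuracy distributions
  (unequal-variance t, Welch–Satterthwaite df, two-sided p, 95 % CI),
  verified against an independent reference implementation at 1e−10.
* **Temporal aggregation** (the privacy-threat measurement): all contiguous
  runs of a subject's time-ordered frames spanning ≥ 7 s are majority-voted
  and binned by duration (1 s bins); the cohort curve reports, per
  duration, the fraction of subjects whose per-bin accuracy has reached
  95 %. Runs may cross window boundaries (the start-time gap there is 4 s);
  within a window a run of k frames spans 4 + 0.5(k−1) s, so the shortest
  qualifying run is 7 frames.
* **Grad-CAM** hooks the fourth convolution stage: channel weights are the
  spatial means of the class-score gradient (the logit for class 1, its
  negation for class 0), maps are rectified weighted activation sums,
  bilinearly upsampled and averaged per class over correctly classified
  instances only.

## What the synthetic data does and does not show

The simulator reproduces the *structure* the analysis relies on: quadrature
geometry with channel distortions, spectrally separated respiration and
cardiac components, class-dependent cardiac parameters, subject-level
clustering. It does not model real thorax mechanics, radar clutter,
posture changes, or the actual effect sizes of sex and age on chest
motion — those magnitudes are configuration, not claims. Passing tests
therefore demonstrate that the pipeline recovers class structure when it
exists and reports chance when it does not; they say nothing about how
large demographic leakage is in real radar data.

## Problem sizes

Desk-scale runs use 12-subject cohorts (40 s per subject, 32×32
scalograms, ~600 images) for the recovery experiments and 6-subject
cohorts for the full-pipeline integration test; the null condition is
averaged over six repeated subject-wise splits because windows within a
subject are strongly correlated (the effective sample is the number of
held-out subjects). Full-scale settings (30 subjects, ~10 min recordings,
200×200 images, 151 GAN epochs) are the library defaults.

## Known limitations

* The generator's output head (projection + resize) and the critic's
  adaptive pooling are reconstructions around stated layer tables that do
  not by themselves produce consistent shapes; any alternative honoring the
  same printed widths would be admissible.
* The FD-HVP penalty gradient is exact only to O(h²) and within activation
  cells; at h = 1e−4 the error is orders of magnitude below the optimizer
  step noise, but it is not bit-identical to true double backpropagation.
* MODWT boundary mitigation assumes the dominant sub-0.5 Hz component is
  narrowband; pathological breathing (e.g. apnea transitions) would violate
  this, and such scenarios are out of scope.
* Probabilities are uncalibrated; the 0.5 threshold and voting conventions
  are fixed.
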