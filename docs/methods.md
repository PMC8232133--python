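# Methods

This note documents the models, protocols, and numerical choices behind
`ccecg`, and what the synthetic data do and do not establish.

## Scope and data model

The unit of analysis is a 10 s single-lead ECG strip recorded through
defibrillation pads while chest compressions are ongoing: 1250 samples
at 125 Hz, integer microvolts quantized to 5 µV/LSB, band-limited to
1–30 Hz (the AED monitoring bandwidth). Rhythm labels are VF (shockable;
coarse fibrillation with peak-to-peak amplitude > 200 µV), OR (organized
rhythms), and asystole (peak-to-peak < 100 µV). Amplitudes are kept in
raw microvolts end to end — the classifier input is deliberately not
normalized, because absolute amplitude carries class information (the
100 µV asystole boundary, the 200 µV coarse-VF floor).

## Synthetic CC-ECG simulator

Real resuscitation databases are not publicly available, so the
simulator emulates the statistical structure of corrupted strips. The
rhythm and artifact waveform models are constrained by the amplitude and
rate definitions above, not by physiology:

* **VF** — an amplitude-modulated oscillator whose instantaneous
  frequency performs a smoothed random walk inside 4–7 Hz, plus a weak
  second harmonic and broadband component; band-passed and scaled to a
  requested peak-to-peak amplitude (default 500 µV). Its spectral
  centroid stays within the 3–8 Hz fibrillatory band.
* **OR** — a PQRST template (sum of Gaussian deflections) convolved with
  an impulse train at the requested heart rate with 3% RR jitter and 5%
  beat-amplitude jitter, plus 8 µV baseline noise. Default R amplitude
  1000 µV.
* **Asystole** — low-pass noise plus a 0.2–0.5 Hz drift, scaled to
  60 µV peak-to-peak before quantization.
* **CC artifact** — a harmonic series (fundamental at rate/60 Hz and
  three harmonics at relative amplitudes 0.45/0.22/0.10) with slow 1%
  frequency jitter and 15% amplitude modulation; a `spiky` mode adds one
  45 ms Gaussian pulse per compression (the sharp morphology that can
  mimic QRS or fibrillatory waves); `mixed` blends the two. A `30:2`
  pause pattern gates one 4 s ventilation gap into the strip with 0.2 s
  raised-cosine edges; the default is continuous compressions because
  analysis-grade strips require compressions over the whole window.

Mixtures are formed at a controlled SNR, where SNR compares the clean
strip's power to the corrupted strip's power (variance about the mean,
taken literally — no detrending). Because the corrupted strip contains
the clean rhythm, the artifact component along the clean signal is first
projected out; the orthogonal remainder is scaled to the analytic
solution P_art = P_clean·(10^(−SNR/10) − 1), which makes the achieved
metric exact up to requantization (within 0.2 dB across −20…−1 dB
targets). Targets ≥ 0 dB are unreachable for an additive artifact under
this metric; they fall back to artifact power P_clean·10^(−SNR/10) and
the achieved metric value is recorded on the strip. This keeps a single
reported corruption metric for every strip.

Default study conditions (`make_dataset`): class mix follows cardiac
arrest prevalence (~14% VF, ~36% OR, ~50% asystole in the fixture
datasets), compression rates uniform over the 100–120 min⁻¹ guideline
range around the 110 min⁻¹ metronome, morphologies drawn uniformly,
target SNR uniform over a requested range. All generators are
deterministic given their seed; a dataset is reproducible bit-for-bit
from its master seed.

**What passing tests show** — that the pipeline's arithmetic, protocol,
and code paths behave correctly, and that the classifier family can
learn the amplitude/rate/spectral distinctions the simulator encodes.
**What they do not show** — clinical performance: real CC artifacts have
rescuer-specific, non-stationary morphologies coupled through the
skin–electrode interface, and real rhythms are far more heterogeneous
than the three waveform models here.

## Classifier and training protocol

The network is a stack of N blocks (valid 1D convolution → ReLU →
max-pool 2 → dropout 0.3), global max-pooling, and a one-unit sigmoid
classifier. Shape calculus and the closed-form parameter count are in
the README. Implementation notes:

* The forward/backward passes are numpy. Convolutions use two
  BLAS-backed strategies: an im2col buffer and single matrix product
  when the layer has ≤ 16 input channels, otherwise K per-tap matrix
  products. Gradients are exact (verified against central finite
  differences at 1e−3 relative tolerance in float64 for both paths).
* Weights use the uniform(−0.05, 0.05) kernel initializer convention
  with zero biases; float32 by default, float64 available for numerical
  studies. Same seed ⇒ identical initialization.
* Dropout is active only during training and uses inverted scaling
  (kept activations divided by 1 − α), so inference needs no rescaling
  and train/test activation expectations match.
* Max-pooling truncates a trailing odd sample (floor division), the
  reading consistent with the preset's printed shape chain
  1241 → 620 and 281 → 140.
* Training: 6× replication of the minority (shockable) class — the
  factor that balances the ~1:6 imbalance of the emulated databases —
  shuffled batches of 256, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−7),
  binary cross-entropy, at most 400 epochs, early stop after 150 epochs
  without a strict increase of validation BAC, best-validation weights
  restored at the end. The per-epoch BAC is computed over the full
  validation set at threshold 0.5; the per-epoch training BAC
  aggregates the within-epoch batch predictions. The operating
  threshold is a separate, post-training choice: the BAC-maximizing
  point of the validation ROC, with ties broken toward higher
  sensitivity, then lower threshold.
* Training supports callbacks (epoch index + log row → stop flag); the
  provided `StopAtValidationBac` halts once a target validation BAC is
  reached, which the test suite uses to avoid running schedules past
  their success criterion.

### Preset resolution

The selected three-block network is published with an internally
inconsistent first kernel: the architecture table prints K₁ = 5
alongside a block-1 parameter count of 55 and output shape (620, 5),
and the feature figures print 1241 first-block convolution samples.
Under the parameter formula and the shape calculus, all printed numbers
except the bare "K₁ = 5" require K₁ = 10 (5·(10·1+1) = 55;
1250 − 10 + 1 = 1241 → 620). The preset therefore uses kernels
(10, 20, 20); the conflict cannot be resolved in the other direction.

## Random search

Depth is drawn uniformly from {2..7}; the filter and kernel vectors are
drawn independently by first picking uniformly among the trend
scenarios realizable at that depth (three at depth 2, seven at depth
≥ 3), then uniformly among grid values compatible with the scenario;
the joint candidate is rejected and redrawn until shape feasibility and
the 250,000-parameter cap hold (termination is guaranteed: minimal
constant vectors are always feasible). The cap is enforced at sampling
time, before any training cost is spent. Candidates are trained under
identical conditions with seeds derived from a single master seed and
ranked by validation BAC (ties: smaller model, then draw order), making
the whole search reproducible.

## Evaluation

Sensitivity is reported over shockable strips, specificity over
non-shockable strips overall and per rhythm, BAC as their mean, the ROC
by sweeping every unique score as a threshold (decision score ≥
threshold) with trapezoidal AUC (equal to the Mann–Whitney pair
statistic with ties counted one half). Stratified tables report the
correct-decision rate per SNR band and per compression-rate band with
Wilson 95% confidence intervals (the CI method is this package's
choice; the interval family is not dictated by the protocol).
Stratification keys absent from a strip leave it out of the table;
empty strata are absent rather than zero. Display rounding is one
decimal in percent. Boundary conventions: the STRONG and MODERATE SNR
intervals include their upper bounds (−9 dB is VERY_STRONG, −6 dB
STRONG, −3 dB MODERATE), and a compression rate of exactly 110 min⁻¹
belongs to the upper normal band. Compression rate is estimated as 60
times the dominant Hann-windowed periodogram frequency in 1.33–2.67 Hz
with parabolic sub-bin interpolation; the peak must exceed ten times
the broadband median periodogram level, otherwise the rate is declared
undetectable rather than guessed.

## Problem sizes in the test suite

The suite exercises the full pipeline at sizes chosen to keep the whole
run on a single CPU while preserving the study's structure: the
end-to-end check trains the preset on 600 weak-artifact strips
(82/218/300 across VF/OR/asystole) against a 300-strip validation set
for three initialization seeds, stopping once validation BAC reaches
0.90 (all seeds reach it within 9–12 epochs); the miniature random
search trains 10 sampled candidates for 50 epochs each on a 30-strip
training set and is run twice end-to-end to demonstrate bit-identical
ranking. Property suites run at the sizes stated in their tests (200
random configurations for the parameter-count identity, 1000 sampler
draws, 100 random score sets for the ROC oracles).

## Known limitations

* The simulator is a statistical stand-in, not a physiological model;
  absolute performance numbers on it do not transfer to clinical data.
* The numpy network trains small models efficiently but is not suited
  to large-scale searches (the published scale of 1500 candidates on
  thousands of strips assumes GPU training).
* SNR targets ≥ 0 dB are definitionally unreachable under the additive
  artifact model; the fallback documents, rather than hides, this.
* Per-compression (instantaneous) rate tracking and impedance-based
  references are out of scope; the rate estimate is one number per
  strip.
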