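# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not establish about
real recordings.

## The paradigm and its synthetic model

Each trial of the three-level paradigm lasts 2.5 s (500 ms fixation, 1250 ms
stimulus, 750 ms relaxation); a session is 600 stimuli in 5 runs with
NT/ST/DT at 75/12.5/12.5%. Sequences are built by exact multinomial rounding
of the target ratios followed by a seeded shuffle, so the realized
proportions are within one trial of the targets for every seed — the ±2%
design band holds structurally rather than in expectation. DT task answers
are Bernoulli(0.5) by default. The behavioural score is the *answers ratio*
|correct − response| / correct, where the correct count adds +1 per colour
match and a further +10 per positively-answered deep target.

The EEG generator renders, per channel in μV:

* an **ERP source**: two Gaussian-windowed bumps, 250 ms (σ 40 ms) and
  400 ms (σ 80 ms), with per-class amplitudes. Defaults grade the 400 ms
  peak 1.0 / 2.5 / 4.0 μV (NT/ST/DT) and give the 250 ms peak a
  processing-vs-no-processing contrast (1.0 / 2.0 / 2.2 μV);
* **α and β sources**: stationary narrowband Gaussian noise (unit-RMS
  band-passed white noise × 2.0 μV for α, 1.0 μV for β) whose envelope dips
  after each stimulus: a trapezoid starting 300 ms post-stimulus with 100 ms
  ramps, class-specific depth and plateau duration (α defaults 0.05/200 ms,
  0.30/400 ms, 0.45/800 ms for NT/ST/DT — the envelope minimum sits near
  500 ms and deep processing desynchronizes deepest and longest);
* **background**: 8 sources of 1/f noise (exponent 1.0, 3 μV RMS each)
  through a random channel-smoothed mixing, plus 1.5 μV white sensor noise.

ERP and oscillatory sources project through a fixed centro-parietal template
(row-wise gains peaking at Pz, Gaussian lateral falloff, zero on the EOG
channel, maximum entry exactly 1 so configured amplitudes are what a Pz
electrode sees). There is no volume-conduction head model — the mixing is a
documented simplification. The ERD is implemented subtractively,
`(1 − dip)·osc = osc − dip·osc`, so a rendered session decomposes *exactly*
into background + per-event contributions; the superposition and
effect-recovery tests rely on this. Reduced montages (< 64 channels) keep
scalp coverage plus the channels the cleaning rules and EOG control need,
rather than truncating the electrode list.

What the generator does **not** emulate: realistic head-model topographies,
eye-movement dynamics between the two stimulus objects, latency jitter of
the deep-processing decision, inter-subject variability, and the
post-stimulus synchronization rebound. Passing tests therefore demonstrate
correctness of the analysis machinery under the stated generative
assumptions, not performance figures transferable to recorded data.

## Preprocessing

Anti-aliasing uses a Chebyshev-II low-pass of order 10 with a 42 Hz
pass-band edge and a 49 Hz stop band. A single pass of order 10 cannot meet
both 3 dB ripple at 42 Hz and 50 dB at 49 Hz (the transition would need
order 12), so the filter is applied forward-backward with half-dB per-pass
specifications and a `cheb2ord`-chosen critical frequency; the realized
zero-phase response measures ≤0.2 dB ripple at 42 Hz and ≥50 dB at 49 Hz,
and the test suite asserts the measured transfer function, not
coefficients. Drift removal is a linear-phase least-squares FIR high-pass
(1 Hz, order 3× the 100 Hz analysis rate) applied forward-backward.

Rejection rules run on a 5–40 Hz band-passed copy; surviving data keep
their unfiltered (post low/high-pass) values. "Excessive variance" — which
the cleaning rule needs but is not a universal constant — defaults to
per-channel variance > median + 5·MAD across epochs. Channel rejection runs
before epoch rejection. Every rejection appends a log record sufficient to
reconstruct the surviving-index mapping.

## Univariate analysis

Signed r² is computed pointwise as the Pearson correlation between amplitude
and the binary class indicator, squared, carrying sign(μ_A − μ_B). Spectral
discriminability correlates **log** Welch band power (1 s windows, 50%
overlap, 0–2000 ms) with the class label — band power is approximately
lognormal and the correlation is better behaved on the log scale; the sign
convention survives the monotone transform. ERD/ERS curves are
Hilbert-envelope averages per class, referenced to a −200…0 ms baseline
(exactly zero-mean there by construction), in μV; a squared-amplitude
variant is not provided — the curves are reported as signed amplitude
changes.

Interval selection scores each time point by |r²| summed over the channels
agreeing with the dominant sign, after ~50 ms smoothing. The best point
seeds a window grown while the spatial pattern stays correlated ≥0.8 with
the seed pattern, capped at 150 ms per window; the window is zeroed out and
the search repeats, up to five windows. Points under 25% of the global peak
cannot seed a window (an all-noise map yields an empty set), and under 5%
cannot extend one. The width cap makes a sustained component contribute
several adjacent windows — a mean over one long window would average its
time course away, and five windows per subject is the expected regime. An
exhaustive-search oracle cross-checks single-bump cases in the tests.

## Spatial filtering

SSD solves `C_signal w = λ C_flanker w` on continuous (or concatenated)
broadband data; defaults put 2 Hz flankers separated by 1 Hz gaps around the
signal band. The signal covariance is first eigendecomposed and directions
below 10⁻⁶ of the largest eigenvalue are discarded (low-rank
factorization); a logged 10⁻⁹·trace ridge handles singular flanker
covariances. λ is the band-to-flanker power ratio, sorted descending.
Because CSP is invariant to any invertible linear transform, SSD only helps
CSP when it *truncates*: the kept subspace is λ > 1.2 × median λ — broadband
noise produces a common baseline ratio (set by the band/flanker bandwidth
ratio), oscillatory sources stand above it. Within cross-validation, SSD is
refit per training fold from cached per-trial band covariances (band-pass
filtering itself is label-free and done once).

CSP solves `C_A w = λ (C_A + C_B) w` with per-trial covariances averaged per
class, so λ ∈ [0, 1] is the class-A variance fraction and λ_A + λ_B = 1 per
component. Up to three components per eigenvalue extreme are kept, ranked by
max(λ, 1−λ), subject to |λ − 0.5| > 0.01 and a median consistency check: the
median per-trial variance ordering across classes must agree with λ's side
by ≥5% (medians resist the outlier trials that can fabricate extreme
eigenvalues of the mean covariance). Filters are scaled so the
largest-magnitude entry of the corresponding pattern (A = C W (WᵀC W)⁻¹) is
positive.

## Decoding and validation

ERP features are mean amplitudes per (channel, selected window); spectral
features are log-variances of the retained CSP components over 350–2000 ms
(the cognitive process is assumed under way from the P300 peak; the right
edge is the epoch end and configurable). Tables are concatenated; optional
z-scoring uses training-fold statistics only. LDA shrinks the pooled
within-class covariance toward scaled identity with the analytic
Ledoit-Wolf intensity; the bias centers the decision value between class
means. AUC is the normalized Mann-Whitney U with ties counted ½.

Cross-validation is stratified 10-fold × 10-repetition with a seeded RNG.
The default is fully nested — interval selection, SSD, CSP, scaling and LDA
all inside training folds; `nested=False` reproduces the partially nested
variant (SSD and interval selection on all data), which carries a known
small optimism and exists for comparison. Classes are decoded strictly
pairwise (NT-ST, NT-DT, ST-DT). A permutation test for chance level
permutes labels against the fixed cross-validated scores (1000 draws by
default); refitting the pipeline per permutation would multiply the cost a
thousand-fold without changing the exchangeability null being tested.

## Calibrated parameter recovery

The recovery study asks: given effects whose decodability is known, does the
nested pipeline recover it? The observable-data Bayes optimum (a
template-projection matched filter with full temporal whitening) is *not*
the right yardstick for an interval-mean pipeline: boxcar means cannot
whiten colored noise or exploit the high-pass filter's undershoot, and they
retain only part of the data-level discriminability regardless of sample
size. The calibration therefore targets the Bayes optimum **of the
spatio-temporal feature representation**: with the effect confined to the
400 ms ERP component and white sensor noise, the feature-level
discriminability of interval means over five canonical 60 ms tiles
(250–550 ms) is computable in closed form from the generative parameters —
`d = amp · √(δᵀ Σ_f⁻¹ δ)` with δ the tiled means of the filtered unit
kernel and Σ_f the feature covariance of an effect-free session — and the
DT amplitude is set so AUC_Bayes = Φ(d/√2) = 0.85 (ST at 0.6× that). An
oracle discriminant built from these true parameters verifies the
calibration (it scores ≈0.85 on fresh sessions); the nested pipeline is
then required to land within ±0.05 and to reproduce the injected effect
ordering NT-DT > NT-ST > ST-DT. The study uses 1200-trial sessions on an
8-channel reduced montage so the ±0.05 band reflects pipeline fidelity
rather than the learning noise of the 12.5%-rare DT class.

## Problem sizes and defaults

Synthetic studies in the test suite use 200 Hz generation decimated to
100 Hz, 8–16 channel reduced montages and 120–1200 trials; the full-scale
smoke run uses the complete 600-trial, 64-channel session. All published
analysis constants (0.5 μV², 10%, 20%, 150 μV, 42/49 Hz, 1 Hz, 100 Hz,
8–14/16–20 Hz, 10⁻⁶, 3 filters/class, 350 ms, 10×10 CV) are configuration
defaults (`PipelineConfig`), never hard-coded in stage logic. A θ band
(5–7 Hz) can be analyzed through the same functions but is excluded from
decoding by default — its discriminability is marginal and inconsistent
across level pairs.

## Known limitations

* No ICA-based artifact-component removal; the hook is the modular pipeline
  (an ICA cleaner can be inserted before epoching) but no trained artifact
  classifier ships with the package.
* Filters are non-causal (zero-phase); online use would need causal
  redesigns.
* The EOG-control mode shares the generator's simplification that ocular
  channels carry no class information unless artifacts are injected; with
  strong cortical effects a small residue reaches frontal derivations
  through the mixing, so the control is interpreted relative to the
  full-montage result.
* Group-level statistics across participants (ANOVA and friends) are out of
  scope; the permutation test covers the single-session case.
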