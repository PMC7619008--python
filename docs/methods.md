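# Methods

This note documents the models behind `quantalglu`, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not establish about real recordings.

## Signal model

A linescan is a 2-D array F(x, t): fluorescence along one spatial line
across a synaptic terminal, sampled at the line rate (1 kHz by default).
The model underlying both the generator and the decomposition is

    F(x, t) = F0 · [ B(x) · (1 − β t) + Σ_e a_e · g_{s(e)}(x) · h(t − t_e) ] + ε

* `B(x)` — baseline spatial profile: a sum of Gaussian point sources
  (active zones) plus a uniform background. Active zones are treated as
  point sources because vesicle fusion is confined to a sub-resolution
  region; a fitted component with FWHM ≥ 1.5 µm most likely conflates
  several zones and is excluded from event analysis.
* `β` — linear bleaching rate (fraction of baseline per second). Real
  bleaching is approximately exponential; over recordings of tens of
  seconds at the bleach rates typical of iGluSnFR the linear term is an
  adequate first-order correction, and the same linear model is used for
  generation and correction.
* `h(t) = A·e^(−t/τ_f)·(1 − e^(−t/τ_r))` — the reporter impulse response,
  rise τ_r = 1 ms, fall τ_f = 60 ms by default. Its maximum sits at
  t* = τ_r·ln(1 + τ_f/τ_r). The kernel's two time constants are the
  parameters a user is most likely to need to adjust for a different
  reporter variant. (The printed form of this kernel sometimes repeats
  τ_r in both factors; here the decay carries τ_f and the rise τ_r, as
  the definitions of "rise and fall time constants" require.)
* `a_e = k_e · q` — event amplitude: an integer number of vesicles k_e
  times the unitary quantal amplitude q (ΔF/F₀ per vesicle). The reporter
  is assumed linear over the observed range, which is what licenses both
  the convolutional model and the integer-multiple amplitude structure.
* `ε` — additive Gaussian noise, SD in ΔF/F₀ units. An optional
  shot-noise-like signal dependence is deliberately left out of the
  default: at photon rates where quantal events are resolvable at all,
  the additive term dominates the detector's behaviour.

## Release model

Event times within a stimulus cycle are homogeneous Poisson with rate
r(c) set by the cycle's contrast c — either linear
(`base_rate + rate_gain·max(c − c₀, 0)`) or Hill-shaped
(`base_rate + r_max·cⁿ/(cⁿ + C₁/₂ⁿ)`). A phase-locked option (von Mises
phase distribution) exists because real bipolar-cell release is strongly
phase-locked to the stimulus; the information and SNR analyses operate on
counts, so the default uniform phase keeps the generator minimal. Quanta
per event are drawn from an explicit MVR probability vector
{k: p_k}. A single quantum's amplitude has fractional spread
`amplitude_cv`; a k-quantum event's spread scales with √k by default
(variance additivity of k independently variable vesicles), with a
fixed-spread alternative.

The quantal amplitude in ΔF/F₀ units is a free parameter of the
generator (default 1.0): no published calibration pins it, and every
downstream statistic is invariant to its absolute value.

## Decomposition choices

* **Number of spatial components** — selected by BIC over 1…max
  components; on the short spatial profiles of a linescan an unpenalized
  residual criterion overfits readily.
* **Collinearity guard** — extraction fails loudly when two fitted
  components' shapes have cosine similarity > 0.999, naming the pair:
  their amplitudes are then not separable by the linear solve.
* **Bleach slope** — Theil–Sen (median of pairwise slopes) on a uniform
  1500-point subsample. Release transients are sparse, positive
  excursions; an OLS slope is biased by them, the median-based slope is
  not. The subsample keeps the O(n²) estimator cheap at 1 kHz.
* **F₀** — mode of the corrected trace via a Gaussian KDE (Silverman
  bandwidth, 512-point grid, histogram fallback for degenerate input).
  The mode, unlike the mean, is insensitive to the activity riding on the
  baseline.
* **Wiener filter** — Ĥ*·F̂/(|Ĥ|² + N/S(f)). With `noise_power="auto"`,
  the white-noise floor N is the 10th percentile of the smoothed tail PSD
  (above 250 Hz, where the 60-ms kernel passes essentially nothing), and
  the signal PSD S(f) is the smoothed spectrum minus the floor minus a
  4·SD fluctuation margin, floored at a tiny positive value. The
  percentile makes the floor robust to broadband signal content leaking
  into the tail; the margin makes the filter collapse to a matched filter
  on noise-only input instead of amplifying spectral flukes. An explicit
  scalar `noise_power` bypasses all of this (useful for noiseless
  round-trip checks, where near-inverse filtering is wanted).
* **Detection** — local maxima above `threshold_sd` × MAD-based noise SD
  of the deconvolved trace (MAD because the events themselves inflate a
  naive SD), earliest sample winning on tied plateaus, 5-ms refractory
  window so one impulse is never counted twice. Default threshold 3.5 SD;
  for long traces the expected number of spurious noise maxima grows
  linearly with duration, and the Gaussian exceedance budget then argues
  for the top of the conventional 3–4 SD range — the 60-s validation
  studies use 4 SD.
* **Amplitude read-out** — the deconvolved local maximum (not an
  integral). The Wiener filter attenuates all events by a common factor,
  which the scale-equivariant clustering absorbs.
* **Quantal clustering** — the unitary amplitude q̂ maximizes a profile
  likelihood: Gaussian components at k·q̂ (k = 1…K), component SD
  √(noise² + σ₁²·k), mixture weights and σ₁ re-estimated by EM at each
  candidate q̂, plus one uniform outlier component so a stray sub- or
  super-quantal event cannot drag the estimate. Candidates are compared
  by BIC: a sub-multiple of the true quantum matches the data equally
  well but needs more components, so the fundamental quantum wins. The
  measurement noise floor (the deconvolved trace's noise SD) is what
  prevents the classic collapse onto ever-finer pseudo-quanta; σ₁ has an
  absolute floor of 10⁻³ × median amplitude so noiseless input stays
  non-singular. Events are assigned their maximum-posterior k. Below 10
  events the quantal size is not estimable and must be supplied.
* **Polarity** — ON if the event rate during positive-contrast steps is
  at least twice the negative-step rate (and vice versa); anything less
  decisive is reported `unknown` rather than forced.

## Response measures

* **Cycle assignment** uses half-open intervals [start, end); an event at
  exactly a cycle boundary belongs to the following cycle.
* **Hill fits** are inverse-variance weighted by the per-contrast SEM
  (Poisson-like counts are strongly heteroscedastic; weighting removes
  most of the small-sample bias in ĉ_half). Bounds n ∈ [0.5, 8],
  C₁/₂ ∈ (1, 100]% prevent degenerate fits on shallow data. Fits that hit
  a bound, fail to converge, or face monotone-decreasing data are
  *flagged*, never silently returned.
* **Contrast gain** is the OLS slope of release rate vs contrast over
  C₁/₂ ± 10%, normalized to the rate at the window's lowest contrast.
  Note an estimator property that matters in practice: normalizing each
  noisy unit to its own lowest-contrast rate pins that point at exactly 1
  while inflating the others by the denominator's squared CV, adding a
  common positive slope bias. Population analyses should pool counts
  across units before normalizing, which is what the gain-ratio
  validation study does.
* **Factorization** — vesicle rate = event rate × mean event amplitude,
  an identity by construction (total quanta / time factorizes exactly).
  Mean amplitude averages over events within a contrast (not over
  cycles); cycles without events contribute rate zero and are excluded
  from the amplitude mean.
* **Amplitude distributions** are over the symbols
  {no-response, 1, 2, 3, …} with the no-response bin counting empty
  stimulus cycles; two conditions are compared by chi-squared on the
  count tables.
* **Band-pass calls** require an interior frequency maximum exceeding
  both endpoint rates by ≥ 20%; with typical 3–6 frequency samples a
  smaller margin would label sampling noise.

## Information measures

Responses are discretized into 20-ms bins aligned to cycles (10 bins per
200-ms cycle); the bin width must divide the cycle exactly. At this width
a bin almost never holds two events; when it does, quanta are summed into
one symbol and the violation rate is reported. p(Q|S) is the empirical
bin-frequency table; p(S) is taken from the protocol *design* (exactly
uniform for a balanced set), not re-estimated. Everything downstream is
plug-in with log₂ and 0·log 0 ≡ 0: I(S;Q) as the double sum over the
joint, I₂(S,q) = H(S) − H(S|q). Per-cycle information defaults to
bits/bin × bins/cycle (treating bins as conditionally independent given
the contrast); a per-cycle total-quanta alphabet is available as
`cycle_information="cycle_symbols"` and is bounded by H(S).

No small-sample bias correction is applied: the plug-in estimator is
positively biased at finite data (the convergence test documents the
bias decaying over 10²→10⁴ bins), and a shuffle-null diagnostic
(`shuffle_null_information`) quantifies it at the user's sample size.
SNR uses the unbiased (n−1) trial variance; zero-variance contrasts are
flagged infinite rather than raised.

## Validation studies and their scope

The reference studies in `quantalglu.studies` fix one set of realistic
conditions each (stated in that module's docstring): a 60-s, 1-kHz
round trip at event SNR ≈ 6.7 with quantal CV 0.15 scoring detection
recall/precision (5-ms matching tolerance) and quantal assignment;
Hill-C₁/₂ recovery from Poisson counts at 30 cycles/contrast over 100
seeds; and an 8-fold gain-ratio recovery between a shallow and a steep
generator at 60 cycles/contrast over 100 pooled seeds.

What passing these studies shows: the pipeline's stages are mutually
consistent and recover the generative parameters under the stated noise
model. What they do not show: robustness to features the generator
omits — motion, non-Gaussian photon noise at low counts, exponential or
non-monotonic bleaching, overlapping active zones closer than the
spatial fit can separate, reporter saturation at high glutamate, and
phase-locked release colliding with the ≥ 3·τ_f event-separation
condition of the round trip. Real recordings with event rates well above
~10 s⁻¹ will also pile events within a kernel width, where detection
recall necessarily degrades.

## Degenerate inputs and edge behaviour

Empty event trains propagate as valid empty results everywhere (counts
of zero, undefined amplitude means reported as missing). Exactly
noiseless traces are handled by the explicit-noise-power path; the
SD-relative detection threshold is undefined in the zero-noise limit, so
exact-recovery guarantees are stated at noise ≤ q/10. Flat likelihood
surfaces in clustering, baselines ≤ 0, non-dividing bin widths, orphan
events outside the protocol, and unknown config keys all raise with
messages naming the offending value; a pipeline stage failure names the
stage and preserves completed outputs.
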