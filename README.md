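# quantalglu

Quantal analysis of glutamatergic synaptic transmission imaged with the
fluorescent glutamate reporter iGluSnFR.

Ribbon synapses of retinal bipolar cells encode stimulus contrast not as a
binary spike/no-spike code but through both the *rate* of glutamate
release events and their *amplitude*: multivesicular release (MVR) fuses
two or more vesicles synchronously, so event amplitudes are integer
multiples of a unitary quantum. `quantalglu` turns two-photon linescan
recordings of single synaptic terminals (position × time fluorescence at
~1 kHz) into a time series of quantized release events, and from those
events computes the standard measures of synaptic performance:
contrast-response functions and their half-maximal contrast C₁/₂,
maximum contrast gain, low-pass/band-pass frequency responses, the
rate × amplitude factorization of the vesicle code, trial-to-trial
signal-to-noise ratio, and the mutual information between stimulus and
response.

It is written for synaptic physiologists who have linescan data (TIFF or
HDF5) or who want a fully synthetic test bed: the generator in
`quantalglu.synthetic` renders recordings with known ground-truth release,
so every stage of the pipeline can be scored exactly.

## The pipeline

1. **Spatial decomposition** — the time-averaged linescan profile is fitted
   with a sum of Gaussians, one per active zone (components wider than
   1.5 µm FWHM are excluded as likely conflations of several zones).
2. **Time-series extraction** — per time point, the amplitudes of the
   fixed-shape components are solved by linear least squares.
3. **Baseline correction** — a linear bleach trend is removed (Theil–Sen
   slope) and the trace expressed as ΔF/F₀, with F₀ the mode of the
   corrected trace.
4. **Wiener deconvolution** against the double-exponential reporter kernel

       h(t) = A · e^(−t/τ_f) · (1 − e^(−t/τ_r)),   τ_r ≈ 1 ms, τ_f ≈ 60 ms

   turning release transients into approximate impulses.
5. **Event extraction** — local maxima of the deconvolved trace above a
   threshold in robust (MAD-based) baseline-noise SDs (default 3.5).
6. **Quantal clustering** — maximum-likelihood partition of event
   amplitudes into integer multiples k·q̂ of a unitary quantum, with
   EM-profiled mixture weights and spread and BIC selection of q̂.

Downstream, `quantalglu.response` computes per-cycle vesicle counts, Hill
fits r(c) = r_max·cⁿ/(cⁿ + C₁/₂ⁿ), contrast gain over C₁/₂ ± 10%, and the
factorization *vesicle rate = event rate × mean event amplitude*;
`quantalglu.info` computes SNR = S²/σ² and, on 20-ms-binned responses,
the plug-in mutual information I(S;Q) = H(S) − H(S|Q) and the specific
information I₂(S,q) = H(S) − H(S|q) of each event amplitude.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data: a morning-like condition (shallow contrast dependence, mostly
univesicular release) against an afternoon-like condition (steep
contrast-response, strong MVR). Outputs land under `results/`.

```bash
python analysis/01_simulate_and_decompose.py
python analysis/02_contrast_response.py
python analysis/03_vesicle_code.py
python analysis/04_information.py
python analysis/05_validation.py
```

prints, among other lines:

```
[AM] C1/2 = 34.8%  r_max = 1.64 ves/cycle  gain slope = 0.0223 /%
[PM] C1/2 = 61.4%  r_max = 7.09 ves/cycle  gain slope = 0.0513 /%
PM/AM gain ratio: 2.30
[AM] at 100%: event rate 4.17/s x amplitude 1.16 = 4.83 vesicles/s
[PM] at 100%: event rate 13.83/s x amplitude 1.99 = 27.50 vesicles/s
AM vs PM amplitude distributions: chi2 = 238.0, p = 2.09e-49
[AM] I = 0.68 bits/s (stimulus holds 19.0 bits/s); median SNR 0.66
[PM] I = 3.30 bits/s (stimulus holds 19.0 bits/s); median SNR 1.46
PM/AM information ratio: 4.88
round trip: 139 true events, recall 1.000, precision 1.000, quantal accuracy 0.993
```

Reading the numbers: the afternoon-like synapse has a ~2.3-fold higher
maximum contrast gain; at full contrast its vesicle output (27.5 s⁻¹) is
carried by both more events (13.8 vs 4.2 s⁻¹) and larger events (2.0 vs
1.2 quanta/event — the MVR shift, which the chi-squared test confirms);
and it transmits ~4.9× more information about contrast, still a small
fraction of the 19 bits/s available in the stimulus ensemble. The last
line scores the pipeline against the generator's ground truth.

The same stages are scriptable via the `quantalglu` CLI
(`simulate | detect | respond | info | run`), e.g.

```bash
quantalglu detect --in recording.h5 --kernel tau_r=0.001,tau_f=0.06 --threshold 3.5
```

## Layout

```
src/quantalglu/     library: protocol, kernel, synthetic, decompose,
                    response, info, io, pipeline, cli, studies
analysis/           numbered study drivers (write to results/)
scripts/            acceptance.py (reproduction script)
tests/              pytest suite
docs/methods.md     models, assumptions, numerical choices
```
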