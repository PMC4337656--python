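# Methods

This note records the models implemented in `duokit`, the defaults and why
they were chosen, the numerical details that matter for reproducing results,
and what the synthetic validation does and does not demonstrate.

## Data model

Activity and temperature series are uniform bins; timestamps are the *left
edges* of half-open bins `[t, t + dt)`, in decimal hours from the recording
origin (no calendar handling). The canonical resolution is `dt = 0.1` hr
(6-min wheel-revolution bins). Missing bins are carried as a boolean mask and
never imputed: the Lomb–Scargle stage simply drops them (that tolerance to
gaps is why the estimator was chosen), and stages that require contiguous
input (cosinor, filters) refuse masked data, while the wavelet stage
linearly interpolates and says so. Dialysate dopamine profiles are short
evenly spaced traces (canonically 12 samples at 20-min intervals = 4 hr);
their timestamps are sample-interval midpoints, which aligns the dopamine
samples with the times at which the cosinor is evaluated.

Rebinning treats counts as a uniform density within each source bin and
integrates across the new bin edges. This conserves the total count exactly
and also handles non-integer bin-width ratios — the pipeline's standard
0.1-hr → 20-min rebin is a factor of 10/3. Temperature is averaged with
overlap weights. A new bin is missing only when every overlapping source bin
is missing.

## Period determination

Power is the Scargle statistic divided by the sample variance (ddof = 1),
the "standard" normalization under which a single noise frequency is
asymptotically unit-exponential. The grid is uniform in period: 0.02-hr
steps below 5 hr (ultradian precision at the 0.1-hr data resolution) and
0.1-hr steps above, over 1–40 hr by default.

The significance threshold at level α uses the Horne–Baliunas form
`z = −ln(1 − (1 − α)^(1/M))` with `M` equal to the number of evaluated grid
frequencies. On an oversampled grid this over-counts the truly independent
frequencies, so the test is conservative; the calibration (any-peak false
alarm rate ≤ 0.05 at α = 0.01 on white noise) is itself asserted by the test
suite rather than assumed.

The called period τ is the highest local maximum above the threshold;
absence of any significant peak is a valid outcome, not an error. Harmonic
vetting is automated: power near τ/2 and 2τ (within one grid step; evaluated
off-grid directly from the retained samples when the band excludes the
harmonic) is compared against the peak, raising `half_period_stronger` /
`double_period_stronger` flags. The modulo-τ actogram remains available for
the traditional visual confirmation.

Derived amplitude per grid point is `sqrt(4 · power · var / n)`, which
recovers the true amplitude of a pure sinusoid in white noise. **Amplitude
spectral density (ASD)** integrates this amplitude (trapezoid over the
period axis) across grid points at or above the threshold, within a band,
divided by the same integral over the full computed range, × 100. When
nothing is significant anywhere the result is 0% with an explicit
empty-spectrum flag. Integrating amplitude rather than raw power matches
amplitude-displaying periodogram conventions; the raw-power variant is a
one-line change on the `Periodogram` fields if ever needed.

The **circadian arrhythmia screen** (inclusion criterion for lesioned
animals) requires ≥ 7 days of data and declares arrhythmia when no
significant α = 0.01 peak exists in the 20–28-hr band.

## Cosinor and the permutation FDR

The cosinor `y(t) = M + A·cos(2πt/τ − φ)` at fixed τ is an ordinary linear
least-squares problem on the basis {1, cos, sin}; amplitude and acrophase
come from the quadrature coefficients, so the fit is deterministic and
exact. τ is taken from the Lomb–Scargle analysis of the 20 hr of activity
following dialysate sampling, rebinned to 20 min to match the dialysate
cadence and fit raw (unsmoothed). When no significant peak exists the
pipeline refuses to compute an FDR rather than guessing τ.

Concordance between the cosinor (evaluated at the dopamine sample times) and
the dopamine profile is the sum of squared differences after min–max
normalizing both traces to [0, 1]. The normalization makes the score
dimensionless and comparable across animals with different absolute
dopamine (nM) and activity scales; it is also order-invariant, so it is
applied once per profile regardless of permutation. A constant dopamine
profile cannot be normalized and is reported as incomparable; a
zero-amplitude cosinor is mapped to the constant ½ so that all permutations
tie (FDR 100%), the conservative outcome.

The FDR is the percentage of `n_perm` (default 100,000) permutations of the
dopamine values across the fixed sample times whose SSE is *equal to or
better than* the observed one. Permutations are independent uniform draws of
orderings (with replacement — the identity may recur), generated from a
recorded seed. Ties use a 1e-9 relative tolerance so the identity
permutation always counts, keeping the FDR strictly positive. For profiles
of length ≤ 8 an exhaustive n! enumeration is provided and serves as the
exact reference in the tests.

For cohort-level work, the per-animal mean dopamine is estimated as the
**rhythm-adjusted mean**: the intercept of the {1, cos, sin} regression on
the dopamine profile at the animal's called period. A raw 4-hr sample mean
is biased by whatever oscillator phase the sampling window happened to
cover — severe when the period exceeds the window, as in high-tone animals —
while the mesor removes that phase dependence. The period-vs-dopamine
relationship is then an ordinary least-squares regression of τ on the
rhythm-adjusted means with a two-sided slope test.

## Wavelet scalograms and ridges

The continuous wavelet transform uses the complex Morlet wavelet with center
frequency ω₀ = 6 (the conventional admissibility-respecting default; the
analysis is run through PyWavelets' `cmor` with bandwidth 2, i.e. a unit
Gaussian envelope). Scales are log-spaced at 32 voices per octave over
1–12 hr, giving ≈ 0.09-hr resolution at 4 hr. Scale maps to Fourier period
via `p = 4πs / (ω₀ + √(2 + ω₀²))`; with the √s amplitude normalization this
puts a pure sinusoid's amplitude ridge at its true period (verified to
< 0.4% across 1.5–10 hr, well under one voice step). Amplitudes are
displayed as dB relative to the scalogram maximum, making the display
invariant to positive rescaling of the input.

The cone of influence marks points closer to an edge than the e-folding
distance √2·s; COI points are excluded from ridge statistics (the record
edges would otherwise bias 7-day windows). The default ridge is the per-time
argmax of amplitude across periods; a dynamic-programming variant with a
per-voice jump penalty is available for noisy scalograms. Per-animal period
variability is the mean and SD of the non-COI ridge periods (≥ 100 points
required).

## Filtering and waveforms

Both display filters are zero-phase by forward–backward application and have
unit DC gain. The Butterworth low-pass (default cutoff period 1 hr, order 2
per pass → effective order 4) is designed with the bilinear transform; its
exact two-pass magnitude `1 / (1 + (tan(πf/fs)/tan(πf_c/fs))^{2n})` is used
as the closed-form oracle in the tests. "Recursive smoothing" (default span
2 hr) is a single-pole exponential smoother with per-pass time constant
span/2 — the same convention as pandas' `ewm(span=…)` — initialized at
steady state so constants pass exactly, run forward then backward for a
symmetric, unshifted impulse response. Both filters reflect-pad by five
cutoff/span lengths to suppress endpoint transients on short (20-hr)
windows. Filtered activity traces are floored at zero, since filter
undershoot below zero counts is a display artifact.

Daily (or modulo-τ) waveforms fold the series at the chosen period and
report per-phase-bin mean ± SEM across cycles, excluding masked bins, with a
numerically stable two-pass variance. Bout counting finds local maxima of
the folded mean treated circularly, with a prominence threshold of 20% of
the waveform's range.

Actograms wrap the record row-wise at a chosen modulo (trailing partial
cycle dropped, missing bins blank). Double plotting places cycle i and i+1
side by side — the standard chronobiology convention. Temperature actograms
map 34–38 °C to tick height by default.

## The DUO generator

The generator realizes a dual-oscillator picture: an ultradian oscillator
whose output is gated by a circadian process, the two integrating at a
common effector into the observed activity. Its defaults are the study
conditions the analysis stages are validated against:

| Parameter | Default | Meaning |
| --- | --- | --- |
| τ₀ | 4 hr | baseline ultradian period at tone 1 (control animals) |
| k (period_slope) | 4 hr/tone | linear period–tone law τ = τ₀ + k·(tone − 1); tone 3 (transporter-knockout regime) triples the period |
| bout_shape p | 2 | rectified-cosine exponent of the bout envelope |
| mean_rate | 50 counts / 0.1-hr bin | intensity at a bout peak; Poisson counts per bin |
| cycle_jitter_sd | 0.2 hr | SD of per-cycle period; carried by the *phase*, so ridge SD statistics can recover it |
| gate_depth g | 0.1 | fraction of activity permitted in the light (or subjective-rest) phase |
| duration, dt | 168 hr, 0.1 hr | 7 days at the canonical bin width |
| dialysate | 12 × 20 min, mean 2 nM, 30% relative amplitude, 0.2 nM noise | phase-locked dopamine profile |

Phase, not amplitude, carries the cycle-to-cycle jitter: per-cycle periods
are drawn Normal(τ(tone), jitter), truncated at τ/4, and the phase advances
piecewise-linearly through them. The initial phase defaults to 0.5 cycles
(first bout peak half a period into the record); cohort animals draw it
uniformly at random, since dialysis in free-running animals starts at an
arbitrary oscillator phase — with a shared fixed phase, the 4-hr dopamine
window would systematically cover the same part of the cycle in every
animal and bias the cohort regression. Dose–tone maps for methamphetamine,
amphetamine and haloperidol are monotone placeholders (linear gains for the
stimulants calibrated so 100 mg/l methamphetamine maps to tone 3; an
exponential decay toward a 0.4 floor for haloperidol); no pharmacokinetics
are modeled.

What the generator does **not** emulate: bout waveform asymmetry and
duty-cycle variation (real bouts are skewed; the rectified-cosine family is
a parameterization choice), activity-independent dopamine sources,
overdispersion beyond Poisson (a negative-binomial option exists but is off
by default), temperature rhythms, and drug kinetics. Passing tests
demonstrate that the analysis chain recovers the structure this model
plants at realistic noise levels — not that real recordings satisfy the
model.

## Numerical choices and degenerate inputs

- Lomb–Scargle equals the classical (Schuster) periodogram on gap-free even
  sampling **at frequencies commensurate with the record span**; the oracle
  tests evaluate on such a span-aligned grid, where agreement is at machine
  precision. At arbitrary frequencies the two differ at O(1/N) by
  construction.
- Constant series: periodogram power is defined as identically zero
  (variance 0); cosinor amplitude is 0 with mesor = mean; a constant
  dopamine profile is incomparable (normalization error).
- Problem sizes: the validation suite uses 7-day records at 0.1-hr bins
  (1,680 samples), 100-replicate recovery/power sweeps, 500-replicate
  calibration, 10,000–100,000 permutations, and 8-animal cohorts — sizes at
  which every statistic is stable yet the full suite runs in about a
  minute.
- Seeds are threaded explicitly everywhere (generator, permutation test,
  cohort construction); identical seeds give bit-identical counts and
  reports.

## Known limitations

- The significance threshold's independent-frequency count M is the grid
  size, which is deliberately conservative; absolute power values and the
  threshold line are therefore not comparable with proprietary software
  (ClockLab) output, only called periods and band summaries are.
- The min–max normalization before the concordance SSE is one of several
  defensible schemes; reported SSE magnitudes depend on it.
- The exact recursive-smoothing and ridge-extraction variants used in prior
  Matlab analyses are unrecoverable; quantitative values are defined
  against the conventions documented here.
- `rhythm_adjusted_mean` on windows much shorter than one period leans on
  the cosinor shape assumption; with heavy model mismatch the raw mean may
  be preferable despite its phase bias.
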