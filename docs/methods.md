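# Methods

This note documents the generative model behind the synthetic closed-loop
sessions, the analysis chain, the numerical conventions, and the design
choices that were genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The scientific setting

In an alpha-triggered TMS-EEG experiment, a real-time system watches one
occipital EEG channel and fires a TMS pulse whenever 8–13 Hz band power
exceeds a per-subject threshold, so every pulse lands in a high-alpha brain
state. The analysis then asks how the occipital alpha rhythm behaves after
the pulse: an initial event-related desynchronisation (ERD) back to the
resting level while the TMS-evoked potential (TEP) plays out, followed by an
induced event-related synchronisation (ERS) whose amplitude and *duration*
depend on the stimulated site. The duration — how long the rest-state
z-scored alpha power stays above the two-sided 5% normal critical value
1.96 — is the headline statistic; stimulating a default-mode node (MPFC-like
condition) yields a higher and longer ERS than a dorsal-attention node
(SPL-like condition).

## Synthetic session generator

One session at sampling rate `fs` (default 1000 Hz; desk-scale rather than
a hardware-grade 5 kHz) and 8 channels contains:

* **Background EEG**: per-channel 1/f Gaussian noise (amplitude spectrum
  `f^(−1/2)`, SD 3 µV) plus an alpha carrier `e(t)·cos(2π·10 t + φ)` scaled
  by an occipitally dominant channel topography. The envelope `e(t)` is a
  base level (4 µV) plus Poisson-arriving Hann-shaped bursts (40/min,
  0.3–0.9 s long, lognormal amplitudes with log-mean 1.25, log-SD 0.35).
  Dense, moderate bursts were chosen over sparse large ones so that
  trial-averaged envelope traces are stable at ~70 trials; rest-window
  variability of the averaged scout envelope is then ≈ 4–5% of its mean.
* **Closed-loop triggering**: the generator runs the *same* window scan as
  the offline detector (non-overlapping 250 ms rectangular-window FFTs,
  band-inclusive bin sum, 5 s minimum ISI) on the signal as it is being
  built. The threshold is a quantile of window powers over a separate 60 s
  rest segment. The stimulator fires 5 ms after the end of the detecting
  window (a trigger-to-pulse latency equal to the artifact's pre-width), so
  the detecting window itself is never contaminated by the artifact and an
  offline re-run of the detector reproduces the embedded trigger times
  sample-exactly — the property the closed-loop tests assert.
* **Per-pulse response**, all anchored at the pulse time:
  * a biphasic artifact confined to −5 … +10 ms (500 µV scale);
  * a TEP of two Gaussian deflections (N100 at 100 ms, −8 µV; P200 at
    200 ms, +6 µV) tapered to be exactly zero from 0.5 s on;
  * a multiplicative envelope modulation: raised-cosine ERD from the
    pre-pulse value down to `min(0.8·e₀, rest)` reached at 0.3 s, held to
    the ERS onset (0.45 s); a 0.1 s raised-cosine rise to
    `rest·(1 + A/100)`; a plateau; a 0.1 s fall back to rest. The plateau
    is sized so that the bump's full width at half height equals the
    configured `ers_duration` — the quantity the duration estimator
    recovers. Defaults: MPFC-like A = 35%, D = 1.08 s; SPL-like A = 20%,
    D = 0.8 s.

Three structural choices deserve explanation because they address a genuine
selection bias of closed-loop designs:

1. **Detection quantile 0.6 for generation** (the offline calibration
   default stays at 0.9). When the threshold is high, the detector spends
   long stretches waiting sub-threshold after the 5 s lockout expires; the
   pre-pulse "rest" window (−1.9 … −0.5 s) of such trials is then
   *conditioned on sub-threshold power* and sits systematically below the
   unconditioned background. With a lower quantile the post-lockout wait is
   typically shorter than the 0.5 s gap between the rest window and the
   pulse, so the rest window falls inside the detector's refractory period
   and stays unbiased. This also produces a pre-TMS baseline elevation of
   ~10–15% over rest, the realistic scale for alpha-triggered designs.
2. **Per-trial rest anchoring**: each trial's ERD/ERS profile relaxes to the
   mean background envelope over *that trial's own* rest window, making
   rest-referenced z-scores self-consistent whatever the residual
   conditioning.
3. **Slow burst recovery**: after the ERS decays, the envelope crossfades
   from the profile's rest level back to the stochastic background over
   1.5 s — spontaneous bursting resumes gradually after the perturbation.
   A side benefit is that the late epoch tail is quasi-deterministic, so
   supra-threshold excursions there reflect the modelled response, not
   background burst wander.

About 5% of trials receive an additional 400 µV muscle-like burst at a
random post-pulse time; these are the trials the automated rejection stage
is expected to remove.

**Cohorts** draw per-subject condition parameters as
`condition mean + shared subject effect + residual`. For durations the
shared effect SD is 0.48 and the residual SD 0.19 (fractions of the grand
mean ≈ 0.94 s), giving marginal spreads ≈ 0.49 s per condition and a
within-subject condition correlation high enough that a paired test on 10
subjects has realistic power for a 0.28 s mean difference; matching both
the marginal spreads and paired-test behaviour of group data requires such
a shared component. Non-positive draws are rejection-sampled and counted.
Amplitude effects use fractional SDs 0.25 (shared) and 0.10 (residual).

Cohorts can also emit **trial-averaged trace mode** data: the per-subject
averaged scout envelope is built directly from the same profile functions
(rest level ~5 µV lognormal across subjects; pre-pulse elevation
`1 + 0.35·e^{t/0.3}`; smoothed Gaussian noise with ≈ 100 ms correlation and
SD 4.5% of the rest level, calibrated to the variability the full session
generator produces at 70 trials). This path feeds Monte-Carlo studies —
hundreds of cohort replicates through the real duration estimator and the
real paired test — where synthesising hundreds of full EEG sessions would
be pointlessly slow. Trace mode shares the generative profile but not the
signal path: it exercises the estimator and the group statistics, not the
preprocessing chain, which is covered by full-session runs.

What the generator does **not** emulate: anatomy (no head model — the
minimum-norm module runs on a random full-rank gain fixture with
heterogeneous column norms, and the default analysis path uses a
sensor-level occipital scout), ocular or cardiac artifacts, non-stationary
alpha frequency, phase-locked components of the induced response, and any
coupling between TEP amplitude and alpha state. Passing tests therefore
demonstrate that the *procedures* are correct and recover known ground
truth under the assumed signal structure, not that the assumed structure
exhausts real TMS-EEG data.

## Analysis conventions

* **Window band power**: mean-removed rectangular-window DFT; one-sided
  per-bin mean-square contributions; bins with `8 ≤ f ≤ 13` Hz inclusive
  are summed (an on-bin sinusoid of amplitude `a` in the band contributes
  `a²/2`; Parseval over all bins recovers the window's mean square).
* **Epochs**: half-open `[−2, 4)` s, exactly `6·fs` samples. The artifact
  cut replaces samples with `−0.005 ≤ t ≤ 0.010` s; the interpolation line
  joins the nearest samples outside the cut, and the added white noise SD
  matches the linearly detrended −60 … −10 ms segment.
* **Filtering**: zero-phase (forward-backward) everywhere, switchable to
  causal; high-pass Butterworth order 2 at 0.5 Hz; band-pass for the
  envelope is a 4th-order Butterworth 8–13 Hz with mirror padding of one
  filter length, trimmed after the Hilbert transform.
* **Downsampling**: analysis default 250 Hz so the factor from 1 kHz is an
  integer, handled by a single-stage order-8 zero-phase IIR decimator;
  non-integer ratios fall back to polyphase resampling.
* **"Alpha power"** is the envelope magnitude, not its square (a squared
  switch exists, off by default).
* **Rejection bound**: ±100 µV post-interpolation, an automated and
  reproducible stand-in for by-eye trial screening.
* **Minimum norm**: whitening by `C^{−1/2}` via eigendecomposition; depth
  order γ = 0.5; when λ² is unset it is `trace(G̃RG̃ᵀ)/n_ch / SNR²` with
  SNR = 3. Scouts are unweighted, sign-unflipped means.
* **Cluster test**: paired t per time point; two-sided cluster-forming
  threshold at α = 0.05 on n−1 degrees of freedom; clusters are maximal
  contiguous same-sign supra-threshold runs scored by their signed t-sum;
  the null is the maximum |mass| over sign flips of the subject difference
  traces — exhaustive (deterministic, seed-free) when `2ⁿ ≤ n_perm`, else
  Monte-Carlo with the `(b+1)/(m+1)` estimator. Zero-variance columns map
  to ±10⁶ rather than NaN so degenerate shifts behave as infinite-t limits.
  In the exhaustive path the observed t is taken from the identity row of
  the permutation computation, so enumerated p-values are bounded below by
  `2⁻ⁿ` bit-exactly.
* **Duration**: z against the rest-window mean and *time*-SD; threshold
  1.96; supra runs within `(0, 4]` s; the longest run is reported (a
  total-time variant sits behind a flag). A run's length is its sample
  count times the sample period.
* **Mann-Whitney U**: exact two-sided p by full enumeration of labelings
  for `n+m ≤ 12`, `min(1, 2·min(P(U≤u), P(U≥u)))`; otherwise the
  tie-corrected normal approximation with continuity correction.
* **Randomness**: one master seed; every stage derives named substreams via
  `SeedSequence` tuples, so reruns are byte-identical and stages are
  independently reproducible.

## Problem sizes used by the tests

The suite runs desk-scale versions of every study-shaped computation: 12- to
70-trial sessions, a 10-subject full-pipeline cohort for duration recovery,
200 trace-mode cohort replicates for the group-difference power check, 100
trace-mode null cohorts for the false-positive rate of the duration
comparison, and 1000 AR(1) null datasets × 1000 permutations for the
familywise error rate of the cluster test (the same computation
`scripts/acceptance.py` reports).

## Known limitations

* The closed-loop selection bias described above is intrinsic to
  alpha-triggered designs; the generator's countermeasures keep it from
  contaminating rest-referenced statistics, but analyses of real data
  should expect a conditioned rest window when detection thresholds are
  high.
* The duration estimator's crossing points depend on the ratio of the
  rest-window SD to the ERS amplitude; for weak responses (z-height near
  1.96) durations are censored toward zero, and occasional noise-induced
  run splitting or merging produces single-subject outliers. Group means
  are accurate to within a few percent under the default conditions;
  single cells are not guaranteed to be.
* The EDF writer stores 16-bit samples with per-channel physical scaling
  (quantisation ≈ range/65535) and pads the final 1 s record with zeros.
* Sessions are generated causally; envelope modulations multiply only the
  alpha component, so the 1/f noise floor is response-independent —
  convenient for testing, slightly unphysiological.
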