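# Methods

This note documents the models, numerical choices and limitations behind
`assrlab`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Envelope enhancement

**Model.** Speech is resampled to 16 kHz and analyzed with a Hann-windowed
STFT (frame length 128, hop 32; frame rate 500 Hz). Bin powers are pooled
into critical-band channels; the band envelope is
E(t, k) = √(Σ_bins w(k, bin) |X(t, bin)|²). A slow envelope
E_slow = A_slow · max(0, LP(E)) uses a causal 4th-order Butterworth low-pass
at 20 Hz along the frame axis and A_slow = 8; the peak envelope is
E_peak = A_peak · max(0, E − E_slow) with A_peak = 3.5. E_peak is mapped
back to bins, given the original frame phases, inverse-transformed and
recombined by weighted overlap-add (WOLA) into the peak signal p(t), and
s_EE = s + p.

Because A_slow > 1 and the low-pass has unit DC gain, E_slow converges to
8·E on any stationary segment, forcing E_peak = 0 there: the algorithm adds
energy only where the band envelope rises faster than the 20 Hz low-pass can
track. This is the testable core identity (stationarity ⇒ s_EE = s).

**Critical bands.** Band limits follow the Fastl & Zwicker critical-band
edges (100, 200, …, 6400, 7700 Hz) with the top band extended to the 8 kHz
Nyquist. That grid yields 22 bands; the published channel count for this
processing is 23, so the lowest 0–100 Hz band is split at 50 Hz — every
standard Bark limit is kept and the extra boundary sits where the 125 Hz FFT
resolution is coarsest, so it has no audible consequence. Each FFT bin is
modeled as a rectangle of one bin spacing; a band's analysis weight on a bin
is the fractional overlap. The weights therefore form a partition of unity
over bins, which makes band-power pooling exactly conservative (Σ_k band
power = Σ_bins bin power per frame) — an invariant the tests assert.
Synthesis weights are the per-band-normalized transpose.

**Framing and reconstruction.** `analyze_frames` itself is pad-free and
drops the incomplete tail frame (a 16000-sample input yields 497 frames).
The `enhance` entry point prepends `frame_length − hop` zeros (centering
frame 0 near t = 0), appends one frame of zeros (so every input sample is
covered), and trims the output to the input length. WOLA divides out the
explicitly accumulated overlap-sum of squared Hann windows, so resynthesis
of unmodified spectra reproduces the input to machine precision wherever the
window sum is non-zero; the round-trip test asserts < 1e−6 relative error.

**Phase of the peak signal.** The resynthesized peak spectrum reuses each
frame's original phase on every bin. This places the onset burst at the
correct temporal position and makes p add constructively to s (per-bin
|X + P| = |X| + |P| when phases match), so onset energy strictly increases —
the property the onset tests check. A fixed or zero phase would be equally
consistent with the envelope math but would neither localize nor guarantee
constructive addition.

**Filtering.** The 20 Hz low-pass runs forward-only (causal) from zero
initial conditions. The enhancement is conceptually an online process whose
defining feature is that the slow envelope *lags* onsets; zero-phase
filtering would erase that lag. The settling transient (~0.3 s) is excluded
from stationarity assertions.

## Stimuli

The carrier is seeded Gaussian noise shaped to a long-term average speech
spectrum model — piecewise-linear in dB on a log-frequency axis, flat to
500 Hz and −8 dB/octave above by default, RMS-normalized to 1. The true
spectrum of the original sentence corpus is not published; the model is a
configuration input (`CarrierSpec.ltass_breakpoints`) and the tests verify
the generated spectrum against whatever model is configured, not against a
fixed curve.

SAM: m(t) = (1 − d·cos 2πf t)/(1 + d), which spans [0, 1] at d = 1 and has
measured depth (max−min)/(max+min) = d exactly. PULS: per period, a linear
0→1 ramp over 30 ms, an immediate linear 1→0 ramp over 10 ms (no plateau —
the plateau behavior is unspecified in the source method; immediate decay is
the simplest convention and is what the timing verifier assumes), and zero
for the rest of the period. Both modulators use bin-locked rates
(4 → 3.90625 Hz, 20 → 19.53125 Hz, i.e. exactly 4 and 20 cycles per 1.024-s
epoch) so the steady-state response falls in one FFT bin of the analysis
epochs; "approximately 4 and 20 Hz" plus 1.024-s epochs is only mutually
consistent under this standard ASSR convention.

`measure_envelope_timing` folds the (Hilbert) envelope on the exact
modulation period into phase bins and cycle-averages; rise time is the
5%→95% crossing interval divided by 0.9 (rescaling to the full ramp), decay
likewise on the falling flank. On the pure modulator this recovers 30/10 ms
to sub-millisecond accuracy; on the noise-carrier stimulus the Hilbert
envelope blurs the ramp corners by ~1 ms, so stimulus-level checks use a
±1–2 ms tolerance.

Stimuli are written at digital full scale (peak 0.99); absolute acoustic
calibration is out of scope (there is no acoustic chain to calibrate).

## ASSR extraction

The processing order is: 2 Hz high-pass (2nd-order Butterworth, causal) →
hemisphere averaging (nine left, nine right parieto-occipital electrodes;
Cz carried through) → 1.024-s epoching → adaptive artifact rejection →
Cz re-referencing → per-epoch FFT → estimates. Rejection operates on the
three derived channels (LEFT, RIGHT, Cz): epochs are ranked by peak absolute
amplitude across channels and the 448 lowest-peak epochs are kept in
original order, which is exactly the "smallest amplitude threshold leaving
448 epochs" rule with ties broken toward earlier epochs for determinism.

Spectral values use single-sided amplitude scaling 2·X[k]/N so a cosine of
amplitude A µV at the bin yields exactly A e^{iφ}. The noise floor is the
across-epoch *complex* standard deviation (squared moduli of deviations,
n − 1 denominator) divided by √n; the complex convention matches the
bivariate Gaussian model underlying the Hotelling test, and for i.i.d.
complex noise with per-component SD σ it equals σ√2/√n, giving the 1/√n law
the tests regress for. Hotelling: T² = n x̄ᵀS⁻¹x̄ on the (Re, Im) components,
F = T²(n−2)/(2(n−1)) with (2, n−2) df, α = .05. Degenerate covariance
(identical epochs) maps to p → 0 for a non-zero mean and p = 1 for an
all-zero series. The implementation is cross-checked in the tests against an
independent multivariate-test implementation (pingouin).

The 2 Hz high-pass has passband gain 0.967 at 3.90625 Hz and 0.99994 at
19.53125 Hz. This is a property of the published chain, not a defect of the
implementation: exact-unity amplitude recovery is only observable at the
20 Hz condition, and the recovery checks are run there. No gain compensation
is applied, since the original chain applies none.

Recordings are assumed continuous and artifact-annotated-free; there is no
bad-channel interpolation. EDF/BDF input is supported through a thin
optional `mne` wrapper that resamples to a rate at which 1.024 s is an
integer sample count; the package's native container is a seeded `.npz`.

## Synthetic cohorts

One recording is 19 channels (18 montage electrodes + Cz) at 1000 Hz — the
rate at which a 1.024-s epoch is exactly 1024 samples — and 520 epochs
(532.48 s). Electrodes within a hemisphere carry the same injected sinusoid
(no spatial covariance model: the pipeline averages them anyway) plus
independent pink noise; Cz carries noise only.

**Pink noise** is white Gaussian noise passed through a standard 1/f
"pinking" IIR filter (warm-up discarded), normalized exactly to the target
RMS (default 20 µV per electrode). The filtered stream is mixing, so
successive epochs decorrelate the way real EEG background does. This matters
more than it looks: synthesizing 1/f noise in the frequency domain produces
a strictly periodic signal whose component at the epoch-commensurate
response bin stays phase-coherent across *all* epochs and is therefore
detected as a spurious "response" — in development this inflated the null
rejection rate from 5% to ~50%. The time-domain construction restores the
nominal type-I error, which the calibration tests verify.

**Artifacts** are 100-ms uniform bursts of ±300 µV added to all channels in
a random `artifact_rate` fraction of epochs (default 5%, capped at 12% so
448 clean epochs always survive). They only need to be separable by peak
amplitude, which is what the rejection rule uses.

**Between-subject variation** is a unit-mean log-normal multiplier
(σ = 0.3 on the log scale, i.e. ~30% coefficient of variation) drawn once
per subject and applied to both hemispheres and all conditions. Sharing the
multiplier within subject keeps each subject's left/right *difference*
proportional to their overall response size, which is what makes the small
0.04 µV group asymmetry statistically recoverable at n = 26; independent
per-hemisphere draws would bury it in between-subject variance at any
sensor-noise level. Response phase is uniform per subject and shared across
hemispheres (hemispherically coherent sources).

**Default group effect table** (µV, left/right): typical readers (TR)
0.50/0.70 for 4 Hz SAM (rightward +0.20), 0.77/0.50 for 4 Hz PULS (leftward
+0.27), symmetric 0.20/0.20 at 20 Hz; dyslexic readers (DR) symmetric
0.60/0.60 at 4 Hz and 0.18/0.22 at 20 Hz (rightward +0.04). Group sizes
default to 52 TR and 26 DR. Baseline amplitudes (~0.2–0.8 µV) and the 20 µV
electrode noise are set so that 448-epoch detection rates land in the
80–90% range typical of pediatric ASSR recordings, as the detection
proportions computed by the examples and tests show.

**What the simulator does not emulate:** volume-conducted spatial
correlation between electrodes, eye-blink/EMG spectral structure,
non-stationary alertness drift, and any test-phase (longitudinal) effects.
Passing tests demonstrate that the pipeline recovers what this signal model
injects — unbiased amplitudes, calibrated detection, correct lateralization
directions — not that real recordings satisfy the model.

## Group statistics

The lateralization contrast is the mean within-subject right-minus-left
amplitude; inference is a two-sided sign-flip permutation test (default
5000 resamples, p = (b+1)/(n_perm+1), minimum attainable p =
1/(n_perm+1)). A robust linear mixed-effects model with bootstrap inference
would be the full-data analysis; the permutation contrast tests the same
directional hypotheses per cell, is exact under the symmetric null, and
keeps the package free of model-fitting machinery. Holm correction (via
statsmodels) is applied within each group × modulation-frequency family,
mirroring per-interaction post-hoc families.

**Check problem sizes.** The end-to-end acceptance tests use: the full
default cohort (52 + 26 subjects) for the two 4 Hz conditions; a separate
26-subject dyslexic-reader cohort at 20 Hz simulated at a reduced 5 µV noise
setting, because a power analysis of the default noise gives a per-subject
paired-difference SE of ~0.13 µV — a 0.04 µV effect at n = 26 is then
undetectable by design, and reducing measurement noise (not inflating the
effect) is the honest way to verify the pipeline recovers it; a 10-subject
cohort at the 20 Hz condition for amplitude recovery (per-subject error
< 3 × noise floor; cohort-mean within 10%); and 2000 Monte-Carlo replicates
of 448 epochs for Hotelling type-I calibration.

## Interface

The package is a library: the importable API plus the narrative scripts in
`examples/` are the intended surface, with `scripts/acceptance.py` as the
reproducibility entry point. YAML loading for the two parameter blocks lives
in `assrlab.config`. No shell CLI is shipped; every operation is one or two
function calls from Python.

## Known limitations

* The exact band-weight construction and peak-signal phase convention of the
  original enhancement implementation are not published; the partition-of-
  unity weights and original-phase resynthesis used here are documented
  choices validated by their conservation/localization properties, not by
  comparison to the original code.
* The LTASS carrier model is generic, not the original sentence corpus.
* Envelope-timing measurement assumes the modulator is strictly periodic at
  the stated rate.
* The simulator's independence assumptions (noise across electrodes and
  epochs) are optimistic relative to real EEG; detection-rate numbers from
  simulations should be read as calibration checks, not clinical forecasts.
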