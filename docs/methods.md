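# Methods

`smrloop` re-implements, as a fully synthetic-testable pipeline, the
computational chain of a closed-loop sensorimotor-rhythm (SMR)
neurofeedback study: online event-related desynchronization (ERD) scoring,
per-participant spectral calibration, offline event-related spectral
perturbation (ERSP) evaluation, EMG reaction-time extraction, motor-evoked
potential (MEP) and short-interval intracortical inhibition (SICI)
quantification, and the group statistics layer. This note documents the
models, the estimator choices, and what the synthetic data can and cannot
show.

## Signal model of the synthetic EEG

Each channel of the generated EEG is

    x_c(t) = g_c · a(t) · [sin(2π f_mu t + φ_k) + β sin(4π f_mu t + ψ_k)]
             + n_c(t) + m(t) + L sin(2π · 50 t + θ)

* **Mu oscillator.** An amplitude-modulated sinusoid at `mu_freq`
  (default 11 Hz) with a random phase per trial and an optional beta
  harmonic at twice the mu frequency (`beta_coupling`, default 0.25). The
  amplitude envelope `a(t)` equals `mu_amp_rest` (default 25 µV) at rest and
  `mu_amp_rest · sqrt(1 − erd_depth)` during motor imagery, so that mu-band
  *power* during imagery is `(1 − erd_depth)` × rest power by construction.
  The attenuation ramps linearly across the 1-s ready epoch, matching the
  gradual onset of desynchronization between the rest and imagery periods.
* **Spatial structure.** The target channel ("C3") carries the oscillator
  at unit gain; its six Laplacian neighbours at `neighbor_mu_gain`
  (default 0.3), so the large Laplacian keeps a focal residual while the
  common average reference (CAR) keeps 1 − (1 + 6·0.3)/7 = 0.6 of the
  target amplitude.
* **Noise.** Independent 1/f-shaped Gaussian noise per channel
  (`noise_amp`, default 8 µV total sd; `noise_exponent` 1) plus one shared
  common-mode 1/f component (5 µV) that exercises the cancellation
  properties of both spatial filters, plus 50 Hz line noise (2 µV).
* **Trial structure.** 6 s rest, 1 s ready, 5 s imagery per trial
  (configurable).

**Why 25 µV mu against 8 µV noise.** The ERSP estimator divides band power
during imagery by band power at rest; a broadband noise floor N inside the
scoring band biases the recovered depth by ≈ 100·d·(N/S) percentage points
at injected depth d, where S is the mu contribution to band-mean power.
After CAR the target's mu band-mean is S ≈ (0.6·25)²/2/4 ≈ 28 µV²/Hz while
the 1/f floor at ~10 Hz is N ≈ 0.9 µV²/Hz, so the worst-case bias at
d = 0.6 stays under ~2 points. These amplitudes are at the strong end of
the physiological range for a well-expressed central mu rhythm.

Inter-trial depth variability (`erd_depth_sd`) is exposed as a free
parameter (default 0 for the generator; 0.05 in the cohort simulation)
because trial-to-trial ERD variability is not well characterised enough to
assert a canonical value.

## Online ERD scoring

The causal chain is Laplacian re-referencing (center minus the mean of six
neighbours), a causal 4th-order Butterworth band-pass 1–70 Hz with a 50 Hz
IIR notch (Q = 30; a standard narrow notch — no design was prescribed),
then a trailing 1-s Hann-tapered FFT every 100 ms (adjacent windows overlap
90 %; 1 Hz resolution at 1 kHz). Band power `A(t)` is the mean PSD across
the integer-Hz bins of the individually calibrated alpha band; the baseline
`R` is the band-mean of the stored median rest spectrum. The score is

    ERD(t) = (R − A(t)) / R × 100

clipped to [0, 100] for display (a hand-aperture display cannot go
negative); the raw value is retained for analysis. Filter state persists
across the session; the first second is excluded as warm-up. A trial's
score is the mean over imagery-epoch updates whose whole window lies inside
the imagery epoch. Yoked-sham feedback replays a donor participant's score
sequence on the recipient's trial clock and ignores the recipient's EEG
entirely.

## Calibration

From a no-feedback evaluation block, the per-frequency median PSD across
all rest windows gives R(f). The individual alpha frequency (IAF) band is
the integer-edged 3-Hz window inside 8–13 Hz ([8–11], [9–12] or [10–13])
maximising the mean per-bin ERD over imagery windows; ties go to the
lowest band (deterministic). The band center serves as the IAF median, and
the individual beta frequency (IBF) band is twice that center ± 2 Hz. The
1-Hz FFT grid makes integer band edges the only natural choice; whether the
"median of the IAF" should instead be an ERD-weighted median frequency is
left open — the band center is the only scalar consistent with the ± 2 Hz
construction.

## Offline ERSP

Zero-phase 4th-order Butterworth 3–40 Hz plus 50 Hz notch; epochs span the
rest onset to imagery end + 1 s; epochs whose peak absolute amplitude
exceeds 200 µV on any channel are rejected (the original criteria are
unreported; an absolute threshold is transparent and testable); an optional
ICA hook (FastICA) removes components correlating |r| > 0.8 with a supplied
artifact template; CAR; then the same 1-s / 90 %-overlap STFT.

The per-bin map is ERSP(t, f) = (A(t, f) − R(f)) / R(f) × 100 with R(f)
the per-bin median over all rest windows of the trial set (negative values
= desynchronization). **Band summaries average power before taking the
ratio**: the per-trial band outcome is
(mean band power over imagery windows − R_band) / R_band × 100, with
R_band the median over rest windows of *band-mean* power. Two reasons:
(i) this is the same order of operations as the online score, so online
and offline values agree in magnitude on shared data (verified to within
±5 points); (ii) averaging per-bin ERSP across a band is badly biased
wherever a bin is noise-dominated — windowed PSD values are approximately
scaled chi-squared with two degrees of freedom, whose mean exceeds the
median by a factor 1/ln 2 ≈ 1.44, so a mean-A/median-R per-bin ratio reads
≈ +44 % "synchronization" at pure-noise bins and dilutes the band average.
The imagery mean uses windows fully inside 0.5–5 s after imagery onset,
avoiding windows that straddle the ready/imagery boundary. The block
outcome is the median over trials; block baselines are computed from that
block's own rest epochs, keeping evaluation blocks self-contained.

## EMG reaction time

EMG is band-pass filtered with the acquisition band (10–500 Hz, 2nd-order
Butterworth, causal) and rectified (absolute value). The detection
threshold is 4 × SD of the rectified baseline in the 500 ms before the go
cue. The onset is the first post-go sample that exceeds the threshold *and*
whose following 10 ms of rectified signal exceeds the threshold on
average. The sustained-mean form is what makes a 4×SD rule well-posed for
stochastic EMG: individual rectified samples of a genuine burst dip below
any threshold, while isolated baseline noise spikes cross it, so a literal
"stays above for 10 ms" criterion never fires and a bare first-crossing
rule fires early. Setting `sustain=0` recovers the literal first-crossing
rule. Detection can only lag the true onset; at burst-to-baseline SNR 8
the median lag is ~1 ms and 95 %+ of trials land within ±5 ms.

Trials with pre-cue EMG potentiation (any sustained exceedance in the 1 s
before the cue, thresholded against an earlier quiet reference segment so a
pre-cue burst cannot inflate its own criterion) are flagged and excluded.
Session RT is the mean over accepted trials; pre-movement TMS probes are
scheduled at 50 % and 80 % of the baseline mean RT after the cue.

## MEP and SICI

Sweeps are filtered 10–450 Hz (4th-order Butterworth, zero-phase) with a
50 Hz notch and segmented −100 to +150 ms around the stimulus. The MEP is
quantified as max − min inside a 15–60 ms post-stimulus search window (the
canonical forearm MEP latency range; the window is configurable).
Optional ±2 ms stimulus-artifact blanking is off by default for clean
synthetic sweeps. SICI is the mean paired-pulse MEP expressed as a
percentage of the mean single-pulse MEP per condition (rest, 50 % and 80 %
pre-RT); lower percentages mean stronger inhibition, and pre/post change
scores are post − pre. Because the ratio is scale-invariant, linear
filtering leaves noise-free SICI values exact even though it shaves ~2 %
off individual peak-to-peak amplitudes. Participant-level exclusion rules
(absent SICI, stimulator-output ceiling) are modelled as QC flags on the
outcome table rather than silent drops. The synthetic MEP is a damped
80 Hz sinusoid starting 20 ms post-stimulus, scaled so its noise-free
peak-to-peak equals the configured amplitude.

## Group statistics

The mixed-design repeated-measures ANOVA uses the univariate
sums-of-squares approach on orthonormal within-subject contrasts: for each
within effect (one or two within factors, optionally crossed with one
between-subject factor), the contrast scores yield the effect SS, its
interaction-with-group SS, the subject-by-effect error SS, the
Greenhouse–Geisser epsilon and the Mauchly sphericity statistic from one
pooled covariance. GG-corrected p-values are reported whenever Mauchly's
p < 0.05 (the trigger threshold is a documented choice). The two-way case
is verified against pingouin's independent implementation; on two-level
within designs F equals the squared paired t to 1e-8, and the interaction
type-I error calibrates to 0.05 ± 0.02 under the null. Designs are assumed
balanced (one observation per cell per subject).

The covariate model ("baseline MEP amplitude as a covariate") is realised
as an ANCOVA on change scores — the covariate enters as a
between-participant regressor on post − pre (pingouin backend). This is
one of two natural parameterisations; conclusions should be checked
against the cell-means parameterisation rather than assumed equivalent.

Effect sizes: Cohen's d (paired: mean/sd of differences; independent:
pooled-sd). Partial correlations via linear-regression residuals
(pingouin), p from the t-transform with df = n − 2 − k. FDR correction is
Benjamini–Hochberg (statsmodels), tested against a brute-force step-up
implementation. The a-priori sample size inverts two-tailed noncentral-t
power; for d = 0.60, α = 0.05, power = 0.80 the paired design requires
n = 24 — the paired family is the default because it is the family that
reproduces that total. Between-group standardized mean differences of
change scores come with normal-approximation 95 % CIs.

## End-to-end synthetic study

`smrloop.pipeline` simulates a full two-group pre/post study at the raw
signal level: 11 participants per group; each contributes EEG evaluation
blocks (8 trials per block at 1 kHz — a deliberately compact demonstration
scale; trial counts are configurable), a 10-trial EMG session at 10 kHz,
and MEP sweep sets (10 single + 10 paired at rest, 7 + 7 per pre-RT
condition) at both time points. Real-group participants carry a latent
responsiveness gain g ~ N(1, 0.3) that scales injected pre→post changes of
+0.25 ERD depth, −40 ms reaction time and +20 points of pre-movement SICI
release (a standardized effect of roughly d ≈ 1.5 on the change scores —
chosen so the design has analytic power ≈ 0.93 with headroom for
extraction noise); sham participants have zero true change. The shared
gain induces the between-participant coupling that the ΔSICI–ΔRT partial
correlation (controlling ΔERSP) is designed to detect. Calibration is
performed on the pre block and reused for post, as in a real study.

## What the synthetic data does not show

The generator has no volume conduction or realistic forward model, no
artifact taxonomy beyond amplitude outliers/blink-like templates and line
noise, no TMS pulse artifact in the EEG, no non-stationary background
spectra, and mu rhythm modelled as a narrowband line rather than a broad
physiological peak. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under their own assumptions
— not robustness to real-world EEG/EMG pathologies.

## Numerical choices

* PSD normalisation matches scipy's windowed periodogram (one-sided
  density, window-power compensated); every STFT column equals the direct
  DFT of the identically tapered segment to < 1e-10 relative error.
* Degenerate inputs raise: non-positive baseline power, empty rest/imagery
  window sets, missing design cells (named), all-trials-rejected, empty
  MEP cells (named), zero-variance effect sizes.
* Tie-breaks: IAF candidate ties go to the lowest band; clipping uses
  median(0, raw, 100).
* All generators draw from a single seeded `numpy.random.Generator` per
  call; identical seeds give bit-identical outputs, and seeds are recorded
  in output metadata.
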