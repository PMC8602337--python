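# Methods

This note documents the models, algorithms and numerical choices behind
`sleeposc`, and what the synthetic-data validation does and does not
demonstrate.

## Signal model and preprocessing

Recordings are multi-channel referenced EEG in microvolts. Three
modality presets band-limit and resample the raw signals:

| modality | high-pass | low-pass | target rate | extra |
|----------|-----------|----------|-------------|-------|
| EEG      | 0.5 Hz    | 70 Hz    | 128 Hz      | —     |
| EOG      | 0.16 Hz   | 35 Hz    | 64 Hz       | 5-sample moving average |
| EMG      | 10.61 Hz  | 100 Hz   | 128 Hz      | —     |

Filters are windowed-sinc linear-phase FIRs (Hamming window; the number
of taps is chosen from the transition width, by default half the lower
cutoff, which places the >20 dB stopband within one octave of each
edge). They are applied by centred convolution so the group delay is
fully compensated and event timestamps downstream are unshifted.
Downsampling uses polyphase resampling with its own anti-alias filter.
Only the EEG path feeds the analyses here; the EOG moving-average
window length is a convention without downstream effect (no
EOG/EMG-based analysis is implemented).

Artifact intervals are half-open `[start, end)` in seconds, per channel
or `ALL`. Masking flags samples rather than deleting them, so the time
base is preserved; masked samples are excluded from every detector
statistic and from every density denominator (artifact-free stage
minutes).

## Spindle detection

Per channel and band (slow 9–12, fast 12–15, overall 9–15 Hz), three
criteria are computed:

1. **Moving RMS** of the band-filtered signal, 300 ms windows every
   100 ms. Threshold: mean + 1.5 SD of the night's own RMS series,
   computed *per channel and per stage* over artifact-free N2/N3 bins.
   Per-stage statistics are used because background amplitude differs
   between N2 and N3; a pooled threshold sits above the N2 distribution
   and below the N3 one, trading N3 false positives against N2
   sensitivity (about a threefold N3 excess in simulation).
2. **Moving correlation** (Pearson) between the broadband 0.5–40 Hz
   signal and the band-filtered signal, same grid, threshold 0.65.
3. **Relative power**: band power over broadband power per 2 s Hann
   STFT frame computed every 200 ms, held (previous value) onto the
   100 ms grid, against a per-subject, per-stage threshold: the mean
   relative power over that stage's frames of a designated calibration
   night, averaged across channels. If no calibration night exists,
   thresholds must be supplied explicitly; there is no silent default.

A decision bin is positive when at least two criteria hold and its
window start lies in N2/N3. Runs of positive bins become candidates;
within-channel candidates separated by under 0.3 s are merged (envelope
dips would otherwise split one spindle), then the 0.5–2 s duration gate
is applied. Event frequency is the zero-crossing rate of the
band-filtered segment, amplitude its peak-to-peak range, and each
event's mean relative power is kept for deduplication: events on
different channels with onsets within 500 ms form one group (transitive
closure) of which only the member with maximal relative power survives;
ties go to the earliest onset. Densities are counts per artifact-free
minute; per-channel rows use pre-deduplication events, pooled rows use
the deduplicated set.

NaN criterion values (masked or zero-variance windows) count as "not
met". Raising any threshold can only remove events (monotonicity,
tested).

## Slow-wave detection

C3-A2 only, N3 only (N2 is excluded so K-complexes are not counted).
The signal is band-passed 0.5–3.5 Hz with a linear-phase FIR with a
0.2 Hz transition band. Half-waves are maximal runs of one sign;
each negative half-wave is paired with the immediately following
positive half-wave; down-/up-state durations are the half-wave
durations. Retention bounds (all strict): trough magnitude (40, 300) µV,
positive peak (10, 200) µV, peak-to-peak (75, 500) µV, down-state
(0.3, 1.5) s, up-state (0.1, 1.0) s. Slope is peak-to-peak amplitude
over the trough-to-peak interval (a maximum-first-derivative variant is
available). Stage membership is decided by the trough's epoch; events
with a masked trough are dropped. Amplitudes are measured on the
filtered signal — the same domain in which the criteria are defined.

## Spectral band power

Welch PSD with 8 s Hann segments at 50% overlap, density scaling
(µV²/Hz), so the integral over frequency equals the signal variance
(Parseval, verified to ±5% on stochastic signals). Segments never span
masked samples or stage boundaries; unmasked runs shorter than 8 s are
dropped and runs are combined by segment-count-weighted averaging.
Band powers are trapezoidal integrals; with the 0.125 Hz grid the band
edges 0.5/3.5/9/12/15 fall on grid points and (9–12)+(12–15)=(9–15)
holds to numerical precision. Spindle-band powers are averaged across
channels per stage; the slow-wave band uses C3-A2 in N3 only.

## Sleep statistics

Epoch-resolution arithmetic; "asleep" means any of N1/N2/N3/REM. Sleep
onset is the start of the first sleep epoch, final awakening the end of
the last; SPT is that interval, WASO the wake within it, TST = SPT −
WASO. These definitions make TST + WASO = SPT exact and the per-stage
minutes inside the sleep period sum to TST. Anchoring on the first
sleep epoch (rather than lights-off, which the inputs do not carry) is
a declared convention.

## Mixed-effects inference

Metrics are averaged within (subject, condition, stage, melatonin)
cells — conditions PRE/IN/POST, stages N2/N3 for spindle metrics, no
stage key for slow-wave and global sleep metrics — and modelled with a
random subject intercept:

    y ~ Condition * Stage + Melatonin + (1 | subject)      (spindle metrics)
    y ~ Condition + Melatonin + (1 | subject)              (SW / global metrics)

Melatonin enters as a non-interacting covariate and is dropped
automatically when it never varies. Factors are sum-to-zero coded, which
makes the Wald F-test of each term's coefficients a type-III test.
Fitting is REML via statsmodels' MixedLM (with optimizer fallback:
lbfgs → powell → nm → bfgs, rejecting degenerate likelihoods).

Denominator degrees of freedom are Satterthwaite: for a contrast c,
df = 2·g²/Var(g) with g(θ) = c′(X′V(θ)⁻¹X)⁻¹c, θ = (σ²_resid,
σ²_subject), using the closed-form REML likelihood of the
random-intercept model; Var(g) comes from the delta method with the
inverse observed information, all derivatives by central finite
differences (relative step 10⁻⁴). Multi-df terms eigendecompose the
contrast covariance and combine the per-direction dfs via
df = 2E/(E−q), E = Σ νᵢ/(νᵢ−2). When the subject variance collapses to
zero the fit is flagged singular and the residual df (n − p) is used.
This layer reproduces lme4/lmerTest/emmeans (REML variances, type-III
F, Satterthwaite dfs, EMMs, Tukey p-values, confidence limits, ML AIC)
to at least three decimals on a fixed test dataset.

Estimated marginal means average the fixed-effect predictions over the
factorial grid with equal weights (melatonin balanced). Pairwise
condition contrasts are differences of EMMs; the familywise-adjusted
p-value uses the studentized range (Tukey HSD, k = 3) and the reported
confidence interval uses the Tukey critical value q₀.₉₅/√2 ·SE.
Unadjusted t-based 95% intervals are carried alongside; simulation
coverage checks use the unadjusted interval (the adjusted one is
deliberately conservative, ≈98% per-contrast). Shapiro–Wilk runs on
conditional residuals (BLUPs subtracted). AIC comparisons between
fixed-effect structures refit both models by ML, since REML AICs are
not comparable across different fixed effects.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 4
subjects; 2 PRE, 4 IN and 3 POST nights each; 4 referenced EEG channels
at 256 Hz; melatonin/placebo alternating across PRE and IN nights (one
melatonin-naive subject; POST always placebo); the first PRE placebo
night flagged for threshold calibration.

*Hypnograms* follow ~90 min NREM/REM cycles (N1→N2→N3→N2→REM) with
seeded jitter, at least one initial wake epoch and one WASO bout, N3
front-loaded across cycles. Inflight sleep curtailment converts
trailing sleep epochs to wake (default 41.976 min, entering SPT/TST).

*Background EEG* is Gaussian noise spectrally shaped to 1/f^α (α = 1)
with per-stage RMS scaling (N3 1.4 > N2 1.0 > N1 0.8 > REM 0.7 ≈ W 0.6)
around a 15 µV N2 broadband RMS — conventional values, configurable;
the recordings the design emulates carry no published amplitude norms.

*Spindles* are Hann-windowed sinusoidal bursts (phase aligned so the
envelope centre is a carrier peak) placed by stage-conditional Poisson
processes; each spindle is injected into every channel (full amplitude
on a focal channel, 0.55–0.9 gain elsewhere) because one thalamic event
is visible across the montage — this is what makes cross-channel
deduplication meaningful. Defaults: fast 2.2/min in N2 (0.8 in N3) at
13.4 Hz, slow 1.5/min in N2 (0.8 in N3) at 10.7 Hz, duration
0.9 ± 0.25 s in [0.5, 2] s, peak-to-peak 40 ± 8 µV. Same-kind overlap
beyond 50% is rejected so truth-to-detection matching stays
unambiguous.

*Slow waves* are biphasic half-sine transients in N3 on C3-A2
(3/min, down-state 0.4–1.2 s, up-state 0.2–0.8 s). Because the
detector measures amplitudes on the 0.5–3.5 Hz filtered signal, which
attenuates long biphasic transients by up to ~2.5×, the generator
scales each raw waveform so that its *band-passed* trough equals the
drawn truth amplitude (trough 90 ± 20 µV magnitude); truth records
carry the in-band amplitudes the detector should recover.

*Condition effects* enter as parameter shifts (defaults: fast density
+1.757/min IN, slow frequency +0.170 Hz IN, slow-wave trough −2.530 µV
IN, sleep curtailment 41.976 min IN) and subject heterogeneity as
Gaussian random intercepts — exactly the generative structure of the
random-intercept LMM downstream, so effect recovery is a meaningful
end-to-end test. All randomness derives from one seed, forked per
subject/session/stage by name; identical inputs give bit-identical
cohorts.

### What the synthetic validation does not show

The background is stationary Gaussian 1/f noise: it has no K-complexes,
arousals, ECG/EMG contamination, sharp transients or the strong
non-Gaussian delta bursts of real NREM sleep. Consequences worth
stating plainly:

- Detection recall/precision on these simulations bound the algorithmic
  behaviour (gates, logic, matching), not performance on real EEG.
- The relative-power distribution of the Gaussian background is narrow
  and symmetric, so a calibrated *mean* threshold passes a large
  fraction of background frames. This inflates slow-band (9–12 Hz)
  false positives relative to real recordings, where dominant delta
  power pushes slow-band relative power far below the calibrated
  threshold; the band-selectivity simulation should be read with that
  in mind (true leakage of 13.5 Hz spindles into the slow band is
  small, ~7% of fast-band detections).
- Welch/Parseval and oracle-equivalence checks are exact properties and
  transfer as-is.

## Problem sizes

Simulated validation nights are 90–120 min with 1–2 channels, chosen so
each night carries ≥100 ground-truth events while the whole suite stays
interactive. Statistical recovery uses summary-level simulation at 20
subjects (the cohort size the design emulates is too small for coverage
estimation) with 200 replicates per metric and 300–500 null replicates.

## Known limitations

- Random intercepts only (no random slopes), matching the target model;
  Kenward–Roger dfs are not implemented (Satterthwaite is used; the two
  agree closely for these layouts).
- EDF support is 16-bit EDF with one-second records; EDF+ annotations
  are not written.
- Spindle frequency is a single zero-crossing estimate per event; no
  within-event chirp.
- Only central/occipital referenced channels are modelled; topographic
  analyses are out of scope with a 4-channel montage.
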