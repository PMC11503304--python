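# Methods

## Model and labeling premise

The pipeline decodes a binary stress state from short windows of wearable
physiology. Its central assumption is temporal: a participant starting a
long, demanding task session is in a "non-stress" state and ends it in a
"stress" state, so the first k and last k task blocks of each session can be
used as labelled examples without any per-block annotation. Middle blocks
are deliberately unlabelled — they may be scored for trajectory plots
(`stress_model.score_session`) but never enter training or accuracy.

A support-vector regressor (RBF kernel, C = 1.0, ε = 0.1) is fit on
standardized per-epoch feature vectors against the 0/1 block labels and
emits a continuous stress score. Aggregation to blocks is by majority vote:
an epoch "indicates stress" when its score exceeds 0.5, and a block is
stressed when strictly more than half of its epochs do — an exact tie is
classified not-stressed, reading "more than half" literally. For HRV there
is a single feature row per block, so the vote degenerates to thresholding
that block's score; this is intentional and documented behaviour, not a
special case in the code.

Generalization is measured with leave-one-subject-out (LOSO)
cross-validation: the scaler and SVR are re-fit for every fold on the other
N−1 participants only, so no statistic of the held-out subject leaks into
training. Accuracy is correct labelled blocks over labelled blocks, reported
per participant with mean ± SEM (sample SD / √N).

## Signal processing choices

**R-R chain.** Four steps in fixed order: (1) intervals strictly below
300 ms or above 2000 ms become missing (the bounds themselves are kept);
(2) linear interpolation against index position, with leading/trailing gaps
taking the nearest present value since a two-sided fit is undefined there;
(3) Malik ectopic filter — an interval deviating by more than 20% of the
previous *accepted* interval is removed, and the reference does not advance
past a rejected beat; (4) re-interpolation. An interval is assigned to the
block containing the time of its terminating beat, with block windows
half-open [start, end). SDNN/SDSD use the n−1 sample standard deviation;
pNN50/pNN20 count strict (">") successive differences and normalize by the
number of differences; mean and max heart rate are over per-beat
instantaneous rates 60000/NN, matching the convention of common HRV
libraries rather than 60000/mean(NN). Blocks with fewer than 10 intervals
are flagged low-quality rather than dropped.

**EEG chain.** An order-8 Butterworth band-pass (0.5–40 Hz) is applied
forward–backward (zero phase). The 0.5 Hz pole gives the zero-phase filter
a seconds-long impulse response, so the first/last few seconds of a
recording carry edge transients; recordings are tens of minutes, and tests
characterize the filter on steady-state interior samples. Bipolar channels
are formed by electrode label (T10−Fp2, T9−Fp1; TP9/TP10 labels are
normalized to T9/T10). Epochs are contiguous, non-overlapping 2 s windows
within each block — non-overlap keeps epochs approximately independent for
majority voting; a step size is configurable. A window is "flat" (signal
loss) when its SD falls below 0.1 µV on either channel; flat epochs are
dropped jointly across both channels so channel pivots stay aligned, and a
session with more than 20% flat windows is flagged for exclusion.

**Band powers.** Welch PSD with a window equal to the 2 s epoch; absolute
band power is the mean PSD over band bins, relative power normalizes by the
sum over the five bands. The printed band edges are kept as-is, including
the 13–14 Hz gap between alpha and beta; gamma closes at the 40 Hz filter
ceiling. Band membership is half-open [lo, hi) except gamma, closed at
40 Hz, so no bin is double-counted.

**Sample entropy.** Richman–Moorman estimator: unordered pairs of templates
(lengths m and m+1, both drawn from the first N−m positions, self-matches
excluded) within Chebyshev tolerance r·SD; SampEn = −ln(A/B). Defaults
m = 2, r = 0.2 (in SDs) — unstated by the source description, fixed to the
field's standard values and pinned exactly (to 1e-12) against a naive
O(N²) double-loop oracle. A constant signal returns 0; zero matches at
length m+1 returns +inf with a warning.

**Higuchi FD.** Curve lengths averaged over all k offsets with the standard
(N−1)/(⌊(N−1−m)/k⌋·k) normalization, k = 1..10; FD is the slope of
log L(k) against log(1/k). Smooth curves give ≈1, white noise ≈2; the
estimator is affine-invariant by construction.

**Hjorth parameters.** Activity is the population variance. Complexity is
reported as Var(ΔX)/Var(X) — the squared mobility — the form this pipeline
models with; mobility (its square root) is emitted alongside so the
classical chart-reading convention (mobility of ΔX over mobility of X) can
be reconstructed downstream if needed. Both conventions rise for
faster-changing signals.

The full EEG feature set is 15 per channel × 2 channels (5 absolute + 5
relative powers, SampEn, FD, 3 Hjorth); a config switch restricts to
absolute or relative powers only. The HRV model uses the ultra-short-term
subset {SDNN, RMSSD, pNN50, mean HR} by default, the features established
as stable on sub-5-minute windows; the full 14-feature set is always
computed and available.

## Task engine

The vigilance task's critical-number rule (|tens − units| ∈ {0, 1}),
8-number panels with exactly one critical number on positive/no-go trials,
and the rule-matching task's (6, 2, 2) block composition and adaptive trial
duration (start 5 s, floor 1 s, ±1 s on 9–10 / ≤7 correct, hold on 8) are
implemented as pure functions over a seeded RNG. The per-block class mix for
the vigilance task is not fixed by the paradigm description beyond
"infrequent" criticals; the rule-matching mix (6, 2, 2) is mirrored as the
default. The suspect/rule vocabulary is an abstract attribute system (4
named attributes with 4-value categorical domains, rule = required value per
attribute); negative suspects violate 1..4 rules. Block scoring counts
presses on positive trials and timeouts on negative/no-go trials; reaction
time averages correctly answered positive trials only. Simulated sessions
insert 3 s of stimulus turnover per trial and 3 s between blocks, putting a
10-trial block in the 40–80 s range — consistent with roughly minute-long
blocks, which is also what makes single-block HRV features usable.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical contrasts* the analysis relies
on, not biophysics. EEG channels are sums of band-limited Gaussian noise
(per-band amplitudes δ:10, θ:6, α:8, β:4, γ:2 µV RMS), a 1/f background
(3 µV) and a broadband component (1.5 µV); under stress level s the β/γ
amplitudes scale by (1 + s·effect), α by (1 − s·effect), and the broadband
admixture grows, raising sample entropy. The R-R process combines
respiratory (0.25 Hz) and low-frequency (0.1 Hz) oscillations with
beat-to-beat noise around a per-subject mean near 800 ms; stress scales the
SD by (1 − s·effect) and shortens the mean interval by up to 10%. Sessions
ramp from s = 0 (first block) to s = 1 (last) either linearly or with a
sigmoid whose center/steepness can confine the transition to terminal
blocks. Nuisance structure: per-subject lognormal band-profile and
amplitude offsets (σ = 0.2) that make subject identity a stronger cluster
than stress at low effect sizes (the confound LOSO is designed to face),
NaN dropouts and ±30–50% ectopic excursions in the R-R export, and zeroed
2 s flatline windows in the EEG. Not emulated: ocular/muscle artifacts,
electrode drift, volume conduction, task-evoked potentials, or any claim
about which spectral changes real stress produces — the effect channels are
config-exposed precisely because the generator encodes one plausible
physiological direction, not a finding. Passing recovery tests therefore
shows the *pipeline* is correct and sensitive, not that real stress is
decodable at these accuracies.

The synthetic sampling rate defaults to 125 Hz (consumer dry-electrode
headsets commonly sample at 125–256 Hz; any rate above 80 Hz is accepted so
the 40 Hz analysis ceiling stays below Nyquist). The default cohort is 12
participants × 30 blocks — large enough for stable LOSO estimates and a
k = 1..8 sweep, small enough that the full simulate → features → evaluate
path runs in minutes on one core.

## Numerical and degenerate-input conventions

Timing is seconds from session start, 0-based samples, half-open block
windows. Trailing partial epochs are dropped. Zero-variance windows raise
explicit degenerate-signal errors in FD/Hjorth and are a defined 0 for
sample entropy. All-missing R-R series fail with an insufficient-data error
at interpolation (fewer than two present values). Best-k ties in the sweep
go to the smaller k, the cheaper labelling assumption. Every stochastic
path takes a seeded `numpy` Generator; cohort generation spawns independent
per-participant child seeds from the master seed, so cohorts are
reproducible as a whole and per participant (byte-identical files on
regeneration).

## Known limitations

- The Malik tolerance (20%) and SVR hyperparameters are field defaults, not
  values fitted to any recorded dataset.
- The epoch score threshold (0.5) is the midpoint of the 0/1 label coding;
  no calibration of the regression scores is attempted.
- HRV blocks shorter than ~10 intervals produce unstable features; they are
  flagged, not excluded, and the caller decides.
- The generator's stress effect is stationary within a block; real stress
  fluctuates on faster timescales.
- EDF support is read-only and requires the optional `mne` dependency.
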