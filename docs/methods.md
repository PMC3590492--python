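# Methods

`semcond` reimplements, as a tested pipeline over synthetic data, the
analysis of a semantic classical-conditioning EEG paradigm for binary
("yes"/"no") brain-computer communication: spoken true statements (CS1) and
false statements (CS2) are paired with two aversive noises (US1/US2), and
the conditioned EEG reactions to *unpaired* statements are quantified with
an area-under-the-curve statistic and decoded on single trials with an
RBF-kernel SVM. No public recordings exist for this paradigm, so a
synthetic-data generator defines the study conditions; everything downstream
of the generator follows the published analysis chain.

## Paradigm model

Each participant completes two sessions. A session holds three
100-sentence blocks (50 true / 50 false each): block 1 pairs every sentence
with a US; blocks 2 and 3 leave 20 and 30 sentences unpaired; session 2
ends with a 40-sentence extinction block. Per CS type over both sessions
that yields 250 paired (CS+), 50 unpaired (CS−) and 20 extinction (CS−ext)
trials — 640 trials total. The intertrial interval is 5 s from US end (or
sentence end) to the next sentence onset.

Unpaired trials are placed constructively rather than by rejection
sampling: `k` pairwise non-adjacent positions excluding the block-final slot
are drawn uniformly via the standard bijection from `k`-subsets of
`{0..n−k−1}`, which guarantees in O(n) that every unpaired trial is
immediately followed by a paired one (the rule that protects the
conditioned reaction from extinction). The 30 unpaired trials of block 3
split 15/15 by CS type; this is forced by the two-session per-type totals.
The no-conditioning control arm (`EXP2_G3`) presents the three 100-sentence
blocks per session with no US and no extinction block — 600 all-unpaired
trials, 300 per CS type, which is the pool from which its 70-trial
classification subsets are drawn. Sentence wording is abstracted to
`(cs_type, sentence_id)`; sentence semantics are out of scope.

## Synthetic EEG

Recordings are rendered at 500 Hz on a 12-channel montage: the ten
classification channels (Fz, Cz, CPz, P3, Pz, P4, PO7, POz, PO8, Oz — Cz
and Pz double as the AUC electrodes) plus two EOG channels. Sentence
durations are uniform on 2–4 s with the decisive last word 300–600 ms
before sentence end; these values are modeling choices (the paradigm fixes
only the ITI).

**Conditioned response.** The published reactions show no clear peaked
components, so the default CR template is a broad half-cosine bump
(`cos²`), peak 700 ms after sentence end, width 1200 ms, with a
centro-parietal topography, jittered per trial by a truncated Gaussian
latency shift (SD 50 ms, clipped at ±3 SD so the response stays inside the
2000 ms analysis window). The template shape is a modeling choice; only
its AUC behavior is constrained by the analysis.

**Amplitude calibration.** CR amplitudes are specified as per-trial effect
sizes *d* of the AUC-increase statistic against baseline noise, then
converted to microvolts analytically: the statistic is a fixed linear
functional `c'x` of the 2000 ms window, so its noise SD is
`sqrt(c' Σ c)` with the AR(1) covariance `Σ_ij = σ² ρ^|i−j|`. With the
default background (AR coefficient 0.95, innovation SD 3.12 µV, stationary
RMS ≈ 10 µV) the noise AUC SD is ≈ 20 µV·s, so d = 0.5 / 0.8 (the default
CS1 / CS2 effect sizes) correspond to ≈ 17 / 27 µV peak amplitudes — large
but in the range of slow cortical potentials. The calibration ignores the
band-pass filter, which slightly *reduces* noise AUC variance; measured
post-pipeline effect sizes run ≈ 10–15% above nominal. The null model sets
the CS2 template equal to CS1 (a conditioned response exists but is
non-differential).

**US response and artifacts.** Paired trials add an N1/P2-like biphasic
fronto-central template at US onset (US-kind-specific gain). Blink
transients (Poisson-timed `sin²` pulses, 150 µV on EOG, scaled coupling on
scalp) can be injected to exercise the ocular-regression stage; they are
off in the default pipeline configurations. Background noise is AR(1) by
default, optionally 1/f-colored. All draws derive from a single seeded
generator in fixed order (timing, jitter, noise), so the signal decomposes
exactly into noise plus inserted templates and template-amplitude changes
never perturb the noise realization.

What the generator does **not** emulate: volume conduction from a head
model, non-stationary rhythms (alpha bursts, drowsiness), stimulus
acoustics, muscle artifacts, and trial-to-trial shape variability of the
CR beyond latency jitter. Passing tests therefore certify the analysis
code and its statistical behavior under the stated model, not performance
on real EEG.

## Preprocessing

Band-pass 0.009–30 Hz, realized as zero-phase forward-backward Butterworth
(order 4 per pass; an optional 50 Hz notch is available). The 0.009 Hz
high-pass has poles at |z| ≈ 0.99996 (transient time constant ≈ 46 s);
recordings carry 60 s of quiet padding at both ends so edge transients
never reach analyzed epochs. Ocular artifacts are attenuated by
least-squares regression of each scalp channel on the demeaned EOG
channels over the whole recording — deterministic, idempotent, and exact
for the generator's linear coupling model; it stands in for the
ICA-in-proprietary-software step of the original chain.

Epochs are half-open sample ranges `[round(t·fs), ·+1000)`: 2000 ms
post-sentence windows anchored at sentence end, and 2000 ms baseline
windows ending at sentence onset (inside the preceding ITI, which is never
closer than 5 s to the previous US). Each epoch is offset-corrected by the
per-channel mean of the 100 ms immediately preceding its start; the
correction is stored so the raw segment is recoverable. Baselines are
taken from the same trials as the scheme that uses them; whether the
original analysis pooled baselines differently is unknowable from the
description, and this choice is symmetric across classes.

## AUC statistics

`auc_ri(x, dt) = ∫(x − x₁)` by the trapezoid rule at the native 500 Hz
resolution — the "area under the curve with respect to increase", invariant
under constant shifts (hence under the epoch offset correction) and linear
in the signal. Per participant, the AUC of the last 20 segments of each
trial type is averaged (20 = the number of extinction segments, the
scarcest type; fewer than 20 raises an error rather than silently
shrinking the window), giving the CS Type (CS1, CS2, baseline) × Electrode
(Cz, Pz) × Phase (CS+, CS−, CS−ext) table. Baseline cells inherit the
phase of the trial they precede, pooled over CS types, so the factor
crossing is complete.

The repeated-measures ANOVA uses the univariate projection approach: each
within effect is the Kronecker product of orthonormal per-factor contrasts
and averaging vectors applied to the subject × cell matrix;
Greenhouse–Geisser ε is estimated from the covariance of the projected
scores, `ε = tr(S)²/(q·tr(S²))`, clipped to `[1/q, 1]`, and both
uncorrected and GG-corrected p values are reported with partial η². One
between-subjects factor (split-plot) is supported, with ε from the pooled
within-group covariance. Any number of within factors is handled — the
3-way design above needs this; no installed package combines ≥3 within
factors with GG correction, so the engine is implemented here and checked
in the tests against pingouin (1-within and mixed designs), the squared
paired-t identity (2 levels), and textbook sums-of-squares formulas.
Planned pairwise contrasts are paired t-tests, uncorrected, matching the
original post-hoc treatment. Shapiro–Wilk screening of per-participant
values is advisory: flags are reported, never silently acted on.

A note on the null calibration: the null model's conditioned response is
*present but non-differential*, so the 3-level CS Type factor (which
includes baseline) detects the CS-vs-baseline difference by construction.
The calibration criterion therefore evaluates the differential CS1-vs-CS2
effect, i.e. the ANOVA on the table restricted to the CS1/CS2 cells.

## Single-trial decoding

Features per trial: the 2000 ms window of the 10 classification channels,
smoothed with a 10-sample centered boxcar (window length = decimation
factor; the original description names the filter type only), decimated by
10, concatenated channel-major → 1000 features. Schemes: I = CS1-unpaired
vs CS2-unpaired, II = CS1-unpaired vs baseline, III = CS2-unpaired vs
baseline; unpaired always means CS− and CS−ext combined (70 per type in
the conditioning arms; the control arm subsamples 70 of its 300 per class,
seeded, without replacement). Labels are +1 for the first named class.

The classifier is an RBF-SVM in a pipeline with per-fold standardization,
evaluated by stratified 10-fold cross-validation with seeded shuffling;
hyperparameters (C ∈ {1, 10, 100}, γ ∈ {10⁻⁴, 10⁻³, 10⁻²}) are selected by
an inner 5-fold grid search on each training fold only, and the grid is
recorded in the result provenance. Mean accuracy is the arithmetic mean of
fold accuracies, reported in percent to two decimals. Chance is the
normal-approximation binomial band `50 ± z₀.₉₇₅·100·√(0.25/n)` percent;
n = 80 reproduces the conventional 39.00–61.00% bounds quoted for this
paradigm class (the n behind those printed bounds is not stated in the
source; the function exposes n). Group reports recompute means both from
full precision and from 2-dp-rounded per-participant values, because
published averages can reflect either convention.

## Problem sizes and seeds

Synthetic cohorts use the full 640-trial (or 600-trial control) paradigm
per participant. The shipped analyses and checks use 6-participant cohorts
for the effect model (the size of the variant groups), a 10-participant
cohort for the null Scheme I calibration, and 10 null batches for the
no-differential-effect rate; the type-I calibration of the ANOVA engine
uses 200 small simulated datasets. Every stochastic stage takes an
explicit seed; cohort seeds derive from one master seed via
`numpy.random.SeedSequence`.

## Known limitations

- The EOG regression removes exactly linear, stationary coupling; real
  ocular artifacts are neither, and an ICA-based stage would be needed for
  real data.
- The GG ε for split-plot designs uses the pooled within-group covariance;
  other software sometimes estimates it from the group-mean-centered total
  covariance, giving slightly different ε (F and uncorrected p agree).
- EDF export quantizes to 16 bits with per-channel integer physical
  bounds (error ≤ one digital step, ≈ 0.002 µV at typical amplitudes).
- Synthetic decoding accuracies are not calibrated to the published
  accuracy *levels* (which reflect real-EEG variability); only qualitative
  orderings and chance-level behavior are meaningful points of contact.
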