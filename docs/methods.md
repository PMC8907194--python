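# Methods

This note documents the models and conventions behind `actimetry`: what
each statistic assumes, which parameters matter, and the numerical choices
made where the design was genuinely open.

## Monitor files and time conventions

Monitor files are header-less TSV with exactly 42 columns: record index,
date (`D Mon YY` or ISO, written `D Mon YY`), time (`HH:MM:SS`), monitor
status, five reserved integers (written 0, ignored on read), a light-sensor
column (exposed, never consumed by any analysis), then 32 channel counts.
Timestamps label the *start* of half-open bins `[t, t + interval)`.
Channels are 1-based everywhere users see them, matching the hardware
labels. Rows with status ≠ 1 are flagged by validation but kept — dropping
data silently is worse than reporting it. Empty or non-numeric channel
cells load as explicit missing values, never as zeros.

Zeitgeber time is anchored at the latest light onset at or before the
analysis window start (`zt = (t − anchor) mod cycle_period`); the light
phase is `zt < light_hours`. Cycle period and light hours are free
parameters, so 14L:10D (zebrafish), 16L:8D, or 30-min stimulus cycles all
work; for non-24 h cycles the onset lattice is anchored at the clock
occurrence of the ZT0 time on the window's start date. When several files
are grouped into conditions, each file is annotated with its *own* ZT0, so
series recorded under shifted light schedules share one zeitgeber axis.

## Missing-value imputation (Copy Mean)

For a gap in channel c flanked by observations at rows a and b, the
imputed value is the channel's straight line between its flanks plus the
deviation of the cross-channel mean trajectory from *its* straight line
over the same rows:

    imputed(t) = LI_c(t) + (M(t) − LI_M(t))

with M(t) the mean over channels observed at t (within the same file — no
pooling across experiments). Edge gaps use the flat extension
`v_edge + (M(t) − M(t_edge))`. The method assumes channels share the
population-level within-gap shape; it cannot reconstruct channel-specific
events inside a gap. Results are rounded half-away-from-zero and clipped
at 0, because the file format carries integer counts. Imputation fails, by
design, when every channel is missing at some timestamp.

## Sleep, stops, bouts, death

All scoring reduces to maximal runs of zero-count bins. A run is a *stop*
or *sleep bout* when its duration is **≥** the corresponding threshold
(inclusive, so a threshold equal to an observed run length detects it —
this edge-case choice is deliberate and differs from a strict reading of
"exceed"). Thresholds are minutes of inactivity and must be at least one
bin; defaults follow species conventions (5 min drosophila, 10 min
zebrafish larvae) but are fully adjustable.

Activity bouts are the maximal stretches between consecutive stops (or
series edges) containing at least one nonzero bin; sub-threshold zero runs
inside or at the edges of a bout belong to it, so stop time + bout time +
all-zero sub-threshold edge time partitions the window exactly (a tested
invariant).

Sleep metrics are computed on a per-bin sleep mask, so a bout spanning a
group boundary (e.g. lights-off) is split naturally for phase groupings.
Per dark phase: latency is minutes from lights-off to the first bout
*starting* in that phase (reported missing when none does — not 0, not the
phase length); total sleep time is sleep∧dark coverage; WASO is dark time
awake after the phase's first sleep onset. Groupings: whole series, per
day, per phase, per day-and-phase, or a caller-supplied per-bin key array.

Death detection runs backwards from the window end: a channel is dead iff
its terminal zero run lasts ≥ the death threshold (hours), with time of
death at the last bin with nonzero counts. All-zero channels are scored
dead at the window start with a warning, since they usually mean an empty
channel or sensor fault rather than a death. Censoring uses the analysis
window end. Kaplan–Meier curves are computed per condition with the
product-limit estimator (via lifelines); no confidence bands by default
and no between-curve tests — downstream statistics packages handle those
from the exported tables.

## Periodograms

**Chi-square (folded profile).** Candidate periods are whole-bin multiples
covering the requested range (folding is undefined otherwise). For P bins
per period the series is truncated to K = ⌊n/P⌋ ≥ 2 complete cycles and
the power is

    Q_P = N · Σ_h (M̄_h − M̄)² / Σ_i (x_i − M̄)² ,   N = K·P

normalized so an exactly P-periodic series scores Q_P = P exactly (an
algebraic identity the tests assert). The classical folded-profile
statistic is K·Q_P, so the significance line — the χ²(P−1) quantile at
level α, Bonferroni-corrected across the grid — is divided by K, making
the accept/reject decision identical to the classical test while keeping
the intuitive power scale. The reported peak is the period with the
largest excess of power over its significance line: raw power grows
roughly like P/K under pure noise, so a raw argmax is biased toward long
periods; peak-above-line removes that bias.

**Lomb–Scargle.** Classical variance-normalized least-squares spectral
power (with the τ phase offset; computed via `scipy.signal.lombscargle`),
defined with gaps. The per-period significance solves the false-alarm
relation `p = 1 − (1 − e^(−z))^m` with m = the number of grid periods — a
conservative count of independent frequencies. Constant series yield
undefined power (warned, NaN).

Calibration conditions used by the recovery tests: 10-day recordings of
10-min bins with Poisson counts at rate 10 + 6·cos(2πt/T), T ∈ {24 h,
12.4 h}, 50 seeded replicates per period class; both periodograms must
recover T within one grid step in ≥ 95% of runs. Ten days is a typical
free-running period-estimation experiment; at 4 days the chi-square
fold resolution near 24 h is genuinely coarser than one bin.

## Cosinor and activity phase

Stage 1 fits `y = mesor + A·cos(2π(t − φ)/cycle)` in closed form via
sine/cosine regressors. Stage 2 refines with the anti-logistic transform

    y = min + amp · σ(β(cos(2π(t − φ)/cycle) − α))

(σ = logistic), which accommodates the square-ish on/off activity profiles
the plain cosine distorts; it is fitted by bounded nonlinear least squares
(amp ≥ 0, β ∈ (0, 60], α ∈ [−1, 1]) initialized from stage 1, falling back
to stage 1 (flagged) on non-convergence. The exact parameterization of the
extended-cosinor family varies across implementations; this one is
documented as the package's choice. The acrophase is the zeitgeber time of
the model peak (= φ mod cycle, since σ is monotone in the cosine); the
activity phase is acrophase − lights-on time wrapped to (−cycle/2,
cycle/2]. Requires ≥ 2 cycles of data.

## Nonparametric indices

IS and IV are defined between consecutive *hours*, so input is re-binned
to 1-h bins regardless of the analysis bin, and truncated to K ≥ 2
complete cycles of p = cycle hours (equal day counts keep the hour-of-day
means balanced). With n = K·p hourly values:

    IS = n Σ_h (x̄_h − x̄)² / (p Σ_i (x_i − x̄)²)      ∈ [0, 1]
    IV = n Σ_{i≥2} (x_i − x_{i−1})² / ((n−1) Σ_i (x_i − x̄)²) ≥ 0

IS = 1 for a perfectly repeated daily profile; for iid noise E[IS] ≈ 1/K
and E[IV] ≈ 2 (both asserted by Monte-Carlo tests). M10/L5 are the
max/min means over cyclic 10-h/5-h windows of the average daily profile
(wrapping midnight; ties break to the earliest onset), and
RA = (M10 − L5)/(M10 + L5). Cycles other than 24 h generalize p, an
extension beyond the usual definition.

## DFA

First-order DFA of the integrated, mean-centred profile: non-overlapping
windows of n samples taken from both the series start and end (so trailing
samples count), a least-squares line removed per window, F(n) = RMS
residual, and the scaling exponent the slope of log F vs log n over 20
log-spaced scales in [4, N/4] by default. Known small-scale bias of
first-order detrending (F(4) slightly low for white noise) shifts the
fitted slope by ~+0.01; the calibration anchors (white noise ≈ 0.5,
cumulative sum ≈ 1.5, 20 × 16384-sample series) absorb this within their
±0.05 / ±0.1 tolerances. The exponent is invariant under affine rescaling
of the input.

## Synthetic data

The generator composes a per-bin rate: baseline + sinusoid/square rhythm
components + exponentially decaying transients (emulating e.g. the startle
burst after a sudden light-to-dark switch), clipped at 0, then draws
Poisson counts (beam crossings are event counts) or deterministic rounding
for exact-value tests. Sleep bouts zero their windows, deaths zero the
tail (with the preceding bin pinned ≥ 1 so the time of death is
well-defined), missing cells are blanked last, and everything is returned
alongside as ground truth. The fixture suite covers circadian 14L:10D,
circatidal 12.4 h, arrhythmic, dying-cohort, gappy and transient cases;
the circadian fixture keeps its rate floor near 2 counts/min so planted
sleep bouts stay identifiable against chance zero runs.

What the generator does **not** emulate: inter-individual variability in
period or amplitude, activity autocorrelation beyond the imposed rhythm
(real locomotion is burstier than Poisson), sensor cross-talk, or drifting
baselines. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated models, not robustness to every real
data pathology.

## Problem sizes in the shipped tests

Recovery and calibration tests use 2–10-day recordings at 1–10-min bins,
50-replicate recovery rates, and 20 × 16384-sample DFA calibrations —
sizes chosen so the full suite exercises every pipeline end to end while
remaining quick to run routinely.

## Known limitations

- One rhythm component is fitted at a time (no multi-component cosinor).
- The chi-square periodogram needs complete, evenly spaced data; use
  Lomb–Scargle for gappy series, or impute first.
- Kalman or other smoothing filters are deliberately out of scope; filter
  before import if needed.
- Exported XLSX sheet layout is documented and stable but is this
  package's own convention.
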