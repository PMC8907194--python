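# actimetry

Analysis of count data from infrared (IR) activity monitors — the
tab-separated, 42-column "monitor files" produced by Trikinetics DAM/LAM
systems and by anything converted into that format (video tracking,
wearables). The package is aimed at chronobiology and behavioural labs
working with small organisms (drosophila, zebrafish larvae, *C. elegans*,
intertidal fish, ...) who need species-customisable scoring of activity,
sleep and death, plus quantitative rhythm statistics, from multi-day
beam-crossing recordings.

## What it computes

Given per-bin counts *x\_i* for each of up to 32 channels:

- **Activity**: counts per user-chosen bin, cumulative activity, and
  activity *bouts* — maximal intervals between movement *stops* (zero-count
  runs ≥ an inactivity threshold).
- **Sleep**: zero-count runs ≥ a species-specific threshold (e.g. 5 min for
  adult drosophila, 10 min for zebrafish larvae) and the derived metrics:
  sleep ratio, bout duration, sleep latency, total sleep time, wake after
  sleep onset — per day, per light/dark phase, or custom groupings under
  arbitrary light–dark cycles (12L:12D, 14L:10D, 30 min L : 30 min D, ...).
- **Survival**: backward death detection (terminal zero run ≥ a death
  threshold; time of death = last timepoint with nonzero activity),
  death-handling policies (drop / trim after death / keep), and
  Kaplan–Meier curves S(t) = ∏\_{t\_j ≤ t} (1 − d\_j / n\_j).
- **Rhythms**:
  - chi-square (folded-profile) periodogram
    Q\_P = N·Σ\_h (M̄\_h − M̄)² / Σ\_i (x\_i − M̄)², normalized so an exactly
    P-periodic series scores Q\_P = P, tested against χ²(P−1);
  - Lomb–Scargle periodogram with analytic false-alarm significance;
  - cosinor acrophase via closed-form least squares refined by the extended
    (anti-logistic) cosine model, and the activity phase relative to
    lights-on;
  - nonparametric circadian indices IS, IV and RA = (M10 − L5)/(M10 + L5);
  - DFA (detrended fluctuation analysis) scaling exponent, ~0.5 for white
    noise up to ~1.5 for rigidly regular patterns.
- **Interoperability**: XLSX/CSV export with conditions in columns or in
  rows, descriptive statistics (n, mean, SEM, SD, median, quartiles) and a
  settings sheet echoing every analysis parameter; actogram/chronogram
  matrices for plotting.

A seeded synthetic-data generator (`actimetry.synthetic`) produces monitor
files with known ground truth — programmable rhythms, sleep bouts, deaths,
stimulus transients, missing cells — and backs the test suite.

## Worked example

```python
from actimetry import annotate, preprocess, behavior, rhythms, synthetic

suite = synthetic.make_fixture_suite(seed=0)
rec, ld = suite["circadian"]["recording"], suite["circadian"]["light_cycle"]

s = annotate(rec, ld, channels=[2])[0]          # zeitgeber-time annotation
binned = preprocess.bin_counts(s, 10.0)          # 10-min bins
chi = rhythms.chi_square_periodogram(binned, (16.0, 32.0))
cos = rhythms.cosinor_phase(binned)
npar = rhythms.nonparametric_stats(s)
fr = rhythms.dfa(binned)
```

prints, for the 6-day 14L:10D fixture (24 h sinusoidal rate peaking at ZT6):

```
chi-square peak period : 24.00 h (significant: True)
acrophase              : 5.90 h (activity phase +5.90 h)
IS / IV / RA           : 0.989 / 0.092 / 0.580
DFA scaling exponent   : 1.484
```

The periodogram recovers the generating 24 h period; the acrophase sits at
the simulated peak (ZT6) within the fit tolerance; IS near 1 reflects
near-perfect day-to-day reproducibility, low IV the smooth hourly profile,
and the high scaling exponent the strongly regular (sinusoid-dominated)
fluctuation structure. Sleep scoring on channel 1 of the same fixture finds
exactly the two planted bouts, e.g. a 30-min sleep latency on day 0 (bout
onset 30 min after lights-off).

Command-line equivalents: `actimetry simulate|validate|impute|analyze|
rhythms|survival|export` (see `actimetry --help`).

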