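# Methods

This note documents the models, estimators and numerical choices behind
`semilunar`, and what the synthetic-data generator does and does not
emulate.

## Scientific setting

Many intertidal organisms time reproduction to the spring tides with an
endogenous circasemilunar clock (~14.77-day period, half the lunar cycle).
In the marine midge *Clunio marinus* the clock gates adult emergence: the
whole short-lived adult stage is compressed into a few spring-tide days,
and within those days emergence clusters at a specific hour set by the
circadian clock.  Because each animal emerges exactly once, both rhythms
are *population-level* phenotypes: the observable is a count of emerged
adults per hour or per solar day.

Three functional principles could produce a circasemilunar rhythm:

* **counter** — the clock counts a fixed number *C* of circadian cycles.
  If the circadian clock entrains to a diel T-cycle of length *T* hours,
  the circasemilunar period is τ(T) = C·T/24 days: linear in *T*, with
  slope C/24 (0.625 d/h for the entrained count C = 15).
* **oscillator** — an autonomous ~15-day oscillator; τ is independent of
  *T*.
* **beat** — interference of a circadian oscillation (period *T*) with a
  circatidal one (period k/2, where *k* is the lunar-day length in hours;
  k = 24.8 when entrained).  The envelope repeats every
  τ(T, k) = T·k / (2|T − k|) hours, i.e. /24 in days; tiny changes in *T*
  move τ drastically near T = k.

The package estimates free-running circasemilunar and circadian periods
from emergence-count series recorded under manipulated T-cycles and
discriminates the three principles by least-squares fitting and AICc.

## Data model and preprocessing (`semilunar.series`)

A series is a vector of non-negative integer counts with an explicit
missing mask, a bin width (24 h daily / 1 h hourly), a start label and an
attached light regime.  Files are delimited text (comma or tab,
auto-detected) with a header and a `day`/`hour` label column; `NA`, `NaN`
and empty cells are read as missing and `NA` is always written.  Bin
labels are taken verbatim from the file; windowing keys on labels, not
array positions.  The clock-time of lights-on (`phase_origin`) is not
assumed — it must be supplied as regime metadata, because experiments
differ in it.

Preprocessing rules:

* **Solar-day assignment.**  Daily counts are credited to the 24-h solar
  day containing the most recent light→dark transition at or before the
  event.  "LD transition" always means lights-off, because emergence
  concentrates at the end of the light phase.  Under T > 24 h some solar
  days contain no lights-off; they carry no information and are masked
  (one missing day per 13 under T = 26, one per 5 under T = 30).  An event
  before the first transition (only possible for the first gate) is
  credited to the first transition's day so total counts are conserved.
* **Semilunar window.**  Circasemilunar analysis uses free-run days
  31–112 (82 bins).  The first 30 days are discarded because emergence is
  developmentally predetermined up to ~20 days ahead, so early peaks do
  not reflect the treatment; shorter series are right-padded with missing
  bins.
* **ZT alignment.**  Hourly series are circularly shifted so that the
  middle of the dark phase maps to zeitgeber time 0; a pure roll, so
  counts are conserved exactly.
* **Folding.**  Hourly profiles sum counts per phase bin modulo a fold
  period, skipping missing bins.

Zero-count and all-zero series are valid inputs: they come out
non-significant, they are not errors.

## Period estimation (`semilunar.rhythm`)

All statistics use observed bins only; nothing is imputed.

**Autocorrelation.**  Lag-ℓ covariance over all pairs with both bins
observed, normalized by the lag-0 term (lag 0 ≡ 1).  Used for visual
diagnosis only, never for inference.

**Lomb–Scargle.**  Classical Scargle periodogram (via
`scipy.signal.lombscargle` on the observed bin times, counts centred),
normalized by the sample variance so the power Z is dimensionless; this
makes the statistic exactly invariant under adding a constant to all
counts and under uniform scaling.  Periods are scanned with frequency
spacing 1/(4·span) (oversampling 4), so the period-grid step near period P
is ≈ P²/(4·span); best periods are reported on that grid, which is where
the "± one grid step" tolerances in the tests come from.  The peak's
false-alarm probability is 1 − (1 − e^(−Z))^M with the Horne–Baliunas
effective number of independent frequencies approximated as
M = 2·N_obs·(scanned fraction of the Nyquist band).  This p-value is an
approximation: it is calibrated to be conservative under the null
(≤ 5 % false positives at α = 0.05 in the test suite) and
decision-accurate at α = 0.05, not p-exact against any particular legacy
implementation.

**JTK.**  For every integer period in the scan range and every phase on
that period's bin grid, Kendall's τ_b is computed between the observed
counts and a discretized cosine reference (missing bins dropped
pairwise); the best combination maximises |τ| with smaller p breaking
ties.  The per-test p-value is the exact two-sided tail of the Kendall S
statistic when the observed counts are tie-free and n ≤ 50: the null
distribution of S against a reference with tie groups is obtained by
writing the cross-group concordance count as a Jonckheere–Terpstra
statistic and convolving the independent Mann–Whitney null pmfs of each
group against all earlier groups combined.  With tied counts or n > 50
the tie-corrected normal approximation is used instead (ties make the
untied exact null invalid, and the normal approximation is accurate at
those sizes).  The reported p is Bonferroni-adjusted by the total number
of (period, phase) combinations scanned — the set of alternatives
actually tested.  Series longer than 1000 bins signal method-unavailable
and the integration proceeds LS-only; the limit is configurable upward
but is the default so that long hourly series (e.g. 2184 bins) are
analysed exactly as the daily pipeline's conventions expect.  Symmetric
cosine references only; sawtooth asymmetry is not implemented.

**Integration.**  The integrated period τ is the arithmetic mean of the
available per-method best periods; the combined p-value is Fisher's
method, X = −2Σln pᵢ against χ² with 2·(#methods) degrees of freedom; a
single method passes its p through.  All series analysed in one call form
one Benjamini–Hochberg family (delegated to
`statsmodels.stats.multitest`), and a series is called rhythmic when its
BH q-value is below α = 0.05.

Default scan ranges: 3–20 days for daily integration (3–35 d for
periodogram visualisation), 20–28 h for hourly integration (15–40 h for
visualisation).  The integration ranges cover every period the three
hypotheses predict for the T-cycles used.

## Hypothesis fitting (`semilunar.models`)

Only significant period estimates become (T, τ) observations, and only
T ∈ {22, 24, 26} h enter the comparison (longer cycles yield no
significant free-running period).  Residuals are defined as observed
minus predicted, exactly.

* counter: OLS line τ = a + bT (`scipy.stats.linregress`); slope p-value
  from the two-sided t-test of b = 0.
* oscillator: intercept-only model; prediction is the mean τ.
* beat: one-dimensional nonlinear least squares over *k*.  The objective
  has poles at every observed T, so instead of an unguarded Gauss–Newton
  each pole-free interval between consecutive observed T values (plus the
  tail beyond the largest T up to 40 h and the head below the smallest)
  is searched with bounded Brent and the global minimiser wins; the
  default start k = 24.8 (the entrained lunar day) lies inside one of the
  searched intervals, so the returned objective can never exceed the
  start's.  The standard error of k comes from the Gauss–Newton
  linearisation at the optimum, as a standard `nls` summary reports it.

Parameter counts for AICc include the Gaussian error SD — counter 3,
oscillator 2, beat 2 — matching the conventions of standard
linear/nonlinear least-squares software; with
lnL = −n/2·(ln 2π + ln(rss/n) + 1) and
AICc = −2 lnL + 2p + 2p(p+1)/(n−p−1), this parameterisation is what makes
published AICc values reproducible.  AICc is undefined for n ≤ p+1 and
for zero residual sums of squares (the degenerate exact-fit case is
flagged, not silently scored).  Akaike weights are computed from deltas
to the minimum AICc, numerically stable for large spreads; AICc ties are
broken by fewer parameters, then by name, for deterministic reports.
Because the counter model nests the oscillator, counter RSS ≤ oscillator
RSS always — a structural invariant the tests enforce.

## Synthetic-data generator (`semilunar.clock_sim` → `semilunar.simulate`)

The generator produces the study conditions, not a tunable benchmark.

**Circadian layer.**  Under LD, the clock locks onto the smallest integer
multiple m·T inside the entrainment range (frequency demultiplication:
T = 12 → 24 h at m = 2); the range default is the half-open interval
[20, 28) h, so T = 28 falls outside — this reproduces the observed
arrhythmia at both 28 and 30 h while a closed upper bound would not.
Under LL/DD the clock free-runs at its intrinsic period (default 24.5 h).
Constant-light desynchronization is modelled as per-individual phase
diffusion (`ll_phase_diffusion_sd` > 0 ⇒ the population loses its common
gate); this deliberately does not decide between population-level
desynchrony and individual-level molecular arrhythmicity, which
population emergence data cannot distinguish.

**Semilunar layer.**  Each of `n_individuals` (default 400) animals draws
a readiness day from a Gaussian mixture centred on peaks spaced by the
hypothesis' expected period (readiness SD 1.5 days — sharp enough for
clearly separated fortnightly peaks, wide enough that a peak spans
several days as real emergence peaks do), then emerges in a gate of width
2 h ending at the first gate time after readiness.  Counter populations
count effective circadian cycles (C = 13 free-running by default, 15
entrained; the discrepancy between entrained and free-running counts is
left as an explicit knob, not resolved); with `counter_source="external"`
a contrast generator counts raw T-cycles and gates at every transition,
which halves the apparent semilunar period under LD 6:6 — the signature
that distinguishes an external-cycle counter from a circadian one.
Oscillator populations keep their 15-day spacing under every regime,
including diffusing LL (semilunar rhythm persists while the hourly rhythm
collapses — the discriminating contrast to the counter).  When the
expected period is undefined (counter without a coherent circadian clock)
readiness is uniform and the output arrhythmic, by design not by error.

**Beat populations** allocate individuals across circadian gates with
probability ∝ thresholded (and squared, for peak sharpness) circatidal
cosine sampled at the gate times; sampling a wave of frequency 2/k at
intervals of the effective circadian period reproduces the beat-envelope
spacing T·k/(2|T−k|) exactly, which the tests verify against the
closed-form value at T = 24/k = 24.8 (15.5 d) and T = 22/k = 25 (3.8 d).
Zero tidal amplitude degenerates to a pure circadian series.

Counts are binned hourly; daily series are derived by solar-day
assignment (so T > 24 regimes carry the right missing-day pattern);
optional Poisson thinning resamples each hourly bin.  Everything is
driven by one `numpy` generator, so identical config + seed gives
identical series bit-for-bit.

**What the generator does not emulate:** mechanistic
transcription–translation clock dynamics, temperature compensation,
tidal-vibration entrainment dynamics (semilunar entrainment is assumed
complete at t = 0), age-dependent development rates, and any quantitative
phase-response behaviour of the real circadian clock — the phase-oscillator
choices are stand-ins, and parameters recovered from simulations are not
estimates of the biology.  Passing tests therefore show that the
*analysis chain* is correct and has adequate power under realistic count
noise and missingness, not that the biological parameter values are
right.

## Pipeline recipes and problem sizes

`run_tcycle` windows each daily series, estimates periods as one BH
family, filters significant series at T ∈ {22, 24, 26}, and ranks the
hypotheses; "no rhythmic series" is a first-class outcome (CLI exit
code 4) distinct from a crash.  `run_demultiplication` flags
demultiplication when the LD 6:6 circadian LS period is within 1 h of
24 h and the circasemilunar period within 2 days of the LD 12:12 value.
`run_ll` reports which rhythms survive constant light.  Reports embed the
resolved configuration and seed and are written as JSON plus TSV twins.

Simulation-backed tests use 400 individuals over 112 days (82-day
analysis window; 2688-bin hourly series) — the scale of the real
experiments — and recovery studies use 50 replicate datasets per
generating hypothesis with between-replicate period noise of 0.8 days at
three T-cycles × three replicates, the dispersion the real replicate
periods show.  At these sizes the full suite runs in well under a minute.

## Known limitations

* LS p-values are Horne–Baliunas approximations; only the α = 0.05
  decision, not the exact p, is claimed to match legacy periodogram
  implementations.
* JTK exact p-values require tie-free counts; tied counts fall back to
  the (tie-corrected) normal approximation even at small n.
* The model-recovery power of the counter-vs-oscillator contrast at
  n = 9 observations and 0.8-day noise is intrinsically limited (≈ 70 %
  of draws give the counter a weight above 0.7); this is a property of
  the design, visible in the test suite, not an estimator defect.
* The (T, τ) observations are treated as independent points; no
  per-replicate random effects, bootstrap CIs on the ranking, or Bayesian
  model averaging.
* ARSER-style harmonic autoregressive detection is deliberately absent —
  it cannot handle missing data, which T > 24 h designs always produce.
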