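# semilunar

Circasemilunar and circadian rhythm analysis of emergence-count time
series, with model-based discrimination between three functional
principles of the underlying clock.

## The problem

Intertidal organisms such as the marine midge *Clunio marinus* restrict
reproduction to the spring tides using an endogenous circasemilunar clock
(~14.77-day period).  Because adults live only hours and each individual
emerges exactly once, the rhythm is observable only at the population
level, as counts of emerged adults per hour or per solar day.  Three
principles could generate such a rhythm, and they make different
predictions for how the free-running circasemilunar period τ (days)
responds to the length T (hours) of the diel light–dark cycle:

| hypothesis | mechanism | prediction |
|---|---|---|
| counter | count a fixed number C of circadian cycles | τ(T) = C·T/24 — linear in T, slope C/24 (0.625 d/h at C = 15) |
| oscillator | autonomous ~15-day oscillator | τ independent of T |
| beat | circadian × circatidal interference | τ(T) = T·k / (2·\|T − k\|) / 24, k the lunar-day length in hours |

`semilunar` implements the full analysis chain for such experiments:

* **I/O and preprocessing** (`semilunar.series`) — delimited-text daily
  and hourly emergence series with explicit `NA` missing values,
  solar-day assignment under non-24-h cycles, the day-31–112 free-run
  analysis window, zeitgeber-time alignment, hourly phase profiles.
* **Period estimation** (`semilunar.rhythm`) — missing-data
  autocorrelation, Lomb–Scargle periodograms with Horne–Baliunas
  significance, JTK-style Kendall-tau period/phase estimation with an
  exact small-sample null, integration of the two methods (mean period,
  Fisher-combined p), and Benjamini–Hochberg correction across a family
  of series.
* **Hypothesis fitting** (`semilunar.models`) — least-squares fits of the
  three models to (T, τ) observations, residual standard errors,
  small-sample AICc and Akaike weights.
* **Simulation** (`semilunar.simulate`) — a population-level generator
  for all three clock architectures, with circadian entrainment limits,
  frequency demultiplication under LD 6:6 and constant-light
  desynchronization, providing ground truth for every stage.
* **Recipes and CLI** (`semilunar.pipeline`, `semilunar` console script)
  — end-to-end T-cycle, LD 6:6 and constant-light analyses with
  reproducible JSON/TSV reports.

See `docs/methods.md` for the statistical details and modelling
assumptions.

## Worked example

Simulate a T-cycle experiment with a day-counting clock (C = 13 circadian
cycles per circasemilunar cycle, the free-running count), estimate the
periods and rank the hypotheses:

```python
from semilunar import SimConfig
from semilunar.pipeline import run_tcycle, simulate_tcycle_inputs

cfg = SimConfig(hypothesis="counter", counter_target_C=13)
series = simulate_tcycle_inputs(cfg, t_cycles=(22, 24, 26), replicates=3, seed=7)
report = run_tcycle(series, seed=7)
print(report["comparison_text"])
print(f"significant series: {report['n_significant']}")
print(f"counter slope: {report['counter_slope']:.3f} d/h (p = {report['counter_slope_p']:.2e})")
```

prints

```
Hypothesis  Model                          RSE     AICc     Weight
counter     lm(tau ~ T)                  0.110    -5.69   1.00e+00
oscillator  lm(tau ~ 1)                  0.931    29.19   2.67e-08
beat        nls(tau ~ beat(T, k))        4.976    59.36   7.46e-15
significant series: 9
counter slope: 0.534 d/h (p = 5.81e-08)
```

All nine simulated series are significantly rhythmic; the counter model
wins the AICc comparison with essentially all the Akaike weight, and the
fitted slope of period against cycle length (0.534 d/h) recovers the
generative slope C/24 = 13/24 ≈ 0.542 — a day-counting clock makes the
circasemilunar period track the length of the day it counts.

The same analyses run from the shell:

```sh
semilunar simulate --hypothesis counter --t-cycle 26 --seed 1 --out sim
semilunar period sim_daily.csv --layout daily
semilunar compare observations.csv            # columns T, tau
semilunar run-tcycle series.csv --regimes regimes.yaml --out report
```

Exit codes: 0 success, 2 usage error, 3 invalid input, 4 "no rhythmic
series" (a scientific outcome, not a failure).

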