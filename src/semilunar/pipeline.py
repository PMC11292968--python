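"""End-to-end experiment recipes.

Three recipes mirror the chronobiological assays the package exists for:

* :func:`run_tcycle` - daily series under several diel T-cycle lengths:
  window to the free-run analysis days (31-112), estimate circasemilunar
  periods, keep the significant ones at T in {22, 24, 26} h, and rank the
  counter / oscillator / beat hypotheses by AICc.
* :func:`run_demultiplication` - hourly + daily series under T = 12 h
  (LD 6:6) and T = 24 h: does the circadian rhythm keep a ~24-h period under
  the submultiple cycle (frequency demultiplication), and does the
  circasemilunar period stay near its LD 12:12 value?
* :func:`run_ll` - hourly + daily series under constant light and an LD
  control: which rhythms survive desynchronization of the circadian clock?

Every report embeds the resolved configuration and seed; reports are plain
dictionaries ready for JSON plus delimited-text twins.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import NoRhythmicSeriesError, ValidationError
from .models import PeriodObservation, compare_hypotheses, render_comparison
from .rhythm import (
    HOURLY_SCAN,
    analyze_series,
    estimate_period,
    lomb_scargle,
)
from .series import EmergenceSeries, LightRegime, window_semilunar
from .simulate import SimConfig, simulate_population

__all__ = [
    "run_tcycle",
    "run_demultiplication",
    "run_ll",
    "simulate_tcycle_inputs",
    "replicate_supplementary",
    "write_report",
]

#: T-cycle lengths admitted to the hypothesis comparison (hours).
COMPARISON_T = (22.0, 24.0, 26.0)


def _log(lines, stage, label, message):
    lines.append(f"[{stage}] {label}: {message}")


# ---------------------------------------------------------------------------
# T-cycle recipe
# ---------------------------------------------------------------------------

def simulate_tcycle_inputs(
    config: SimConfig,
    t_cycles=(22.0, 24.0, 26.0, 28.0, 30.0),
    replicates: int = 1,
    seed: int = 0,
) -> list[EmergenceSeries]:
    """Simulate daily emergence series for a T-cycle experiment."""
    out = []
    rng = np.random.default_rng(seed)
    for t in t_cycles:
        regime = LightRegime(cycle_length_T=t)
        for r in range(replicates):
            sub = int(rng.integers(0, 2**31 - 1))
            res = simulate_population(config, regime, seed=sub)
            out.append(res.daily.replace(label=f"T{t:g}_rep{r + 1}"))
    return out


def run_tcycle(
    series_list,
    alpha: float = 0.05,
    comparison_t=COMPARISON_T,
    seed: int | None = None,
) -> dict:
    """Full T-cycle analysis: periods, significance filter, model ranking.

    ``series_list`` holds daily series with a :class:`LightRegime` attached
    (the regime supplies T).  Raises :class:`NoRhythmicSeriesError` when no
    series passes the significance filter - a scientific outcome with its
    own CLI exit code, not a crash.
    """
    if not series_list:
        raise ValidationError("no input series")
    log: list[str] = []
    windowed = [window_semilunar(s) for s in series_list]
    table = analyze_series(windowed, layout="daily", alpha=alpha)
    table["T"] = [s.regime.cycle_length_T if s.regime else np.nan for s in windowed]
    for _, row in table.iterrows():
        _log(log, "period", row["label"],
             f"tau={row['tau']:.2f} d q={row['q']:.3g} "
             f"{'significant' if row['significant'] else 'not significant'}")

    keep = table[table["significant"] & table["T"].isin(comparison_t)]
    report = {
        "recipe": "tcycle",
        "alpha": alpha,
        "seed": seed,
        "periods": table.drop(columns=[]).to_dict(orient="records"),
        "log": log,
    }
    if keep.empty:
        report["status"] = "no rhythmic series"
        raise NoRhythmicSeriesError(json.dumps(report))

    obs = [
        PeriodObservation(T=row["T"], tau=row["tau"], label=row["label"])
        for _, row in keep.iterrows()
    ]
    comparison = compare_hypotheses(obs)
    fits = comparison.attrs["fits"]
    counter = fits.get("counter")
    report.update(
        {
            "status": "ok",
            "n_significant": int(keep.shape[0]),
            "observations": [dataclasses.asdict(o) for o in obs],
            "comparison": comparison.drop(columns=[]).to_dict(orient="records"),
            "comparison_text": render_comparison(comparison),
            "best_hypothesis": comparison.iloc[0]["hypothesis"],
        }
    )
    if counter is not None and not isinstance(counter, Exception):
        report["counter_slope"] = counter.params.get("slope")
        report["counter_slope_p"] = counter.params.get("slope_p")
    return report


# ---------------------------------------------------------------------------
# LD 6:6 frequency-demultiplication recipe
# ---------------------------------------------------------------------------

def run_demultiplication(
    hourly_t12: EmergenceSeries,
    hourly_t24: EmergenceSeries,
    daily_t12: EmergenceSeries,
    daily_t24: EmergenceSeries,
    alpha: float = 0.05,
    circadian_tol_h: float = 1.0,
    semilunar_tol_d: float = 2.0,
    seed: int | None = None,
) -> dict:
    """Test frequency demultiplication under LD 6:6 against the LD 12:12 control.

    Demultiplication is flagged when the LD 6:6 circadian period is within
    ``circadian_tol_h`` of 24 h (instead of halving to 12 h) while the
    circasemilunar period stays within ``semilunar_tol_d`` days of the
    LD 12:12 value.
    """
    for s, name in ((hourly_t12, "hourly_t12"), (hourly_t24, "hourly_t24")):
        if s is None:
            raise ValidationError(f"missing required hourly input {name}")
    log: list[str] = []
    circ = analyze_series([hourly_t24, hourly_t12], layout="hourly", alpha=alpha)
    circ["condition"] = ["T24", "T12"]
    semi = analyze_series(
        [window_semilunar(daily_t24), window_semilunar(daily_t12)],
        layout="daily", alpha=alpha,
    )
    semi["condition"] = ["T24", "T12"]
    for frame, stage in ((circ, "circadian"), (semi, "semilunar")):
        for _, row in frame.iterrows():
            _log(log, stage, row["condition"],
                 f"tau={row['tau']:.2f} q={row['q']:.3g} "
                 f"{'significant' if row['significant'] else 'not significant'}")

    circ12 = float(circ.loc[circ["condition"] == "T12", "ls_period"].iloc[0])
    semi12 = float(semi.loc[semi["condition"] == "T12", "tau"].iloc[0])
    semi24 = float(semi.loc[semi["condition"] == "T24", "tau"].iloc[0])
    demultiplied = (
        abs(circ12 - 24.0) <= circadian_tol_h
        and abs(semi12 - semi24) <= semilunar_tol_d
    )
    return {
        "recipe": "demultiplication",
        "alpha": alpha,
        "seed": seed,
        "circadian": circ.to_dict(orient="records"),
        "semilunar": semi.to_dict(orient="records"),
        "circadian_period_t12_h": circ12,
        "semilunar_period_t12_d": semi12,
        "semilunar_period_t24_d": semi24,
        "demultiplication": bool(demultiplied),
        "log": log,
        "status": "ok",
    }


# ---------------------------------------------------------------------------
# constant-light recipe
# ---------------------------------------------------------------------------

def run_ll(
    hourly_ll: EmergenceSeries,
    hourly_ld: EmergenceSeries,
    daily_ll: EmergenceSeries,
    daily_ld: EmergenceSeries,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Compare circadian and circasemilunar rhythmicity under LL vs LD.

    Hourly series longer than the JTK limit are analysed LS-only, as the
    integration layer arranges automatically.
    """
    log: list[str] = []
    circ = analyze_series([hourly_ld, hourly_ll], layout="hourly", alpha=alpha)
    circ["condition"] = ["LD", "LL"]
    semi = analyze_series(
        [window_semilunar(daily_ld), window_semilunar(daily_ll)],
        layout="daily", alpha=alpha,
    )
    semi["condition"] = ["LD", "LL"]
    for frame, stage in ((circ, "circadian"), (semi, "semilunar")):
        for _, row in frame.iterrows():
            _log(log, stage, row["condition"],
                 f"tau={row['tau']:.2f} q={row['q']:.3g} "
                 f"{'significant' if row['significant'] else 'not significant'}")

    def flag(frame, cond):
        return bool(frame.loc[frame["condition"] == cond, "significant"].iloc[0])

    return {
        "recipe": "ll",
        "alpha": alpha,
        "seed": seed,
        "circadian": circ.to_dict(orient="records"),
        "semilunar": semi.to_dict(orient="records"),
        "circadian_significant": {"LD": flag(circ, "LD"), "LL": flag(circ, "LL")},
        "semilunar_significant": {"LD": flag(semi, "LD"), "LL": flag(semi, "LL")},
        "log": log,
        "status": "ok",
    }


# ---------------------------------------------------------------------------
# replication on user-supplied experimental CSVs
# ---------------------------------------------------------------------------

def replicate_supplementary(
    daily_csv,
    regimes: dict[str, LightRegime],
    hourly_csv=None,
    hourly_regimes: dict[str, LightRegime] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Rerun the full analysis on experimental CSV exports.

    ``daily_csv`` holds one column per circasemilunar series (all analysed as
    one Benjamini-Hochberg family) and ``regimes`` maps column labels to
    their light regimes.  The optional ``hourly_csv`` holds circadian series
    analysed LS-only when they exceed the JTK length limit.  Returns the
    T-cycle report plus per-series period calls.
    """
    from .series import read_series

    daily = []
    for s in read_series(daily_csv, layout="daily"):
        if s.label not in regimes:
            raise ValidationError(f"no regime metadata for series {s.label!r}")
        daily.append(s.replace(regime=regimes[s.label]))
    report = run_tcycle(daily, alpha=alpha)

    if hourly_csv is not None:
        hourly = []
        for s in read_series(hourly_csv, layout="hourly"):
            reg = (hourly_regimes or {}).get(s.label)
            hourly.append(s.replace(regime=reg))
        circ = analyze_series(hourly, layout="hourly", alpha=alpha)
        report["circadian"] = circ.to_dict(orient="records")
    return report


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(report: dict, outdir) -> Path:
    """Write a report as JSON plus TSV twins of its tabular parts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = report.get("recipe", "report")
    json_path = outdir / f"{name}.json"
    json_path.write_text(json.dumps(report, indent=2, default=str))
    for key in ("periods", "comparison", "circadian", "semilunar", "observations"):
        if key in report and isinstance(report[key], list) and report[key]:
            pd.DataFrame(report[key]).to_csv(outdir / f"{name}_{key}.tsv",
                                             sep="\t", index=False)
    return json_path
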