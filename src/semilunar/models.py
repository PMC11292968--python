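"""Clock-hypothesis model fitting and selection on (T, tau) period data.

Three competing explanations of how a circasemilunar (~15-day) rhythm could
be generated are fitted to pairs of diel cycle length ``T`` (hours) and
observed circasemilunar period ``tau`` (days):

* **counter** - the clock counts a fixed number of circadian cycles, so tau
  scales linearly with T; fitted as an ordinary least-squares line
  ``tau = a + b T``.
* **oscillator** - an autonomous ~15-day oscillator; tau is independent of
  T, fitted as the intercept-only model (the mean of all observed periods).
* **beat** - the semilunar rhythm is the beat envelope of superimposed
  circadian (period T) and circatidal (period k/2, k the lunar-day length in
  hours) oscillations; ``tau(T, k) = T k / (2 |T - k|) / 24`` days, with k
  the single free parameter fitted by nonlinear least squares.

Models are compared on the same observations via residual standard error,
small-sample AICc and Akaike weights.  Only significant period estimates
should enter (see :mod:`semilunar.rhythm`): the caller filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateFitError,
    InsufficientDataError,
    RankDeficiencyError,
    UndefinedBeatError,
    ValidationError,
)

__all__ = [
    "PeriodObservation",
    "HypothesisFit",
    "beat_period",
    "fit_counter",
    "fit_oscillator",
    "fit_beat",
    "aicc",
    "akaike_weights",
    "compare_hypotheses",
]

#: Default starting value for the lunar-day length k (hours) in the beat fit:
#: the entrained semilunar period of 15 days corresponds to k = 24.8 h.
K_START = 24.8
_K_MAX = 40.0


@dataclass(frozen=True)
class PeriodObservation:
    """One (T-cycle length, observed circasemilunar period) pair."""

    T: float
    tau: float
    label: str = ""
    significant: bool = True


@dataclass
class HypothesisFit:
    """A fitted clock-hypothesis model with its selection statistics."""

    name: str
    params: dict
    predictions: np.ndarray
    residuals: np.ndarray
    rss: float
    rse: float
    n_params_p: int  # parameters counted for AICc, incl. the error SD
    log_likelihood: float | None = None
    aicc: float | None = None
    akaike_weight: float | None = None
    degenerate: bool = False
    formula: str = ""

    @property
    def n_obs(self) -> int:
        return self.residuals.size


def _as_arrays(obs):
    obs = list(obs)
    if not obs:
        raise InsufficientDataError("no observations")
    t = np.array([o.T for o in obs], dtype=float)
    tau = np.array([o.tau for o in obs], dtype=float)
    return t, tau


# ---------------------------------------------------------------------------
# the beat model
# ---------------------------------------------------------------------------

def beat_period(T: float, k: float) -> float:
    """Beat-envelope period in days: ``T k / (2 |T - k|) / 24``.

    Diverges as T approaches k (the two oscillations never drift apart), so
    T = k is an error.
    """
    if T <= 0 or k <= 0:
        raise ValidationError("T and k must be positive")
    if T == k:
        raise UndefinedBeatError("beat period diverges at T = k")
    return T * k / (2.0 * abs(T - k)) / 24.0


def _beat_vec(t: np.ndarray, k: float) -> np.ndarray:
    return t * k / (2.0 * np.abs(t - k)) / 24.0


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------

def _finish(name, formula, params, t, tau, pred, n_params_p, df_resid) -> HypothesisFit:
    resid = tau - pred
    rss = float(resid @ resid)
    rse = float(np.sqrt(rss / df_resid)) if df_resid > 0 else np.nan
    fit = HypothesisFit(
        name=name, formula=formula, params=params, predictions=pred,
        residuals=resid, rss=rss, rse=rse, n_params_p=n_params_p,
    )
    n = tau.size
    if rss <= 0.0:
        fit.degenerate = True
    elif n - n_params_p - 1 > 0:
        fit.log_likelihood = _gaussian_loglik(rss, n)
        fit.aicc = _aicc_value(rss, n, n_params_p)
    return fit


def fit_counter(obs) -> HypothesisFit:
    """OLS line tau = a + b*T (the day-counting prediction).

    Requires >= 3 observations spanning >= 2 distinct T values.  The slope
    p-value is the two-sided t-test of b = 0.  Parameters counted for AICc:
    intercept, slope and error SD (p = 3).
    """
    t, tau = _as_arrays(obs)
    if t.size < 3:
        raise InsufficientDataError("counter fit needs >= 3 observations")
    if np.unique(t).size < 2:
        raise RankDeficiencyError("all T-cycle lengths identical")
    res = stats.linregress(t, tau)
    pred = res.intercept + res.slope * t
    params = {
        "intercept": float(res.intercept),
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "slope_p": float(res.pvalue),
    }
    return _finish("counter", "lm(tau ~ T)", params, t, tau, pred, 3, t.size - 2)


def fit_oscillator(obs) -> HypothesisFit:
    """Intercept-only model: the prediction is the mean observed period.

    Parameters counted for AICc: mean and error SD (p = 2).  Residuals sum
    to zero exactly by construction.
    """
    t, tau = _as_arrays(obs)
    if t.size < 2:
        raise InsufficientDataError("oscillator fit needs >= 2 observations")
    mean_tau = float(tau.mean())
    pred = np.full_like(tau, mean_tau)
    return _finish(
        "oscillator", "lm(tau ~ 1)", {"mean_tau": mean_tau},
        t, tau, pred, 2, t.size - 1,
    )


def fit_beat(obs, k_start: float = K_START) -> HypothesisFit:
    """One-parameter nonlinear least squares for the lunar-day length k.

    The objective ``sum (tau_i - beat(T_i, k))^2`` has poles at every
    observed T, so an unguarded Gauss-Newton can diverge.  Instead each
    pole-free interval between consecutive observed T values (plus the tail
    beyond the largest T, up to 40 h, and the head below the smallest) is
    searched with bounded Brent; the global minimiser wins.  The standard
    error of k comes from the linearised (Gauss-Newton) curvature at the
    optimum, as a standard nls summary would report it.
    """
    t, tau = _as_arrays(obs)
    if t.size < 2:
        raise InsufficientDataError("beat fit needs >= 2 observations")

    def objective(k):
        return float(np.sum((tau - _beat_vec(t, k)) ** 2))

    eps = 1e-6
    edges = np.unique(t)
    bounds = []
    lo = max(eps, edges[0] / 4.0)
    if edges[0] - eps > lo:
        bounds.append((lo, edges[0] - eps))
    for a, b in zip(edges[:-1], edges[1:]):
        bounds.append((a + eps, b - eps))
    bounds.append((edges[-1] + eps, max(_K_MAX, edges[-1] + 10.0)))

    best_k, best_obj = None, np.inf
    for a, b in bounds:
        if b <= a:
            continue
        res = optimize.minimize_scalar(objective, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-10})
        if res.fun < best_obj:
            best_k, best_obj = float(res.x), float(res.fun)
    if best_k is None or not np.isfinite(best_obj):
        raise ConvergenceError("beat fit failed on every interval", last_iterate=best_k)
    if best_obj > objective(k_start) + 1e-9 and abs(k_start - best_k) > 1e-9:
        # should be impossible: the start point lies inside one searched interval
        raise ConvergenceError("beat fit worse than its start value", last_iterate=best_k)

    # linearised standard error and t-test of k (nls-style summary)
    h = 1e-6
    grad = (_beat_vec(t, best_k + h) - _beat_vec(t, best_k - h)) / (2 * h)
    df_resid = t.size - 1
    sigma2 = best_obj / df_resid if df_resid > 0 else np.nan
    jj = float(grad @ grad)
    k_se = float(np.sqrt(sigma2 / jj)) if jj > 0 and df_resid > 0 else np.nan
    k_p = float(2 * stats.t.sf(abs(best_k / k_se), df_resid)) if np.isfinite(k_se) and k_se > 0 else np.nan

    pred = _beat_vec(t, best_k)
    params = {"k": best_k, "k_se": k_se, "k_p": k_p}
    return _finish("beat", "nls(tau ~ beat(T, k))", params, t, tau, pred, 2, df_resid)


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def _gaussian_loglik(rss: float, n: int) -> float:
    return -n / 2.0 * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)


def _aicc_value(rss: float, n: int, p: int) -> float:
    ll = _gaussian_loglik(rss, n)
    return -2.0 * ll + 2.0 * p + 2.0 * p * (p + 1.0) / (n - p - 1.0)


def aicc(fit: HypothesisFit, n: int | None = None) -> float:
    """Second-order (small-sample) AIC of a Gaussian fit.

    ``lnL = -n/2 (ln 2pi + ln(rss/n) + 1)`` and
    ``AICc = -2 lnL + 2p + 2p(p+1)/(n-p-1)`` with p including the error SD.
    Undefined for n <= p+1 and for a zero residual sum of squares.
    """
    n = fit.n_obs if n is None else n
    p = fit.n_params_p
    if n - p - 1 <= 0:
        raise ValidationError(f"AICc undefined for n={n}, p={p} (n <= p+1)")
    if fit.rss <= 0:
        raise DegenerateFitError("zero residual sum of squares: likelihood unbounded")
    return _aicc_value(fit.rss, n, p)


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights ``exp(-delta_i/2) / sum_j exp(-delta_j/2)``.

    Deltas are taken to the minimum AICc first, so the computation is stable
    for arbitrarily large spreads.
    """
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0 or np.any(~np.isfinite(a)):
        raise ValidationError("AICc values must be finite")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

_FITTERS = (("counter", fit_counter), ("oscillator", fit_oscillator), ("beat", fit_beat))


def compare_hypotheses(obs, k_start: float = K_START) -> pd.DataFrame:
    """Fit all three models on the same observations and rank them by AICc.

    Per-model failures are reported in the table without aborting the other
    fits.  Akaike weights are computed over the models with a finite AICc.
    Ties in AICc are broken by fewer parameters, then by name.  The fitted
    objects are attached as ``frame.attrs["fits"]``.
    """
    fits: dict[str, HypothesisFit | Exception] = {}
    for name, fitter in _FITTERS:
        try:
            fits[name] = fitter(obs) if name != "beat" else fitter(obs, k_start=k_start)
        except Exception as exc:  # noqa: BLE001 - reported per model
            fits[name] = exc

    ok = {n: f for n, f in fits.items() if isinstance(f, HypothesisFit) and f.aicc is not None}
    if ok:
        weights = akaike_weights([f.aicc for f in ok.values()])
        for f, w in zip(ok.values(), weights):
            f.akaike_weight = float(w)

    rows = []
    for name, f in fits.items():
        if isinstance(f, HypothesisFit):
            rows.append(
                {
                    "hypothesis": name,
                    "model": f.formula,
                    "rse": f.rse,
                    "aicc": f.aicc if f.aicc is not None else np.nan,
                    "weight": f.akaike_weight if f.akaike_weight is not None else np.nan,
                    "n_params": f.n_params_p,
                    "error": "degenerate (zero residuals)" if f.degenerate else "",
                }
            )
        else:
            rows.append(
                {
                    "hypothesis": name, "model": "", "rse": np.nan,
                    "aicc": np.nan, "weight": np.nan, "n_params": np.nan,
                    "error": f"{type(f).__name__}: {f}",
                }
            )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["aicc", "n_params", "hypothesis"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    frame.attrs["fits"] = fits
    return frame


def render_comparison(frame: pd.DataFrame) -> str:
    """Plain-text rendering of a model-comparison table."""
    lines = [f"{'Hypothesis':<12}{'Model':<26}{'RSE':>8}{'AICc':>9}{'Weight':>11}"]
    for _, row in frame.iterrows():
        if row["error"]:
            lines.append(f"{row['hypothesis']:<12}{row['error']}")
            continue
        lines.append(
            f"{row['hypothesis']:<12}{row['model']:<26}"
            f"{row['rse']:>8.3f}{row['aicc']:>9.2f}{row['weight']:>11.2e}"
        )
    return "\n".join(lines)
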