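"""Synthetic emergence-rhythm generator under three clock architectures.

The simulator produces population-level emergence series (daily + hourly)
under the counter, oscillator and beat hypotheses, with the circadian
machinery that shapes real data: a limited range of entrainment to diel
T-cycles, frequency demultiplication under submultiple cycles (LD 6:6),
and population desynchronization under constant light.

Each simulated animal emerges exactly once.  Its *readiness* day is drawn
from a mixed-age cohort distribution clustered around semilunar peaks
spaced by the hypothesis-specific expected period; it then emerges at the
first circadian *gate* (a short window ending at a light->dark transition,
or at the free-running gate phase when there is no entraining cycle) after
readiness.  When the circadian system is desynchronized - a T-cycle outside
the entrainment range, or constant light with per-individual phase
diffusion - the population loses its common gate and, for clocks that
depend on the circadian system, its semilunar structure as well.

The generative period expectations are exactly the quantities the
hypothesis fits estimate, so simulated data carry a known ground truth for
every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import UndefinedBeatError, ValidationError
from .models import beat_period
from .series import (
    EmergenceEvent,
    EmergenceSeries,
    LightRegime,
    assign_to_solar_days,
)

__all__ = [
    "SimConfig",
    "CircadianState",
    "SimResult",
    "effective_circadian_period",
    "expected_semilunar_period",
    "simulate_population",
    "simulate_beat_population",
    "simulate_period_observations",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class SimConfig:
    """Population and clock parameters for the generator.

    ``counter_target_C`` is the number of circadian cycles counted per
    semilunar cycle: 15 reproduces the entrained 15-day period at T = 24 h,
    while the free-running default 13 mirrors the shorter (12-13 day)
    free-running period seen in practice.  ``beat_k`` is the lunar-day
    length in hours (24.8 h when entrained).  ``entrainment_range`` is the
    half-open interval [lower, upper) of cycle lengths the circadian clock
    can lock onto, so the default [20, 28) leaves T = 28 h outside.
    """

    hypothesis: str = "counter"
    n_individuals: int = 400
    n_days: int = 112
    counter_target_C: int = 13
    oscillator_period_days: float = 15.0
    beat_k: float = 24.8
    beat_tidal_amplitude: float = 1.0
    circadian_intrinsic_period: float = 24.5
    entrainment_range: tuple[float, float] = (20.0, 28.0)
    ll_phase_diffusion_sd: float = 0.0
    emergence_gate_width: float = 2.0
    readiness_sd_days: float = 1.5
    first_peak_day: float | None = None
    counter_source: str = "circadian"  # or "external" (counts T-cycles directly)
    count_noise: str = "none"  # or "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.hypothesis not in ("counter", "oscillator", "beat"):
            raise ValidationError(f"unknown hypothesis {self.hypothesis!r}")
        if self.n_individuals < 1 or self.n_days < 1:
            raise ValidationError("population size and duration must be positive")
        if self.counter_target_C < 1:
            raise ValidationError("counter_target_C must be >= 1")
        lo, hi = self.entrainment_range
        if not lo < hi:
            raise ValidationError("entrainment_range lower bound must be < upper")
        for name in ("oscillator_period_days", "beat_k", "circadian_intrinsic_period"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.counter_source not in ("circadian", "external"):
            raise ValidationError("counter_source must be 'circadian' or 'external'")
        if self.count_noise not in ("none", "poisson"):
            raise ValidationError("count_noise must be 'none' or 'poisson'")


@dataclass
class CircadianState:
    """Population-level circadian state under a regime."""

    effective_period: float | None  # hours; None when not entrained
    synchronized: bool
    demultiple: int = 1  # m such that effective_period = m * T under LD


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    daily: EmergenceSeries
    hourly: EmergenceSeries
    events: list
    config: SimConfig
    regime: LightRegime
    expected_period_days: float | None
    circadian: CircadianState


# ---------------------------------------------------------------------------
# clock-level expectations
# ---------------------------------------------------------------------------

def effective_circadian_period(regime: LightRegime, config: SimConfig) -> float | None:
    """Period (hours) the circadian clock runs at under this regime.

    Under LD the clock locks onto the smallest integer multiple ``m*T`` that
    falls inside the entrainment range (frequency demultiplication for
    submultiple cycles, e.g. T = 12 -> 24).  If no multiple fits, the clock
    cannot entrain and None is returned.  Under LL/DD the clock free-runs at
    its intrinsic period.
    """
    if regime.mode in ("LL", "DD"):
        return config.circadian_intrinsic_period
    lo, hi = config.entrainment_range
    t = regime.cycle_length_T
    m = max(1, int(np.ceil(lo / t)))
    if lo <= m * t < hi:
        return m * t
    return None


def circadian_state(regime: LightRegime, config: SimConfig) -> CircadianState:
    eff = effective_circadian_period(regime, config)
    if regime.mode in ("LL", "DD"):
        sync = config.ll_phase_diffusion_sd == 0.0
        return CircadianState(effective_period=eff, synchronized=sync)
    if eff is None:
        return CircadianState(effective_period=None, synchronized=False)
    m = int(round(eff / regime.cycle_length_T))
    return CircadianState(effective_period=eff, synchronized=True, demultiple=m)


def expected_semilunar_period(
    hypothesis: str, regime: LightRegime, config: SimConfig
) -> float | None:
    """Ground-truth semilunar period (days) under each hypothesis.

    counter: C * (effective circadian period) / 24, or None when the clock
    cannot entrain (no cycles to count); with ``counter_source='external'``
    the raw T-cycle is counted instead.  oscillator: the intrinsic period,
    regardless of regime.  beat: the beat-envelope formula with the regime's
    T and the configured lunar-day length k.
    """
    if hypothesis == "counter":
        if config.counter_source == "external":
            if regime.mode != "LD":
                return None
            return config.counter_target_C * regime.cycle_length_T / HOURS_PER_DAY
        eff = effective_circadian_period(regime, config)
        if eff is None:
            return None
        return config.counter_target_C * eff / HOURS_PER_DAY
    if hypothesis == "oscillator":
        return config.oscillator_period_days
    if hypothesis == "beat":
        return beat_period(regime.cycle_length_T, config.beat_k)
    raise ValidationError(f"unknown hypothesis {hypothesis!r}")


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

def _gate_times(regime: LightRegime, state: CircadianState, config: SimConfig,
                horizon_h: float) -> np.ndarray | None:
    """Population gate times (hours): windows in which emergence can occur."""
    if not state.synchronized:
        return None
    if regime.mode == "LD":
        onsets = regime.dark_onsets(horizon_h + 2 * regime.cycle_length_T)
        return onsets[:: state.demultiple]
    # free-running but synchronized (LL/DD without diffusion): gates at the
    # intrinsic period, anchored at the habitual late-light phase (ZT ~18)
    eff = state.effective_period
    g0 = 0.75 * eff
    n = int(np.ceil(horizon_h / eff)) + 2
    return g0 + eff * np.arange(n)


def _readiness_days(rng, config: SimConfig, period_days: float | None) -> np.ndarray:
    """Developmental readiness day per individual (mixed-age cohorts)."""
    n = config.n_individuals
    if period_days is None:
        return rng.uniform(0.0, config.n_days, size=n)
    first = config.first_peak_day if config.first_peak_day is not None else period_days
    centers = np.arange(first, config.n_days, period_days)
    if centers.size == 0:
        centers = np.array([config.n_days / 2.0])
    chosen = rng.choice(centers, size=n)
    days = rng.normal(chosen, config.readiness_sd_days)
    # resample strays outside the experiment; clip any stubborn remainder
    for _ in range(10):
        bad = (days < 0) | (days >= config.n_days)
        if not bad.any():
            break
        days[bad] = rng.normal(rng.choice(centers, size=int(bad.sum())),
                               config.readiness_sd_days)
    return np.clip(days, 0.0, config.n_days - 1e-6)


def _emergence_times(rng, config: SimConfig, state: CircadianState,
                     gates: np.ndarray | None, readiness_days: np.ndarray) -> np.ndarray:
    t0 = readiness_days * HOURS_PER_DAY
    if gates is None:
        # desynchronized population: each animal's private clock places its
        # emergence at an effectively uniform hour after readiness
        return t0 + rng.uniform(0.0, HOURS_PER_DAY, size=t0.size)
    j = np.searchsorted(gates, t0, side="left")
    j = np.minimum(j, gates.size - 1)
    return gates[j] - rng.uniform(0.0, config.emergence_gate_width, size=t0.size)


def _bin_events(times: np.ndarray, config: SimConfig, regime: LightRegime,
                rng) -> tuple[EmergenceSeries, EmergenceSeries, list]:
    horizon_h = config.n_days * HOURS_PER_DAY
    times = times[(times >= 0) & (times < horizon_h)]
    events = [EmergenceEvent(time=float(t)) for t in np.sort(times)]

    hourly_counts = np.bincount(times.astype(int), minlength=int(horizon_h))
    if config.count_noise == "poisson":
        hourly_counts = rng.poisson(hourly_counts)
    hourly = EmergenceSeries(
        bin_width=1.0, start_index=0, counts=hourly_counts,
        alignment="solar_day", regime=regime,
    )

    if regime.mode == "LD":
        # credit each hour bin to the solar day of the most recent dark onset
        # at or before the bin start, so daily and hourly stay consistent
        # even after Poisson thinning
        bin_events_list = [
            EmergenceEvent(time=h + 0.5, count=int(c))
            for h, c in enumerate(hourly_counts) if c > 0
        ]
        daily = assign_to_solar_days(bin_events_list, regime, config.n_days)
    else:
        daycounts = hourly_counts.reshape(config.n_days, 24).sum(axis=1)
        daily = EmergenceSeries(
            bin_width=24.0, start_index=0, counts=daycounts,
            alignment="solar_day", regime=regime,
        )
    return daily, hourly, events


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig, regime: LightRegime,
                        seed: int | None = None) -> SimResult:
    """Simulate one emergence experiment; deterministic given config + seed.

    Returns daily (solar-day-assigned, with masked days under T > 24 h) and
    hourly series over ``n_days``.  A population whose expected semilunar
    period is undefined (counter outside the entrainment range, or under a
    diffusing LL regime) produces arrhythmic output, not an error.
    """
    if config.hypothesis == "beat":
        return simulate_beat_population(config, regime, seed=seed)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = circadian_state(regime, config)

    period = expected_semilunar_period(config.hypothesis, regime, config)
    external = config.hypothesis == "counter" and config.counter_source == "external"
    if config.hypothesis == "counter" and not external and not state.synchronized:
        period = None  # nothing to count without a coherent circadian clock

    readiness = _readiness_days(rng, config, period)
    if external and regime.mode == "LD":
        # a clock reading the external cycle gates at every transition
        gates = regime.dark_onsets(config.n_days * HOURS_PER_DAY + 2 * regime.cycle_length_T)
    else:
        gates = _gate_times(regime, state, config, config.n_days * HOURS_PER_DAY)
    times = _emergence_times(rng, config, state, gates, readiness)
    daily, hourly, events = _bin_events(times, config, regime, rng)
    return SimResult(daily=daily, hourly=hourly, events=events, config=config,
                     regime=regime, expected_period_days=period, circadian=state)


def simulate_beat_population(config: SimConfig, regime: LightRegime,
                             seed: int | None = None) -> SimResult:
    """Simulate a beat-clock population.

    Emergence propensity at each circadian gate is the thresholded product
    of the circadian gate train and a circatidal sinusoid of period ``k/2``
    (two tides per lunar day of length k hours); sampling the tidal wave at
    the circadian gate times makes the daily peak spacing follow the beat
    formula ``T k / (2 |T - k|)``.  ``beat_tidal_amplitude = 0`` degenerates
    to a pure circadian series with no semilunar structure.
    """
    if regime.mode == "LD" and regime.cycle_length_T == config.beat_k:
        raise UndefinedBeatError("beat undefined at T = k")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = circadian_state(regime, config)
    horizon_h = config.n_days * HOURS_PER_DAY

    if not state.synchronized:
        times = rng.uniform(0.0, horizon_h, size=config.n_individuals)
        period = None
    else:
        gates = _gate_times(regime, state, config, horizon_h)
        gates = gates[gates < horizon_h]
        amp = config.beat_tidal_amplitude
        tidal = np.cos(2 * np.pi * 2.0 * gates / config.beat_k)
        weights = np.maximum(0.0, (1.0 - amp) + amp * tidal) ** 2
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        alloc = rng.multinomial(config.n_individuals, weights / weights.sum())
        times = np.repeat(gates, alloc) - rng.uniform(
            0.0, config.emergence_gate_width, size=config.n_individuals
        )
        period = beat_period(regime.cycle_length_T, config.beat_k)

    daily, hourly, events = _bin_events(times, config, regime, rng)
    return SimResult(daily=daily, hourly=hourly, events=events, config=config,
                     regime=regime, expected_period_days=period, circadian=state)


def simulate_period_observations(
    hypothesis: str,
    t_cycles=(22.0, 24.0, 26.0),
    n_replicates: int = 3,
    noise_sd_days: float = 0.8,
    config: SimConfig | None = None,
    seed: int = 0,
):
    """Draw noisy (T, tau) observations straight from a hypothesis' prediction.

    A light-weight companion to the full population simulator for
    model-recovery studies: tau = expected period + Gaussian noise.
    """
    from .models import PeriodObservation

    cfg = config or SimConfig(hypothesis=hypothesis)
    rng = np.random.default_rng(seed)
    obs = []
    for t in t_cycles:
        regime = LightRegime(cycle_length_T=t)
        mu = expected_semilunar_period(hypothesis, regime, cfg)
        if mu is None:
            continue
        for r in range(n_replicates):
            obs.append(
                PeriodObservation(
                    T=t, tau=float(mu + rng.normal(0.0, noise_sd_days)),
                    label=f"T{t:g}_rep{r}",
                )
            )
    return obs
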