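"""Emergence-count time series: containers, file I/O and preprocessing.

The central object is :class:`EmergenceSeries`, binned emergence counts with
an explicit missing-value mask, tied to a :class:`LightRegime` describing the
diel T-cycle the animals experienced.  Two layouts occur in practice:

* *daily* series (``bin_width = 24`` h): one count per 24-h solar day.  Under
  T-cycles longer than 24 h some solar days contain no light->dark transition
  and therefore carry no information; those days are masked missing.
* *hourly* series (``bin_width = 1`` h): one count per hour, usually aligned
  to zeitgeber time with the middle of the dark phase at ZT 0.

Files are plain delimited text (comma or tab, auto-detected) with a header
row; column 1 is the ``day``/``hour`` label, every further column one series.
Missing bins are written as ``NA`` and accepted as ``NA``, ``NaN`` or an
empty cell.  Day/hour indices are stored internally exactly as labelled in
the file (the free-run day numbering of the experiments), so windowing
operations key on those labels rather than on array positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import UnsupportedRegimeError, ValidationError

__all__ = [
    "LightRegime",
    "EmergenceSeries",
    "EmergenceEvent",
    "read_series",
    "write_series",
    "assign_to_solar_days",
    "window_semilunar",
    "zt_align",
    "hourly_profile",
]

_MISSING_TOKENS = ("NA", "NaN", "")

#: First and last free-run day of the semilunar analysis window (inclusive).
SEMILUNAR_WINDOW = (31, 112)


@dataclass(frozen=True)
class LightRegime:
    """A diel light regime: T-cycle length, light fraction and mode.

    ``LD 6:6`` is encoded as ``cycle_length_T=12, light_fraction=0.5``;
    for LL/DD the light fraction is ignored.  ``phase_origin`` is the clock
    time (hours) of the first lights-on, which files must state explicitly
    because experiments differ in it.
    """

    cycle_length_T: float
    light_fraction: float = 0.5
    mode: str = "LD"
    phase_origin: float = 0.0
    vibration: bool = False

    def __post_init__(self):
        if self.cycle_length_T <= 0:
            raise ValidationError("cycle_length_T must be positive")
        if self.mode not in ("LD", "LL", "DD"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "LD" and not 0.0 <= self.light_fraction <= 1.0:
            raise ValidationError("light_fraction must lie in [0, 1]")

    @property
    def light_duration(self) -> float:
        return self.light_fraction * self.cycle_length_T

    @property
    def dark_duration(self) -> float:
        return (1.0 - self.light_fraction) * self.cycle_length_T

    def dark_onsets(self, t_max: float) -> np.ndarray:
        """Times (hours) of every light->dark transition in ``[0, t_max)``."""
        if self.mode != "LD":
            raise UnsupportedRegimeError(
                f"dark onsets are undefined under mode {self.mode}"
            )
        first = self.phase_origin + self.light_duration
        if first >= t_max:
            return np.empty(0)
        n = int(np.ceil((t_max - first) / self.cycle_length_T))
        onsets = first + self.cycle_length_T * np.arange(n)
        return onsets[onsets < t_max]

    def mid_dark(self) -> float:
        """Clock time (hours) of the middle of the first dark phase."""
        if self.mode != "LD":
            raise UnsupportedRegimeError("mid-dark is undefined without an LD cycle")
        return self.phase_origin + self.light_duration + self.dark_duration / 2.0


@dataclass(frozen=True)
class EmergenceEvent:
    """A single emergence at a continuous time (hours since experiment start)."""

    time: float
    count: int = 1

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError("event time must be >= 0")
        if self.count <= 0:
            raise ValidationError("event count must be positive")


@dataclass
class EmergenceSeries:
    """Binned emergence counts with an explicit missing mask."""

    bin_width: float
    start_index: int
    counts: np.ndarray
    missing: np.ndarray = None
    alignment: str = "solar_day"
    regime: LightRegime | None = None
    label: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise ValidationError("counts must be a non-empty 1-D sequence")
        if self.missing is None:
            missing = np.isnan(counts)
        else:
            missing = np.asarray(self.missing, dtype=bool)
            if missing.shape != counts.shape:
                raise ValidationError("missing mask must match counts in length")
            missing = missing | np.isnan(counts)
        obs = counts[~missing]
        if np.any(obs < 0):
            raise ValidationError("counts must be non-negative")
        stored = np.where(missing, 0, np.nan_to_num(counts)).astype(int)
        self.counts = stored
        self.missing = missing
        if self.alignment not in ("solar_day", "zeitgeber_time"):
            raise ValidationError(f"unknown alignment {self.alignment!r}")

    # -- convenience -------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    @property
    def total_count(self) -> int:
        return int(self.counts[~self.missing].sum())

    def index(self) -> np.ndarray:
        """Bin labels (day or hour numbers) as stored."""
        return self.start_index + np.arange(self.n_bins)

    def values(self) -> np.ndarray:
        """Counts as float with NaN at missing bins."""
        out = self.counts.astype(float)
        out[self.missing] = np.nan
        return out

    def replace(self, **kwargs) -> "EmergenceSeries":
        params = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        params.update(kwargs)
        return EmergenceSeries(**params)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_series(path, layout: str, regime: LightRegime | None = None) -> list[EmergenceSeries]:
    """Read delimited text into one :class:`EmergenceSeries` per count column.

    ``layout`` is ``"daily"`` or ``"hourly"``; it fixes the bin width (24 h or
    1 h).  The first column holds the bin label; labels must be strictly
    increasing.  Label gaps are filled with masked bins so the returned series
    are contiguous.
    """
    if layout not in ("daily", "hourly"):
        raise ValidationError(f"layout must be 'daily' or 'hourly', got {layout!r}")
    frame = pd.read_csv(
        Path(path), sep=None, engine="python",
        na_values=list(_MISSING_TOKENS), keep_default_na=False,
    )
    if frame.shape[1] < 2:
        raise ValidationError("expected an index column plus at least one count column")
    idx = frame.iloc[:, 0].to_numpy()
    try:
        idx = idx.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError("bin-index column is not numeric") from exc
    if np.any(np.isnan(idx)):
        raise ValidationError("bin-index column contains missing values")
    if np.any(np.diff(idx) <= 0):
        raise ValidationError("bin indices must be strictly increasing")
    idx = idx.astype(int)
    start = int(idx[0])
    length = int(idx[-1]) - start + 1
    pos = idx - start

    out = []
    bin_width = 24.0 if layout == "daily" else 1.0
    for col in frame.columns[1:]:
        raw = frame[col].to_numpy(dtype=float)
        if np.any(raw[~np.isnan(raw)] < 0):
            raise ValidationError(f"column {col!r} contains negative counts")
        full = np.full(length, np.nan)
        full[pos] = raw
        out.append(
            EmergenceSeries(
                bin_width=bin_width, start_index=start, counts=full,
                regime=regime, label=str(col),
            )
        )
    return out


def write_series(path, series: Sequence[EmergenceSeries] | EmergenceSeries, sep: str = ",") -> None:
    """Write series sharing one bin grid to delimited text; missing -> ``NA``."""
    if isinstance(series, EmergenceSeries):
        series = [series]
    first = series[0]
    for s in series[1:]:
        if s.start_index != first.start_index or s.n_bins != first.n_bins \
                or s.bin_width != first.bin_width:
            raise ValidationError("all series written together must share one bin grid")
    index_name = "day" if first.bin_width == 24 else "hour"
    data = {index_name: first.index()}
    for i, s in enumerate(series):
        vals = s.values()
        col = s.label or f"series_{i + 1}"
        data[col] = [("NA" if np.isnan(v) else str(int(v))) for v in vals]
    pd.DataFrame(data).to_csv(Path(path), sep=sep, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def assign_to_solar_days(
    events: Iterable[EmergenceEvent],
    regime: LightRegime,
    n_days: int,
) -> EmergenceSeries:
    """Bin events onto 24-h solar days via the most recent light->dark transition.

    Each event is credited to the solar day containing the last lights-off at
    or before the event time.  Under T > 24 h some solar days contain no
    lights-off; those are masked missing.  An event preceding the very first
    transition is credited to the first transition's day so the total count
    is conserved.
    """
    if regime.mode != "LD":
        raise UnsupportedRegimeError("solar-day assignment requires an LD regime")
    events = sorted(events, key=lambda e: e.time)
    horizon = max(n_days * 24.0, (events[-1].time + regime.cycle_length_T) if events else 0.0)
    onsets = regime.dark_onsets(horizon + regime.cycle_length_T)
    if onsets.size == 0:
        raise UnsupportedRegimeError("no light->dark transition inside the horizon")

    counts = np.zeros(n_days, dtype=int)
    times = np.array([e.time for e in events])
    sizes = np.array([e.count for e in events], dtype=int)
    if times.size:
        j = np.searchsorted(onsets, times, side="right") - 1
        j = np.maximum(j, 0)  # pre-first-transition events -> first transition
        days = np.floor(onsets[j] / 24.0).astype(int)
        keep = days < n_days
        np.add.at(counts, days[keep], sizes[keep])

    onset_days = np.unique(np.floor(onsets[onsets < n_days * 24.0] / 24.0).astype(int))
    missing = np.ones(n_days, dtype=bool)
    missing[onset_days[onset_days < n_days]] = False
    return EmergenceSeries(
        bin_width=24.0, start_index=0, counts=counts, missing=missing,
        alignment="solar_day", regime=regime,
    )


def window_semilunar(series: EmergenceSeries, window: tuple[int, int] = SEMILUNAR_WINDOW) -> EmergenceSeries:
    """Restrict a daily series to the semilunar analysis window (days 31-112).

    The first 30 free-run days are discarded because emergence there is
    developmentally predetermined by the entrainment phase.  Series ending
    early are right-padded with missing bins; series starting after the
    window opens cannot be analysed and raise.
    """
    lo, hi = window
    if series.bin_width != 24:
        raise ValidationError("semilunar windowing applies to daily series only")
    if series.start_index > lo:
        raise ValidationError(
            f"series starts at day {series.start_index}, after window start {lo}"
        )
    length = hi - lo + 1
    vals = np.full(length, np.nan)
    src = series.values()
    src_days = series.index()
    sel = (src_days >= lo) & (src_days <= hi)
    vals[src_days[sel] - lo] = src[sel]
    return series.replace(counts=vals, missing=None, start_index=lo)


def zt_align(series: EmergenceSeries, regime: LightRegime | None = None) -> EmergenceSeries:
    """Circularly shift an hourly series so mid-dark maps to ZT 0.

    Total count is conserved (pure roll).  A series already labelled
    ``zeitgeber_time`` is returned unchanged.
    """
    if series.bin_width != 1:
        raise UnsupportedRegimeError("ZT alignment is defined for hourly series only")
    if series.alignment == "zeitgeber_time":
        return series.replace()
    regime = regime or series.regime
    if regime is None:
        raise ValidationError("a light regime is required for ZT alignment")
    shift = int(round(regime.mid_dark() % regime.cycle_length_T))
    vals = np.roll(series.values(), -shift)
    return series.replace(counts=vals, missing=None, alignment="zeitgeber_time")


def hourly_profile(series: EmergenceSeries, fold_period: int) -> np.ndarray:
    """Sum counts per phase bin after folding at ``fold_period`` hours.

    Element ``j`` is the sum of counts at bins congruent to ``j`` modulo the
    fold period; missing bins are skipped, so the grand total is conserved.
    """
    if fold_period is None or int(fold_period) != fold_period or fold_period <= 0:
        raise ValidationError("fold_period must be a positive integer number of hours")
    fold_period = int(fold_period)
    if series.bin_width != 1:
        raise ValidationError("hourly profiles require an hourly series")
    phase = series.index() % fold_period
    obs = ~series.missing
    return np.bincount(phase[obs], weights=series.counts[obs], minlength=fold_period)
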