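"""Hourly-binned, imputed per-stay timelines from raw observation tables.

Raw data arrive as long-format event tables (one row per timestamped
measurement of one channel for one stay).  This module bins them onto an
hourly grid anchored at ICU start with half-open bins [k, k+1), averages
within bins, resolves invasive/noninvasive blood pressure into single
systolic/diastolic series, and imputes gaps by carry-forward (with
back-fill before the first observation).  Channels never observed in a
stay remain all-missing and are flagged rather than fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    ALL_CHANNELS,
    EXTENDED_VITALS,
    PLAUSIBLE_RANGES,
    is_extended_vital,
)


class EmptyStayError(ValueError):
    """Raised when a stay has no extended-vital observations at all."""


@dataclass
class TimelineConfig:
    """Knobs for parsing and timeline construction.

    prefer_invasive_bp
        Within an hour where both invasive and noninvasive blood pressure
        were observed, use the invasive value (clinical convention).
    temperature_unit
        'C' (default) or 'F'; Fahrenheit inputs are converted to Celsius
        at parse time.
    """

    prefer_invasive_bp: bool = True
    temperature_unit: str = "C"
    plausible_ranges: dict = field(default_factory=lambda: dict(PLAUSIBLE_RANGES))


@dataclass
class StayRecord:
    """One ICU stay: static fields plus its raw observations and events."""

    stay_id: object
    age_years: float
    icu_length_h: float
    observations: pd.DataFrame  # columns: time_h, channel, value
    antibiotic_times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    culture_times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    death_in_hospital: bool = False

    def __post_init__(self) -> None:
        if self.icu_length_h <= 0:
            raise ValueError(f"stay {self.stay_id}: icu_length_h must be > 0")
        self.antibiotic_times_h = np.sort(np.asarray(self.antibiotic_times_h, float))
        self.culture_times_h = np.sort(np.asarray(self.culture_times_h, float))


@dataclass
class StayTimeline:
    """Per-channel hourly value arrays with observed-bin masks.

    ``values[ch]`` has length ``n_hours`` and, after imputation, is fully
    populated for every channel observed at least once in the stay;
    ``observed[ch]`` marks bins that contained >= 1 raw observation.
    Derived channels ``sys_bp``, ``dias_bp`` and ``pulse_pressure`` are
    source-resolved from the four raw blood-pressure channels.
    """

    stay_id: object
    n_hours: int
    age_years: float
    values: dict[str, np.ndarray]
    observed: dict[str, np.ndarray]
    missing_channels: frozenset[str] = frozenset()

    def has_channel(self, channel: str) -> bool:
        return channel not in self.missing_channels and channel in self.values

    def value_at(self, channel: str, hour: int) -> float:
        return float(self.values[channel][hour])


def infer_icu_start(observations: pd.DataFrame) -> float:
    """ICU start approximated as 60 minutes before the first extended vital.

    Used when no explicit ICU admission timestamp is available; the
    returned origin is on the same absolute clock as the observations.
    """
    vitals = observations[observations["channel"].map(is_extended_vital)]
    if len(vitals) == 0:
        raise EmptyStayError("no extended-vital observations; cannot infer ICU start")
    return float(vitals["time_h"].min()) - 1.0


def bin_hourly(
    times_h: np.ndarray, values: np.ndarray, n_hours: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average raw observations into half-open hourly bins [k, k+1).

    Returns (binned values with NaN in empty bins, observed mask).
    """
    out = np.full(n_hours, np.nan)
    mask = np.zeros(n_hours, dtype=bool)
    times_h = np.asarray(times_h, float)
    values = np.asarray(values, float)
    if times_h.size == 0:
        return out, mask
    if times_h.min() < 0 or times_h.max() >= n_hours:
        raise ValueError("observation time outside [0, n_hours)")
    # sort by time so bin sums are independent of input row ordering
    order = np.argsort(times_h, kind="mergesort")
    times_h, values = times_h[order], values[order]
    idx = np.floor(times_h).astype(int)
    sums = np.bincount(idx, weights=values, minlength=n_hours)
    counts = np.bincount(idx, minlength=n_hours)
    mask = counts > 0
    out[mask] = sums[mask] / counts[mask]
    return out, mask


def impute(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Carry-forward imputation with back-fill before the first observation.

    After the first observed bin, empty bins take the most recent observed
    bin value; bins preceding the first observation take the first
    observed value.  An array with no observed bins is returned unchanged
    (all-missing); callers flag such channels.
    """
    v = np.array(values, dtype=float, copy=True)
    obs = ~np.isnan(v) if mask is None else np.asarray(mask, bool)
    if not obs.any():
        return v
    idx = np.arange(len(v))
    last_obs = np.maximum.accumulate(np.where(obs, idx, -1))
    first = int(np.argmax(obs))
    last_obs[last_obs < 0] = first  # back-fill region
    return v[last_obs]


def resolve_blood_pressure(
    binned: dict[str, tuple[np.ndarray, np.ndarray]],
    n_hours: int,
    prefer_invasive: bool = True,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge invasive/noninvasive BP into sys_bp and dias_bp per hour.

    Within each hour the preferred source is used when that bin was
    observed, otherwise the other source.  Operates on the raw binned
    (pre-imputation) arrays so preference is decided by actual
    observations, not carried-forward values.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pairs = {"sys_bp": ("sysabp", "nisysabp"), "dias_bp": ("diasabp", "nidiasabp")}
    for name, (inv, noninv) in pairs.items():
        a_vals, a_mask = binned.get(inv, (np.full(n_hours, np.nan), np.zeros(n_hours, bool)))
        b_vals, b_mask = binned.get(noninv, (np.full(n_hours, np.nan), np.zeros(n_hours, bool)))
        if not prefer_invasive:
            a_vals, a_mask, b_vals, b_mask = b_vals, b_mask, a_vals, a_mask
        vals = np.where(a_mask, a_vals, b_vals)
        mask = a_mask | b_mask
        vals = np.where(mask, vals, np.nan)
        out[name] = (vals, mask)
    return out


def build_stay_timeline(stay: StayRecord, config: TimelineConfig | None = None) -> StayTimeline:
    """Bin, source-resolve and impute all channels of one stay."""
    config = config or TimelineConfig()
    obs = stay.observations
    if len(obs) == 0 or not obs["channel"].map(is_extended_vital).any():
        raise EmptyStayError(f"stay {stay.stay_id}: no extended-vital observations")
    n_hours = max(1, math.ceil(stay.icu_length_h))

    binned: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ch, grp in obs.groupby("channel", sort=False):
        binned[str(ch)] = bin_hourly(grp["time_h"].to_numpy(), grp["value"].to_numpy(), n_hours)

    binned.update(
        resolve_blood_pressure(binned, n_hours, prefer_invasive=config.prefer_invasive_bp)
    )

    values: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    missing: set[str] = set()
    for ch in list(ALL_CHANNELS) + ["sys_bp", "dias_bp"]:
        raw, mask = binned.get(ch, (np.full(n_hours, np.nan), np.zeros(n_hours, bool)))
        values[ch] = impute(raw, mask)
        observed[ch] = mask
        if not mask.any():
            missing.add(ch)

    pp = values["sys_bp"] - values["dias_bp"]
    values["pulse_pressure"] = pp
    observed["pulse_pressure"] = observed["sys_bp"] & observed["dias_bp"]
    if np.isnan(pp).all():
        missing.add("pulse_pressure")

    return StayTimeline(
        stay_id=stay.stay_id,
        n_hours=n_hours,
        age_years=stay.age_years,
        values=values,
        observed=observed,
        missing_channels=frozenset(missing),
    )


def parse_observations(
    df: pd.DataFrame, config: TimelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a long-format observation table.

    Rejects rows with unknown channels or values outside the configured
    plausibility range; Fahrenheit temperatures are converted to Celsius
    when the config says the file uses Fahrenheit.  Returns the accepted
    rows and a rejection log (with a ``reason`` column).
    """
    config = config or TimelineConfig()
    df = df.copy()
    required = {"stay_id", "time_h", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"observation table must have columns {sorted(required)}")
    if config.temperature_unit.upper() == "F":
        is_temp = df["channel"] == "temperature"
        df.loc[is_temp, "value"] = (df.loc[is_temp, "value"] - 32.0) * 5.0 / 9.0

    known = df["channel"].isin(ALL_CHANNELS)
    lo = df["channel"].map(lambda c: config.plausible_ranges.get(c, (-np.inf,))[0])
    hi = df["channel"].map(lambda c: config.plausible_ranges.get(c, (None, np.inf))[-1])
    in_range = (df["value"] >= lo) & (df["value"] <= hi)

    ok = known & in_range
    rejected = df.loc[~ok].copy()
    rejected["reason"] = np.where(
        ~known.loc[~ok], "unknown channel", "value outside plausibility range"
    )
    return df.loc[ok].reset_index(drop=True), rejected.reset_index(drop=True)


def timelines_to_frame(timelines: dict[object, StayTimeline]) -> pd.DataFrame:
    """Export a cohort of timelines as one wide table (stay_id, hour, channels, masks)."""
    rows = []
    channels = list(EXTENDED_VITALS) + ["sys_bp", "dias_bp", "pulse_pressure"]
    for sid, tl in timelines.items():
        frame = {"stay_id": sid, "hour": np.arange(tl.n_hours)}
        for ch in channels:
            frame[ch] = tl.values[ch]
            frame[f"{ch}_observed"] = tl.observed[ch]
        rows.append(pd.DataFrame(frame))
    if not rows:
        return pd.DataFrame(columns=["stay_id", "hour"])
    return pd.concat(rows, ignore_index=True)
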