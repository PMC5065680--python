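"""Synthetic ICU cohort generator.

Emulates EHR-style observation streams so every pipeline stage is
exercisable without restricted clinical data: mean-reverting
(Ornstein-Uhlenbeck) vital-sign processes sampled at Poisson observation
times with per-channel cadences close to real per-hour recording rates,
noninvasive blood pressure for (nearly) all stays and an arterial line
for a configurable fraction, culture/antibiotic event pairs, and — for
designed-septic stays — a physiological deterioration that raises the
vitals-visible SOFA total by at least 2 points over its pre-window
baseline.

Deterioration has two phases: a gradual pre-onset ramp that approaches
but deliberately does not cross the +2 SOFA threshold (this is what the
classifier can see at nonzero prediction horizons) and a full-effect
step at the designed onset hour, accompanied by a full vitals assessment
burst such as a bedside team would chart during acute deterioration.
The step is what makes the retrospectively recovered onset land on the
designed hour.  Every stay also gets a complete admission assessment in
its first minutes, so the "all predictors recorded" inclusion filter is
satisfied by design rather than by chance.

The designed truth table (class and onset hour) exists for testing only
and is never an input to the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort
from .timeline import StayRecord


@dataclass
class ChannelModel:
    """Observation cadence and latent-process parameters for one channel.

    rate : Poisson observation rate, events per hour.
    mean / between_sd : population mean and between-stay SD of the
        per-stay baseline.
    ou_sd / theta : stationary SD and mean-reversion rate (per hour) of
        the within-stay Ornstein-Uhlenbeck fluctuation.
    noise_sd : iid measurement noise per observation.
    lo, hi : physiologic clipping bounds.
    """

    rate: float
    mean: float
    between_sd: float
    ou_sd: float
    theta: float
    noise_sd: float
    lo: float
    hi: float


def _default_channels() -> dict[str, ChannelModel]:
    # cadences near the observed per-hour medians of Metavision-era streams
    return {
        "heart_rate": ChannelModel(1.07, 85.0, 8.0, 6.0, 0.15, 2.0, 25.0, 220.0),
        "resp_rate": ChannelModel(1.06, 17.0, 2.5, 2.0, 0.15, 1.0, 5.0, 55.0),
        "spo2": ChannelModel(1.06, 97.0, 1.0, 1.0, 0.20, 0.5, 45.0, 100.0),
        "temperature": ChannelModel(0.27, 37.0, 0.30, 0.25, 0.10, 0.10, 31.0, 43.0),
        "gcs": ChannelModel(0.25, 15.0, 0.0, 0.0, 0.0, 0.15, 3.0, 15.0),
        "nisysabp": ChannelModel(0.88, 120.0, 12.0, 9.0, 0.15, 3.0, 35.0, 270.0),
        "nidiasabp": ChannelModel(0.88, 70.0, 8.0, 6.0, 0.15, 2.0, 16.0, 180.0),
        "sysabp": ChannelModel(0.76, 120.0, 12.0, 9.0, 0.15, 2.0, 35.0, 270.0),
        "diasabp": ChannelModel(0.76, 70.0, 8.0, 6.0, 0.15, 1.5, 16.0, 180.0),
    }


# Full deterioration effect at/after the designed onset, in channel units.
DEFAULT_EFFECTS: dict[str, float] = {
    "heart_rate": 28.0,
    "resp_rate": 9.0,
    "temperature": 1.3,
    "spo2": -17.0,
    "gcs": -4.0,
    "nisysabp": -32.0,
    "nidiasabp": -22.0,
    "sysabp": -32.0,
    "diasabp": -22.0,
}

# Fraction of the full effect reached at the end of the pre-onset ramp;
# chosen so pre-onset SOFA subscores stay below their thresholds (the +2
# rise must occur at the designed onset, not before).
DEFAULT_PREONSET_FRACTION: dict[str, float] = {
    "heart_rate": 0.60,
    "resp_rate": 0.60,
    "temperature": 0.60,
    "spo2": 0.35,
    "gcs": 0.0,
    "nisysabp": 0.30,
    "nidiasabp": 0.30,
    "sysabp": 0.30,
    "diasabp": 0.30,
}


@dataclass
class SynthConfig:
    """Study-condition knobs for the generated cohort."""

    n_stays: int = 500
    prevalence: float = 0.113
    seed: int = 0
    channels: dict[str, ChannelModel] = field(default_factory=_default_channels)
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    preonset_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREONSET_FRACTION)
    )
    effect_scale: float = 1.0          # global multiplier on deterioration effects
    ramp_hours: tuple[float, float] = (6.0, 12.0)
    onset_hour_range: tuple[int, int] = (10, 46)
    post_onset_hours: tuple[int, int] = (8, 48)
    los_median_h: float = 48.0         # median length of stay (~2 days)
    los_log_sd: float = 0.70
    los_min_h: float = 10.0
    los_max_h: float = 400.0
    age_mean: float = 64.0
    age_sd: float = 16.0
    invasive_bp_fraction: float = 0.43
    decoy_abx_fraction: float = 0.10   # nonseptic stays with a lone antibiotic event
    decoy_culture_fraction: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.ramp_hours[0] < 1.0:
            raise ValueError("deterioration ramp must last at least 1 hour")
        if any(m.rate <= 0 for m in self.channels.values()):
            raise ValueError("observation rates must be positive")


def _sample_ou_path(
    times: np.ndarray, model: ChannelModel, baseline: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact OU transition sampling of the latent deviation at given times."""
    dev = np.empty(len(times))
    if model.ou_sd == 0.0 or model.theta == 0.0:
        return np.zeros(len(times))
    d = rng.normal(0.0, model.ou_sd)
    prev_t = 0.0
    for k, t in enumerate(times):
        phi = math.exp(-model.theta * (t - prev_t))
        d = d * phi + rng.normal(0.0, model.ou_sd * math.sqrt(1.0 - phi * phi))
        dev[k] = d
        prev_t = t
    return dev


def _deterioration_offset(
    times: np.ndarray, effect: float, pre_frac: float, onset_h: float, ramp_h: float
) -> np.ndarray:
    """Ramp to pre_frac*effect just before onset, full effect from onset on."""
    ramp_start = onset_h - ramp_h
    progress = np.clip((times - ramp_start) / ramp_h, 0.0, 1.0)
    offset = pre_frac * effect * progress
    return np.where(times >= onset_h, effect, offset)


def generate_stay(
    config: SynthConfig,
    septic: bool,
    rng: np.random.Generator,
    stay_id: object = 0,
) -> tuple[StayRecord, int | None]:
    """One synthetic stay plus its designed onset hour (None if nonseptic)."""
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 16.0, 95.0))
    if septic:
        onset = int(rng.integers(config.onset_hour_range[0], config.onset_hour_range[1] + 1))
        post = int(rng.integers(config.post_onset_hours[0], config.post_onset_hours[1] + 1))
        length = float(onset + post)
    else:
        onset = None
        length = float(
            np.clip(
                rng.lognormal(math.log(config.los_median_h), config.los_log_sd),
                config.los_min_h,
                config.los_max_h,
            )
        )
    ramp = float(rng.uniform(*config.ramp_hours))
    has_invasive = rng.random() < config.invasive_bp_fraction

    rows = []
    for name, model in config.channels.items():
        if name in ("sysabp", "diasabp") and not has_invasive:
            continue
        n_events = rng.poisson(model.rate * length)
        times = np.sort(rng.uniform(0.0, length, n_events))
        # admission assessment in the first minutes of every stay
        times = np.concatenate(([0.05], times))
        if septic:
            # full vitals assessment charted at acute deterioration
            times = np.concatenate((times, [onset + 0.05]))
        times = np.sort(times)
        baseline = rng.normal(model.mean, model.between_sd)
        values = baseline + _sample_ou_path(times, model, baseline, rng)
        values = values + rng.normal(0.0, model.noise_sd, len(times))
        if septic:
            values = values + _deterioration_offset(
                times,
                config.effect_scale * config.effects.get(name, 0.0),
                config.preonset_fraction.get(name, 0.0),
                float(onset),
                ramp,
            )
        values = np.clip(values, model.lo, model.hi)
        if name == "gcs":
            values = np.round(values)
        rows.append(pd.DataFrame({"time_h": times, "channel": name, "value": values}))

    obs = pd.concat(rows, ignore_index=True)
    obs = obs[obs["time_h"] < length].reset_index(drop=True)

    abx_times: list[float] = []
    culture_times: list[float] = []
    if septic:
        abx = float(onset - rng.uniform(0.5, 2.5))
        culture = abx + float(rng.uniform(0.5, min(40.0, length - abx - 0.1)))
        abx_times, culture_times = [abx], [culture]
    else:
        u = rng.random()
        if u < config.decoy_abx_fraction:
            abx_times = [float(rng.uniform(1.0, length - 0.5))]
        elif u < config.decoy_abx_fraction + config.decoy_culture_fraction:
            culture_times = [float(rng.uniform(1.0, length - 0.5))]

    death_p = 0.20 if septic else 0.05
    stay = StayRecord(
        stay_id=stay_id,
        age_years=age,
        icu_length_h=length,
        observations=obs,
        antibiotic_times_h=np.array(abx_times),
        culture_times_h=np.array(culture_times),
        death_in_hospital=bool(rng.random() < death_p),
    )
    return stay, onset


def generate_cohort(config: SynthConfig) -> tuple[Cohort, pd.DataFrame]:
    """A full cohort plus the designed-truth table.

    Septic assignment is an independent Bernoulli draw per stay at the
    configured prevalence; everything is driven by the config seed.
    """
    rng = np.random.default_rng(config.seed)
    stays: dict[object, StayRecord] = {}
    truth_rows = []
    for i in range(config.n_stays):
        sid = f"stay_{i:05d}"
        septic = bool(rng.random() < config.prevalence)
        stay, onset = generate_stay(config, septic, rng, stay_id=sid)
        stays[sid] = stay
        truth_rows.append(
            {"stay_id": sid, "designed_septic": septic, "designed_onset_hour": onset}
        )
    truth = pd.DataFrame(
        truth_rows, columns=["stay_id", "designed_septic", "designed_onset_hour"]
    )
    return Cohort(stays), truth
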