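"""Cohort container and the plain-CSV interchange schemas.

A cohort is exchanged as three long-format tables:

* ``stays.csv`` — stay_id, age_years, icu_length_h, death_in_hospital
* ``observations.csv`` — stay_id, time_h, channel, value
* ``events.csv`` — stay_id, time_h, event_type in {antibiotic, culture}

All times are relative hours since ICU start; headers are required and
the decimal separator is '.'.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeline import StayRecord, TimelineConfig, parse_observations

OBS_COLUMNS = ["stay_id", "time_h", "channel", "value"]
STAY_COLUMNS = ["stay_id", "age_years", "icu_length_h", "death_in_hospital"]
EVENT_COLUMNS = ["stay_id", "time_h", "event_type"]


@dataclass
class Cohort:
    """All stays of one dataset, keyed by stay id."""

    stays: dict[object, StayRecord]

    def __len__(self) -> int:
        return len(self.stays)

    @property
    def stay_ids(self) -> list:
        return list(self.stays.keys())

    def observations_frame(self) -> pd.DataFrame:
        frames = []
        for sid, stay in self.stays.items():
            df = stay.observations.copy()
            df.insert(0, "stay_id", sid)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=OBS_COLUMNS)
        return pd.concat(frames, ignore_index=True)[OBS_COLUMNS]

    def stays_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stay_id": sid,
                    "age_years": s.age_years,
                    "icu_length_h": s.icu_length_h,
                    "death_in_hospital": s.death_in_hospital,
                }
                for sid, s in self.stays.items()
            ],
            columns=STAY_COLUMNS,
        )

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for sid, s in self.stays.items():
            rows += [
                {"stay_id": sid, "time_h": t, "event_type": "antibiotic"}
                for t in s.antibiotic_times_h
            ]
            rows += [
                {"stay_id": sid, "time_h": t, "event_type": "culture"}
                for t in s.culture_times_h
            ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def assemble_cohort(
    stays_df: pd.DataFrame,
    observations_df: pd.DataFrame,
    events_df: pd.DataFrame,
    config: TimelineConfig | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Build a Cohort from the three interchange tables.

    Observations are range-validated (out-of-range rows rejected and
    returned in a log).  Observation times outside [0, icu_length_h) are
    dropped; event times may be negative (pre-ICU antibiotics).
    """
    observations_df, rejected = parse_observations(observations_df, config)
    obs_by_stay = dict(tuple(observations_df.groupby("stay_id", sort=False)))
    ev_by_stay = dict(tuple(events_df.groupby("stay_id", sort=False)))
    stays: dict[object, StayRecord] = {}
    for row in stays_df.itertuples(index=False):
        sid = row.stay_id
        obs = obs_by_stay.get(sid, pd.DataFrame(columns=OBS_COLUMNS))
        obs = obs[(obs["time_h"] >= 0) & (obs["time_h"] < row.icu_length_h)]
        ev = ev_by_stay.get(sid, pd.DataFrame(columns=EVENT_COLUMNS))
        stays[sid] = StayRecord(
            stay_id=sid,
            age_years=float(row.age_years),
            icu_length_h=float(row.icu_length_h),
            observations=obs[["time_h", "channel", "value"]].reset_index(drop=True),
            antibiotic_times_h=ev.loc[ev["event_type"] == "antibiotic", "time_h"].to_numpy(),
            culture_times_h=ev.loc[ev["event_type"] == "culture", "time_h"].to_numpy(),
            death_in_hospital=bool(getattr(row, "death_in_hospital", False)),
        )
    return Cohort(stays), rejected


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("stays", cohort.stays_frame()),
        ("observations", cohort.observations_frame()),
        ("events", cohort.events_frame()),
    ]:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_cohort(in_dir: str | Path, config: TimelineConfig | None = None) -> tuple[Cohort, pd.DataFrame]:
    in_dir = Path(in_dir)
    stays_df = pd.read_csv(in_dir / "stays.csv")
    obs_df = pd.read_csv(in_dir / "observations.csv")
    ev_path = in_dir / "events.csv"
    ev_df = pd.read_csv(ev_path) if ev_path.exists() else pd.DataFrame(columns=EVENT_COLUMNS)
    return assemble_cohort(stays_df, obs_df, ev_df, config)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
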