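"""Benchmark severity scores: qSOFA, SIRS, MEWS at arbitrary hours; SOFA
and SAPS II at admission.

These are the standard bedside/ICU severity scores the minimal-vitals
classifier is compared against.  Banding tables live in a plain-text YAML
data file shipped with the package and every threshold can be overridden
by passing a modified table.  Missing inputs never add points (a
criterion that cannot be evaluated is "not met"), mirroring the
missing-subscore-zero convention used for SOFA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .labels import SofaConfig, hourly_sofa
from .timeline import StayTimeline

SCORE_RANGES = {"sirs": (0, 4), "qsofa": (0, 3), "mews": (0, 14), "sofa": (0, 24), "saps2": (0, 163)}


@lru_cache(maxsize=1)
def default_tables() -> dict:
    """Load the packaged score banding tables."""
    with resources.files("sepsight.data").joinpath("score_tables.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ScorePoint:
    stay_id: object
    hour: int
    score_name: str
    value: int
    components: dict


def _lookup_band(value: float, bands: list[dict]) -> int:
    """Points for a value in a [lo, hi) band table; NaN scores 0."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return 0
    for band in bands:
        lo = band["lo"] if band["lo"] is not None else -math.inf
        hi = band["hi"] if band["hi"] is not None else math.inf
        if lo <= value < hi:
            return int(band["points"])
    return 0


def _nan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def qsofa(rr: float, sbp: float, gcs: float, table: dict | None = None) -> int:
    """Quick-SOFA: one point each for tachypnoea, hypotension, altered mentation."""
    t = (table or default_tables())["qsofa"]
    pts = {
        "resp_rate": int(not _nan(rr) and rr > t["resp_rate_above"]),
        "sys_bp": int(not _nan(sbp) and sbp < t["sysbp_below"]),
        "mentation": int(not _nan(gcs) and gcs < t["gcs_below"]),
    }
    return sum(pts.values())


def sirs(
    temp: float,
    hr: float,
    rr: float,
    paco2: float | None = None,
    wbc: float | None = None,
    table: dict | None = None,
) -> int:
    """Systemic inflammatory response syndrome criteria count (0-4)."""
    t = (table or default_tables())["sirs"]
    pts = {
        "temperature": int(
            not _nan(temp) and (temp > t["temp_high"] or temp < t["temp_low"])
        ),
        "heart_rate": int(not _nan(hr) and hr > t["heart_rate_above"]),
        "resp": int(
            (not _nan(rr) and rr > t["resp_rate_above"])
            or (not _nan(paco2) and paco2 < t["paco2_below"])
        ),
        "wbc": int(not _nan(wbc) and (wbc > t["wbc_high"] or wbc < t["wbc_low"])),
    }
    return sum(pts.values())


def avpu_from_gcs(gcs: float) -> str:
    """Collapse GCS onto the AVPU consciousness scale."""
    if _nan(gcs):
        return "alert"
    if gcs >= 15:
        return "alert"
    if gcs >= 9:
        return "voice"
    if gcs >= 4:
        return "pain"
    return "unresponsive"


def mews(
    sbp: float, hr: float, rr: float, temp: float, gcs: float, table: dict | None = None
) -> int:
    """Modified Early Warning Score: five banded components, 0-14."""
    t = (table or default_tables())["mews"]
    pts = {
        "sys_bp": _lookup_band(sbp, t["sys_bp"]),
        "heart_rate": _lookup_band(hr, t["heart_rate"]),
        "resp_rate": _lookup_band(rr, t["resp_rate"]),
        "temperature": _lookup_band(temp, t["temperature"]),
        "avpu": int(t["avpu"][avpu_from_gcs(gcs)]),
    }
    return sum(pts.values())


def score_at_hour(
    timeline: StayTimeline, name: str, hour: int, table: dict | None = None
) -> int:
    """Evaluate qSOFA, SIRS or MEWS on the imputed timeline at one hour."""
    v = timeline.values
    get = lambda ch: float(v[ch][hour])
    if name == "qsofa":
        return qsofa(get("resp_rate"), get("sys_bp"), get("gcs"), table)
    if name == "sirs":
        return sirs(get("temperature"), get("heart_rate"), get("resp_rate"),
                    get("paco2"), get("wbc"), table)
    if name == "mews":
        return mews(get("sys_bp"), get("heart_rate"), get("resp_rate"),
                    get("temperature"), get("gcs"), table)
    raise ValueError(f"unknown hourly score {name!r}")


def saps2_at_admission(
    timeline: StayTimeline,
    age_years: float | None = None,
    admission_window_h: int = 24,
    chronic_points: int = 0,
    admission_type_points: int = 0,
    table: dict | None = None,
) -> int:
    """SAPS II from worst values within the admission window.

    "Worst" means the value attracting the most points among the hourly
    imputed values of the first ``admission_window_h`` hours.  Variables
    that were never measured contribute 0 points; chronic-disease and
    admission-type points default to 0 unless supplied.
    """
    t = (table or default_tables())["saps2"]
    age = timeline.age_years if age_years is None else age_years
    end = min(admission_window_h, timeline.n_hours)

    def worst(channel: str, key: str) -> int:
        if not timeline.has_channel(channel):
            return 0
        vals = timeline.values[channel][:end]
        return max(_lookup_band(float(x), t[key]) for x in vals)

    pts = {
        "age": _lookup_band(age, t["age"]),
        "heart_rate": worst("heart_rate", "heart_rate"),
        "sys_bp": worst("sys_bp", "sys_bp"),
        "temperature": worst("temperature", "temperature"),
        "gcs": worst("gcs", "gcs"),
        "wbc": worst("wbc", "wbc"),
        "bilirubin": worst("bilirubin", "bilirubin"),
        "chronic": chronic_points,
        "admission_type": admission_type_points,
    }
    if timeline.has_channel("urine_output"):
        daily_l = float(np.nansum(timeline.values["urine_output"][:end])) * 24.0 / end / 1000.0
        pts["urine_output"] = _lookup_band(daily_l, t["urine_output_l_per_day"])
    return sum(pts.values())


def sofa_at_admission(timeline: StayTimeline, config: SofaConfig | None = None) -> int:
    """Total SOFA at the first hourly bin of the imputed timeline."""
    return int(hourly_sofa(timeline, config)["total"].iloc[0])
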