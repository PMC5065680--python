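"""Retrospective Sepsis-3 gold standard and study inclusion filters.

Sepsis-3 defines sepsis as life-threatening organ dysfunction caused by a
dysregulated host response to infection, operationalised retrospectively
as:

* **suspicion of infection** — a culture draw and an antibiotic
  administration co-occurring within defined windows (antibiotics first:
  culture within 72 h; culture first: antibiotics within 24 h);
* **organ dysfunction** — an acute rise of the total SOFA score by >= 2
  points over its value at the start of a window reaching from 48 h
  before the suspicion time (limited by data availability) to 24 h after
  it (limited by ICU departure).  The first hour at which the rise is
  observed is the sepsis onset.

SOFA is computed hourly from the imputed timeline.  A subscore whose
inputs are absent scores 0 ("normal").  The respiration subscore is a
modified, ventilation-free variant driven by the SpO2/FiO2 ratio, with
room air (FiO2 = 0.21) assumed when FiO2 is not recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import DYNAMIC_PREDICTORS
from .timeline import StayRecord, StayTimeline


@dataclass
class SofaConfig:
    """Threshold tables for the hourly SOFA computation.

    ``spo2_fio2_thresholds`` maps the modified respiration subscore:
    ratio > first entry scores 0; each (upper bound, score) row applies
    for ratios <= bound, the highest matching score winning.
    """

    # (upper bound on SpO2/FiO2 ratio, subscore); evaluated from worst to best
    spo2_fio2_thresholds: tuple = ((150.0, 4), (235.0, 3), (315.0, 2), (400.0, 1))
    fio2_room_air: float = 0.21
    map_threshold: float = 70.0  # mm Hg, cardiovascular subscore 1 below this


ABX_TO_CULTURE_WINDOW_H = 72.0
CULTURE_TO_ABX_WINDOW_H = 24.0
SUSPICION_LOOKBACK_H = 48
SUSPICION_LOOKAHEAD_H = 24
SOFA_RISE = 2


@dataclass
class SepsisLabel:
    stay_id: object
    is_septic: bool
    suspicion_hour: int | None = None
    window_start_hour: int | None = None
    window_end_hour: int | None = None
    baseline_sofa: int | None = None
    onset_hour: int | None = None


def modified_respiration_subscore(
    spo2, fio2=None, config: SofaConfig | None = None
) -> np.ndarray:
    """Ventilation-free respiration subscore from the SpO2/FiO2 ratio.

    Vectorised; ``fio2`` defaults to room air where missing (NaN).
    Monotone non-increasing in the ratio.
    """
    config = config or SofaConfig()
    spo2 = np.asarray(spo2, float)
    if fio2 is None:
        fio2 = np.full_like(spo2, np.nan)
    fio2 = np.where(np.isnan(np.asarray(fio2, float)), config.fio2_room_air, fio2)
    ratio = spo2 / fio2
    if np.any(ratio[~np.isnan(ratio)] <= 0):
        raise ValueError("SpO2/FiO2 ratio must be positive")
    score = np.zeros_like(ratio)
    # tolerance absorbs float error at exact threshold ratios (e.g. 84/0.21)
    for bound, pts in sorted(config.spo2_fio2_thresholds, key=lambda t: -t[0]):
        score = np.where(ratio <= bound * (1 + 1e-12), pts, score)
    return np.where(np.isnan(ratio), 0, score).astype(int)


def _band(values: np.ndarray, rows: list[tuple[float, int]], default: int = 0) -> np.ndarray:
    """Score by descending thresholds: first (bound, pts) with value <= bound wins."""
    score = np.full(values.shape, default)
    for bound, pts in sorted(rows, key=lambda t: -t[0]):
        score = np.where(values <= bound, pts, score)
    return np.where(np.isnan(values), 0, score).astype(int)


def cns_subscore(gcs) -> np.ndarray:
    g = np.asarray(gcs, float)
    return _band(g, [(5.999, 4), (9.0, 3), (12.0, 2), (14.0, 1)])


def coagulation_subscore(platelets) -> np.ndarray:
    p = np.asarray(platelets, float)
    return _band(p, [(19.999, 4), (49.999, 3), (99.999, 2), (149.999, 1)])


def liver_subscore(bilirubin) -> np.ndarray:
    b = np.asarray(bilirubin, float)
    score = np.zeros_like(b)
    score = np.where(b >= 1.2, 1, score)
    score = np.where(b >= 2.0, 2, score)
    score = np.where(b >= 6.0, 3, score)
    score = np.where(b >= 12.0, 4, score)
    return np.where(np.isnan(b), 0, score).astype(int)


def renal_subscore(creatinine) -> np.ndarray:
    c = np.asarray(creatinine, float)
    score = np.zeros_like(c)
    score = np.where(c >= 1.2, 1, score)
    score = np.where(c >= 2.0, 2, score)
    score = np.where(c >= 3.5, 3, score)
    score = np.where(c >= 5.0, 4, score)
    return np.where(np.isnan(c), 0, score).astype(int)


def cardiovascular_subscore(map_mmhg, config: SofaConfig | None = None) -> np.ndarray:
    """MAP-based cardiovascular subscore (vasopressor dosing not carried)."""
    config = config or SofaConfig()
    m = np.asarray(map_mmhg, float)
    score = np.where(m < config.map_threshold, 1, 0)
    return np.where(np.isnan(m), 0, score).astype(int)


def hourly_sofa(timeline: StayTimeline, config: SofaConfig | None = None) -> pd.DataFrame:
    """Six SOFA subscores plus total, one row per hour of the stay.

    Absent inputs score 0.  MAP comes from the measured channel when
    present, otherwise from dias + pulse_pressure/3.
    """
    config = config or SofaConfig()
    v = timeline.values
    map_vals = v["map"]
    if np.isnan(map_vals).all():
        map_vals = v["dias_bp"] + v["pulse_pressure"] / 3.0

    df = pd.DataFrame(
        {
            "hour": np.arange(timeline.n_hours),
            "respiration": modified_respiration_subscore(v["spo2"], v["fio2"], config),
            "coagulation": coagulation_subscore(v["platelets"]),
            "liver": liver_subscore(v["bilirubin"]),
            "cardiovascular": cardiovascular_subscore(map_vals, config),
            "cns": cns_subscore(v["gcs"]),
            "renal": renal_subscore(v["creatinine"]),
        }
    )
    df["total"] = df[
        ["respiration", "coagulation", "liver", "cardiovascular", "cns", "renal"]
    ].sum(axis=1)
    return df


def find_suspicion_times(
    antibiotic_times_h: np.ndarray, culture_times_h: np.ndarray
) -> list[int]:
    """All qualifying suspicion hours, earliest first.

    A pair qualifies if the culture falls within 72 h after the
    antibiotic, or the antibiotic within 24 h after the culture; the
    suspicion time of a pair is its first event, floored to the hour bin.
    """
    abx = np.asarray(antibiotic_times_h, float)
    cult = np.asarray(culture_times_h, float)
    firsts: set[int] = set()
    for a in abx:
        if np.any((cult >= a) & (cult <= a + ABX_TO_CULTURE_WINDOW_H)):
            firsts.add(math.floor(a))
    for c in cult:
        if np.any((abx >= c) & (abx <= c + CULTURE_TO_ABX_WINDOW_H)):
            firsts.add(math.floor(c))
    return sorted(firsts)


def find_suspicion_hour(
    antibiotic_times_h: np.ndarray, culture_times_h: np.ndarray
) -> int | None:
    """Earliest qualifying suspicion hour, or None."""
    times = find_suspicion_times(antibiotic_times_h, culture_times_h)
    return times[0] if times else None


def detect_onset(
    sofa_totals: np.ndarray,
    suspicion_hour: int | None,
    data_start_hour: int = 0,
    icu_end_hour: int | None = None,
    stay_id: object = None,
) -> SepsisLabel:
    """Scan the suspicion window for an acute SOFA rise of >= 2 points.

    The window runs from up to 48 h before the suspicion hour (clamped to
    data availability) to 24 h after it (clamped to ICU departure); the
    baseline is the total at the window start and the onset is the first
    later hour in the window whose total is at least baseline + 2.
    """
    if suspicion_hour is None:
        return SepsisLabel(stay_id=stay_id, is_septic=False)
    totals = np.asarray(sofa_totals)
    if icu_end_hour is None:
        icu_end_hour = len(totals) - 1
    ws = max(suspicion_hour - SUSPICION_LOOKBACK_H, data_start_hour)
    ws = min(ws, icu_end_hour)
    we = min(suspicion_hour + SUSPICION_LOOKAHEAD_H, icu_end_hour)
    baseline = int(totals[ws])
    label = SepsisLabel(
        stay_id=stay_id,
        is_septic=False,
        suspicion_hour=suspicion_hour,
        window_start_hour=ws,
        window_end_hour=we,
        baseline_sofa=baseline,
    )
    for h in range(ws + 1, we + 1):
        if totals[h] >= baseline + SOFA_RISE:
            label.is_septic = True
            label.onset_hour = h
            break
    return label


def label_stay(
    stay: StayRecord,
    timeline: StayTimeline,
    sofa_config: SofaConfig | None = None,
    try_later_windows: bool = True,
) -> SepsisLabel:
    """Sepsis-3 label for one stay.

    Suspicion windows are evaluated in chronological order of suspicion
    time; the first window that yields an onset defines the label.  When
    ``try_later_windows`` is False only the earliest suspicion is tried.
    """
    totals = hourly_sofa(timeline, sofa_config)["total"].to_numpy()
    candidates = find_suspicion_times(stay.antibiotic_times_h, stay.culture_times_h)
    if not try_later_windows:
        candidates = candidates[:1]
    first_label = None
    for susp in candidates:
        label = detect_onset(totals, susp, 0, timeline.n_hours - 1, stay_id=stay.stay_id)
        if first_label is None:
            first_label = label
        if label.is_septic:
            return label
    return first_label or SepsisLabel(stay_id=stay.stay_id, is_septic=False)


def labels_to_frame(labels: dict[object, SepsisLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stay_id": lab.stay_id,
                "is_septic": lab.is_septic,
                "suspicion_hour": lab.suspicion_hour,
                "onset_hour": lab.onset_hour,
                "baseline_sofa": lab.baseline_sofa,
                "window_start_hour": lab.window_start_hour,
                "window_end_hour": lab.window_end_hour,
            }
            for lab in labels.values()
        ]
    )


ONSET_MIN_HOUR = 7
ONSET_MAX_HOUR = 500
MIN_AGE_YEARS = 15


def apply_inclusion_criteria(
    stays: dict[object, StayRecord],
    timelines: dict[object, StayTimeline],
    labels: dict[object, SepsisLabel],
    exclude_pre_icu_abx: bool = False,
) -> tuple[list[object], pd.DataFrame]:
    """Sequential study inclusion filters with per-filter exclusion counts.

    In order: age < 15; no ICU measurements; any of the 8 predictor
    measurements never recorded; septic with onset earlier than 7 h or
    later than 500 h into the stay; optionally, any antibiotic
    administration before ICU start.  Labels must have been computed on
    the full (non-thinned) data before filtering.
    """
    filters = [
        ("age < 15 years", lambda sid: stays[sid].age_years < MIN_AGE_YEARS),
        ("no measurements recorded", lambda sid: len(stays[sid].observations) == 0),
        (
            "predictor measurement never recorded",
            lambda sid: sid not in timelines
            or any(not timelines[sid].observed[ch].any() for ch in DYNAMIC_PREDICTORS),
        ),
        (
            "septic onset outside [7, 500] hours",
            lambda sid: labels[sid].is_septic
            and not (ONSET_MIN_HOUR <= labels[sid].onset_hour <= ONSET_MAX_HOUR),
        ),
    ]
    if exclude_pre_icu_abx:
        filters.append(
            (
                "antibiotics before ICU start",
                lambda sid: len(stays[sid].antibiotic_times_h) > 0
                and stays[sid].antibiotic_times_h[0] < 0,
            )
        )

    remaining = list(stays.keys())
    report = []
    for name, pred in filters:
        excluded = [sid for sid in remaining if pred(sid)]
        remaining = [sid for sid in remaining if sid not in set(excluded)]
        report.append({"filter": name, "excluded": len(excluded), "remaining": len(remaining)})
    return remaining, pd.DataFrame(report)
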