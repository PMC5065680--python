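"""Convenience composition of the pipeline stages over whole cohorts."""

from __future__ import annotations

import pandas as pd

from .io import Cohort
from .labels import (
    SepsisLabel,
    SofaConfig,
    apply_inclusion_criteria,
    label_stay,
)
from .timeline import EmptyStayError, StayTimeline, TimelineConfig, build_stay_timeline


def build_timelines(
    cohort: Cohort, config: TimelineConfig | None = None
) -> dict[object, StayTimeline]:
    """Hourly timelines for every stay that has any extended-vital data.

    Stays with no usable observations are omitted (the inclusion filters
    exclude them downstream).
    """
    timelines: dict[object, StayTimeline] = {}
    for sid, stay in cohort.stays.items():
        try:
            timelines[sid] = build_stay_timeline(stay, config)
        except EmptyStayError:
            continue
    return timelines


def label_cohort(
    cohort: Cohort,
    timelines: dict[object, StayTimeline],
    sofa_config: SofaConfig | None = None,
    try_later_windows: bool = True,
) -> dict[object, SepsisLabel]:
    """Sepsis-3 labels for every stay; stays without a timeline are nonseptic."""
    labels: dict[object, SepsisLabel] = {}
    for sid, stay in cohort.stays.items():
        if sid in timelines:
            labels[sid] = label_stay(stay, timelines[sid], sofa_config, try_later_windows)
        else:
            labels[sid] = SepsisLabel(stay_id=sid, is_septic=False)
    return labels


def prepare_cohort(
    cohort: Cohort,
    timeline_config: TimelineConfig | None = None,
    sofa_config: SofaConfig | None = None,
    exclude_pre_icu_abx: bool = False,
):
    """Timelines, labels and the included-stay list in one call.

    Returns (timelines, labels, included_ids, exclusion_report).
    """
    timelines = build_timelines(cohort, timeline_config)
    labels = label_cohort(cohort, timelines, sofa_config)
    included, report = apply_inclusion_criteria(
        cohort.stays, timelines, labels, exclude_pre_icu_abx=exclude_pre_icu_abx
    )
    return timelines, labels, included, report


def label_accuracy(labels: dict, truth: pd.DataFrame, tolerance_h: int = 1) -> dict:
    """Agreement between recovered labels and a designed-truth table.

    Returns the fraction of designed-septic stays labeled septic with
    onset within the tolerance, and the fraction of designed-nonseptic
    stays labeled nonseptic.
    """
    septic = truth[truth["designed_septic"]]
    nonseptic = truth[~truth["designed_septic"]]
    hits = 0
    for row in septic.itertuples(index=False):
        lab = labels[row.stay_id]
        if lab.is_septic and abs(lab.onset_hour - row.designed_onset_hour) <= tolerance_h:
            hits += 1
    correct_neg = sum(1 for row in nonseptic.itertuples(index=False)
                      if not labels[row.stay_id].is_septic)
    return {
        "septic_recovery": hits / len(septic) if len(septic) else float("nan"),
        "nonseptic_specificity": correct_neg / len(nonseptic) if len(nonseptic) else float("nan"),
        "n_septic": int(len(septic)),
        "n_nonseptic": int(len(nonseptic)),
    }
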