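"""Channel registry for ICU observation streams.

Channels are the named measurement types carried through the pipeline:
the "extended vitals" used by the predictor (bedside vitals plus SpO2 and
the Glasgow Coma Score), the raw blood-pressure sources they are resolved
from, and optional laboratory channels consumed only by the SOFA and
SAPS II scores.  Each channel has a plausibility range; raw observations
outside it are rejected at parse time.
"""

from __future__ import annotations

# Raw extended-vital channels as recorded at the bedside.  Invasive
# (arterial-line) and noninvasive blood pressure are separate sources and
# are resolved into single sys_bp / dias_bp series per hour downstream.
EXTENDED_VITALS: tuple[str, ...] = (
    "heart_rate",
    "resp_rate",
    "temperature",
    "spo2",
    "gcs",
    "sysabp",
    "diasabp",
    "nisysabp",
    "nidiasabp",
)

# Optional laboratory / derived channels (SOFA, SAPS II only; never features).
LAB_CHANNELS: tuple[str, ...] = (
    "platelets",      # 10^3 / uL
    "bilirubin",      # mg/dL
    "creatinine",     # mg/dL
    "map",            # mm Hg, measured mean arterial pressure
    "fio2",           # fraction of inspired oxygen, 0.21-1.0
    "wbc",            # 10^3 / uL
    "paco2",          # mm Hg
    "urine_output",   # mL/h
)

ALL_CHANNELS: tuple[str, ...] = EXTENDED_VITALS + LAB_CHANNELS

# Source-resolved channels derived inside a timeline.
DERIVED_CHANNELS: tuple[str, ...] = ("sys_bp", "dias_bp", "pulse_pressure")

# The 7 dynamic predictor channels (two-hour window, deltas) and the full
# 8-variable predictor set including age as a static covariate.
DYNAMIC_PREDICTORS: tuple[str, ...] = (
    "sys_bp",
    "pulse_pressure",
    "heart_rate",
    "resp_rate",
    "temperature",
    "spo2",
    "gcs",
)
PREDICTORS: tuple[str, ...] = DYNAMIC_PREDICTORS + ("age",)

# Plausibility ranges (inclusive); observations outside are rejected and
# counted.  Values are in the channel units listed above; temperature is
# stored in degrees Celsius.
PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "heart_rate": (10.0, 300.0),
    "resp_rate": (0.0, 80.0),
    "temperature": (25.0, 45.0),
    "spo2": (10.0, 100.0),
    "gcs": (3.0, 15.0),
    "sysabp": (20.0, 300.0),
    "diasabp": (5.0, 225.0),
    "nisysabp": (20.0, 300.0),
    "nidiasabp": (5.0, 225.0),
    "platelets": (0.0, 2000.0),
    "bilirubin": (0.0, 80.0),
    "creatinine": (0.0, 40.0),
    "map": (10.0, 250.0),
    "fio2": (0.21, 1.0),
    "wbc": (0.0, 300.0),
    "paco2": (5.0, 200.0),
    "urine_output": (0.0, 5000.0),
}


def is_extended_vital(channel: str) -> bool:
    return channel in EXTENDED_VITALS


def validate_channel(channel: str) -> None:
    if channel not in ALL_CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
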