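# Published banding tables for the comparator severity scores.
# Bands are [lo, hi) half-open intervals on the input value; the first
# matching band wins.  null means unbounded.  All thresholds can be
# overridden by passing a modified table to the scoring functions.

qsofa:
  resp_rate_above: 22      # breaths/min, strictly above scores 1
  sysbp_below: 100         # mm Hg, strictly below scores 1
  gcs_below: 15            # altered mentation proxy: GCS < 15 scores 1
  positive_at: 2

sirs:
  temp_high: 38.0          # deg C, strictly above
  temp_low: 36.0           # deg C, strictly below
  heart_rate_above: 90     # beats/min, strictly above
  resp_rate_above: 20      # breaths/min, strictly above
  paco2_below: 32          # mm Hg, strictly below
  wbc_high: 12.0           # 10^3/uL, strictly above
  wbc_low: 4.0             # 10^3/uL, strictly below

mews:
  sys_bp:
    - {lo: null, hi: 71, points: 3}
    - {lo: 71, hi: 81, points: 2}
    - {lo: 81, hi: 101, points: 1}
    - {lo: 101, hi: 200, points: 0}
    - {lo: 200, hi: null, points: 2}
  heart_rate:
    - {lo: null, hi: 41, points: 2}
    - {lo: 41, hi: 51, points: 1}
    - {lo: 51, hi: 101, points: 0}
    - {lo: 101, hi: 111, points: 1}
    - {lo: 111, hi: 130, points: 2}
    - {lo: 130, hi: null, points: 3}
  resp_rate:
    - {lo: null, hi: 9, points: 2}
    - {lo: 9, hi: 15, points: 0}
    - {lo: 15, hi: 21, points: 1}
    - {lo: 21, hi: 30, points: 2}
    - {lo: 30, hi: null, points: 3}
  temperature:
    - {lo: null, hi: 35.0, points: 2}
    - {lo: 35.0, hi: 38.5, points: 0}
    - {lo: 38.5, hi: null, points: 2}
  avpu:                    # derived from GCS: 15 Alert; 9-14 Voice; 4-8 Pain; 3 Unresponsive
    alert: 0
    voice: 1
    pain: 2
    unresponsive: 3

saps2:
  age:
    - {lo: null, hi: 40, points: 0}
    - {lo: 40, hi: 60, points: 7}
    - {lo: 60, hi: 70, points: 12}
    - {lo: 70, hi: 75, points: 15}
    - {lo: 75, hi: 80, points: 16}
    - {lo: 80, hi: null, points: 18}
  heart_rate:              # worst = highest points in window
    - {lo: null, hi: 40, points: 11}
    - {lo: 40, hi: 70, points: 2}
    - {lo: 70, hi: 120, points: 0}
    - {lo: 120, hi: 160, points: 4}
    - {lo: 160, hi: null, points: 7}
  sys_bp:
    - {lo: null, hi: 70, points: 13}
    - {lo: 70, hi: 100, points: 5}
    - {lo: 100, hi: 200, points: 0}
    - {lo: 200, hi: null, points: 2}
  temperature:
    - {lo: null, hi: 39.0, points: 0}
    - {lo: 39.0, hi: null, points: 3}
  gcs:
    - {lo: null, hi: 6, points: 26}
    - {lo: 6, hi: 9, points: 13}
    - {lo: 9, hi: 11, points: 7}
    - {lo: 11, hi: 14, points: 5}
    - {lo: 14, hi: null, points: 0}
  wbc:
    - {lo: null, hi: 1.0, points: 12}
    - {lo: 1.0, hi: 20.0, points: 0}
    - {lo: 20.0, hi: null, points: 3}
  bilirubin:
    - {lo: null, hi: 4.0, points: 0}
    - {lo: 4.0, hi: 6.0, points: 4}
    - {lo: 6.0, hi: null, points: 9}
  urine_output_l_per_day:
    - {lo: null, hi: 0.5, points: 11}
    - {lo: 0.5, hi: 1.0, points: 4}
    - {lo: 1.0, hi: null, points: 0}
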