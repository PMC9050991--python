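"""The seven retrospective clinical cases used for model evaluation.

Each case records the active-electrode length, the two reported durations
(total time above 60 °C and time at the 90 °C target), the three ablation
diameters measured by the radiologist on post-procedure MR images, and the
corresponding diameters measured on the simulated damage field.  Diameters
follow the clinical convention: "longest" along the electrode axis,
"shortest" and "other" orthogonal to it.
"""

from __future__ import annotations

import pandas as pd

_CASES = [
    # case, electrode_cm, t>60 (min), t@90 (min),
    #   radiological (short, other, long), simulated (short, other, long)
    (1, 2, 12, 10, 26, 40, 42, 36, 39, 41),
    (2, 3, 10, 8, 41, 52, 63, 42, 42, 54),
    (3, 3, 10, 6, 28, 39, 48, 36, 36, 48),
    (4, 2, 10, 9, 40, 42, 43, 39, 40, 43),
    (5, 2, 9, 9, 43, 48, 51, 42, 42, 45),
    (6, 3, 10, 8, 37, 34, 46, 45, 38, 41),
    (7, 2, 10, 9, 24, 30, 30, 27, 29, 37),
]

COLUMNS = [
    "case",
    "electrode_length_cm",
    "time_over_60_min",
    "time_at_90_min",
    "radiological_shortest_mm",
    "radiological_other_mm",
    "radiological_longest_mm",
    "simulated_shortest_mm",
    "simulated_other_mm",
    "simulated_longest_mm",
]


def clinical_cases() -> pd.DataFrame:
    """The evaluation cohort as a DataFrame (one row per case)."""
    return pd.DataFrame(_CASES, columns=COLUMNS)
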