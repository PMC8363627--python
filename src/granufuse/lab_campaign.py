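"""Bundled lab-scale granulation campaign used in the worked example.

Fourteen high-shear wet granulation runs on a 1 L / 2 L lab granulator
(bowl radii 0.070 m and 0.087 m): seven model-improvement runs and seven
external-validation runs on MCC/lactose/HPMC binary and ternary blends.
Two runs (7 and 14) over-saturated (S'max above 100%) and produced slurry
instead of granules.

The validation table carries both the observed median granule size
(``y_obs_um``) and the fused model's recorded prediction (``y_pred_um``),
so the external-validation arithmetic (RMSEP, accuracies, stratified
errors) can be recomputed from this module alone.

``fr_reported`` / ``smax_reported`` are the values tabulated with the
campaign; ``impeller_rpm`` and ``radius_m`` are the raw inputs from which
the Froude number is recomputed.
"""

from __future__ import annotations

import pandas as pd

_CAL_COLUMNS = ["run", "scale_L", "radius_m", "component_1", "frac1_pct",
                "component_2", "frac2_pct", "ls", "impeller_rpm",
                "fr_reported", "smax_reported", "g50_um", "failed"]

#: Seven model-improvement runs (run 7 failed: slurry at S'max 154.2%).
CALIBRATION_RUNS = pd.DataFrame([
    (1, 1, 0.070, "MCC PH101", 64, "Lactose 110M", 36,
     0.858, 1030, 4.212, 75.5, 1400.0, False),
    (2, 1, 0.070, "MCC PH101", 81, "Lactose 200M", 19,
     0.999, 1149, 5.239, 82.7, 1394.0, False),
    (3, 1, 0.070, "MCC PH101", 95, "Lactose 110M", 5,
     1.333, 895, 3.178, 92.2, 2017.0, False),
    (4, 1, 0.070, "MCC PH101", 38, "Lactose 200M", 62,
     0.315, 496, 0.975, 41.3, 205.0, False),
    (5, 1, 0.070, "HPMC E15LV", 62, "Anhydrous lactose", 38,
     0.158, 770, 2.352, 19.1, 142.0, False),
    (6, 2, 0.087, "MCC PH101", 81, "Granulac 200", 19,
     0.999, 810, 3.239, 82.4, 1054.0, False),
    (7, 1, 0.070, "MCC PH101", 13, "Lactose 110M", 87,
     1.209, 626, 1.557, 154.2, None, True),
], columns=_CAL_COLUMNS)

_VAL_COLUMNS = ["run", "scale_L", "radius_m", "component_1", "frac1_pct",
                "component_2", "frac2_pct", "ls", "impeller_rpm",
                "fr_reported", "smax_reported", "y_obs_um", "y_pred_um",
                "failed"]

#: Seven external-validation runs (run 14 failed: slurry at S'max 107.1%).
#: Run 12 is the ternary robustness check: component 1 is itself a
#: 74.3 : 25.7 MCC PH101 / HPMC E15LV premix.
VALIDATION_RUNS = pd.DataFrame([
    (8, 2, 0.087, "MCC PH101", 64, "Granulac 200", 36,
     0.396, 587, 1.70, 39.3, 424.0, 458.0, False),
    (9, 1, 0.070, "MCC PH101", 81, "Lactose 200M", 19,
     0.862, 852, 2.878, 71.4, 1088.0, 774.0, False),
    (10, 1, 0.070, "MCC PH101", 95, "Lactose 110M", 5,
     0.882, 812, 2.619, 61.0, 978.0, 798.0, False),
    (11, 1, 0.070, "HPMC E15LV", 62, "Anhydrous lactose", 38,
     0.296, 655, 1.70, 35.8, 207.0, 198.0, False),
    (12, 1, 0.070, "MCC PH101/HPMC E15LV 74.3:25.7", 70,
     "Anhydrous lactose", 30,
     0.299, 1149, 5.239, 30.6, 194.0, 158.0, False),
    (13, 2, 0.087, "MCC PH101", 64, "Granulac 200", 36,
     0.658, 670, 2.212, 65.2, 641.0, 632.0, False),
    (14, 2, 0.087, "MCC PH101", 38, "Lactose 200M", 62,
     0.816, 1200, 7.001, 107.1, None, None, True),
], columns=_VAL_COLUMNS)

#: L/S threshold separating the high- and low-liquid validation strata.
LS_STRATUM_THRESHOLD = 0.5
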