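"""Bundled reference tables.

The published method-comparison table: landmark RMSE of the template
morphing baseline versus the parametric landmark prediction, for twelve
internal landmarks at the four half-turn angles of the first one and a
half turns, as printed in the original validation study.  The final-row
p-values of that table (paired two-tailed t-test across the twelve
landmark pairs per turn) are the quantitative anchor the statistics
module is validated against.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "method_comparison_rmse",
    "PUBLISHED_TTEST_P",
]

_LANDMARKS = ["a", "b", "c", "d", "e", "f", "h", "i", "k", "l", "o", "p"]

_MORPH = {
    0: [2.85, 4.55, 15.17, 8.60, 6.91, 7.11, 11.81, 11.19, 4.71, 10.49, 6.20, 6.65],
    180: [4.35, 11.61, 7.93, 5.19, 5.57, 4.37, 14.97, 14.55, 11.30, 11.15, 16.39, 17.25],
    360: [3.95, 17.23, 13.45, 16.73, 10.65, 7.80, 18.75, 18.00, 11.89, 17.53, 8.29, 12.69],
    540: [6.78, 8.43, 22.94, 9.89, 10.98, 8.23, 16.47, 15.89, 23.65, 18.21, 11.06, 9.99],
}

_PREDICTION = {
    0: [0.97, 5.89, 1.57, 9.87, 10.16, 2.78, 9.99, 7.52, 5.76, 9.85, 10.16, 6.55],
    180: [3.65, 8.43, 2.55, 4.83, 6.91, 3.76, 5.66, 5.41, 6.55, 6.98, 6.91, 21.18],
    360: [2.09, 18.90, 8.91, 9.84, 6.07, 7.67, 8.51, 8.70, 6.81, 9.47, 6.07, 9.18],
    540: [2.25, 9.34, 4.30, 7.17, 3.80, 3.72, 8.81, 9.70, 4.59, 11.68, 3.80, 14.73],
}

#: Printed per-turn t-test p-values of the reference comparison.
PUBLISHED_TTEST_P = {0: 0.3656, 180: 0.0188, 360: 0.0012, 540: 0.0067}


def method_comparison_rmse() -> pd.DataFrame:
    """The reference RMSE comparison as a long table.

    Columns: method ("template_morphing" | "landmark_prediction"),
    turn_deg, landmark, rmse — the dialect
    :func:`cochleagen.stats.compare_methods` consumes.
    """
    rows = []
    for method, data in (
        ("template_morphing", _MORPH),
        ("landmark_prediction", _PREDICTION),
    ):
        for turn, values in data.items():
            for lname, r in zip(_LANDMARKS, values):
                rows.append(
                    {"method": method, "turn_deg": float(turn),
                     "landmark": lname, "rmse": r}
                )
    return pd.DataFrame(rows)
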