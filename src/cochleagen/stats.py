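"""Validation statistics for landmark-prediction methods.

Implements the landmark RMSE in its published product form

    RMSE = sqrt( sum |(x_m - x_p) * (y_m - y_p)| / n )

(m = measured, p = predicted), the per-turn paired two-tailed t-test used
to compare two prediction methods across landmarks, a generic two-way
ANOVA (Type II sums of squares on unbalanced layouts), and the aggregated
method-comparison report.

Note the product form is insensitive to error confined to a single axis:
if either coordinate matches exactly the pair contributes nothing.  That
is a property of the published formula, implemented verbatim; a
conventional Euclidean mode is available behind ``mode="euclidean"`` but
is never the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LandmarkComparison",
    "landmark_rmse",
    "paired_t_test",
    "two_way_anova",
    "compare_methods",
    "rmse_table",
]

VALIDATION_TURNS = (0.0, 180.0, 360.0, 540.0)


@dataclass(frozen=True)
class LandmarkComparison:
    """Matched measured/predicted points for a set of landmarks."""

    measured: dict[str, np.ndarray]
    predicted: dict[str, np.ndarray]

    def pairs(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        names = sorted(set(self.measured) & set(self.predicted))
        return [
            (n, np.asarray(self.measured[n], float), np.asarray(self.predicted[n], float))
            for n in names
        ]


def landmark_rmse(pairs, mode: str = "product") -> float:
    """Landmark RMSE over matched (measured, predicted) point pairs.

    ``pairs`` is an iterable of (measured, predicted) 2D points, or a
    :class:`LandmarkComparison`.  ``mode="product"`` (default) is the
    published form sqrt(sum |dx*dy| / n); ``mode="euclidean"`` is
    sqrt(sum (dx^2 + dy^2) / n).
    """
    if isinstance(pairs, LandmarkComparison):
        pairs = [(m, p) for _, m, p in pairs.pairs()]
    pairs = list(pairs)
    if not pairs:
        raise ValueError("landmark_rmse needs at least one pair")
    m = np.array([np.asarray(a, float) for a, _ in pairs])
    p = np.array([np.asarray(b, float) for _, b in pairs])
    d = m - p
    if mode == "product":
        return float(np.sqrt(np.sum(np.abs(d[:, 0] * d[:, 1])) / len(pairs)))
    if mode == "euclidean":
        return float(np.sqrt(np.sum(d**2) / len(pairs)))
    raise ValueError(f"unknown rmse mode {mode!r}")


def paired_t_test(a, b, paired: bool = True) -> tuple[float, float]:
    """Two-tailed t-test comparing two matched sets of values.

    Default is the paired test on the differences a - b with n - 1
    degrees of freedom; identical inputs return (0, 1) by convention.
    ``paired=False`` gives the two-sample (pooled-variance) test.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired t-test needs equal-length samples")
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need at least two value pairs")
    if paired:
        d = a - b
        if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
            return 0.0, 1.0
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def two_way_anova(values, factor_a, factor_b) -> dict[str, float]:
    """Two-way ANOVA p-values for two crossed factors and the interaction.

    Uses Type II sums of squares so unbalanced layouts are handled;
    the interaction term is dropped automatically when the layout has no
    replication.  Returns {"factor_a": p, "factor_b": p, "interaction": p}
    (interaction NaN when not estimable).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, float),
            "A": pd.Categorical(factor_a),
            "B": pd.Categorical(factor_b),
        }
    )
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    n_cells = df.groupby(["A", "B"], observed=True).size()
    replicated = (n_cells > 1).any() and len(n_cells) < len(df)
    formula = "y ~ A + B + A:B" if replicated else "y ~ A + B"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {
        "factor_a": float(table.loc["A", "PR(>F)"]),
        "factor_b": float(table.loc["B", "PR(>F)"]),
        "interaction": float(table.loc["A:B", "PR(>F)"]) if replicated else math.nan,
    }
    return out


def rmse_table(
    measured: Mapping[float, Mapping[str, np.ndarray]],
    predicted_by_method: Mapping[str, Mapping[float, Mapping[str, np.ndarray]]],
    mode: str = "product",
) -> pd.DataFrame:
    """Per-method, per-turn, per-landmark RMSE table.

    ``measured`` maps turn angle -> landmark -> point(s); a landmark entry
    may be a single 2D point or an (n_sections, 2) stack, in which case
    the RMSE pools the sections.  Each method in ``predicted_by_method``
    has the same nesting.  Landmarks missing from a method at a turn are
    reported as NaN and excluded pairwise downstream.
    Returns a long DataFrame (method, turn_deg, landmark, rmse).
    """
    rows = []
    for method, per_turn in predicted_by_method.items():
        for turn, meas in measured.items():
            pred = per_turn.get(turn, {})
            for lname, mpt in meas.items():
                if lname in pred:
                    m = np.atleast_2d(np.asarray(mpt, float))
                    p = np.atleast_2d(np.asarray(pred[lname], float))
                    if m.shape != p.shape:
                        raise ValueError(
                            f"landmark {lname!r} at turn {turn}: section "
                            "counts differ between measured and predicted"
                        )
                    r = landmark_rmse(list(zip(m, p)), mode=mode)
                else:
                    r = math.nan
                rows.append(
                    {"method": method, "turn_deg": float(turn),
                     "landmark": lname, "rmse": r}
                )
    return pd.DataFrame(rows)


def compare_methods(table: pd.DataFrame, reference: str, candidate: str):
    """Per-turn paired t-tests between two methods' RMSE columns.

    ``table`` is the long RMSE table from :func:`rmse_table` (or the same
    dialect read from CSV).  For every turn the two methods' per-landmark
    RMSE values are paired by landmark name (missing landmarks dropped
    pairwise) and compared with the paired two-tailed t-test.  Returns a
    DataFrame (turn_deg, n_landmarks, t, p) plus, as ``.attrs["anova"]``,
    per-landmark two-way ANOVA p-values (method x turn) when both factors
    have enough levels.
    """
    need = {"method", "turn_deg", "landmark", "rmse"}
    if not need.issubset(table.columns):
        raise ValueError(f"RMSE table needs columns {sorted(need)}")
    rows = []
    for turn, grp in table.groupby("turn_deg"):
        wide = grp.pivot_table(index="landmark", columns="method", values="rmse")
        if reference not in wide or candidate not in wide:
            raise KeyError(f"methods {reference!r}/{candidate!r} not both present")
        wide = wide[[reference, candidate]].dropna()
        if len(wide) < 2:
            continue
        t, p = paired_t_test(wide[reference].values, wide[candidate].values)
        rows.append(
            {"turn_deg": float(turn), "n_landmarks": int(len(wide)),
             "t": t, "p": p}
        )
    out = pd.DataFrame(rows).sort_values("turn_deg").reset_index(drop=True)

    anova = {}
    sub = table[table["method"].isin([reference, candidate])].dropna(subset=["rmse"])
    for lname, grp in sub.groupby("landmark"):
        if grp["method"].nunique() == 2 and grp["turn_deg"].nunique() >= 2:
            try:
                res = two_way_anova(grp["rmse"], grp["method"], grp["turn_deg"])
                anova[lname] = res["factor_a"]
            except (ValueError, KeyError):
                continue
    out.attrs["anova"] = anova
    return out
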