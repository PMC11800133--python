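"""Tidy cohort-level result tables.

Three shapes cover the study battery: a two-group demographic/imaging
comparison (patients vs controls), an outcome-split comparison within
patients (favorable vs poor 90-day modified Rankin Scale), and the
multivariable logistic model for favorable outcome with the ALPS odds
ratio reported per 0.1 increase. Continuous rows use the pooled Student's
t-test; binary rows use a 2x2 test (Fisher exact when any expected cell
is below 5, else Pearson chi-square).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as st

__all__ = [
    "group_comparison_table",
    "outcome_comparison_table",
    "outcome_logistic_table",
    "alps_correlation_table",
    "FAVORABLE_MRS_MAX",
]

FAVORABLE_MRS_MAX = 2

BINARY_VARS = ["female", "hypertension", "diabetes", "hyperlipemia", "smoking"]


def _binary_row(name: str, x1: pd.Series, x0: pd.Series) -> dict:
    a, b = int((x1 == 1).sum()), int((x1 == 0).sum())
    c, d = int((x0 == 1).sum()), int((x0 == 0).sum())
    res = st.categorical_2x2(a, b, c, d)
    return {
        "variable": name, "kind": "binary",
        "group1_summary": f"{a} ({100 * a / max(a + b, 1):.1f}%)",
        "group0_summary": f"{c} ({100 * c / max(c + d, 1):.1f}%)",
        "statistic": res.statistic, "p": res.p, "method": res.method,
    }


def _continuous_row(name: str, x1: pd.Series, x0: pd.Series) -> dict:
    x1 = x1.dropna().to_numpy(dtype=float)
    x0 = x0.dropna().to_numpy(dtype=float)
    res = st.ttest_two_sample(x1, x0)
    return {
        "variable": name, "kind": "continuous",
        "group1_summary": f"{x1.mean():.2f} +/- {x1.std(ddof=1):.2f}",
        "group0_summary": f"{x0.mean():.2f} +/- {x0.std(ddof=1):.2f}",
        "statistic": res.statistic, "p": res.p, "method": res.method,
    }


def group_comparison_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Patients vs healthy controls: demographics and ALPS indices.

    Patient ipsilateral and contralateral indices are each compared against
    the controls' per-subject average index (controls have no lesion side).
    """
    sich = cohort[cohort["group"] == "sICH"]
    hc = cohort[cohort["group"] == "HC"]
    rows = [_continuous_row("age", sich["age"], hc["age"])]
    rows += [_binary_row(v, sich[v], hc[v]) for v in BINARY_VARS]
    for col in ("ipsilateral_alps", "contralateral_alps"):
        rows.append(_continuous_row(col, sich[col], hc["average_alps"]))
    rows.append(_continuous_row("average_alps", sich["average_alps"], hc["average_alps"]))
    return pd.DataFrame(rows)


def outcome_comparison_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Favorable (mRS <= 2) vs poor outcome within the patient group."""
    sich = cohort[cohort["group"] == "sICH"].copy()
    fav = sich["mrs_90d"] <= FAVORABLE_MRS_MAX
    g1, g0 = sich[fav], sich[~fav]
    rows = [_continuous_row("age", g1["age"], g0["age"])]
    rows += [_binary_row(v, g1[v], g0[v]) for v in BINARY_VARS]
    for col in ("baseline_nihss", "hemorrhage_ml", "edema_ml", "relative_edema_ratio",
                "ipsilateral_alps", "contralateral_alps", "average_alps"):
        rows.append(_continuous_row(col, g1[col], g0[col]))
    return pd.DataFrame(rows)


def outcome_logistic_table(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...] = (
        "age", "female", "baseline_nihss", "hemorrhage_ml", "ipsilateral_alps",
    ),
) -> pd.DataFrame:
    """Multivariable logistic model for favorable outcome.

    Fit on supratentorial patients (the only ones with a defined
    ipsilateral index when it is among the predictors). The ALPS odds
    ratio is additionally reported per 0.1 increase.
    """
    sich = cohort[cohort["group"] == "sICH"].copy()
    cols = list(predictors)
    data = sich[cols + ["mrs_90d"]].dropna()
    y = (data["mrs_90d"] <= FAVORABLE_MRS_MAX).astype(int)
    rescale = {"ipsilateral_alps": 0.1} if "ipsilateral_alps" in cols else None
    fit = st.logistic_fit(data[cols], y, rescale=rescale)
    out = fit.or_ci.copy()
    out["p"] = fit.pvalues
    out.index.name = "predictor"
    out = out.reset_index()
    for name, (orr, lo, hi) in fit.rescaled_or.items():
        sel = out["predictor"] == name
        out.loc[sel, ["OR", "ci_low", "ci_high"]] = (orr, lo, hi)
        out.loc[sel, "predictor"] = f"{name}_per_0.1"
    return out[out["predictor"] != "const"].reset_index(drop=True)


def alps_correlation_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Correlations of the lesion-side ALPS index with lesion severity."""
    sich = cohort[cohort["group"] == "sICH"]
    rows = []
    for alps_col in ("ipsilateral_alps", "contralateral_alps", "average_alps"):
        for target in ("hemorrhage_ml", "edema_ml", "relative_edema_ratio"):
            sub = sich[[alps_col, target]].dropna()
            res = st.correlation(sub[alps_col], sub[target], method="pearson")
            rows.append({"alps": alps_col, "against": target, "r": res.r,
                         "n": res.n, "p": res.p})
    return pd.DataFrame(rows)
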