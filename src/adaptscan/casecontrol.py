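"""Covariate-adjusted single-case versus control-sample comparisons.

Each patient score is compared against the control sample by regressing the
control scores on the covariate (age by default), predicting the patient's
expected score at their own covariate value, and testing the standardised
prediction error with a t statistic on n − 2 degrees of freedom:

    t = (y_case − ŷ) / ( s · sqrt(1 + 1/n + (x_case − x̄)² / SS_x) )

where s² is the residual variance of the control regression.  This treats
the patient as a new draw from the control population under the null, so
the test keeps its nominal size at any control sample size.  Without a
covariate the test reduces to the classic single-case t with df = n − 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats.inference import bh_adjust

__all__ = ["CaseControlResult", "crawford_covariate_test", "batch_case_control"]


@dataclass(frozen=True)
class CaseControlResult:
    case_id: str
    measure: str
    case_value: float
    predicted: float
    t: float
    df: int
    p: float
    direction: str  # "below" or "above" the control prediction
    n_controls: int
    effect_z: float  # (case − predicted) / residual sd, a case-level effect size


def crawford_covariate_test(
    case_value: float,
    case_covariate: float | None,
    control_values: Sequence[float],
    control_covariates: Sequence[float] | None = None,
    case_id: str = "",
    measure: str = "",
    alternative: str = "two-sided",
) -> CaseControlResult:
    """Single-case t-test against controls, optionally covariate-adjusted."""
    y = np.asarray(control_values, dtype=float)
    n = y.size
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    if control_covariates is None or case_covariate is None:
        if n < 2:
            raise ValueError("need at least 2 controls")
        pred = float(y.mean())
        s = float(y.std(ddof=1))
        df = n - 1
        denom = s * np.sqrt(1.0 + 1.0 / n)
    else:
        x = np.asarray(control_covariates, dtype=float)
        if x.size != n:
            raise ValueError("control values and covariates must align")
        if n < 3:
            raise ValueError("need at least 3 controls for a covariate-adjusted test")
        xbar = x.mean()
        ssx = float(((x - xbar) ** 2).sum())
        if ssx <= 0:
            raise ValueError("control covariate has zero variance")
        slope = float(((x - xbar) * (y - y.mean())).sum() / ssx)
        intercept = float(y.mean() - slope * xbar)
        resid = y - (intercept + slope * x)
        df = n - 2
        s = float(np.sqrt((resid**2).sum() / df))
        pred = intercept + slope * float(case_covariate)
        denom = s * np.sqrt(1.0 + 1.0 / n + (float(case_covariate) - xbar) ** 2 / ssx)
    if s <= 0:
        raise ValueError("control residual variance is zero")
    t = (float(case_value) - pred) / denom
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        p = stats.t.sf(t, df)
    return CaseControlResult(
        case_id=case_id,
        measure=measure,
        case_value=float(case_value),
        predicted=pred,
        t=float(t),
        df=int(df),
        p=float(p),
        direction="below" if t < 0 else "above",
        n_controls=int(n),
        effect_z=float((float(case_value) - pred) / s),
    )


def batch_case_control(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    value_col: str = "value",
    covariate_col: str | None = "age",
    id_col: str = "participant_id",
    measure_cols: Sequence[str] = ("measure",),
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Run the single-case test for every case row against matching controls.

    Controls are matched on ``measure_cols`` (for example measure and
    category), and p-values are BH-corrected within each measure family.
    """
    rows = []
    keys = list(measure_cols)
    ctrl_groups = dict(tuple(controls.groupby(keys, dropna=False)))
    for _, case in cases.iterrows():
        key = tuple(case[k] for k in keys)
        key = key[0] if len(key) == 1 else key
        ctrl = ctrl_groups.get(key)
        if ctrl is None or ctrl.empty:
            continue
        ctrl = ctrl.dropna(
            subset=[value_col] + ([covariate_col] if covariate_col else [])
        )
        if not np.isfinite(case[value_col]):
            continue
        res = crawford_covariate_test(
            case_value=float(case[value_col]),
            case_covariate=(
                float(case[covariate_col]) if covariate_col else None
            ),
            control_values=ctrl[value_col].to_numpy(dtype=float),
            control_covariates=(
                ctrl[covariate_col].to_numpy(dtype=float) if covariate_col else None
            ),
            case_id=str(case[id_col]),
            measure=str(key),
            alternative=alternative,
        )
        row = {k: case[k] for k in keys}
        row.update(
            {
                "case_id": res.case_id,
                "case_value": res.case_value,
                "predicted": res.predicted,
                "t": res.t,
                "df": res.df,
                "p_raw": res.p,
                "direction": res.direction,
                "effect_z": res.effect_z,
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_bh"] = np.nan
    for _, idx in out.groupby(keys[0] if len(keys) == 1 else keys).groups.items():
        out.loc[idx, "p_bh"] = bh_adjust(out.loc[idx, "p_raw"].to_numpy())
    return out
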