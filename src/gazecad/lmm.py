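"""Crossed-random-intercept mixed models for the condition contrast.

For each gaze metric the model is

    y_ijk = b0 + b1 * 1[condition = session1] + u_i (case) + v_j (reader) + e_ijk

with independent random intercepts for case and reader.  The design is
fully crossed — every reader reads every case in both sessions — so the
random structure is crossed, not nested; it is expressed through variance
components on a single trivial grouping, the standard statsmodels MixedLM
encoding of crossed factors.  Estimation is REML; the fixed effect is
reported with a Wald 95 % CI and p-value.  A positive ``b1`` means the
metric is larger in session 1 (boxes displayed).

Variance components may legitimately hit the zero boundary (three readers
give little information about the reader variance); boundary fits are
reported as-is, with the convergence flag carried on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMError",
    "LMMResult",
    "METRIC_COLUMNS",
    "build_analysis_table",
    "fit_condition_lmm",
    "residual_diagnostics",
]


class LMMError(ValueError):
    pass


#: metric name -> column in the metrics table
METRIC_COLUMNS = {
    "interpretation_time": "interpretation_time_s",
    "dwell_time": "dwell_s",
    "time_to_first_fixation": "ttff_s",
    "path_length": "path_px",
    "coverage": "coverage_pct",
}


@dataclass
class LMMResult:
    """Condition fixed effect (session 1 minus session 2) for one metric."""

    metric: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    var_case: float
    var_reader: float
    var_residual: float
    n_rows: int
    n_cases: int
    n_readers: int
    n_dropped_missing: int = 0
    converged: bool = True
    boundary: bool = False
    inference: str = "Wald (normal) CI and p on the REML fixed effect"
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and not (
            self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9
        ):
            raise LMMError("confidence interval does not contain the estimate")
        for v in (self.var_case, self.var_reader, self.var_residual):
            if v < -1e-9:
                raise LMMError("negative variance component")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "var_case": self.var_case,
            "var_reader": self.var_reader,
            "var_residual": self.var_residual,
            "n_rows": self.n_rows,
            "n_cases": self.n_cases,
            "n_readers": self.n_readers,
            "n_dropped_missing": self.n_dropped_missing,
            "converged": self.converged,
            "boundary": self.boundary,
            "inference": self.inference,
        }


def build_analysis_table(
    metrics: pd.DataFrame,
    pairing,
    metric: str,
) -> tuple[pd.DataFrame, int]:
    """Long-format rows for one metric, restricted to paired cases.

    ``pairing`` is the listwise-pairing output (``PairingSummary`` list):
    for each reader only cases valid in both sessions enter, two rows per
    case (one per condition).  Rows with a missing value — a read where the
    gaze never entered the lesion AOI, for the TTFF model — are dropped and
    counted, not imputed.  Returns ``(table, n_dropped_missing)``.

    Raises if the assembled row count does not reconcile with the pairing
    summary (before missing-value drops).
    """
    col = METRIC_COLUMNS.get(metric, metric)
    if col not in metrics.columns:
        raise LMMError(f"metrics table has no column {col!r} for metric {metric!r}")
    frames = []
    expected_rows = 0
    for summ in pairing:
        cases = set(summ.paired_cases)
        expected_rows += 2 * len(cases)
        sub = metrics[
            (metrics["reader"] == summ.reader) & metrics["case_id"].isin(cases)
        ]
        frames.append(sub)
    if not frames:
        df = metrics.iloc[0:0]
    else:
        df = pd.concat(frames, ignore_index=True)
    if len(df) != expected_rows:
        raise LMMError(
            f"reconciliation failure for {metric}: {len(df)} rows assembled, "
            f"pairing summary implies {expected_rows}"
        )
    out = df[["reader", "case_id", "session", col]].rename(columns={col: "value"})
    out["condition"] = np.where(out["session"] == 1, "session1", "session2")
    missing = out["value"].isna()
    n_dropped = int(missing.sum())
    out = out[~missing].reset_index(drop=True)
    return out, n_dropped


def fit_condition_lmm(rows: pd.DataFrame, metric: str = "metric") -> LMMResult:
    """Fit the crossed-random-intercept model and extract the contrast."""
    required = {"reader", "case_id", "condition", "value"}
    if missing := required - set(rows.columns):
        raise LMMError(f"analysis rows lack columns {sorted(missing)}")
    conds = set(rows["condition"].unique())
    if conds != {"session1", "session2"}:
        raise LMMError(f"need both conditions, got {sorted(conds)}")
    n_readers = rows["reader"].nunique()
    n_cases = rows["case_id"].nunique()
    if n_readers < 2 or n_cases < 2:
        raise LMMError("need at least 2 readers and 2 cases")

    df = rows.copy()
    df["cond1"] = (df["condition"] == "session1").astype(float)
    df["_one"] = 1

    if np.ptp(df["value"].to_numpy(dtype=float)) == 0.0:
        # constant response: the contrast and every variance component are
        # exactly zero and the optimizer has nothing to do
        return LMMResult(
            metric=metric, estimate=0.0, se=0.0, ci_low=0.0, ci_high=0.0,
            p_value=float("nan"), var_case=0.0, var_reader=0.0, var_residual=0.0,
            n_rows=len(df), n_cases=n_cases, n_readers=n_readers,
        )

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", ConvergenceWarning)
        model = sm.MixedLM.from_formula(
            "value ~ cond1",
            groups="_one",
            re_formula="0",
            vc_formula={"case": "0 + C(case_id)", "reader": "0 + C(reader)"},
            data=df,
        )
        try:
            res = model.fit(reml=True)
        except Exception as exc:  # no silent fallback: surface the failure
            raise LMMError(f"mixed-model fit failed for {metric}: {exc}") from exc
        caught = [str(w.message) for w in wlist]

    est = float(res.fe_params["cond1"])
    se = float(res.bse["cond1"])
    ci = res.conf_int().loc["cond1"]
    p = float(res.pvalues["cond1"])
    vc = res.vcomp
    vc_names = model.exog_vc.names
    var_case = float(vc[vc_names.index("case")])
    var_reader = float(vc[vc_names.index("reader")])
    boundary = bool(min(var_case, var_reader) < 1e-8) or any(
        "boundary" in m for m in caught
    )
    converged = bool(getattr(res, "converged", True))
    if not converged:
        caught.append("optimizer reported non-convergence; estimates are diagnostic only")
    return LMMResult(
        metric=metric,
        estimate=est,
        se=se,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=p,
        var_case=max(var_case, 0.0),
        var_reader=max(var_reader, 0.0),
        var_residual=float(res.scale),
        n_rows=len(df),
        n_cases=n_cases,
        n_readers=n_readers,
        converged=converged,
        boundary=boundary,
        warnings_=caught,
    )


def residual_diagnostics(result: LMMResult, rows: pd.DataFrame) -> dict:
    """Advisory checks of residual normality and homoscedasticity.

    Recomputes conditional residuals by removing the fixed effect and the
    BLUP-like per-level means, then reports a Shapiro-Wilk statistic and a
    scale-location slope (regression of sqrt(|standardised residual|) on
    fitted value; a slope near 0 is consistent with constant variance).
    Purely advisory: nothing here alters the fitted result.
    """
    df = rows.copy()
    df["fitted"] = np.where(
        df["condition"] == "session1", result.estimate, 0.0
    )
    resid = df["value"].to_numpy(dtype=float) - df["fitted"].to_numpy(dtype=float)
    # partial out additive case and reader levels (moment estimate of the
    # conditional residual; adequate for an advisory check)
    for key in ("case_id", "reader"):
        means = pd.Series(resid).groupby(df[key].to_numpy()).transform("mean")
        resid = resid - means.to_numpy() + resid.mean()
    resid = resid - resid.mean()
    sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
    if sd == 0 or len(resid) < 3:
        return {
            "shapiro_stat": float("nan"),
            "shapiro_p": float("nan"),
            "scale_location_slope": float("nan"),
            "n": len(resid),
            "normality_flag": False,
        }
    sample = resid if len(resid) <= 5000 else resid[:: len(resid) // 5000 + 1]
    stat, p = scipy.stats.shapiro(sample)
    z = resid / sd
    fitted = df["fitted"].to_numpy(dtype=float)
    if np.ptp(fitted) > 0:
        slope = float(np.polyfit(fitted, np.sqrt(np.abs(z)), 1)[0])
    else:
        slope = float("nan")
    return {
        "shapiro_stat": float(stat),
        "shapiro_p": float(p),
        "scale_location_slope": slope,
        "n": int(len(resid)),
        "normality_flag": bool(p < 0.05),
    }
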