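"""Diagnostic-performance and prompt-concordance summaries.

Tabulates reader decisions against case truth: per-group accuracy in each
session, improved/worsened counts between sessions, the box-adoption rate
(concordance of the session-1 decision with what the CAD display showed),
and overall sensitivity/specificity per reader and session.  All reads are
used here — tracking-validity filtering applies only to the gaze-metric
analysis, never to diagnostic performance.

"Adoption" is operationalised as decision-display concordance in session 1:
calling positive when a box was displayed and negative when none was.  This
is a convention of this package (it is the only definition that also yields
an adoption rate for box-free groups such as TN); it is recorded in the
output metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import CaseSpec, Group, cases_to_frame

__all__ = [
    "PerformanceError",
    "accuracy_by_group",
    "improved_worsened",
    "bb_adoption_rate",
    "reader_sensitivity_specificity",
    "performance_table",
]

ADOPTION_DEFINITION = (
    "session-1 decision concordant with the display: positive when a box "
    "was shown, negative when not"
)


class PerformanceError(ValueError):
    pass


def _reads_frame(reads: pd.DataFrame) -> pd.DataFrame:
    df = reads.copy()
    required = {"reader", "session", "case_id", "decision"}
    missing = required - set(df.columns)
    if missing:
        raise PerformanceError(f"reads table lacks columns {sorted(missing)}")
    if df.duplicated(["reader", "session", "case_id"]).any():
        raise PerformanceError("duplicate read for a reader x session x case")
    bad = set(df["decision"].unique()) - {"positive", "negative"}
    if bad:
        raise PerformanceError(f"unknown decisions {sorted(bad)}")
    return df


def _case_truth(cases: list[CaseSpec] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(cases, pd.DataFrame):
        df = cases
    else:
        df = cases_to_frame(cases)
    return df[["case_id", "lesion_present", "group"]].assign(
        has_box=df["group"].isin([g.value for g in Group if g.has_displayed_box])
    )


def _merged(reads: pd.DataFrame, cases) -> pd.DataFrame:
    df = _reads_frame(reads).merge(_case_truth(cases), on="case_id", how="left")
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "case_id"].unique()
        raise PerformanceError(f"reads reference unknown cases {list(missing)[:5]}")
    df["positive"] = df["decision"].eq("positive")
    df["correct"] = df["positive"] == df["lesion_present"].astype(bool)
    return df


def accuracy_by_group(reads: pd.DataFrame, cases) -> pd.DataFrame:
    """Percent-correct per reader x group x session, with denominators.

    A decision is correct when it matches lesion presence: positive on a
    lesion-positive case or negative on a lesion-negative case.  Cases a
    reader never read in a session are reported through the denominator
    (``n``), not silently dropped.
    """
    df = _merged(reads, cases)
    expected = df.groupby(["reader", "session", "group"], observed=True)["case_id"].nunique()
    out = (
        df.groupby(["reader", "session", "group"], observed=True)
        .agg(n=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index()
    )
    out["accuracy_pct"] = 100.0 * out["n_correct"] / out["n"]
    n_cases_per_group = (
        _case_truth(cases).groupby("group", observed=True)["case_id"].nunique()
    )
    out["n_group_cases"] = out["group"].map(n_cases_per_group)
    gaps = out[out["n"] < out["n_group_cases"]]
    if len(gaps):
        warnings.warn(
            f"coverage gap: {len(gaps)} reader/session/group cells have "
            "fewer reads than cases",
            stacklevel=2,
        )
    _ = expected
    return out


def improved_worsened(
    reads_s1: pd.DataFrame,
    reads_s2: pd.DataFrame,
    cases,
    group: str | Group,
) -> pd.DataFrame:
    """Counts of cases that changed correctness between sessions, per reader.

    "Improved" means incorrect without the display (session 2) but correct
    with it (session 1); "worsened" is the reverse.  Cases lacking a
    decision in either session are excluded with a warning.
    """
    group = Group(group).value
    s1 = _merged(reads_s1, cases)
    s2 = _merged(reads_s2, cases)
    s1 = s1[s1["group"] == group]
    s2 = s2[s2["group"] == group]
    m = s1.merge(
        s2, on=["reader", "case_id"], suffixes=("_s1", "_s2"), how="outer", indicator=True
    )
    unpaired = m["_merge"] != "both"
    if unpaired.any():
        warnings.warn(
            f"{int(unpaired.sum())} unpaired {group} decisions excluded "
            "from improved/worsened counts",
            stacklevel=2,
        )
        m = m[~unpaired]
    m["improved"] = m["correct_s1"] & ~m["correct_s2"]
    m["worsened"] = ~m["correct_s1"] & m["correct_s2"]
    return (
        m.groupby("reader")
        .agg(improved=("improved", "sum"), worsened=("worsened", "sum"), n=("improved", "size"))
        .reset_index()
    )


def bb_adoption_rate(
    reads_s1: pd.DataFrame, cases, group: str | Group | None = None
) -> pd.DataFrame:
    """Percent of session-1 decisions concordant with the CAD display.

    ``group=None`` gives the rate over all cases ("Total").
    """
    df = _merged(reads_s1, cases)
    if group is not None:
        df = df[df["group"] == Group(group).value]
    if df.empty:
        raise PerformanceError("adoption rate undefined: no reads in scope")
    df = df.assign(adopted=df["positive"] == df["has_box"])
    out = (
        df.groupby("reader")
        .agg(n=("adopted", "size"), n_adopted=("adopted", "sum"))
        .reset_index()
    )
    out["adoption_pct"] = 100.0 * out["n_adopted"] / out["n"]
    out["group"] = Group(group).value if group is not None else "Total"
    return out


def reader_sensitivity_specificity(
    reads: pd.DataFrame, cases, session: int
) -> pd.DataFrame:
    """Per-reader sensitivity and specificity over all cases in one session.

    Computed against true lesion presence (never display-group labels):
    sensitivity over all lesion-positive cases, specificity over all
    lesion-negative cases.
    """
    df = _merged(reads, cases)
    df = df[df["session"] == session]
    if df.empty:
        raise PerformanceError(f"no reads for session {session}")
    rows = []
    for reader, sub in df.groupby("reader"):
        pos = sub[sub["lesion_present"].astype(bool)]
        neg = sub[~sub["lesion_present"].astype(bool)]
        if pos.empty or neg.empty:
            raise PerformanceError(
                f"reader {reader} session {session}: need both lesion-positive "
                "and lesion-negative reads"
            )
        rows.append(
            {
                "reader": reader,
                "session": session,
                "sensitivity_pct": 100.0 * pos["positive"].mean(),
                "specificity_pct": 100.0 * neg["positive"].eq(False).mean(),
                "n_positive": len(pos),
                "n_negative": len(neg),
            }
        )
    return pd.DataFrame(rows)


def performance_table(reads: pd.DataFrame, cases) -> dict:
    """Full diagnostic-performance report (Table-1-shaped).

    Returns a dict with the long-format accuracy table, improved/worsened
    counts per group, adoption rates per group and total, per-session
    sensitivity/specificity, and metadata recording denominators and the
    adoption-rate definition.
    """
    reads = _reads_frame(reads)
    s1 = reads[reads["session"] == 1]
    s2 = reads[reads["session"] == 2]
    acc = accuracy_by_group(reads, cases)
    present = set(_case_truth(cases)["group"])
    groups = [g.value for g in Group if g.value in present]
    change = pd.concat(
        [improved_worsened(s1, s2, cases, g).assign(group=g) for g in groups],
        ignore_index=True,
    )
    adoption = pd.concat(
        [bb_adoption_rate(s1, cases, g) for g in groups]
        + [bb_adoption_rate(s1, cases, None)],
        ignore_index=True,
    )
    sens_spec = pd.concat(
        [reader_sensitivity_specificity(reads, cases, s) for s in (1, 2)],
        ignore_index=True,
    )
    for name, table in (("accuracy", acc), ("adoption", adoption)):
        col = "accuracy_pct" if name == "accuracy" else "adoption_pct"
        vals = table[col].to_numpy(dtype=float)
        assert np.all((vals >= 0) & (vals <= 100)), f"{name} percentage out of range"
    return {
        "accuracy": acc,
        "improved_worsened": change,
        "adoption": adoption,
        "sensitivity_specificity": sens_spec,
        "metadata": {
            "adoption_definition": ADOPTION_DEFINITION,
            "n_reads": int(len(reads)),
            "n_cases": int(_case_truth(cases)["case_id"].nunique()),
        },
    }
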