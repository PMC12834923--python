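"""End-to-end orchestration: recordings -> metrics -> pairing -> models.

`compute_metrics_table` turns a simulated (or loaded) study into the
per-read metrics table; `run_analysis` applies the validity criterion,
listwise pairing over the primary case group, fits the five mixed models,
and assembles the diagnostic-performance and metric-summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CaseSpec, Group, cases_to_frame
from .lmm import (
    LMMResult,
    METRIC_COLUMNS,
    build_analysis_table,
    fit_condition_lmm,
    residual_diagnostics,
)
from .metrics import (
    GazeRecording,
    LesionAOI,
    dwell_time,
    interpretation_time,
    lung_coverage,
    path_length,
    time_to_first_fixation,
)
from .performance import performance_table
from .simulate import StudyBundle
from .validity import (
    PairingSummary,
    capture_ratio,
    listwise_pair,
    make_validity_record,
    pairing_frame,
    validity_frame,
)

__all__ = ["AnalysisReport", "compute_metrics_table", "run_analysis", "run_pipeline"]


def compute_metric_row(
    rec: GazeRecording,
    case: CaseSpec,
    mask: np.ndarray,
    margin: float = 50.0,
    cell: int = 50,
    buffer: float = 50.0,
) -> dict:
    """All five metrics plus the capture ratio for one read.

    Lesion-referenced metrics (dwell, TTFF) are computed only when the case
    has a lesion; they are missing values otherwise.
    """
    row = {
        "interpretation_time_s": interpretation_time(rec),
        "path_px": path_length(rec),
        "coverage": lung_coverage(rec, mask, cell=cell, buffer=buffer),
        "capture_ratio": capture_ratio(rec),
        "dwell_s": np.nan,
        "ttff_s": np.nan,
    }
    if case.lesion_present and case.lesion_box is not None:
        aoi = LesionAOI(case.lesion_box, margin=margin)
        row["dwell_s"] = dwell_time(rec, aoi)
        ttff = time_to_first_fixation(rec, aoi)
        row["ttff_s"] = np.nan if ttff is None else ttff
    row["coverage_pct"] = 100.0 * row["coverage"]
    return row


def compute_metrics_table(
    bundle: StudyBundle,
    margin: float = 50.0,
    cell: int = 50,
    buffer: float = 50.0,
) -> pd.DataFrame:
    """Per-read metrics for every recording of a study bundle.

    Reads are processed case by case so each lung mask is regenerated only
    once.
    """
    by_case: dict[str, list] = {}
    for read in bundle.reads:
        by_case.setdefault(read.case_id, []).append(read)
    case_of = {c.case_id: c for c in bundle.cases}
    rows = []
    for case_id, reads in by_case.items():
        case = case_of[case_id]
        mask = bundle.mask_for(case)
        for read in reads:
            row = compute_metric_row(
                read.recording, case, mask, margin=margin, cell=cell, buffer=buffer
            )
            row.update(
                reader=read.reader,
                session=read.session,
                case_id=case_id,
                group=Group(case.group).value,
            )
            rows.append(row)
    cols = [
        "reader", "session", "case_id", "group",
        "interpretation_time_s", "dwell_s", "ttff_s", "path_px",
        "coverage", "coverage_pct", "capture_ratio",
    ]
    return pd.DataFrame(rows)[cols]


@dataclass
class AnalysisReport:
    validity: pd.DataFrame
    pairing: list[PairingSummary]
    lmm_results: dict[str, LMMResult]
    diagnostics: dict[str, dict]
    table1: dict
    table2: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def pairing_table(self) -> pd.DataFrame:
        return pairing_frame(self.pairing)


def _table2(
    metrics: pd.DataFrame,
    pairing: list[PairingSummary],
    results: dict[str, LMMResult],
) -> pd.DataFrame:
    """Metric summary shaped like the study's Table 2: per-reader medians
    and IQRs over the paired cases, next to the modelled contrast."""
    rows = []
    for metric, col in METRIC_COLUMNS.items():
        res = results[metric]
        row: dict = {"metric": metric}
        for summ in pairing:
            sub = metrics[
                (metrics["reader"] == summ.reader)
                & metrics["case_id"].isin(summ.paired_cases)
            ]
            for session in (1, 2):
                vals = sub.loc[sub["session"] == session, col].dropna()
                key = f"{summ.reader}_s{session}"
                if len(vals):
                    row[f"{key}_median"] = float(vals.median())
                    row[f"{key}_q1"] = float(vals.quantile(0.25))
                    row[f"{key}_q3"] = float(vals.quantile(0.75))
                else:
                    row[f"{key}_median"] = row[f"{key}_q1"] = row[f"{key}_q3"] = np.nan
            row[f"{summ.reader}_n_pairs"] = summ.n_pairs
        row.update(
            diff=res.estimate, ci_low=res.ci_low, ci_high=res.ci_high,
            p_value=res.p_value, n_rows=res.n_rows,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(
    metrics: pd.DataFrame,
    reads: pd.DataFrame,
    cases: list[CaseSpec],
    validity_threshold: float = 0.5,
    primary_group: Group = Group.TP,
) -> AnalysisReport:
    """Validity filtering, listwise pairing, performance tables, and the
    five condition mixed models.

    The gaze-metric models run on the paired primary-group cases only;
    the diagnostic-performance tabulation uses every read.
    """
    records = [
        make_validity_record(
            r.reader, r.session, r.case_id, r.capture_ratio, validity_threshold
        )
        for r in metrics.itertuples()
    ]
    scope = {c.case_id for c in cases if Group(c.group) is primary_group}
    pairing = listwise_pair(records, scope=scope, threshold=validity_threshold)

    results: dict[str, LMMResult] = {}
    diagnostics: dict[str, dict] = {}
    for metric in METRIC_COLUMNS:
        rows, n_dropped = build_analysis_table(metrics, pairing, metric)
        res = fit_condition_lmm(rows, metric=metric)
        res.n_dropped_missing = n_dropped
        results[metric] = res
        diagnostics[metric] = residual_diagnostics(res, rows)

    table1 = performance_table(reads, cases)
    # diagnostic performance must see every read, never the validity filter
    assert table1["metadata"]["n_reads"] == len(reads)
    table2 = _table2(metrics, pairing, results)
    metadata = {
        "validity_threshold": validity_threshold,
        "primary_group": primary_group.value,
        "n_reads": int(len(reads)),
        "n_metric_rows": int(len(metrics)),
        "per_metric_n": {m: results[m].n_rows for m in results},
        "per_metric_dropped_missing": {m: results[m].n_dropped_missing for m in results},
    }
    return AnalysisReport(
        validity=validity_frame(records),
        pairing=pairing,
        lmm_results=results,
        diagnostics=diagnostics,
        table1=table1,
        table2=table2,
        metadata=metadata,
    )


def run_pipeline(config) -> tuple[StudyBundle, pd.DataFrame, AnalysisReport]:
    """Simulate a study and run the complete analysis on it."""
    from .simulate import simulate_study

    bundle = simulate_study(config)
    metrics = compute_metrics_table(
        bundle,
        margin=config.aoi_margin,
        cell=config.coverage_cell,
        buffer=config.coverage_buffer,
    )
    report = run_analysis(metrics, bundle.reads_table, bundle.cases)
    return bundle, metrics, report
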