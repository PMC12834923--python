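"""Tracking-validity filtering and listwise pairing across sessions.

A read is valid when strictly more than a threshold fraction (default 50 %)
of the gaze samples expected over its duration were actually captured.  The
paired analysis set for each reader is the intersection of that reader's
valid cases across the two crossover sessions (listwise deletion), usually
restricted to a case-group scope (the primary analysis uses TP cases only).
Diagnostic-performance tabulation is *not* filtered: every interpretation
is retained there regardless of tracking validity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import GazeRecording, RecordingError

__all__ = [
    "ValidityRecord",
    "PairingSummary",
    "capture_ratio",
    "filter_valid",
    "listwise_pair",
    "validity_frame",
    "pairing_frame",
]

DEFAULT_VALIDITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class ValidityRecord:
    """Per-read capture ratio and the validity verdict it implies."""

    reader: str
    session: int
    case_id: str
    capture_ratio: float
    valid: bool


@dataclass(frozen=True)
class PairingSummary:
    """Per-reader listwise-deletion outcome over the in-scope cases."""

    reader: str
    n_valid_s1: int
    n_valid_s2: int
    n_pairs: int
    pct_pairs: float           # pairs as a percentage of the in-scope cases
    paired_cases: tuple[str, ...]


def capture_ratio(rec: GazeRecording) -> float:
    """Valid samples over the expected count round(duration * rate), capped at 1."""
    if rec.duration <= 0:
        raise RecordingError("capture ratio undefined for zero-duration recording")
    expected = round(rec.duration * rec.sampling_rate)
    if expected == 0:
        raise RecordingError("capture ratio undefined: zero expected samples")
    return min(1.0, rec.n_valid / expected)


def make_validity_record(
    reader: str,
    session: int,
    case_id: str,
    ratio: float,
    threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> ValidityRecord:
    return ValidityRecord(
        reader=reader,
        session=int(session),
        case_id=case_id,
        capture_ratio=float(ratio),
        valid=bool(ratio > threshold),
    )


def filter_valid(
    records: list[ValidityRecord], threshold: float = DEFAULT_VALIDITY_THRESHOLD
) -> list[ValidityRecord]:
    """Keep reads whose capture ratio is strictly greater than the threshold.

    The criterion is "more than", so a ratio exactly at the threshold is
    excluded.
    """
    return [r for r in records if r.capture_ratio > threshold]


def listwise_pair(
    records: list[ValidityRecord],
    scope: set[str] | None = None,
    threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> list[PairingSummary]:
    """Per-reader intersection of valid case sets across sessions 1 and 2.

    ``scope`` restricts to a case subset (e.g. the TP group) and supplies
    the denominator for the paired-case percentage; with ``scope=None`` the
    denominator is the union of case ids seen for the reader.
    """
    kept = filter_valid(records, threshold)
    readers = sorted({r.reader for r in records})
    out: list[PairingSummary] = []
    for reader in readers:
        sets: dict[int, set[str]] = {1: set(), 2: set()}
        for r in kept:
            if r.reader == reader and r.session in sets:
                if scope is None or r.case_id in scope:
                    sets[r.session].add(r.case_id)
        if scope is None:
            denom = len({
                r.case_id for r in records if r.reader == reader
            })
        else:
            denom = len(scope)
        pairs = sorted(sets[1] & sets[2])
        out.append(
            PairingSummary(
                reader=reader,
                n_valid_s1=len(sets[1]),
                n_valid_s2=len(sets[2]),
                n_pairs=len(pairs),
                pct_pairs=100.0 * len(pairs) / denom if denom else float("nan"),
                paired_cases=tuple(pairs),
            )
        )
    return out


def validity_frame(records: list[ValidityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reader": r.reader,
                "session": r.session,
                "case_id": r.case_id,
                "capture_ratio": r.capture_ratio,
                "valid": int(r.valid),
            }
            for r in records
        ]
    )


def pairing_frame(summaries: list[PairingSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reader": s.reader,
                "n_valid_s1": s.n_valid_s1,
                "n_valid_s2": s.n_valid_s2,
                "n_pairs": s.n_pairs,
                "pct_pairs": s.pct_pairs,
            }
            for s in summaries
        ]
    )
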