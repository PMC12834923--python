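"""Case allocation for the CAD-display reader study.

The study mixes five display-level case groups: true-positive cases where
the CAD bounding box (BB) marks the lesion, false-negatives with no box,
false-negative-plus-false-positive cases where the lesion is unmarked but a
wrong box is shown elsewhere, true-negatives with no box, and lesion-free
false-positive cases with a spurious box.  The group counts fix the
display-level operating point of the simulated CAD (sensitivity and
specificity of the box display itself, independent of any reader).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PixelBox

__all__ = [
    "Group",
    "CaseSpec",
    "DesignConfig",
    "DesignError",
    "allocate_cases",
    "display_sensitivity",
    "display_specificity",
    "cases_to_frame",
    "frame_to_cases",
]


class DesignError(ValueError):
    """Invalid study-design configuration or undefined design ratio."""


class Group(str, enum.Enum):
    """Display-level truth group of a case."""

    TP = "TP"        # lesion present, box on the lesion
    FN = "FN"        # lesion present, no box anywhere
    FN_FP = "FN_FP"  # lesion present, box elsewhere
    TN = "TN"        # no lesion, no box
    FP = "FP"        # no lesion, spurious box

    @property
    def lesion_present(self) -> bool:
        return self in (Group.TP, Group.FN, Group.FN_FP)

    @property
    def has_displayed_box(self) -> bool:
        return self in (Group.TP, Group.FN_FP, Group.FP)


@dataclass
class CaseSpec:
    """One study case: truth group, lesion box, and the box shown on screen."""

    case_id: str
    lesion_present: bool
    group: Group
    lesion_box: PixelBox | None = None
    displayed_box: PixelBox | None = None
    image_width: int = 2560
    image_height: int = 1440
    mask_seed: int | None = field(default=None, compare=False)

    def validate(self, check_boxes: bool = True, aoi_margin: float = 50.0) -> None:
        """Check group/box consistency.

        ``check_boxes=False`` validates only the group/lesion flags, for
        specs produced by allocation before boxes are attached.  For FN_FP
        cases the displayed box must not touch the lesion AOI (lesion box
        plus ``aoi_margin``), so a wrong prompt can never contaminate the
        lesion dwell metric.
        """
        g = Group(self.group)
        if g.lesion_present != bool(self.lesion_present):
            raise DesignError(
                f"{self.case_id}: lesion_present={self.lesion_present} "
                f"inconsistent with group {g.value}"
            )
        if not check_boxes:
            return
        if g.lesion_present and self.lesion_box is None:
            raise DesignError(f"{self.case_id}: group {g.value} requires a lesion box")
        if not g.lesion_present and self.lesion_box is not None:
            raise DesignError(f"{self.case_id}: lesion-negative case has a lesion box")
        if g.has_displayed_box and self.displayed_box is None:
            raise DesignError(f"{self.case_id}: group {g.value} requires a displayed box")
        if not g.has_displayed_box and self.displayed_box is not None:
            raise DesignError(f"{self.case_id}: group {g.value} must not display a box")
        if g is Group.TP and self.displayed_box != self.lesion_box:
            raise DesignError(f"{self.case_id}: TP displayed box must equal the lesion box")
        if g is Group.FN_FP:
            aoi = self.lesion_box.expand(aoi_margin).clip(self.image_width, self.image_height)
            if self.displayed_box.intersects(aoi):
                raise DesignError(
                    f"{self.case_id}: FN_FP displayed box intersects the lesion AOI"
                )


@dataclass(frozen=True)
class DesignConfig:
    """Group counts and the display operating point they imply."""

    n_tp: int
    n_fn: int
    n_fnfp: int
    n_tn: int
    n_fp: int
    target_sensitivity: float = 0.80
    target_specificity: float = 0.80

    def __post_init__(self) -> None:
        counts = (self.n_tp, self.n_fn, self.n_fnfp, self.n_tn, self.n_fp)
        if any(c < 0 for c in counts):
            raise DesignError(f"negative group count in {counts}")
        n_pos = self.n_tp + self.n_fn + self.n_fnfp
        n_neg = self.n_tn + self.n_fp
        if n_pos and not np.isclose(self.n_tp / n_pos, self.target_sensitivity):
            raise DesignError(
                f"counts give display sensitivity {self.n_tp / n_pos:.4f}, "
                f"target is {self.target_sensitivity:.4f}"
            )
        if n_neg and not np.isclose(self.n_tn / n_neg, self.target_specificity):
            raise DesignError(
                f"counts give display specificity {self.n_tn / n_neg:.4f}, "
                f"target is {self.target_specificity:.4f}"
            )

    @property
    def n_total(self) -> int:
        return self.n_tp + self.n_fn + self.n_fnfp + self.n_tn + self.n_fp


#: The study's allocation: 96 TP / 12 FN / 12 FN+FP / 48 TN / 12 FP,
#: i.e. a box-display sensitivity of 96/120 and specificity of 48/60.
STUDY_DESIGN = DesignConfig(n_tp=96, n_fn=12, n_fnfp=12, n_tn=48, n_fp=12)


def allocate_cases(
    config: DesignConfig, case_ids: list[str], seed: int
) -> list[CaseSpec]:
    """Randomly allocate case ids to the five display groups.

    A seeded permutation of the ids is sliced into groups in the fixed order
    TP, FN, FN_FP, TN, FP; the result is deterministic for a given seed.
    Lesion and displayed boxes are not set here — they come from annotations
    or from the synthetic generator.  The returned list follows the input id
    order.
    """
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate case ids")
    if len(ids) != config.n_total:
        raise DesignError(
            f"{len(ids)} case ids for a design of {config.n_total} cases"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    group_of: dict[str, Group] = {}
    start = 0
    for group, count in (
        (Group.TP, config.n_tp),
        (Group.FN, config.n_fn),
        (Group.FN_FP, config.n_fnfp),
        (Group.TN, config.n_tn),
        (Group.FP, config.n_fp),
    ):
        for k in perm[start:start + count]:
            group_of[ids[k]] = group
        start += count
    specs = [
        CaseSpec(case_id=i, lesion_present=group_of[i].lesion_present, group=group_of[i])
        for i in ids
    ]
    for s in specs:
        s.validate(check_boxes=False)
    return specs


def _marks_lesion(case: CaseSpec) -> bool:
    if case.displayed_box is None:
        return False
    if case.lesion_box is not None:
        return case.displayed_box == case.lesion_box
    return False


def display_sensitivity(cases: list[CaseSpec]) -> float:
    """Fraction of lesion-positive cases whose displayed box marks the lesion."""
    pos = [c for c in cases if c.lesion_present]
    if not pos:
        raise DesignError("display sensitivity undefined: no lesion-positive cases")
    if all(c.lesion_box is None for c in pos):
        # boxes not attached yet: fall back on the group label, which encodes
        # the same fact by construction
        marked = sum(c.group is Group.TP for c in pos)
    else:
        marked = sum(_marks_lesion(c) for c in pos)
    return marked / len(pos)


def display_specificity(cases: list[CaseSpec]) -> float:
    """Fraction of lesion-negative cases shown without any box."""
    neg = [c for c in cases if not c.lesion_present]
    if not neg:
        raise DesignError("display specificity undefined: no lesion-negative cases")
    clean = sum(c.displayed_box is None and c.group is not Group.FP for c in neg)
    return clean / len(neg)


_BOX_COLS = ("x_min", "y_min", "x_max", "y_max")


def cases_to_frame(cases: list[CaseSpec]) -> pd.DataFrame:
    """Case table with VinDR-style box columns (empty where absent)."""
    rows = []
    for c in cases:
        row: dict = {
            "case_id": c.case_id,
            "lesion_present": int(c.lesion_present),
            "group": Group(c.group).value,
        }
        for prefix, box in (("lesion", c.lesion_box), ("displayed", c.displayed_box)):
            for col in _BOX_COLS:
                row[f"{prefix}_{col}"] = getattr(box, col) if box is not None else np.nan
        row["image_width"] = c.image_width
        row["image_height"] = c.image_height
        row["mask_seed"] = c.mask_seed if c.mask_seed is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _box_from_row(row: pd.Series, prefix: str) -> PixelBox | None:
    vals = [row[f"{prefix}_{c}"] for c in _BOX_COLS]
    if any(pd.isna(v) for v in vals):
        return None
    return PixelBox(*[float(v) for v in vals])


def frame_to_cases(frame: pd.DataFrame) -> list[CaseSpec]:
    cases = []
    for _, row in frame.iterrows():
        cases.append(
            CaseSpec(
                case_id=str(row["case_id"]),
                lesion_present=bool(int(row["lesion_present"])),
                group=Group(row["group"]),
                lesion_box=_box_from_row(row, "lesion"),
                displayed_box=_box_from_row(row, "displayed"),
                image_width=int(row["image_width"]),
                image_height=int(row["image_height"]),
                mask_seed=None if pd.isna(row.get("mask_seed", np.nan)) else int(row["mask_seed"]),
            )
        )
    return cases
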