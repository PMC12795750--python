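"""Historical redlining score (HRS) and mortgage-discrimination index.

HRS is the area-weighted mean HOLC grade (A=1 ... D=4) over the graded
portion of a tract, defined only when at least 20% of the tract overlaps
graded neighborhoods; the weighting renormalizes by the graded area so the
score stays in [1, 4].  The discrimination index D is the minority loan
share divided by the minority household share; D < 1 indicates
discriminatory lending ("sustained discrimination" when paired with
redlining).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HolcOverlap",
    "StructuralIndices",
    "HRS_MIN_OVERLAP",
    "compute_hrs",
    "compute_mortgage_discrimination",
    "classify_sustained",
    "structural_indices_table",
]

#: Minimum graded-area overlap for the HRS to be defined.
HRS_MIN_OVERLAP = 0.20

_GRADE_WEIGHTS = np.array([1.0, 2.0, 3.0, 4.0])


@dataclass(frozen=True)
class HolcOverlap:
    tract_id: str
    overlap_a: float
    overlap_b: float
    overlap_c: float
    overlap_d: float

    def __post_init__(self) -> None:
        props = self.proportions
        if (props < 0).any() or (props > 1).any():
            raise ValueError("overlap proportions must be in [0, 1]")
        if props.sum() > 1.0 + 1e-9:
            raise ValueError("overlap proportions sum to more than 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.overlap_a, self.overlap_b,
                         self.overlap_c, self.overlap_d])

    @property
    def total_graded(self) -> float:
        return float(self.proportions.sum())


@dataclass(frozen=True)
class StructuralIndices:
    tract_id: str
    hrs: float | None
    d_index: float | None
    sustained: bool | None


def compute_hrs(overlap: HolcOverlap) -> float | None:
    """Area-weighted HOLC grade in [1, 4]; None below the 20% overlap rule."""
    total = overlap.total_graded
    if total < HRS_MIN_OVERLAP:
        return None
    return float((_GRADE_WEIGHTS @ overlap.proportions) / total)


def compute_mortgage_discrimination(loans_minority: float, loans_total: float,
                                    households_minority: float,
                                    households_total: float) -> float | None:
    """D = minority loan share / minority household share; None if undefined."""
    for name, v in (("loans_minority", loans_minority),
                    ("loans_total", loans_total),
                    ("households_minority", households_minority),
                    ("households_total", households_total)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if loans_total == 0 or households_total == 0 or households_minority == 0:
        return None
    return float((loans_minority / loans_total)
                 / (households_minority / households_total))


def classify_sustained(d_index: float | None) -> bool | None:
    """True iff D is strictly below 1; None for missing D."""
    if d_index is None:
        return None
    return d_index < 1.0


def structural_indices_table(holc: pd.DataFrame,
                             mortgage: pd.DataFrame) -> pd.DataFrame:
    """Per-tract HRS, D and sustained-discrimination flag.

    Rows come from the union of tract ids in the two inputs; missing values
    propagate as NaN (hrs/d_index) and <NA> (sustained).
    """
    hrs_by_id: dict[str, float | None] = {}
    for row in holc.itertuples():
        ov = HolcOverlap(str(row.tract_id), float(row.overlap_a),
                         float(row.overlap_b), float(row.overlap_c),
                         float(row.overlap_d))
        hrs_by_id[str(row.tract_id)] = compute_hrs(ov)
    d_by_id: dict[str, float | None] = {}
    for row in mortgage.itertuples():
        d_by_id[str(row.tract_id)] = compute_mortgage_discrimination(
            float(row.loans_minority), float(row.loans_total),
            float(row.households_minority), float(row.households_total))
    ids = sorted(set(hrs_by_id) | set(d_by_id))
    rows = []
    for tid in ids:
        d = d_by_id.get(tid)
        sustained = classify_sustained(d) if d is not None else None
        rows.append({
            "tract_id": tid,
            "hrs": np.nan if hrs_by_id.get(tid) is None else hrs_by_id.get(tid),
            "d_index": np.nan if d is None else d,
            "sustained": sustained,
        })
    frame = pd.DataFrame(rows, columns=["tract_id", "hrs", "d_index", "sustained"])
    frame["sustained"] = frame["sustained"].astype("boolean")
    return frame
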