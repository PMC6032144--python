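"""Histological quality scoring of surgical disc samples.

Small annulus fibrosus (AF) and nucleus pulposus (NP) biopsies are graded on
two rubrics by a human rater:

* the **IVD score** — 6 items (tissue character, matrix staining, impurity
  evidence), each graded 0/1/2, maximum 12.  A sample is *clear* (defined
  AF or NP character, free of foreign tissue) when its total exceeds 6 and
  no single item was graded 0.
* the **DD score** — 3 items grading cellular-level disc degeneration, each
  0/1/2, maximum 6.  A sample is *severe* when the total exceeds 3 or any
  item was graded 2 (an alternative "ge3" rule classifies totals of 3 as
  severe as well; both are supported).

Samples that are clear *and* mildly degenerated are eligible for expression
profiling; a per-donor deduplication then yields the microarray cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Tuple

from .errors import ValidationError

Compartment = Literal["AF", "NP"]
Rubric = Literal["IVD", "DD"]
IvdClass = Literal["clear", "unknown"]
DdClass = Literal["mild", "severe"]
DdRule = Literal["strict_gt3", "ge3"]

IVD_N_ITEMS = 6
DD_N_ITEMS = 3
IVD_MAX = 12
DD_MAX = 6

#: default threshold in the "DD total" part of the severe rule
DD_THRESHOLD = 3


def score_rubric(items: Sequence[int], rubric: Rubric) -> Tuple[int, bool]:
    """Aggregate item grades of one rubric into (total, flag).

    For the IVD rubric the flag is "any item graded 0" (which voids a clear
    classification); for the DD rubric it is "any item graded 2" (which
    forces a severe classification).

    Parameters
    ----------
    items
        6 (IVD) or 3 (DD) integer grades, each 0, 1 or 2.
    rubric
        ``"IVD"`` or ``"DD"``.
    """
    if rubric == "IVD":
        n_expected = IVD_N_ITEMS
    elif rubric == "DD":
        n_expected = DD_N_ITEMS
    else:
        raise ValidationError(f"unknown rubric {rubric!r}")
    if len(items) != n_expected:
        raise ValidationError(
            f"{rubric} rubric expects {n_expected} item grades, got {len(items)}"
        )
    for i, g in enumerate(items, start=1):
        if not isinstance(g, (int,)) or isinstance(g, bool) or g not in (0, 1, 2):
            raise ValidationError(
                f"{rubric} item {i} grade must be 0, 1 or 2, got {g!r}"
            )
    total = int(sum(items))
    flag = (min(items) == 0) if rubric == "IVD" else (max(items) == 2)
    return total, flag


def classify_ivd(total: int, any_zero: bool) -> IvdClass:
    """Clear iff the IVD total exceeds 6 and no item was graded 0."""
    if not 0 <= total <= IVD_MAX:
        raise ValidationError(f"IVD total must be in [0, {IVD_MAX}], got {total}")
    return "clear" if (total > 6 and not any_zero) else "unknown"


def classify_dd(total: int, any_two: bool, threshold_mode: DdRule = "strict_gt3") -> DdClass:
    """Severe iff the DD total exceeds 3 (or reaches 3 in ``ge3`` mode) or any item was graded 2."""
    if not 0 <= total <= DD_MAX:
        raise ValidationError(f"DD total must be in [0, {DD_MAX}], got {total}")
    if threshold_mode == "strict_gt3":
        severe = total > DD_THRESHOLD or any_two
    elif threshold_mode == "ge3":
        severe = total >= DD_THRESHOLD or any_two
    else:
        raise ValidationError(f"unknown DD threshold mode {threshold_mode!r}")
    return "severe" if severe else "mild"


@dataclass(frozen=True)
class SampleRecord:
    """One surgical disc sample with its identity and rubric outcome.

    Either item-level grades (``ivd_items``/``dd_items``) or aggregated
    totals+flags are given per rubric; when items are present the aggregates
    are derived and must not be supplied separately.
    """

    donor_id: str
    gender: str
    age: int
    sample_id: int
    disc_level: str
    mri_grade: int
    compartment: Compartment
    ivd_items: Optional[Tuple[int, ...]] = None
    dd_items: Optional[Tuple[int, ...]] = None
    ivd_total: Optional[int] = None
    ivd_any_zero: Optional[bool] = None
    dd_total: Optional[int] = None
    dd_any_two: Optional[bool] = None

    def __post_init__(self):
        if self.gender not in ("f", "m"):
            raise ValidationError(f"gender must be 'f' or 'm', got {self.gender!r}")
        if not 1 <= self.mri_grade <= 5:
            raise ValidationError(f"mri_grade must be 1-5, got {self.mri_grade}")
        if self.compartment not in ("AF", "NP"):
            raise ValidationError(f"compartment must be AF or NP, got {self.compartment!r}")
        if self.age < 0:
            raise ValidationError(f"age must be non-negative, got {self.age}")
        for rubric, items, total, flag in (
            ("IVD", self.ivd_items, self.ivd_total, self.ivd_any_zero),
            ("DD", self.dd_items, self.dd_total, self.dd_any_two),
        ):
            if items is not None:
                if total is not None or flag is not None:
                    raise ValidationError(
                        f"{rubric}: give item grades OR total+flag, not both"
                    )
                t, f = score_rubric(items, rubric)  # validates the grades
                object.__setattr__(
                    self, "ivd_total" if rubric == "IVD" else "dd_total", t
                )
                object.__setattr__(
                    self, "ivd_any_zero" if rubric == "IVD" else "dd_any_two", f
                )
            else:
                if total is None or flag is None:
                    raise ValidationError(
                        f"{rubric}: either item grades or total+flag are required"
                    )
                maxtotal = IVD_MAX if rubric == "IVD" else DD_MAX
                if not 0 <= total <= maxtotal:
                    raise ValidationError(
                        f"{rubric} total must be in [0, {maxtotal}], got {total}"
                    )

    def verdict(self, dd_rule: DdRule = "strict_gt3") -> "QualityVerdict":
        return QualityVerdict(
            ivd_class=classify_ivd(self.ivd_total, self.ivd_any_zero),
            dd_class=classify_dd(self.dd_total, self.dd_any_two, dd_rule),
        )


@dataclass(frozen=True)
class QualityVerdict:
    ivd_class: IvdClass
    dd_class: DdClass

    @property
    def eligible_microarray(self) -> bool:
        """Clear tissue character AND mild cellular degeneration."""
        return self.ivd_class == "clear" and self.dd_class == "mild"


@dataclass(frozen=True)
class CohortSummary:
    n_af: int
    n_np: int
    n_af_clear: int
    n_np_clear: int
    n_af_eligible: int
    n_np_eligible: int
    n_severe: int
    fraction_severe: float


@dataclass(frozen=True)
class MicroarrayCohort:
    af_sample_ids: Tuple[int, ...]
    np_sample_ids: Tuple[int, ...]
    donor_ids: Tuple[str, ...]
    mean_age: float
    mean_age_rounded: int
    age_range: Tuple[int, int]
    female_count: int
    male_count: int

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)


def summarize_cohort(
    records: Iterable[SampleRecord], dd_rule: DdRule = "strict_gt3"
) -> CohortSummary:
    """Pass-rate summary of a scored cohort under the configured DD rule."""
    records = list(records)
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    n = {"AF": 0, "NP": 0}
    n_clear = {"AF": 0, "NP": 0}
    n_eligible = {"AF": 0, "NP": 0}
    n_severe = 0
    for rec in records:
        v = rec.verdict(dd_rule)
        n[rec.compartment] += 1
        if v.ivd_class == "clear":
            n_clear[rec.compartment] += 1
        if v.eligible_microarray:
            n_eligible[rec.compartment] += 1
        if v.dd_class == "severe":
            n_severe += 1
    return CohortSummary(
        n_af=n["AF"],
        n_np=n["NP"],
        n_af_clear=n_clear["AF"],
        n_np_clear=n_clear["NP"],
        n_af_eligible=n_eligible["AF"],
        n_np_eligible=n_eligible["NP"],
        n_severe=n_severe,
        fraction_severe=n_severe / len(records),
    )


def select_microarray_cohort(
    records: Iterable[SampleRecord], dd_rule: DdRule = "strict_gt3"
) -> MicroarrayCohort:
    """Select the expression-profiling cohort: eligible samples, one per donor per compartment.

    When a donor contributed several eligible samples of one compartment,
    the one with the highest IVD total is kept (ties: lowest DD total, then
    lowest sample id).  The donor-level summary (donor union, mean age, age
    range, gender split) does not depend on this tie-break.
    """
    eligible = [r for r in records if r.verdict(dd_rule).eligible_microarray]
    best: dict = {}
    for rec in eligible:
        key = (rec.donor_id, rec.compartment)
        cur = best.get(key)
        if cur is None or (
            (-rec.ivd_total, rec.dd_total, rec.sample_id)
            < (-cur.ivd_total, cur.dd_total, cur.sample_id)
        ):
            best[key] = rec
    selected = list(best.values())
    af_ids = tuple(sorted(r.sample_id for r in selected if r.compartment == "AF"))
    np_ids = tuple(sorted(r.sample_id for r in selected if r.compartment == "NP"))
    donors: dict = {}
    for r in selected:
        donors[r.donor_id] = r
    if donors:
        ages = [r.age for r in donors.values()]
        mean_age = sum(ages) / len(ages)
        age_range = (min(ages), max(ages))
        f = sum(1 for r in donors.values() if r.gender == "f")
        m = sum(1 for r in donors.values() if r.gender == "m")
    else:
        mean_age, age_range, f, m = math.nan, (0, 0), 0, 0
    return MicroarrayCohort(
        af_sample_ids=af_ids,
        np_sample_ids=np_ids,
        donor_ids=tuple(sorted(donors, key=str)),
        mean_age=mean_age,
        mean_age_rounded=int(math.floor(mean_age + 0.5)) if donors else 0,
        age_range=age_range,
        female_count=f,
        male_count=m,
    )
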