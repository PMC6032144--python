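"""Marker-panel range classification of disc samples.

The panel comprises 5 AF markers (LDB2, ADGRL4, EMCN, ANKRD29, OLFML2A) and
6 NP markers (SPTLC3, ERFE, DSC3, DEFB1, ARAP2, CDKN2B).  For each marker
an expression range (min, max) is fitted on samples with *clear*
characteristics of the marker's own tissue.  A test sample's value is then
called:

* ``+``  within the range (boundaries inclusive),
* ``++`` above the range,
* ``-``  below the range or no expression at all,
* ``NA`` measurement not available.

The marker match of a sample is the percentage of positive (+ or ++) calls
among its non-NA calls of one marker set, rounded to the nearest integer
percent.  A sample is assigned an AF verdict when every available AF marker
is positive; an NP verdict when no AF marker is positive and the NP match
reaches the configured minimum (default 83%, i.e. at least 5 of 6
available); anything else remains undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Mapping, Optional, Sequence, Tuple

from .errors import ValidationError

Call = Literal["-", "+", "++", "NA"]
Verdict = Literal["AF", "NP", "undefined"]

AF_MARKERS = ("LDB2", "ADGRL4", "EMCN", "ANKRD29", "OLFML2A")
NP_MARKERS = ("SPTLC3", "ERFE", "DSC3", "DEFB1", "ARAP2", "CDKN2B")

POSITIVE_CALLS = ("+", "++")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class MarkerPanel:
    af_markers: Tuple[str, ...] = AF_MARKERS
    np_markers: Tuple[str, ...] = NP_MARKERS
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.af_markers) & set(self.np_markers)
        if overlap:
            raise ValidationError(f"markers in both sets: {sorted(overlap)}")
        for m, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValidationError(f"range of {m} has low > high ({lo} > {hi})")

    @property
    def markers(self) -> Tuple[str, ...]:
        return self.af_markers + self.np_markers

    def tissue_of(self, marker: str) -> str:
        if marker in self.af_markers:
            return "AF"
        if marker in self.np_markers:
            return "NP"
        raise ValidationError(f"unknown marker {marker!r}")


def fit_ranges(
    expression: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    panel: Optional[MarkerPanel] = None,
) -> MarkerPanel:
    """Fit each marker's (min, max) range on clear samples of its own tissue.

    Parameters
    ----------
    expression
        marker -> {sample_id -> relative expression}; missing measurements
        simply absent (or NaN).
    groups
        sample_id -> "AF" | "NP" (the *clear* samples only).
    panel
        marker-set definition; defaults to the 5+6 panel.
    """
    panel = panel or MarkerPanel()
    ranges: Dict[str, Tuple[float, float]] = {}
    for marker in panel.markers:
        tissue = panel.tissue_of(marker)
        if marker not in expression:
            raise ValidationError(f"no expression values for marker {marker}")
        vals = [
            v
            for s, v in expression[marker].items()
            if groups.get(s) == tissue and v is not None and not math.isnan(v)
        ]
        if len(vals) < 2:
            raise ValidationError(
                f"marker {marker}: need >= 2 clear {tissue} values, got {len(vals)}"
            )
        if min(vals) < 0:
            raise ValidationError(f"marker {marker}: negative expression value")
        ranges[marker] = (min(vals), max(vals))
    return MarkerPanel(
        af_markers=panel.af_markers, np_markers=panel.np_markers, ranges=ranges
    )


def call_marker(value: Optional[float], rng: Tuple[float, float]) -> Call:
    """Range call for one marker value; ``NA`` when the value is missing."""
    lo, hi = rng
    if lo > hi:
        raise ValidationError(f"range has low > high ({lo} > {hi})")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if value < 0:
        raise ValidationError(f"expression value must be non-negative, got {value}")
    if value == 0:
        return "-"  # no expression
    if value > hi:
        return "++"
    if value >= lo:
        return "+"
    return "-"


def match_percent(calls: Sequence[str]) -> Optional[int]:
    """Positive calls (+ or ++) over non-NA calls, nearest-integer percent.

    Returns ``None`` (undefined) when every call is NA.
    """
    available = [c for c in calls if c != "NA"]
    if not available:
        return None
    positive = sum(1 for c in available if c in POSITIVE_CALLS)
    return _round_half_up(100.0 * positive / len(available))


@dataclass(frozen=True)
class PanelRule:
    af_match_required: int = 100
    np_match_min: int = 83
    np_requires_af_zero: bool = True
    min_available: int = 3


@dataclass(frozen=True)
class MarkerCallProfile:
    """One sample's calls on the full panel, with origin label if known."""

    sample_id: str
    calls: Mapping[str, str]  # marker -> call
    origin: Optional[str] = None  # resection site, "AF" | "NP"

    def set_calls(self, markers: Sequence[str]) -> List[str]:
        return [self.calls.get(m, "NA") for m in markers]


def classify_profile(
    profile: MarkerCallProfile,
    panel: Optional[MarkerPanel] = None,
    rule: PanelRule = PanelRule(),
) -> Tuple[Verdict, Optional[int], Optional[int]]:
    """Assign AF / NP / undefined and return (verdict, af_match, np_match).

    A verdict is only asserted when the asserted marker set has at least
    ``rule.min_available`` non-NA calls.
    """
    panel = panel or MarkerPanel()
    af_calls = profile.set_calls(panel.af_markers)
    np_calls = profile.set_calls(panel.np_markers)
    af_match = match_percent(af_calls)
    np_match = match_percent(np_calls)
    n_af = sum(1 for c in af_calls if c != "NA")
    n_np = sum(1 for c in np_calls if c != "NA")

    if af_match is not None and n_af >= rule.min_available and af_match >= rule.af_match_required:
        return "AF", af_match, np_match
    af_zero = (af_match == 0) if rule.np_requires_af_zero else True
    if (
        np_match is not None
        and n_np >= rule.min_available
        and af_zero
        and np_match >= rule.np_match_min
    ):
        return "NP", af_match, np_match
    return "undefined", af_match, np_match


@dataclass(frozen=True)
class CohortClassification:
    verdicts: Tuple[Tuple[str, Verdict], ...]  # (sample label, verdict) per row
    n_af_verdict: int
    n_np_verdict: int
    n_undefined: int
    n_af_origin: int
    n_np_origin: int
    n_confirmed_af: int  # AF-origin rows with AF verdict
    n_confirmed_np: int  # NP-origin rows with NP verdict


def classify_cohort(
    profiles: Iterable[MarkerCallProfile],
    panel: Optional[MarkerPanel] = None,
    rule: PanelRule = PanelRule(),
) -> CohortClassification:
    """Verdicts and confirmation counts for a table of call profiles."""
    panel = panel or MarkerPanel()
    verdicts: List[Tuple[str, Verdict]] = []
    counts = {"AF": 0, "NP": 0, "undefined": 0}
    origin_counts = {"AF": 0, "NP": 0}
    confirmed = {"AF": 0, "NP": 0}
    for prof in profiles:
        verdict, _, _ = classify_profile(prof, panel, rule)
        verdicts.append((prof.sample_id, verdict))
        counts[verdict] += 1
        if prof.origin in origin_counts:
            origin_counts[prof.origin] += 1
            if verdict == prof.origin:
                confirmed[prof.origin] += 1
    return CohortClassification(
        verdicts=tuple(verdicts),
        n_af_verdict=counts["AF"],
        n_np_verdict=counts["NP"],
        n_undefined=counts["undefined"],
        n_af_origin=origin_counts["AF"],
        n_np_origin=origin_counts["NP"],
        n_confirmed_af=confirmed["AF"],
        n_confirmed_np=confirmed["NP"],
    )
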