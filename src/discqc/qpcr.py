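"""Efficiency-corrected relative qPCR quantification and group comparison.

A target's abundance on one sample is taken as E^(-Cq) with the assay's
amplification efficiency E (2.0 for perfect doubling per cycle) and the
mean quantification cycle Cq of up to three replicates.  Relative
expression normalises that abundance by the geometric mean of the two
reference-gene abundances (defaults ATP5F1B and RPL13A):

    rel = E_t^(-Cq_t) / sqrt(E_r1^(-Cq_r1) * E_r2^(-Cq_r2))

A target that never amplified ("no expression") is reported as relative
expression 0, feeding the marker-panel "-" call.  AF-vs-NP differences per
marker are tested with the Mann-Whitney U test (exact for small groups).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

REFERENCE_GENES = ("ATP5F1B", "RPL13A")

# exact U distribution is enumerated only for small groups
EXACT_MIN_N = 10
EXACT_TOTAL = 25


@dataclass(frozen=True)
class QpcrAssay:
    gene_id: str
    efficiency: float = 2.0
    is_reference: bool = False

    def __post_init__(self):
        if not 1.0 < self.efficiency <= 2.2:
            raise ValidationError(
                f"assay {self.gene_id}: efficiency must be in (1, 2.2], "
                f"got {self.efficiency}"
            )


def default_assays(genes: Iterable[str]) -> Dict[str, QpcrAssay]:
    """Perfect-efficiency assays for the given targets plus the two references."""
    assays = {g: QpcrAssay(g) for g in genes}
    for ref in REFERENCE_GENES:
        assays[ref] = QpcrAssay(ref, is_reference=True)
    return assays


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    gene_id: str
    cq_replicates: Tuple[float, ...] = ()
    undetected: bool = False

    def __post_init__(self):
        if not self.undetected:
            if not self.cq_replicates:
                raise ValidationError(
                    f"{self.sample_id}/{self.gene_id}: no Cq replicates and not "
                    "flagged undetected"
                )
            if len(self.cq_replicates) > 3:
                raise ValidationError(
                    f"{self.sample_id}/{self.gene_id}: at most 3 replicates"
                )
            if any(c <= 0 for c in self.cq_replicates):
                raise ValidationError(
                    f"{self.sample_id}/{self.gene_id}: Cq values must be positive"
                )

    @property
    def cq_mean(self) -> float:
        if self.undetected:
            return math.nan
        return float(np.mean(self.cq_replicates))


def relative_expression(
    target: QpcrMeasurement,
    refs: Sequence[QpcrMeasurement],
    assays: Mapping[str, QpcrAssay],
) -> float:
    """Efficiency-corrected abundance of the target over the geometric mean of two references."""
    if len(refs) != 2:
        raise ValidationError(f"exactly two reference measurements required, got {len(refs)}")
    for r in refs:
        if r.sample_id != target.sample_id:
            raise ValidationError(
                f"reference {r.gene_id} is from sample {r.sample_id}, "
                f"target from {target.sample_id}"
            )
        if r.undetected:
            raise ValidationError(
                f"sample {target.sample_id}: reference {r.gene_id} undetected; "
                "sample not quantifiable"
            )
    if target.undetected:
        return 0.0
    # work in log space to avoid underflow of E^(-Cq)
    log_t = -target.cq_mean * math.log(assays[target.gene_id].efficiency)
    log_refs = [
        -r.cq_mean * math.log(assays[r.gene_id].efficiency) for r in refs
    ]
    return math.exp(log_t - 0.5 * (log_refs[0] + log_refs[1]))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_a, U_b).

    The p-value is exact (enumeration of the U null) when both groups are
    small (min n <= 10, total <= 25) and there are no cross-group ties;
    otherwise the normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # all observations identical: complete overlap
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = min(a.size, b.size) <= EXACT_MIN_N and (a.size + b.size) <= EXACT_TOTAL
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_b = a.size * b.size - u_a
    return min(u_a, u_b), float(res.pvalue)


def significance_tier(p: float) -> str:
    """ns / * (p < 0.05) / ** (p < 0.01)."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# cohort quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerGroupTest:
    marker: str
    n_af: int
    n_np: int
    u: float
    p: float
    tier: str


def quantify_cohort(
    measurements: Iterable[QpcrMeasurement],
    assays: Mapping[str, QpcrAssay],
    markers: Sequence[str],
    groups: Mapping[str, str],
) -> Tuple[pd.DataFrame, List[MarkerGroupTest]]:
    """Relative expression per (sample, marker) and an AF-vs-NP test per marker.

    Parameters
    ----------
    measurements
        all Cq measurements (targets and references) of the cohort.
    groups
        sample_id -> "AF" | "NP" | "unknown": only clear AF/NP samples enter
        the group test; every sample is quantified.

    Returns
    -------
    A samples x markers DataFrame (NaN where a measurement is missing) and
    the per-marker test results; samples lacking a reference measurement
    are skipped entirely.
    """
    by_sample: Dict[str, Dict[str, QpcrMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {})[m.gene_id] = m
    ref_names = [g for g, a in assays.items() if a.is_reference]
    if len(ref_names) != 2:
        raise ValidationError(
            f"exactly two reference assays required, got {len(ref_names)}"
        )
    rows = {}
    skipped: List[str] = []
    for sample_id, genes in by_sample.items():
        refs = [genes.get(r) for r in ref_names]
        if any(r is None or r.undetected for r in refs):
            skipped.append(sample_id)
            continue
        row = {}
        for marker in markers:
            meas = genes.get(marker)
            row[marker] = (
                math.nan if meas is None else relative_expression(meas, refs, assays)
            )
        rows[sample_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(markers))
    table.index.name = "sample_id"
    table = table.sort_index()
    table.attrs["skipped_samples"] = skipped

    tests: List[MarkerGroupTest] = []
    af_ids = [s for s in table.index if groups.get(s) == "AF"]
    np_ids = [s for s in table.index if groups.get(s) == "NP"]
    for marker in markers:
        va = table.loc[af_ids, marker].dropna().to_numpy()
        vb = table.loc[np_ids, marker].dropna().to_numpy()
        if va.size < 3 or vb.size < 3:
            continue
        u, p = mann_whitney_u(va, vb)
        tests.append(
            MarkerGroupTest(
                marker=marker,
                n_af=va.size,
                n_np=vb.size,
                u=u,
                p=p,
                tier=significance_tier(p),
            )
        )
    return table, tests
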