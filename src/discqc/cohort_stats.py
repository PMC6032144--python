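"""Rank correlation of scoring outcomes with donor age and MRI grade.

Tie-corrected (average-rank) Spearman correlation with a two-sided p-value
from the t approximation on n - 2 degrees of freedom, plus the conventional
verbal interpretation bands on |r| (very weak < 0.2 <= weak < 0.4 <=
moderate < 0.6 <= strong < 0.8 <= very strong).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .scoring import SampleRecord

Band = Literal["very weak", "weak", "moderate", "strong", "very strong"]

_BAND_EDGES = [(0.2, "very weak"), (0.4, "weak"), (0.6, "moderate"), (0.8, "strong")]


def interpretation_band(r: float) -> Band:
    """Verbal strength band for a correlation coefficient (on |r|)."""
    a = abs(r)
    for edge, name in _BAND_EDGES:
        if a < edge:
            return name
    return "very strong"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    band: Band


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected Spearman correlation of two equal-length vectors.

    Average ranks are assigned to ties and Pearson correlation is taken on
    the ranks; the two-sided p-value uses the t approximation with n - 2
    degrees of freedom (the default of common statistics packages).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant vector: correlation undefined")
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    return CorrelationResult(r=r, p=p, n=n, band=interpretation_band(r))


def correlate_scores(
    records: Iterable[SampleRecord],
) -> Dict[Tuple[str, str, str], CorrelationResult]:
    """The 2x2x2 correlation table: {IVD, DD} x {AF, NP} x {age, MRI}.

    Each cell correlates the rubric totals of all samples of one
    compartment against donor age or MRI degeneration grade.
    """
    records = list(records)
    out: Dict[Tuple[str, str, str], CorrelationResult] = {}
    for score in ("IVD", "DD"):
        for comp in ("AF", "NP"):
            sub = [r for r in records if r.compartment == comp]
            totals = [r.ivd_total if score == "IVD" else r.dd_total for r in sub]
            for covariate in ("age", "mri"):
                cov = [r.age if covariate == "age" else r.mri_grade for r in sub]
                out[(score, comp, covariate)] = spearman(totals, cov)
    return out
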