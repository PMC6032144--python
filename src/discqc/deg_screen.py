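"""All-pairwise AF x NP chip comparison screen for differentially expressed genes.

For every gene, every AF chip is compared with every NP chip.  A pairwise
comparison yields a signal log ratio (SLR, the median log2 ratio over the
probe-level replicates), its fold-change FC = 2^SLR, a p-value from an
exact Wilcoxon signed-rank test on the per-probe log ratios, and a change
call (increased / decreased / no change).  A gene is a DEG when a
consistent change call is made in at least a given fraction (default 80%)
of all pairwise comparisons at fold-change > 2.

Two candidate tiers follow the screen:

* AF candidates - very high fold-change, significant, and *absent* in NP
  (detection% = 0): the on/off pattern.
* NP candidates - moderate up-regulation in NP with stable detection and
  signal there (no gene is exclusively expressed in NP).

The exact signed-rank null distribution is computed once per probe count by
the classic dynamic-programming recursion (coefficients of
prod_k (1 + x^k)), which keeps the ~10^5 pairwise tests of a full screen
vectorised and fast.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError

ChangeCall = Literal["increased", "decreased", "no_change"]
Direction = Literal["AF_up", "NP_up"]

DEFAULT_DETECTION_FLOOR = 100.0
EXACT_MAX_N = 25  # exact signed-rank null up to this many probe pairs


# ---------------------------------------------------------------------------
# expression container
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x chips linear-scale signals with optional probe-level replicates.

    ``signal`` holds one summary value per (gene, chip); ``probe_signals``
    optionally holds the P probe-level replicates it was summarised from
    (10% trimmed mean).  ``detection`` marks per-chip presence calls; when
    absent it is derived as ``signal >= detection_floor``.
    """

    gene_ids: List[str]
    chip_ids: List[str]
    groups: Dict[str, str]  # chip_id -> "AF" | "NP"
    signal: np.ndarray  # (G, C)
    probe_signals: Optional[np.ndarray] = None  # (G, C, P)
    detection: Optional[np.ndarray] = None  # (G, C) bool
    detection_floor: float = DEFAULT_DETECTION_FLOOR

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        G, C = len(self.gene_ids), len(self.chip_ids)
        if self.signal.shape != (G, C):
            raise ValidationError(
                f"signal shape {self.signal.shape} != (genes={G}, chips={C})"
            )
        if np.any(self.signal < 0):
            raise ValidationError("signals must be non-negative")
        missing = [c for c in self.chip_ids if c not in self.groups]
        if missing:
            raise ValidationError(f"chips without group assignment: {missing}")
        bad = {g for g in self.groups.values() if g not in ("AF", "NP")}
        if bad:
            raise ValidationError(f"groups must be AF or NP, got {sorted(bad)}")
        if self.probe_signals is not None:
            self.probe_signals = np.asarray(self.probe_signals, dtype=float)
            if self.probe_signals.shape[:2] != (G, C):
                raise ValidationError("probe_signals must be (genes, chips, P)")
            if np.any(self.probe_signals <= 0):
                raise ValidationError("probe signals must be positive")
        if self.detection is None:
            self.detection = self.signal >= self.detection_floor
        else:
            self.detection = np.asarray(self.detection, dtype=bool)
            if self.detection.shape != (G, C):
                raise ValidationError("detection must be (genes, chips)")
        if np.any(self.signal[self.detection] <= 0):
            raise ValidationError("signal must be positive where detected")

    def chip_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.chip_ids) if self.groups[c] == group],
            dtype=int,
        )

    def swapped_groups(self) -> "ExpressionMatrix":
        """A view of the same data with AF and NP labels exchanged."""
        flipped = {c: ("NP" if g == "AF" else "AF") for c, g in self.groups.items()}
        return replace(self, groups=flipped)


# ---------------------------------------------------------------------------
# detection and exact signed-rank machinery
# ---------------------------------------------------------------------------

def detection_call(signal: float, floor: float) -> str:
    """Present/absent call: detected iff signal >= floor."""
    if floor <= 0:
        raise ValidationError(f"detection floor must be positive, got {floor}")
    if signal <= 0:
        raise ValidationError(f"signal must be positive, got {signal}")
    return "detected" if signal >= floor else "not_detected"


@functools.lru_cache(maxsize=64)
def _signed_rank_null(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """(cdf, sf) of the exact W+ null over ranks 1..n, on the grid 0..n(n+1)/2.

    Counts are the coefficients of prod_{k=1..n} (1 + x^k); each of the 2^n
    sign assignments is equally likely under H0.
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    total = counts.sum()  # == 2**n
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    return cdf, sf


def signed_rank_exact_p(w: float, n: int) -> float:
    """Two-sided exact p for signed-rank statistic ``w`` on ``n`` pairs.

    p = min(1, 2 * min(P(W <= w), P(W >= w))).  Half-integer W (average
    ranks under ties) is handled conservatively by flooring/ceiling onto
    the integer grid; the exact null assumes no ties in |ratio|.
    """
    if n == 0:
        return 1.0
    cdf, sf = _signed_rank_null(n)
    lo = int(math.floor(w))
    hi = int(math.ceil(w))
    p_le = cdf[min(lo, len(cdf) - 1)]
    p_ge = sf[min(hi, len(sf) - 1)]
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _signed_rank_approx_p(w: float, n: int, tie_term: float = 0.0) -> float:
    """Normal approximation for large n, with tie correction."""
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return 1.0
    z = (w - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank_p(log_ratios: Sequence[float]) -> float:
    """Two-sided signed-rank p of per-probe log ratios against zero.

    Zero ratios are dropped (Wilcoxon's original treatment); the test is
    exact for up to 25 remaining pairs, normal-approximated beyond.
    """
    r = np.asarray(log_ratios, dtype=float)
    r = r[r != 0.0]
    n = r.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(r))
    w = float(ranks[r > 0].sum())
    if n <= EXACT_MAX_N:
        return signed_rank_exact_p(w, n)
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    return _signed_rank_approx_p(w, n, tie_term)


# ---------------------------------------------------------------------------
# pairwise comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseComparison:
    slr: float  # log2 ratio AF/NP
    fc: float  # 2**slr
    change_call: ChangeCall
    p: float


def _change_call(fc: float, p: float, fc_call_threshold: float, alpha: float) -> ChangeCall:
    significant = (not math.isnan(p)) and p < alpha
    if fc > fc_call_threshold and significant:
        return "increased"
    if fc < 1.0 / fc_call_threshold and significant:
        return "decreased"
    return "no_change"


def pairwise_compare(
    gene_probes_af: Sequence[float],
    gene_probes_np: Sequence[float],
    fc_call_threshold: float = 2.0,
    alpha: float = 0.05,
) -> PairwiseComparison:
    """Compare one gene between one AF chip and one NP chip at probe level.

    SLR is the median over probes of log2(af/np) (a robust one-step
    estimator); the p-value is the exact two-sided signed-rank test of the
    per-probe log ratios against zero.
    """
    a = np.asarray(gene_probes_af, dtype=float)
    b = np.asarray(gene_probes_np, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("probe vectors must be 1-d and of equal length")
    if a.size < 5:
        raise ValidationError(f"need at least 5 probes per set, got {a.size}")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("probe signals must be positive")
    r = np.log2(a / b)
    slr = float(np.median(r))
    fc = float(2.0**slr)
    p = wilcoxon_signed_rank_p(r)
    return PairwiseComparison(
        slr=slr, fc=fc, change_call=_change_call(fc, p, fc_call_threshold, alpha), p=p
    )


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGRecord:
    """Per-gene summary over all AF x NP pairwise comparisons.

    ``fc_mean``/``fc_sd`` are on the scale of the gene's own direction
    (AF/NP for AF-up genes, NP/AF for NP-up genes), so both read > 1.
    """

    gene_id: str
    direction: Direction
    fc_mean: float
    fc_sd: float
    change_pct: float
    detection_pct_af: float
    detection_pct_np: float
    p_median: float
    signal_mean_af: float
    signal_mean_np: float


def _pairwise_stats(
    matrix: ExpressionMatrix, fc_threshold: float, alpha: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-(gene, pair) slr, p, increased, decreased arrays.

    Shapes are (G, nAF * nNP).  With probe replicates the p-value is the
    exact signed-rank test; without them the change call rests on the
    fold-change margin alone and p is NaN.
    """
    ia = matrix.chip_indices("AF")
    ib = matrix.chip_indices("NP")
    G = len(matrix.gene_ids)
    if matrix.probe_signals is not None:
        probes = matrix.probe_signals
        P = probes.shape[2]
        # (G, nA, nB, P) log2 ratios
        r = np.log2(probes[:, ia][:, :, None, :] / probes[:, ib][:, None, :, :])
        r = r.reshape(G, ia.size * ib.size, P)
        slr = np.median(r, axis=-1)
        absr = np.abs(r)
        ranks = stats.rankdata(absr, axis=-1)
        zero_mask = r == 0.0
        w = np.sum(ranks * (r > 0), axis=-1)
        cdf, sf = _signed_rank_null(P)
        lo = np.floor(w).astype(int)
        hi = np.minimum(np.ceil(w).astype(int), len(sf) - 1)
        p = np.minimum(1.0, 2.0 * np.minimum(cdf[lo], sf[hi]))
        # cells containing exact-zero ratios need the reduced-n null
        bad = np.argwhere(zero_mask.any(axis=-1))
        for g, k in bad:
            p[g, k] = wilcoxon_signed_rank_p(r[g, k])
    else:
        sig = matrix.signal
        with np.errstate(divide="ignore"):
            slr = np.log2(
                sig[:, ia][:, :, None] / sig[:, ib][:, None, :]
            ).reshape(G, ia.size * ib.size)
        p = np.full_like(slr, np.nan)
    fc = 2.0**slr
    if matrix.probe_signals is not None:
        significant = p < alpha
    else:
        significant = np.ones_like(fc, dtype=bool)
    increased = (fc > fc_threshold) & significant
    decreased = (fc < 1.0 / fc_threshold) & significant
    return slr, p, increased, decreased


def screen_degs(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    consistency: float = 0.8,
    alpha: float = 0.05,
) -> List[DEGRecord]:
    """Retain genes changed consistently across all AF x NP pairwise comparisons.

    A gene is AF-up when at least ``consistency`` of all pairs call it
    increased at fold-change > ``fc_threshold`` (NP-up symmetric with
    decreased calls).
    """
    ia = matrix.chip_indices("AF")
    ib = matrix.chip_indices("NP")
    if ia.size < 2 or ib.size < 2:
        raise ValidationError(
            f"need at least 2 chips per group, got AF={ia.size}, NP={ib.size}"
        )
    slr, p, increased, decreased = _pairwise_stats(matrix, fc_threshold, alpha)
    n_pairs = increased.shape[1]
    frac_inc = increased.sum(axis=1) / n_pairs
    frac_dec = decreased.sum(axis=1) / n_pairs
    det_af = 100.0 * matrix.detection[:, ia].mean(axis=1)
    det_np = 100.0 * matrix.detection[:, ib].mean(axis=1)
    mean_af = matrix.signal[:, ia].mean(axis=1)
    mean_np = matrix.signal[:, ib].mean(axis=1)
    out: List[DEGRecord] = []
    for g, gene in enumerate(matrix.gene_ids):
        if frac_inc[g] >= consistency:
            direction: Direction = "AF_up"
            fc_pairs = 2.0 ** slr[g]
            change_pct = 100.0 * frac_inc[g]
        elif frac_dec[g] >= consistency:
            direction = "NP_up"
            fc_pairs = 2.0 ** (-slr[g])  # report NP-up genes on the NP/AF scale
            change_pct = 100.0 * frac_dec[g]
        else:
            continue
        out.append(
            DEGRecord(
                gene_id=gene,
                direction=direction,
                fc_mean=float(fc_pairs.mean()),
                fc_sd=float(fc_pairs.std(ddof=1)) if n_pairs > 1 else 0.0,
                change_pct=float(change_pct),
                detection_pct_af=float(det_af[g]),
                detection_pct_np=float(det_np[g]),
                p_median=float(np.median(p[g])),
                signal_mean_af=float(mean_af[g]),
                signal_mean_np=float(mean_np[g]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateCriteria:
    """Two-tier marker-candidate filters applied to the ranked DEG lists."""

    af_fc_min: float = 24.4
    af_p_max: float = 0.05
    af_np_detection_pct: float = 0.0
    np_fc_min: float = 3.0
    np_detection_pct_min: float = 100.0
    np_signal_floor_mult: float = 2.0
    top_k_af: int = 25
    top_k_np: int = 16
    exclusion_list: FrozenSet[str] = frozenset()

    def __post_init__(self):
        for name in ("af_fc_min", "np_fc_min", "np_signal_floor_mult"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def select_candidates(
    degs: Sequence[DEGRecord],
    criteria: CandidateCriteria = CandidateCriteria(),
    noise_floor: float = DEFAULT_DETECTION_FLOOR,
) -> Tuple[List[DEGRecord], List[DEGRecord]]:
    """(AF candidates, NP candidates) from a screened DEG list.

    Each direction is ranked by mean fold-change (descending; ties broken
    by gene id), user-excluded genes are dropped, the top-k window is
    taken, and the tier's thresholds are applied inside that window.
    """
    if not degs:
        raise ValidationError("DEG list is empty")

    def ranked(direction: Direction) -> List[DEGRecord]:
        sub = [d for d in degs if d.direction == direction]
        sub.sort(key=lambda d: (-d.fc_mean, d.gene_id))
        return [d for d in sub if d.gene_id not in criteria.exclusion_list]

    af = [
        d
        for d in ranked("AF_up")[: criteria.top_k_af]
        if d.fc_mean >= criteria.af_fc_min
        and (not math.isnan(d.p_median) and d.p_median < criteria.af_p_max)
        and d.detection_pct_np == criteria.af_np_detection_pct
    ]
    np_ = [
        d
        for d in ranked("NP_up")[: criteria.top_k_np]
        if d.fc_mean >= criteria.np_fc_min
        and d.detection_pct_np >= criteria.np_detection_pct_min
        and d.signal_mean_np >= criteria.np_signal_floor_mult * noise_floor
    ]
    return af, np_
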