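"""Synthetic cohorts with known ground truth for every pipeline stage.

Three generators emulate the structure of the study data:

* ``simulate_score_sheet`` - item-level rubric sheets for a cohort of
  donors, each sample drawn from a latent quality tier (clear/unknown x
  mild/severe) with configurable mixing proportions.  The default mix
  mirrors the observed cohort composition (59% clear, 38% severe under
  the inclusive DD rule).
* ``simulate_expression`` - a probe-level expression matrix for two chip
  groups (11 AF + 9 NP by default) with planted differential structure:
  AF-up genes follow an on/off pattern (signal below the detection floor
  on every NP chip, median fold-change 10), NP-up genes a moderate shift
  (median fold-change 4) with stable NP detection, and the remaining
  genes share their group means.  Signals carry multiplicative lognormal
  chip noise and probe-specific affinities that cancel in pairwise ratios.
* ``simulate_qpcr`` - triplicate Cq tables for the marker panel with the
  planted fold-differences of the expression truth, Gaussian Cq noise,
  and AF-exclusive markers undetected in NP samples.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .deg_screen import ExpressionMatrix
from .marker_panel import AF_MARKERS, NP_MARKERS
from .qpcr import REFERENCE_GENES
from .scoring import SampleRecord

TIERS = ("clear_mild", "clear_severe", "unknown_mild", "unknown_severe")

#: tier proportions chosen to mirror the observed cohort composition
DEFAULT_QUALITY_MIX = {
    "clear_mild": 0.46,
    "clear_severe": 0.13,
    "unknown_mild": 0.16,
    "unknown_severe": 0.25,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # score sheet
    n_donors: int = 17
    n_discs: int = 28
    quality_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY_MIX)
    )
    # expression matrix
    n_genes: int = 1000
    n_af_chips: int = 11
    n_np_chips: int = 9
    n_af_up: int = 50
    n_np_up: int = 20
    af_fc_median: float = 10.0
    np_fc_median: float = 4.0
    fc_sigma: float = 0.25  # lognormal spread of planted fold-changes
    noise_sigma: float = 0.25  # lognormal sigma of chip-level signals
    probes_per_set: int = 11
    detection_floor: float = 100.0
    # qPCR
    cq_sigma: float = 0.15
    efficiency: float = 2.0
    n_af_qpcr: int = 9
    n_np_qpcr: int = 5

    def __post_init__(self):
        if self.n_af_up + self.n_np_up > self.n_genes:
            raise ValidationError("planted DEG counts exceed n_genes")
        total = sum(self.quality_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"quality_mix probabilities sum to {total}, not 1")
        unknown = set(self.quality_mix) - set(TIERS)
        if unknown:
            raise ValidationError(f"unknown quality tiers: {sorted(unknown)}")
        if self.n_discs < self.n_donors:
            raise ValidationError("need at least one disc per donor")


@dataclass
class GroundTruth:
    """Planted structure of one simulated data set."""

    gene_labels: Optional[np.ndarray] = None  # "AF_up" | "NP_up" | "null"
    planted_fc: Optional[np.ndarray] = None  # on the direction's own scale
    group_means: Optional[pd.DataFrame] = None  # gene x {af_mean, np_mean}
    sample_tiers: Optional[Dict[Tuple[int, str], str]] = None
    marker_truth: Optional[pd.DataFrame] = None  # marker x {af_mean, np_mean, fold}


# ---------------------------------------------------------------------------
# score sheets
# ---------------------------------------------------------------------------

def _draw_items(rng: np.random.Generator, tier: str) -> Tuple[List[int], List[int]]:
    """(ivd_items, dd_items) guaranteed to realise the tier's classes.

    Tier semantics use the default decision rules: clear = IVD total > 6
    with no 0 item; severe = DD total > 3 or any DD item 2.
    """
    clear = tier.startswith("clear")
    severe = tier.endswith("severe")
    if clear:
        ivd = list(rng.choice([1, 2], size=6, p=[0.4, 0.6]))
        if 2 not in ivd:  # total would be exactly 6; clear needs > 6
            ivd[rng.integers(6)] = 2
    else:
        ivd = list(rng.integers(0, 3, size=6))
        if min(ivd) > 0 and sum(ivd) > 6:  # would be clear: plant a zero
            ivd[rng.integers(6)] = 0
    if severe:
        dd = list(rng.integers(0, 3, size=3))
        if max(dd) < 2 and sum(dd) <= 3:  # would be mild: plant a two
            dd[rng.integers(3)] = 2
    else:
        dd = list(rng.choice([0, 1], size=3))  # total <= 3, no item 2
    return [int(g) for g in ivd], [int(g) for g in dd]


def simulate_score_sheet(
    config: SimulationConfig,
) -> Tuple[List[SampleRecord], GroundTruth]:
    """Item-level AF+NP score sheet for a simulated surgical cohort."""
    rng = np.random.default_rng(config.seed)
    tiers = list(config.quality_mix)
    probs = np.array([config.quality_mix[t] for t in tiers])
    # every donor gets one disc, remaining discs are spread at random
    donor_of_disc = list(range(config.n_donors)) + list(
        rng.integers(0, config.n_donors, size=config.n_discs - config.n_donors)
    )
    donor_age = rng.integers(36, 78, size=config.n_donors)
    donor_gender = rng.choice(["f", "m"], size=config.n_donors)
    levels = ["C3/4", "C4/5", "C5/6", "C6/7"]
    records: List[SampleRecord] = []
    sample_tiers: Dict[Tuple[int, str], str] = {}
    for disc, donor in enumerate(sorted(donor_of_disc), start=1):
        level = levels[int(rng.integers(len(levels)))]
        mri = int(rng.choice([3, 4]))
        for compartment in ("AF", "NP"):
            tier = tiers[int(rng.choice(len(tiers), p=probs))]
            ivd_items, dd_items = _draw_items(rng, tier)
            records.append(
                SampleRecord(
                    donor_id=str(donor + 1),
                    gender=str(donor_gender[donor]),
                    age=int(donor_age[donor]),
                    sample_id=disc,
                    disc_level=level,
                    mri_grade=mri,
                    compartment=compartment,
                    ivd_items=tuple(ivd_items),
                    dd_items=tuple(dd_items),
                )
            )
            sample_tiers[(disc, compartment)] = tier
    return records, GroundTruth(sample_tiers=sample_tiers)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _trimmed_mean(x: np.ndarray, frac: float = 0.1) -> np.ndarray:
    """Trimmed mean over the last axis (the probe summary)."""
    n = x.shape[-1]
    k = int(frac * n)
    xs = np.sort(x, axis=-1)
    if k:
        xs = xs[..., k : n - k]
    return xs.mean(axis=-1)


def simulate_expression(
    config: SimulationConfig,
) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Probe-level AF/NP expression matrix with planted DEG structure."""
    rng = np.random.default_rng(config.seed + 1)
    G = config.n_genes
    floor = config.detection_floor
    labels = np.array(
        ["AF_up"] * config.n_af_up
        + ["NP_up"] * config.n_np_up
        + ["null"] * (G - config.n_af_up - config.n_np_up)
    )
    rng.shuffle(labels)
    af_idx = np.flatnonzero(labels == "AF_up")
    np_idx = np.flatnonzero(labels == "NP_up")

    af_mean = np.empty(G)
    np_mean = np.empty(G)
    planted = np.ones(G)
    # null genes: shared mean, a mix of expressed and near-floor genes
    base = np.exp(rng.normal(math.log(6.0 * floor), 0.9, size=G))
    af_mean[:] = base
    np_mean[:] = base
    # AF-up on/off: NP below the detection floor, AF = fc x NP level.
    # Planted folds are clipped away from the DEG threshold so the planted
    # truth is unambiguous at zero noise.
    fc_af = np.exp(rng.normal(math.log(config.af_fc_median), config.fc_sigma,
                              size=af_idx.size))
    fc_af = np.maximum(fc_af, 4.0)
    np_mean[af_idx] = 0.5 * floor
    af_mean[af_idx] = fc_af * np_mean[af_idx]
    planted[af_idx] = fc_af
    # NP-up shift: both tissues detected, NP = fc x AF
    fc_np = np.exp(rng.normal(math.log(config.np_fc_median), config.fc_sigma,
                              size=np_idx.size))
    fc_np = np.maximum(fc_np, 2.5)
    af_mean[np_idx] = np.exp(
        rng.normal(math.log(4.0 * floor), 0.3, size=np_idx.size)
    )
    np_mean[np_idx] = fc_np * af_mean[np_idx]
    planted[np_idx] = fc_np

    nA, nB, P = config.n_af_chips, config.n_np_chips, config.probes_per_set
    chip_ids = [f"AF{i+1:02d}" for i in range(nA)] + [
        f"NP{i+1:02d}" for i in range(nB)
    ]
    groups = {c: ("AF" if c.startswith("AF") else "NP") for c in chip_ids}
    group_mean = np.column_stack([af_mean] * nA + [np_mean] * nB)  # (G, C)
    # chip-level biological/technical noise
    chip_noise = np.exp(rng.normal(0.0, config.noise_sigma, size=(G, nA + nB)))
    # probe affinities are probe-specific but shared across chips, so they
    # cancel in pairwise per-probe ratios (as sequence affinities do)
    affinity = np.exp(rng.normal(0.0, 0.25, size=(G, 1, P))) if config.noise_sigma > 0 \
        else np.ones((G, 1, P))
    probe_noise = (
        np.exp(rng.normal(0.0, config.noise_sigma, size=(G, nA + nB, P)))
        if config.noise_sigma > 0
        else np.ones((G, nA + nB, P))
    )
    probes = (group_mean * chip_noise)[:, :, None] * affinity * probe_noise
    signal = _trimmed_mean(probes)
    matrix = ExpressionMatrix(
        gene_ids=[f"G{i:05d}" for i in range(G)],
        chip_ids=chip_ids,
        groups=groups,
        signal=signal,
        probe_signals=probes,
        detection_floor=floor,
    )
    # marker truth for the qPCR generator: first planted genes of each
    # direction stand for the named panel markers
    marker_rows = {}
    for name, g in zip(AF_MARKERS, af_idx):
        marker_rows[name] = (af_mean[g], 0.0, planted[g])  # NP: no expression
    for name, g in zip(NP_MARKERS, np_idx):
        marker_rows[name] = (af_mean[g], np_mean[g], planted[g])
    marker_truth = pd.DataFrame.from_dict(
        marker_rows, orient="index", columns=["af_mean", "np_mean", "fold"]
    )
    truth = GroundTruth(
        gene_labels=labels,
        planted_fc=planted,
        group_means=pd.DataFrame(
            {"af_mean": af_mean, "np_mean": np_mean}, index=matrix.gene_ids
        ),
        marker_truth=marker_truth,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def simulate_qpcr(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Triplicate Cq table for the marker panel from planted marker means.

    Cq = -log_E(abundance) + per-sample loading offset + N(0, cq_sigma)
    per replicate; markers with zero planted abundance in a tissue are
    undetected there (blank replicates).
    """
    if truth.marker_truth is None:
        raise ValidationError("truth lacks marker_truth; run simulate_expression first")
    rng = np.random.default_rng(config.seed + 2)
    E = config.efficiency
    logE = math.log(E)
    samples = [(f"AF{i+1:02d}", "AF") for i in range(config.n_af_qpcr)] + [
        (f"NP{i+1:02d}", "NP") for i in range(config.n_np_qpcr)
    ]
    # abundances are expressed relative to the references; scale chosen so
    # Cq values land in a realistic 15-35 cycle window
    ref_abund = 1e-6
    rows = []
    for sample_id, tissue in samples:
        offset = rng.normal(0.0, 0.5)  # loading/RT yield shift, cancels out
        genes = dict(truth.marker_truth[f"{tissue.lower()}_mean"])
        scale = 1.0 / max(truth.marker_truth[["af_mean", "np_mean"]].values.max(), 1.0)
        for gene in list(genes) + list(REFERENCE_GENES):
            if gene in REFERENCE_GENES:
                abund = ref_abund
            else:
                abund = genes[gene] * scale * 1e-4
            if abund <= 0:
                rows.append((sample_id, tissue, gene, "", "", ""))
                continue
            cq0 = -math.log(abund) / logE + offset
            reps = cq0 + rng.normal(0.0, config.cq_sigma, size=3)
            rows.append((sample_id, tissue, gene, *(f"{c:.4f}" for c in reps)))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "gene_id", "cq1", "cq2", "cq3"]
    )
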