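"""End-to-end orchestration: score -> select -> correlate -> screen -> panel -> qPCR.

``run_pipeline`` executes the stages on a score sheet and call table (the
packaged fixtures by default), optionally inserting a simulated expression
matrix and qPCR table so the screen and quantification stages have data
with known ground truth.  Per-stage outputs are written as TSV/JSON under
the configured output directory and the headline numbers are collected in
a single report dict (also written as ``report.json``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np

from . import io as qio
from .cohort_stats import correlate_scores
from .deg_screen import CandidateCriteria, screen_degs, select_candidates
from .errors import DiscqcError, PipelineError, ValidationError
from .marker_panel import MarkerPanel, PanelRule, classify_cohort, fit_ranges
from .qpcr import default_assays, quantify_cohort
from .scoring import select_microarray_cohort, summarize_cohort
from .synthetic import SimulationConfig, simulate_expression, simulate_qpcr

logger = logging.getLogger("discqc")


@dataclass
class RunConfig:
    score_sheet: Optional[str] = None  # None -> packaged fixture
    call_table: Optional[str] = None  # None -> packaged fixture
    dd_rule: str = "strict_gt3"
    fc_threshold: float = 2.0
    consistency: float = 0.8
    alpha: float = 0.05
    criteria: CandidateCriteria = field(default_factory=CandidateCriteria)
    panel_rule: PanelRule = field(default_factory=PanelRule)
    simulate: bool = True  # plant a synthetic matrix + qPCR run
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    outdir: str = "discqc_out"
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "criteria" in raw:
            raw["criteria"] = CandidateCriteria(**raw["criteria"])
        if "panel_rule" in raw:
            raw["panel_rule"] = PanelRule(**raw["panel_rule"])
        if "sim" in raw:
            raw["sim"] = SimulationConfig(**raw["sim"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except DiscqcError as e:
                raise PipelineError(name, str(e)) from e
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Run all stages; returns (and writes) the summary report."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, Any] = {"dd_rule": config.dd_rule, "seed": config.seed}

    # -- scoring ------------------------------------------------------------
    @_stage("score")
    def stage_score():
        path = config.score_sheet or qio.fixture_path("table3.tsv")
        records = qio.read_score_sheet(path)
        qio.write_verdicts(records, outdir / "verdicts.tsv", config.dd_rule)
        summary = summarize_cohort(records, config.dd_rule)
        logger.info(
            "IVD clear: %d/%d AF, %d/%d NP; eligible: %d AF, %d NP "
            "(DD rule %s)",
            summary.n_af_clear, summary.n_af, summary.n_np_clear, summary.n_np,
            summary.n_af_eligible, summary.n_np_eligible, config.dd_rule,
        )
        return records, summary

    records, summary = stage_score()
    report["scoring"] = dataclasses.asdict(summary)

    # -- cohort selection ---------------------------------------------------
    @_stage("select")
    def stage_select():
        cohort = select_microarray_cohort(records, config.dd_rule)
        payload = dataclasses.asdict(cohort)
        payload["n_donors"] = cohort.n_donors
        (outdir / "cohort.json").write_text(
            json.dumps(payload, indent=1), encoding="utf-8"
        )
        return cohort

    cohort = stage_select()
    report["cohort"] = {
        "n_af": len(cohort.af_sample_ids),
        "n_np": len(cohort.np_sample_ids),
        "n_donors": cohort.n_donors,
        "mean_age": cohort.mean_age_rounded,
        "age_range": list(cohort.age_range),
        "female_male": [cohort.female_count, cohort.male_count],
    }

    # -- correlations -------------------------------------------------------
    @_stage("correlate")
    def stage_correlate():
        table = correlate_scores(records)
        lines = ["score\tcompartment\tcovariate\tr\tp\tn\tband"]
        cells = {}
        for (score, comp, cov), res in table.items():
            lines.append(
                f"{score}\t{comp}\t{cov}\t{res.r:.6g}\t{res.p:.6g}\t{res.n}\t{res.band}"
            )
            cells[f"{score}_{comp}_{cov}"] = {
                "r": round(res.r, 2), "p": round(res.p, 3), "band": res.band
            }
        (outdir / "correlations.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
        return cells

    report["correlations"] = stage_correlate()

    # -- DEG screen on a planted matrix --------------------------------------
    if config.simulate:
        @_stage("deg-screen")
        def stage_screen():
            sim = dataclasses.replace(config.sim, seed=config.seed)
            matrix, truth = simulate_expression(sim)
            degs = screen_degs(
                matrix, config.fc_threshold, config.consistency, config.alpha
            )
            qio.write_degs(degs, outdir / "degs.tsv")
            called = {d.gene_id for d in degs}
            planted = {
                g for g, lab in zip(matrix.gene_ids, truth.gene_labels)
                if lab != "null"
            }
            recall = len(called & planted) / len(planted) if planted else 1.0
            precision = len(called & planted) / len(called) if called else 1.0
            af_c, np_c = select_candidates(
                degs, config.criteria, matrix.detection_floor
            )
            (outdir / "candidates.json").write_text(
                json.dumps(
                    {
                        "af": [d.gene_id for d in af_c],
                        "np": [d.gene_id for d in np_c],
                    },
                    indent=1,
                ),
                encoding="utf-8",
            )
            logger.info(
                "screen: %d DEGs, recall %.3f, precision %.3f",
                len(degs), recall, precision,
            )
            return truth, {
                "n_degs": len(degs),
                "n_af_up": sum(d.direction == "AF_up" for d in degs),
                "n_np_up": sum(d.direction == "NP_up" for d in degs),
                "recall": recall,
                "precision": precision,
                "n_af_candidates": len(af_c),
                "n_np_candidates": len(np_c),
            }

        truth, screen_report = stage_screen()
        report["deg_screen"] = screen_report

    # -- marker-panel classification of the call-table ------------------------
    @_stage("panel-classify")
    def stage_panel():
        path = config.call_table or qio.fixture_path("table5.tsv")
        profiles = qio.read_call_table(path)
        result = classify_cohort(profiles, rule=config.panel_rule)
        (outdir / "panel_verdicts.tsv").write_text(
            "sample\tverdict\n"
            + "\n".join(f"{s}\t{v}" for s, v in result.verdicts)
            + "\n",
            encoding="utf-8",
        )
        return {
            "n_af_verdict": result.n_af_verdict,
            "n_np_verdict": result.n_np_verdict,
            "n_undefined": result.n_undefined,
            "confirmed_af": [result.n_confirmed_af, result.n_af_origin],
            "confirmed_np": [result.n_confirmed_np, result.n_np_origin],
        }

    report["panel"] = stage_panel()

    # -- qPCR quantification on a simulated Cq table --------------------------
    if config.simulate:
        @_stage("qpcr")
        def stage_qpcr():
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cq = simulate_qpcr(sim, truth)
            measurements = []
            groups = {}
            for _, row in cq.iterrows():
                groups[row.sample_id] = row.tissue
            qio.write_cq_table(
                [
                    m for m in (
                        _measurement_from_row(row) for _, row in cq.iterrows()
                    )
                ],
                outdir / "cq.tsv",
            )
            measurements = qio.read_cq_table(outdir / "cq.tsv")
            panel = MarkerPanel()
            assays = default_assays(panel.markers)
            table, tests = quantify_cohort(measurements, assays, panel.markers, groups)
            table.to_csv(outdir / "relative_expression.tsv", sep="\t",
                         float_format="%.6g")
            # recovered fold per NP marker vs planted
            af_ids = [s for s, g in groups.items() if g == "AF"]
            np_ids = [s for s, g in groups.items() if g == "NP"]
            recovered = {}
            for marker in panel.np_markers:
                fold = float(
                    table.loc[np_ids, marker].mean()
                    / table.loc[af_ids, marker].mean()
                )
                recovered[marker] = {
                    "planted": float(truth.marker_truth.loc[marker, "fold"]),
                    "recovered": fold,
                }
            return {
                "tests": {
                    t.marker: {"U": t.u, "p": t.p, "tier": t.tier} for t in tests
                },
                "np_marker_folds": recovered,
            }

        report["qpcr"] = stage_qpcr()

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, default=float), encoding="utf-8"
    )
    return report


def _measurement_from_row(row):
    from .qpcr import QpcrMeasurement

    reps = tuple(float(row[c]) for c in ("cq1", "cq2", "cq3") if str(row[c]).strip())
    return QpcrMeasurement(
        sample_id=row.sample_id,
        gene_id=row.gene_id,
        cq_replicates=reps,
        undetected=not reps,
    )
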