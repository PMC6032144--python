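"""Readers and writers for the delimited-text formats of the pipeline.

All tabular formats are tab-separated UTF-8 with one header row.  Floats
are written with 6 significant digits; displayed percentages as integers.
Unicode minus (U+2212) is accepted anywhere ASCII ``-`` is, since source
tables copied from typeset documents often carry it.

Packaged fixtures transcribe the study's per-sample scoring table
(``table3.tsv``) and the unknown-sample marker call table (``table5.tsv``).
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .deg_screen import CandidateCriteria, DEGRecord, ExpressionMatrix
from .errors import ValidationError
from .marker_panel import MarkerCallProfile, MarkerPanel, PanelRule
from .qpcr import QpcrAssay, QpcrMeasurement
from .scoring import SampleRecord

PathLike = Union[str, Path]

_SCORE_BASE_COLS = [
    "donor_id", "gender", "age", "sample_id", "disc_level", "mri_grade",
    "compartment",
]
_ITEM_COLS = [f"ivd_i{i}" for i in range(1, 7)] + [f"dd_i{i}" for i in range(1, 4)]
_AGG_COLS = ["ivd_total", "ivd_any_zero", "dd_total", "dd_any_two"]

_CALL_TOKENS = {"-", "+", "++", "NA"}


def _ascii_minus(s: str) -> str:
    return s.replace("−", "-")


def _parse_bool(token: str, where: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValidationError(f"{where}: cannot parse boolean {token!r}")


def _parse_int(token: str, where: str) -> int:
    try:
        return int(_ascii_minus(token.strip()))
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: cannot parse integer {token!r}") from None


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture file (``table3.tsv``, ``table5.tsv``)."""
    return Path(resources.files("discqc").joinpath("fixtures", name))


# ---------------------------------------------------------------------------
# score sheets
# ---------------------------------------------------------------------------

def read_score_sheet(path: PathLike) -> List[SampleRecord]:
    """Parse a score-sheet TSV (item-level or aggregated dialect)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValidationError(f"{path}: score sheet has no data rows")
    missing = [c for c in _SCORE_BASE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    has_items = all(c in df.columns for c in _ITEM_COLS)
    has_agg = all(c in df.columns for c in _AGG_COLS)
    if not has_items and not has_agg:
        raise ValidationError(
            f"{path}: need either item columns ({_ITEM_COLS}) or aggregated "
            f"columns ({_AGG_COLS})"
        )
    records: List[SampleRecord] = []
    seen = set()
    for i, row in df.iterrows():
        where = f"{path}:row {i + 2}"  # 1-based incl. header
        common = dict(
            donor_id=row["donor_id"].strip(),
            gender=row["gender"].strip(),
            age=_parse_int(row["age"], where),
            sample_id=_parse_int(row["sample_id"], where),
            disc_level=row["disc_level"].strip(),
            mri_grade=_parse_int(row["mri_grade"], where),
            compartment=row["compartment"].strip(),
        )
        try:
            if has_items:
                rec = SampleRecord(
                    **common,
                    ivd_items=tuple(
                        _parse_int(row[c], where) for c in _ITEM_COLS[:6]
                    ),
                    dd_items=tuple(
                        _parse_int(row[c], where) for c in _ITEM_COLS[6:]
                    ),
                )
            else:
                rec = SampleRecord(
                    **common,
                    ivd_total=_parse_int(row["ivd_total"], where),
                    ivd_any_zero=_parse_bool(row["ivd_any_zero"], where),
                    dd_total=_parse_int(row["dd_total"], where),
                    dd_any_two=_parse_bool(row["dd_any_two"], where),
                )
        except ValidationError as e:
            raise ValidationError(f"{where}: {e}") from None
        key = (rec.sample_id, rec.compartment)
        if key in seen:
            raise ValidationError(f"{where}: duplicate (sample_id, compartment) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_score_sheet(records: Sequence[SampleRecord], path: PathLike) -> None:
    """Write a score sheet; item dialect when every record has items."""
    item_dialect = all(r.ivd_items is not None and r.dd_items is not None
                       for r in records)
    rows = []
    for r in records:
        row = {
            "donor_id": r.donor_id, "gender": r.gender, "age": r.age,
            "sample_id": r.sample_id, "disc_level": r.disc_level,
            "mri_grade": r.mri_grade, "compartment": r.compartment,
        }
        if item_dialect:
            row.update({f"ivd_i{i+1}": g for i, g in enumerate(r.ivd_items)})
            row.update({f"dd_i{i+1}": g for i, g in enumerate(r.dd_items)})
        else:
            row.update(
                ivd_total=r.ivd_total,
                ivd_any_zero=str(r.ivd_any_zero).lower(),
                dd_total=r.dd_total,
                dd_any_two=str(r.dd_any_two).lower(),
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_table3() -> List[SampleRecord]:
    """The packaged per-sample scoring fixture (28 AF + 28 NP records)."""
    return read_score_sheet(fixture_path("table3.tsv"))


def write_verdicts(
    records: Sequence[SampleRecord], path: PathLike, dd_rule: str = "strict_gt3"
) -> None:
    rows = []
    for r in records:
        v = r.verdict(dd_rule)
        rows.append(
            {
                "sample_id": r.sample_id,
                "compartment": r.compartment,
                "donor_id": r.donor_id,
                "ivd_total": r.ivd_total,
                "ivd_any_zero": str(r.ivd_any_zero).lower(),
                "dd_total": r.dd_total,
                "dd_any_two": str(r.dd_any_two).lower(),
                "ivd_class": v.ivd_class,
                "dd_class": v.dd_class,
                "eligible_microarray": str(v.eligible_microarray).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    matrix_path: PathLike,
    groups_path: PathLike,
    detection_path: Optional[PathLike] = None,
    probes_path: Optional[PathLike] = None,
    detection_floor: float = 100.0,
) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from its TSV/JSON parts.

    The matrix TSV has ``gene_id`` plus one column per chip; the optional
    detection TSV mirrors it with ``detected``/``not_detected`` tokens; the
    optional probe TSV is long format (gene_id, chip_id, p1..pP).
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    with open(groups_path, encoding="utf-8") as fh:
        groups = json.load(fh)
    gene_ids = [str(g) for g in df.index]
    chip_ids = [str(c) for c in df.columns]
    detection = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col="gene_id")
        if list(det.index) != gene_ids or list(det.columns) != chip_ids:
            raise ValidationError("detection table does not match the signal matrix")
        bad = set(np.unique(det.values)) - {"detected", "not_detected"}
        if bad:
            raise ValidationError(f"unknown detection tokens: {sorted(bad)}")
        detection = det.values == "detected"
    probes = None
    if probes_path is not None:
        pl = pd.read_csv(probes_path, sep="\t")
        pcols = [c for c in pl.columns if c.startswith("p")]
        pl = pl.set_index(["gene_id", "chip_id"])
        probes = np.empty((len(gene_ids), len(chip_ids), len(pcols)))
        for gi, g in enumerate(gene_ids):
            for ci, c in enumerate(chip_ids):
                probes[gi, ci] = pl.loc[(g, c), pcols].to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        chip_ids=chip_ids,
        groups={str(k): str(v) for k, v in groups.items()},
        signal=df.to_numpy(dtype=float),
        probe_signals=probes,
        detection=detection,
        detection_floor=detection_floor,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, outdir: PathLike, prefix: str = "expression"
) -> Dict[str, Path]:
    """Write signal/groups (+ detection, probes when present); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    sig = pd.DataFrame(
        matrix.signal, index=pd.Index(matrix.gene_ids, name="gene_id"),
        columns=matrix.chip_ids,
    )
    paths["matrix"] = outdir / f"{prefix}_signal.tsv"
    sig.to_csv(paths["matrix"], sep="\t", float_format="%.6g")
    paths["groups"] = outdir / f"{prefix}_groups.json"
    paths["groups"].write_text(json.dumps(matrix.groups, indent=1), encoding="utf-8")
    det = pd.DataFrame(
        np.where(matrix.detection, "detected", "not_detected"),
        index=pd.Index(matrix.gene_ids, name="gene_id"),
        columns=matrix.chip_ids,
    )
    paths["detection"] = outdir / f"{prefix}_detection.tsv"
    det.to_csv(paths["detection"], sep="\t")
    if matrix.probe_signals is not None:
        G, C, P = matrix.probe_signals.shape
        long = pd.DataFrame(
            matrix.probe_signals.reshape(G * C, P),
            columns=[f"p{i+1}" for i in range(P)],
        )
        long.insert(0, "chip_id", np.tile(matrix.chip_ids, G))
        long.insert(0, "gene_id", np.repeat(matrix.gene_ids, C))
        paths["probes"] = outdir / f"{prefix}_probes.tsv"
        long.to_csv(paths["probes"], sep="\t", index=False, float_format="%.6g")
    return paths


def write_degs(degs: Sequence[DEGRecord], path: PathLike) -> None:
    rows = [vars(d) for d in degs]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "direction", "fc_mean", "fc_sd", "change_pct",
            "detection_pct_af", "detection_pct_np", "p_median",
            "signal_mean_af", "signal_mean_np",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_degs(path: PathLike) -> List[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    return [DEGRecord(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()]


def read_criteria(path: PathLike) -> CandidateCriteria:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    known = set(CandidateCriteria.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown criteria keys {sorted(unknown)}")
    if "exclusion_list" in raw:
        raw["exclusion_list"] = frozenset(raw["exclusion_list"])
    return CandidateCriteria(**raw)


# ---------------------------------------------------------------------------
# marker panels and call tables
# ---------------------------------------------------------------------------

def write_panel(panel: MarkerPanel, path: PathLike) -> None:
    payload = {
        "af_markers": list(panel.af_markers),
        "np_markers": list(panel.np_markers),
        "ranges": {m: list(r) for m, r in panel.ranges.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_panel(path: PathLike) -> MarkerPanel:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return MarkerPanel(
        af_markers=tuple(raw["af_markers"]),
        np_markers=tuple(raw["np_markers"]),
        ranges={m: (float(lo), float(hi)) for m, (lo, hi) in
                raw.get("ranges", {}).items()},
    )


def read_rule(path: PathLike) -> PanelRule:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    known = set(PanelRule.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown rule keys {sorted(unknown)}")
    return PanelRule(**raw)


def read_call_table(
    path: PathLike, panel: Optional[MarkerPanel] = None
) -> List[MarkerCallProfile]:
    """Parse a call-table TSV (origin, sample_id, one column per marker)."""
    panel = panel or MarkerPanel()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("origin", "sample_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    marker_cols = [c for c in df.columns if c not in ("origin", "sample_id")]
    unknown = set(marker_cols) - set(panel.markers)
    if unknown:
        raise ValidationError(
            f"{path}: columns {sorted(unknown)} are not markers of the panel"
        )
    profiles = []
    for i, row in df.iterrows():
        calls = {}
        for m in marker_cols:
            token = _ascii_minus(row[m].strip())
            if token not in _CALL_TOKENS:
                raise ValidationError(
                    f"{path}:row {i + 2}: unknown call token {row[m]!r} for {m}"
                )
            calls[m] = token
        profiles.append(
            MarkerCallProfile(
                sample_id=row["sample_id"].strip(),
                calls=calls,
                origin=row["origin"].strip() or None,
            )
        )
    return profiles


def write_call_table(
    profiles: Sequence[MarkerCallProfile],
    path: PathLike,
    panel: Optional[MarkerPanel] = None,
) -> None:
    panel = panel or MarkerPanel()
    rows = []
    for p in profiles:
        row = {"origin": p.origin or "", "sample_id": p.sample_id}
        for m in panel.markers:
            row[m] = p.calls.get(m, "NA")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_table5() -> List[MarkerCallProfile]:
    """The packaged unknown-sample call-table fixture (16 profiles)."""
    return read_call_table(fixture_path("table5.tsv"))


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def write_assays(assays: Mapping[str, QpcrAssay], path: PathLike) -> None:
    payload = [
        {"gene_id": a.gene_id, "efficiency": a.efficiency,
         "is_reference": a.is_reference}
        for a in assays.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_assays(path: PathLike) -> Dict[str, QpcrAssay]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        a["gene_id"]: QpcrAssay(
            gene_id=a["gene_id"],
            efficiency=float(a.get("efficiency", 2.0)),
            is_reference=bool(a.get("is_reference", False)),
        )
        for a in raw
    }


def read_cq_table(path: PathLike) -> List[QpcrMeasurement]:
    """Parse a Cq TSV (sample_id, gene_id, cq1..cq3; blank cell = missing).

    A row with every replicate blank is an undetected measurement (no
    amplification).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "gene_id", "cq1", "cq2", "cq3"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for i, row in df.iterrows():
        reps = []
        for col in ("cq1", "cq2", "cq3"):
            token = _ascii_minus(row[col].strip())
            if token:
                try:
                    reps.append(float(token))
                except ValueError:
                    raise ValidationError(
                        f"{path}:row {i + 2}: cannot parse Cq {row[col]!r}"
                    ) from None
        out.append(
            QpcrMeasurement(
                sample_id=row["sample_id"].strip(),
                gene_id=row["gene_id"].strip(),
                cq_replicates=tuple(reps),
                undetected=not reps,
            )
        )
    return out


def write_cq_table(measurements: Sequence[QpcrMeasurement], path: PathLike) -> None:
    rows = []
    for m in measurements:
        reps = list(m.cq_replicates) + [None] * (3 - len(m.cq_replicates))
        rows.append(
            {
                "sample_id": m.sample_id,
                "gene_id": m.gene_id,
                **{
                    f"cq{i+1}": ("" if r is None or m.undetected else f"{r:.6g}")
                    for i, r in enumerate(reps)
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
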