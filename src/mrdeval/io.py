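"""Reading and writing the delimited measurement tables and run reports.

The canonical measurement table is comma-separated UTF-8 with a
mandatory header (TSV is auto-detected).  Columns: ``patient_id``,
``assay`` (NGS|MFC), ``cells_assayed``, ``tumor_count``, optional
``tumor_load``, ``response``, ``timepoint``.  Numeric fields accept
plain integers, scientific notation ("1.1e6") and the typeset form
"1.1 × 10^6".  One row per (patient, assay); the two assay rows of a
patient are merged into one :class:`PatientRecord`.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .core_metrics import (
    Assay,
    AssayConstants,
    AssayMeasurement,
    DEFAULT_CONSTANTS,
    ValidationError,
    compute_metrics,
)
from .cohort_analysis import (
    ConcordanceResult,
    PatientRecord,
    Response,
    SweepResult,
    Timepoint,
    TLComparison,
)
from .status_engine import MRDCall, MRDCutoff, MRDStatus

logger = logging.getLogger(__name__)

__all__ = [
    "read_measurements",
    "write_measurements",
    "write_report",
    "parse_number",
]

REQUIRED_COLUMNS = ("patient_id", "assay", "cells_assayed", "tumor_count")

# "1.1 × 10^6", "1.1 x 10^-5", with or without the caret
_TYPESET_RE = re.compile(
    r"^\s*([0-9.]+)\s*[×x]\s*10\s*\^?\s*(?:\((−?-?[0-9]+)\)|(−?-?[0-9]+))\s*$"
)


def parse_number(token: str) -> float:
    """Parse a numeric field: plain, e-notation or '1.1 × 10^6' form."""
    token = token.strip().replace("−", "-")
    m = _TYPESET_RE.match(token)
    if m:
        mantissa = float(m.group(1))
        exponent = int(m.group(2) or m.group(3))
        return mantissa * 10.0**exponent
    return float(token)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_measurements(path: Union[str, Path]) -> List[PatientRecord]:
    """Read a measurement table into validated patient records.

    Rows violating an invariant (e.g. tumor_count > cells_assayed,
    unknown assay or response token) raise :class:`ValidationError`
    carrying the offending line number.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    partial: Dict[str, dict] = {}
    order: List[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        missing = set(REQUIRED_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValidationError(
                f"{path}: missing mandatory column(s) {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["patient_id"].strip()
                assay = Assay(row["assay"].strip().upper())
                tl_raw = (row.get("tumor_load") or "").strip()
                count_raw = (row.get("tumor_count") or "").strip()
                m = AssayMeasurement(
                    patient_id=pid,
                    assay=assay,
                    cells_assayed=int(round(parse_number(row["cells_assayed"]))),
                    tumor_count=(
                        int(round(parse_number(count_raw))) if count_raw else None
                    ),
                    tumor_load_override=parse_number(tl_raw) if tl_raw else None,
                )
                response = Response((row.get("response") or "NA").strip() or "NA")
                timepoint = Timepoint(
                    (row.get("timepoint") or "NA").strip() or "NA"
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            slot = partial.setdefault(
                pid, {"response": response, "timepoint": timepoint}
            )
            if pid not in order:
                order.append(pid)
            key = "ngs" if assay is Assay.NGS else "mfc"
            if key in slot:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate {assay.value} row for patient {pid}"
                )
            slot[key] = m
    return [
        PatientRecord(
            patient_id=pid,
            ngs=partial[pid].get("ngs"),
            mfc=partial[pid].get("mfc"),
            response=partial[pid]["response"],
            timepoint=partial[pid]["timepoint"],
        )
        for pid in order
    ]


def write_measurements(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write patient records back to the canonical CSV dialect."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "patient_id",
                "assay",
                "cells_assayed",
                "tumor_count",
                "tumor_load",
                "response",
                "timepoint",
            ]
        )
        for rec in records:
            for m in (rec.ngs, rec.mfc):
                if m is None:
                    continue
                writer.writerow(
                    [
                        m.patient_id,
                        m.assay.value,
                        m.cells_assayed,
                        "" if m.tumor_count is None else m.tumor_count,
                        "" if m.tumor_load_override is None else repr(m.tumor_load_override),
                        rec.response.value,
                        rec.timepoint.value,
                    ]
                )


def _pct(x: Optional[float]) -> str:
    return "" if x is None else f"{100 * x:.1f}"


def write_report(
    out_dir: Union[str, Path],
    *,
    calls: Sequence[MRDCall] = (),
    sweep: Optional[SweepResult] = None,
    conc: Optional[ConcordanceResult] = None,
    stratified: Optional[dict] = None,
    tl_comparison: Optional[TLComparison] = None,
    config: Optional[dict] = None,
) -> List[Path]:
    """Emit the standard report files for whichever analyses were run.

    Writes calls.csv, sweep.csv, concordance.json, stratified.csv and
    tl_comparison.json as applicable, plus run_metadata.json (version,
    config hash, timestamp).  CSV proportions are percentages to one
    decimal; JSON carries full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    if calls:
        p = out_dir / "calls.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "patient_id",
                    "assay",
                    "cutoff",
                    "tl",
                    "lod",
                    "loq",
                    "status",
                    "tl_quantifiable",
                    "rule_fired",
                ]
            )
            for call in calls:
                w.writerow(
                    [
                        call.patient_id or "",
                        call.assay or "",
                        f"{call.cutoff.value:g}",
                        repr(call.metrics.tumor_load),
                        repr(call.metrics.lod),
                        repr(call.metrics.loq),
                        call.status.value,
                        call.tl_quantifiable.value,
                        call.rule_fired.value,
                    ]
                )
        written.append(p)

    if sweep is not None:
        p = out_dir / "sweep.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["assay", "cutoff", "status", "count", "percent_of_cohort"]
            )
            for (assay, cutoff), tally in sorted(
                sweep.counts.items(), key=lambda kv: (kv[0][0].value, -kv[0][1])
            ):
                n = sweep.n_cohort[assay]
                for status in MRDStatus:
                    w.writerow(
                        [
                            assay.value,
                            f"{cutoff:g}",
                            status.value,
                            tally[status],
                            _pct(tally[status] / n) if n else "",
                        ]
                    )
        written.append(p)

    if conc is not None:
        p = out_dir / "concordance.json"
        p.write_text(json.dumps(conc.as_dict(), indent=2))
        written.append(p)

    if stratified is not None:
        p = out_dir / "stratified.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "assay",
                    "response",
                    "n",
                    "n_negative",
                    "n_positive",
                    "n_nonassessable",
                    "percent_negative",
                ]
            )
            for (assay, resp), row in stratified["strata"].items():
                props = row["proportions"]
                w.writerow(
                    [
                        assay.value,
                        resp.value,
                        row["n"],
                        row["counts"][MRDStatus.NEGATIVE],
                        row["counts"][MRDStatus.POSITIVE],
                        row["counts"][MRDStatus.NONASSESSABLE],
                        _pct(props[MRDStatus.NEGATIVE] if props else None),
                    ]
                )
            for assay, agg in stratified["vgpr_or_better"].items():
                w.writerow(
                    [
                        assay.value,
                        ">=VGPR",
                        agg["n"],
                        agg["n_negative"],
                        "",
                        "",
                        _pct(agg["negativity_rate"]),
                    ]
                )
        written.append(p)

    if tl_comparison is not None:
        p = out_dir / "tl_comparison.json"
        p.write_text(json.dumps(tl_comparison.as_dict(), indent=2))
        written.append(p)

    meta = {
        "package": "mrdeval",
        "version": _version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config or {},
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    p = out_dir / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, default=str))
    written.append(p)
    return written


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("mrdeval")
    except Exception:  # pragma: no cover - uninstalled source tree
        return "unknown"
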