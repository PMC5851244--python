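"""Cohort and grouped-table I/O, eligibility filtering, and the embedded
reference fixture.

The cohort CSV schema is one flat row per measurement:

    id, outcome, sbp, rr, hr, temp, map, avpu, lactate, wbc, paco2,
    platelets, bilirubin, creatinine, pf_ratio, vasopressor,
    source_uncontrolled

Blank cells are missing values, never zero. Repeated measurements for the
same patient appear as multiple rows and are reduced per field, by default
to the most abnormal value in the scoring direction (severity scores are
conventionally computed on worst values during the stay). Records without
any lactate measurement are excluded with reason ``MISSING_LACTATE``;
records flagged ``source_uncontrolled`` are excluded with reason
``SOURCE_UNCONTROLLED``.

The reference fixture embeds the published grouped score-by-outcome count
tables of a 457-patient surgical ED cohort (50 in-hospital deaths): the
qSOFA, qSOFA+lactate and binary-lactate distributions per outcome class,
shipped as TSV files under ``sepscore/data``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diagnostics import GroupedScoreTable
from .errors import CohortParseError
from .scores import (LabPanel, MentalStatus, Outcome, PatientRecord, Vasopressor,
                     VitalSigns)

logger = logging.getLogger(__name__)

__all__ = [
    "Reduction",
    "ExclusionReason",
    "CohortFile",
    "Table2Fixture",
    "read_cohort",
    "write_cohort",
    "expand_grouped",
    "tabulate",
    "table2_fixture",
    "read_grouped_tsv",
    "write_grouped_tsv",
    "write_report",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "id", "outcome", "sbp", "rr", "hr", "temp", "map", "avpu", "lactate",
    "wbc", "paco2", "platelets", "bilirubin", "creatinine", "pf_ratio",
    "vasopressor", "source_uncontrolled",
]

_NUMERIC = ["sbp", "rr", "hr", "temp", "map", "lactate", "wbc", "paco2",
            "platelets", "bilirubin", "creatinine", "pf_ratio"]

_AVPU = {"A": "ALERT", "V": "VERBAL", "P": "PAIN", "U": "UNRESPONSIVE"}

_VASO_SEVERITY = {v: i for i, v in enumerate(Vasopressor)}


class Reduction(Enum):
    """How to collapse repeated measurements per patient: FIRST row wins,
    or WORST = most abnormal in the scoring direction of each field."""

    FIRST = "FIRST"
    WORST = "WORST"


class ExclusionReason(Enum):
    MISSING_LACTATE = "MISSING_LACTATE"
    SOURCE_UNCONTROLLED = "SOURCE_UNCONTROLLED"


@dataclass(frozen=True)
class CohortFile:
    """Parsed cohort: eligible records plus the excluded ids with
    machine-readable reasons. Records and exclusions are disjoint."""

    records: tuple[PatientRecord, ...]
    exclusions: tuple[tuple[str, ExclusionReason], ...]

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Table2Fixture:
    """The published grouped distributions of the reference cohort."""

    qsofa_table: GroupedScoreTable
    qsofa_lactate_table: GroupedScoreTable
    lactate_binary_table: GroupedScoreTable
    n_total: int = 457
    n_pos: int = 50
    n_neg: int = 407

    def __post_init__(self) -> None:
        for t in (self.qsofa_table, self.qsofa_lactate_table, self.lactate_binary_table):
            assert t.n_pos == self.n_pos and t.n_neg == self.n_neg


def _parse_outcome(raw: str, line: int) -> Outcome:
    v = raw.strip().lower()
    if v in ("survived", "0"):
        return Outcome.SURVIVED
    if v in ("died", "1"):
        return Outcome.DIED
    raise CohortParseError(line, f"unknown outcome label {raw!r}")


def _worst(field: str, values: list) -> object:
    """Most abnormal value in the direction the scores penalise."""
    if field in ("sbp", "map", "platelets", "pf_ratio", "paco2"):
        return min(values)
    if field in ("rr", "hr", "lactate", "bilirubin", "creatinine"):
        return max(values)
    if field == "temp":
        return max(values, key=lambda t: abs(t - 37.0))
    if field == "wbc":
        return max(values, key=lambda w: abs(w - 8.0))
    if field == "avpu":
        order = ["ALERT", "VERBAL", "PAIN", "UNRESPONSIVE"]
        return max(values, key=order.index)
    if field == "vasopressor":
        return max(values, key=lambda v: _VASO_SEVERITY[Vasopressor(v)])
    raise KeyError(field)


def _build_record(pid: str, rows: list[dict], reduction: Reduction) -> PatientRecord:
    def collect(field):
        vals = [r[field] for r in rows if r[field] is not None]
        if not vals:
            return None
        if reduction is Reduction.FIRST:
            return vals[0]
        return _worst(field, vals)

    avpu = collect("avpu")
    mental = MentalStatus(avpu) if avpu else MentalStatus.ALERT
    vaso_raw = collect("vasopressor")
    return PatientRecord(
        id=pid,
        outcome=rows[0]["outcome"],
        vitals=VitalSigns(sbp=collect("sbp"), rr=collect("rr"), hr=collect("hr"),
                          temp=collect("temp"), map=collect("map")),
        labs=LabPanel(lactate=collect("lactate"), wbc=collect("wbc"),
                      paco2=collect("paco2"), platelets=collect("platelets"),
                      bilirubin=collect("bilirubin"), creatinine=collect("creatinine"),
                      pf_ratio=collect("pf_ratio"),
                      vasopressor=Vasopressor(vaso_raw) if vaso_raw else None),
        mental=mental,
    )


def read_cohort(path: str | Path, reduction: Reduction = Reduction.WORST) -> CohortFile:
    """Read a cohort CSV into one record per patient id.

    Repeated rows per id are reduced per field (default WORST = most
    abnormal). Records without lactate go to exclusions with reason
    MISSING_LACTATE; rows flagged source_uncontrolled=1 exclude the whole
    id with reason SOURCE_UNCONTROLLED. An empty file yields an empty
    cohort. Malformed rows raise :class:`CohortParseError` with the line
    number.
    """
    path = Path(path)
    by_id: dict[str, list[dict]] = {}
    uncontrolled: set[str] = set()
    order: list[str] = []

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return CohortFile(records=(), exclusions=())
        unknown = set(reader.fieldnames) - set(COHORT_COLUMNS)
        if unknown:
            raise CohortParseError(1, f"unknown columns: {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            pid = (row.get("id") or "").strip()
            if not pid:
                raise CohortParseError(lineno, "missing id")
            parsed: dict = {"outcome": _parse_outcome(row.get("outcome") or "", lineno)}
            for f in _NUMERIC:
                raw = (row.get(f) or "").strip()
                if raw == "":
                    parsed[f] = None
                else:
                    try:
                        parsed[f] = float(raw)
                    except ValueError:
                        raise CohortParseError(lineno, f"non-numeric {f}={raw!r}") from None
            avpu_raw = (row.get("avpu") or "").strip().upper()
            if avpu_raw in _AVPU:
                parsed["avpu"] = _AVPU[avpu_raw]
            elif avpu_raw in _AVPU.values() or avpu_raw == "":
                parsed["avpu"] = avpu_raw or None
            else:
                raise CohortParseError(lineno, f"unknown AVPU level {avpu_raw!r}")
            vaso_raw = (row.get("vasopressor") or "").strip().upper()
            if vaso_raw:
                try:
                    Vasopressor(vaso_raw)
                except ValueError:
                    raise CohortParseError(lineno, f"unknown vasopressor class {vaso_raw!r}") from None
                parsed["vasopressor"] = vaso_raw
            else:
                parsed["vasopressor"] = None
            flag = (row.get("source_uncontrolled") or "").strip()
            if flag in ("1", "true", "True", "yes"):
                uncontrolled.add(pid)
            if pid not in by_id:
                by_id[pid] = []
                order.append(pid)
            else:
                if by_id[pid][0]["outcome"] is not parsed["outcome"]:
                    raise CohortParseError(lineno, f"conflicting outcome for id {pid!r}")
            by_id[pid].append(parsed)

    records: list[PatientRecord] = []
    exclusions: list[tuple[str, ExclusionReason]] = []
    for pid in order:
        if pid in uncontrolled:
            exclusions.append((pid, ExclusionReason.SOURCE_UNCONTROLLED))
            continue
        rec = _build_record(pid, by_id[pid], reduction)
        if rec.labs.lactate is None:
            exclusions.append((pid, ExclusionReason.MISSING_LACTATE))
        else:
            records.append(rec)

    logger.info("read %s: %d ids -> %d records, %d exclusions (%s)",
                path, len(order), len(records), len(exclusions),
                ", ".join(sorted({r.value for _, r in exclusions})) or "none")
    return CohortFile(records=tuple(records), exclusions=tuple(exclusions))


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records as the cohort CSV schema (one row per record)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for r in records:
            def fmt(v):
                return "" if v is None else (f"{v:g}" if isinstance(v, float) else str(v))
            w.writerow([
                r.id,
                "died" if r.outcome is Outcome.DIED else "survived",
                fmt(r.vitals.sbp), fmt(r.vitals.rr), fmt(r.vitals.hr),
                fmt(r.vitals.temp), fmt(r.vitals.map),
                r.mental.value,
                fmt(r.labs.lactate), fmt(r.labs.wbc), fmt(r.labs.paco2),
                fmt(r.labs.platelets), fmt(r.labs.bilirubin),
                fmt(r.labs.creatinine), fmt(r.labs.pf_ratio),
                r.labs.vasopressor.value if r.labs.vasopressor else "",
                "",
            ])


def expand_grouped(table: GroupedScoreTable) -> tuple[np.ndarray, np.ndarray]:
    """Expand a grouped table into per-record (score, label) arrays.

    Deterministic order: ascending level, negatives before positives.
    Tabulating the result reproduces the table exactly.
    """
    scores: list[float] = []
    labels: list[int] = []
    for level, cp, cn in zip(table.levels, table.counts_pos, table.counts_neg):
        scores.extend([level] * cn)
        labels.extend([0] * cn)
        scores.extend([level] * cp)
        labels.extend([1] * cp)
    return np.array(scores, dtype=float), np.array(labels, dtype=int)


def tabulate(scores: Sequence[float], labels: Sequence[int]) -> GroupedScoreTable:
    """Inverse of :func:`expand_grouped`: count records per (level, class)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    levels = np.unique(s)
    cp = tuple(int(np.sum((s == lv) & (y == 1))) for lv in levels)
    cn = tuple(int(np.sum((s == lv) & (y == 0))) for lv in levels)
    return GroupedScoreTable(levels=tuple(float(lv) for lv in levels),
                             counts_pos=cp, counts_neg=cn)


def read_grouped_tsv(path: str | Path) -> GroupedScoreTable:
    """Read a 3-column grouped-count TSV: level, count_survivor,
    count_nonsurvivor, with a one-line header."""
    df = pd.read_csv(path, sep="\t")
    expected = ["level", "count_survivor", "count_nonsurvivor"]
    if list(df.columns) != expected:
        raise CohortParseError(1, f"expected header {expected}, got {list(df.columns)}")
    return GroupedScoreTable(
        levels=tuple(float(v) for v in df["level"]),
        counts_pos=tuple(int(v) for v in df["count_nonsurvivor"]),
        counts_neg=tuple(int(v) for v in df["count_survivor"]),
    )


def write_grouped_tsv(table: GroupedScoreTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("level\tcount_survivor\tcount_nonsurvivor\n")
        for lv, cp, cn in zip(table.levels, table.counts_pos, table.counts_neg):
            lv_str = f"{int(lv)}" if float(lv).is_integer() else f"{lv:g}"
            fh.write(f"{lv_str}\t{cn}\t{cp}\n")


def table2_fixture() -> Table2Fixture:
    """The embedded reference-cohort grouped distributions (457 patients,
    50 non-survivors), loaded from the committed TSV fixtures."""
    base = resources.files("sepscore.data")

    def load(name: str) -> GroupedScoreTable:
        with resources.as_file(base.joinpath(name)) as p:
            return read_grouped_tsv(p)

    return Table2Fixture(
        qsofa_table=load("qsofa_by_outcome.tsv"),
        qsofa_lactate_table=load("qsofa_lactate_by_outcome.tsv"),
        lactate_binary_table=load("lactate_binary_by_outcome.tsv"),
    )


class ReportFormat(Enum):
    JSON = "JSON"
    CSV = "CSV"
    MARKDOWN = "MARKDOWN"


def write_report(metrics: dict, path: str | Path, format: ReportFormat = ReportFormat.JSON) -> None:
    """Write a metric panel (as produced by ``MetricPanel.to_dict``) in a
    stable, diff-friendly form: one row per score with sensitivity,
    specificity and AUROC plus their CIs. Bit-stable for fixed input."""
    path = Path(path)
    rows = metrics.get("scores", {})
    if format is ReportFormat.JSON:
        with path.open("w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    header = ["score", "sensitivity_pct", "sens_ci", "specificity_pct",
              "spec_ci", "auroc", "auroc_ci"]
    lines: list[list[str]] = []
    for name in sorted(rows):
        r = rows[name]
        if r.get("unavailable"):
            lines.append([name, "NA", "NA", "NA", "NA", "NA", "NA"])
            continue
        lines.append([
            name,
            str(r["sensitivity_pct"]),
            f"{r['sens_ci_pct'][0]}-{r['sens_ci_pct'][1]}",
            str(r["specificity_pct"]),
            f"{r['spec_ci_pct'][0]}-{r['spec_ci_pct'][1]}",
            f"{r['auroc']:.3f}",
            f"{r['auroc_ci'][0]:.3f}-{r['auroc_ci'][1]:.3f}",
        ])
    if format is ReportFormat.CSV:
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(lines)
    else:
        with path.open("w") as fh:
            fh.write("| " + " | ".join(header) + " |\n")
            fh.write("|" + "---|" * len(header) + "\n")
            for line in lines:
                fh.write("| " + " | ".join(line) + " |\n")
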