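"""Cohort CSV round-trip and report serialisation.

The cohort data dictionary (one row per patient, empty string = missing):

============================  ======================================================
column                        contents
============================  ======================================================
patient_id                    opaque identifier
age_dx                        age at diagnosis, years
psa                           PSA, ng/ml
t_stage                       T1 | T2 | T3 | T4
grade_group                   1..5
ppc                           proportion of positive biopsy cores, 0..1
treatment                     conservative | prostatectomy | radiotherapy | adt
conservative_subtype          active_surveillance | watchful_waiting | other_conservative
comorbid                      true | false
metastatic                    true | false
dx_date                       ISO-8601 date
followup_years                years from diagnosis, >= 0
event                         pca_death | other_death | censored
============================  ======================================================
"""

from __future__ import annotations

import csv
import datetime
import json
from pathlib import Path
from typing import Optional, Sequence

from .cohort import ConservativeSubtype, Event, PatientRecord, Treatment

COHORT_COLUMNS = [
    "patient_id",
    "age_dx",
    "psa",
    "t_stage",
    "grade_group",
    "ppc",
    "treatment",
    "conservative_subtype",
    "comorbid",
    "metastatic",
    "dx_date",
    "followup_years",
    "event",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


class CohortSchemaError(ValueError):
    pass


def _parse_optional(raw: str, parser, column: str, row_num: int):
    if raw == "":
        return None
    try:
        return parser(raw)
    except (ValueError, KeyError) as exc:
        raise CohortSchemaError(
            f"row {row_num}: bad value {raw!r} in column {column!r}: {exc}"
        ) from exc


def _parse_bool(raw: str) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise ValueError(f"expected true/false, got {raw!r}")


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV into PatientRecords (missing fields -> None)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [c for c in header if c not in COHORT_COLUMNS]
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if unknown or missing:
            raise CohortSchemaError(
                f"cohort CSV schema mismatch: unknown columns {unknown}, "
                f"missing columns {missing}; expected exactly {COHORT_COLUMNS}"
            )
        for row_num, row in enumerate(reader, start=2):
            try:
                records.append(
                    PatientRecord(
                        patient_id=row["patient_id"],
                        age_dx=_parse_optional(row["age_dx"], float, "age_dx", row_num),
                        psa=_parse_optional(row["psa"], float, "psa", row_num),
                        t_stage=row["t_stage"] or None,
                        grade_group=_parse_optional(
                            row["grade_group"], int, "grade_group", row_num
                        ),
                        ppc=_parse_optional(row["ppc"], float, "ppc", row_num),
                        treatment=_parse_optional(
                            row["treatment"], Treatment, "treatment", row_num
                        ),
                        conservative_subtype=_parse_optional(
                            row["conservative_subtype"],
                            ConservativeSubtype,
                            "conservative_subtype",
                            row_num,
                        ),
                        comorbid=_parse_optional(
                            row["comorbid"], _parse_bool, "comorbid", row_num
                        ),
                        metastatic=_parse_optional(
                            row["metastatic"], _parse_bool, "metastatic", row_num
                        ),
                        dx_date=_parse_optional(
                            row["dx_date"], datetime.date.fromisoformat, "dx_date", row_num
                        ),
                        followup_years=_parse_optional(
                            row["followup_years"], float, "followup_years", row_num
                        ),
                        event=_parse_optional(row["event"], Event, "event", row_num),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, CohortSchemaError):
                    raise
                raise CohortSchemaError(f"row {row_num}: {exc}") from exc
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (Treatment, ConservativeSubtype, Event)):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    """Write a cohort CSV; float fields use repr for lossless round-trip."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in cohort:
            writer.writerow([_fmt(getattr(rec, col)) for col in COHORT_COLUMNS])


# ---------------------------------------------------------------------------
# Report rendering (pure views over the report dict)
# ---------------------------------------------------------------------------


def write_report(report, out_dir) -> list[Path]:
    """Write report JSON plus CSV views (discrimination table, subgroup
    calibration table, per-quintile calibration-curve data).

    Every CSV number is copied from the report JSON; the renderers do no
    arithmetic of their own.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = report.as_dict() if hasattr(report, "as_dict") else dict(report)
    written = []

    p = out_dir / "report.json"
    with open(p, "w") as fh:
        json.dump(d, fh, indent=2)
    written.append(p)

    p = out_dir / "discrimination.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["outcome", "group_or_system", "tool", "c", "se", "ci_lo", "ci_hi", "p_vs_model"])
        for oc, per_group in d["concordance"].items():
            for grp, r in per_group.items():
                w.writerow([oc, grp, "model", r["c"], r["se"], r["ci95"][0], r["ci95"][1], ""])
        for system, per_oc in d["comparators"].items():
            for oc, r in per_oc.items():
                w.writerow([oc, "overall", system, r["c_b"], "", "", "", r["p"]])
    written.append(p)

    p = out_dir / "subgroup_calibration.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "outcome", "n", "observed", "expected", "oe", "percent_difference"])
        for r in d["subgroups"]["rows"]:
            w.writerow(
                [r["group"], r["outcome"], r["n"], r["observed"], r["expected"], r["oe"], r["percent_difference"]]
            )
    written.append(p)

    p = out_dir / "calibration_curve.csv"
    with open(p, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["outcome", "group", "n", "observed", "expected", "observed_prob", "expected_prob", "chi_square", "df", "p"]
        )
        for oc, table in d["quintiles"].items():
            for r in table["rows"]:
                w.writerow(
                    [
                        oc,
                        r["group"],
                        r["n"],
                        r["observed"],
                        r["expected"],
                        r["observed"] / r["n"] if r["n"] else "",
                        r["expected"] / r["n"] if r["n"] else "",
                        table["chi_square"],
                        table["df"],
                        table["p"],
                    ]
                )
    written.append(p)
    return written
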