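"""Ordinal comparator risk classifiers: CAPRA-style points, a 3-stratum
EAU-style grouping and an NCCN-style 4-stratum table.

The schedules ship as configuration with documented defaults. Two
imputations are hard-wired as defaults because the registry variables
require them: clinical stage T2 without sub-stage is read as T2a, and an
unknown proportion of positive cores scores in the < 34% band.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

from .cohort import PatientRecord

SYSTEMS = ("capra", "eau", "nccn")

#: grade group -> (primary, secondary) Gleason pattern used by point schedules
GG_TO_GLEASON = {1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}

EAU_LABELS = ("low", "intermediate", "high")
NCCN_LABELS = ("low", "intermediate", "high", "very_high")


@dataclass(frozen=True)
class RiskGroupLabel:
    """Ordinal classification under one comparator system."""

    system: str
    value: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")
        if self.value < 0:
            raise ValueError("ordinal value must be >= 0")


def default_schedule(system: str) -> dict:
    """Bundled default configuration for one comparator system."""
    path = resources.files("crval.data").joinpath(f"{system}.json")
    return json.loads(path.read_text())


def _check_basics(rec: PatientRecord, need_age: bool = True) -> None:
    missing = []
    if need_age and rec.age_dx is None:
        missing.append("age_dx")
    for f in ("psa", "grade_group", "t_stage"):
        if getattr(rec, f) is None:
            missing.append(f)
    if missing:
        raise ValueError(f"patient {rec.patient_id}: missing {', '.join(missing)}")
    if rec.psa is not None and rec.psa <= 0:
        raise ValueError(f"patient {rec.patient_id}: PSA must be > 0")
    if rec.grade_group is not None and not 1 <= rec.grade_group <= 5:
        raise ValueError(f"patient {rec.patient_id}: grade group outside 1-5")


def _band_points(value: float, bands: Sequence[Mapping]) -> int:
    """Points from ordered (upper-bound, points) bands; last band open."""
    for band in bands:
        upper = band.get("upper")
        if upper is None or value <= upper:
            return int(band["points"])
    raise ValueError("band table exhausted")  # pragma: no cover


def capra_score(
    record: PatientRecord, schedule: Optional[Mapping] = None
) -> RiskGroupLabel:
    """CAPRA-style point total over age, PSA, Gleason patterns, stage and
    biopsy involvement.

    Missing PPC scores as the < 34% band; grade groups are mapped to
    (primary, secondary) Gleason patterns before scoring.
    """
    schedule = schedule or default_schedule("capra")
    _check_basics(record, need_age=True)

    pts = 0
    pts += int(schedule["age_points_ge_cutoff"]) if record.age_dx >= schedule["age_cutoff"] else 0
    pts += _band_points(record.psa, schedule["psa_bands"])
    primary, secondary = GG_TO_GLEASON[record.grade_group]
    if primary >= 4:
        pts += int(schedule["gleason_primary_45_points"])
    elif secondary >= 4:
        pts += int(schedule["gleason_secondary_45_points"])
    if record.t_stage in schedule["stage_high_bands"]:
        pts += int(schedule["stage_high_points"])
    ppc = record.ppc  # None -> low band per default imputation
    if ppc is not None and ppc >= schedule["ppc_cutoff"]:
        pts += int(schedule["ppc_high_points"])
    return RiskGroupLabel(system="capra", value=pts)


def _effective_stage_rank(t_stage: str) -> int:
    """Stage rank with the T2 -> T2a imputation baked in: T1/T2 rank as
    organ-confined low stage; T3/T4 rank as the top band."""
    return {"T1": 1, "T2": 2, "T3": 3, "T4": 4}[t_stage]


def eau_risk_group(
    record: PatientRecord, definition: Optional[Mapping] = None
) -> RiskGroupLabel:
    """Three-stratum grouping: low / intermediate / high.

    Low requires PSA below the low cut-off, grade group 1 and stage at
    most T2a-equivalent (plain T2 counts, per the sub-stage imputation);
    high is PSA above the high cut-off, grade group >= 4 or stage >= T3.
    """
    definition = definition or default_schedule("eau")
    _check_basics(record, need_age=False)
    rank = _effective_stage_rank(record.t_stage)
    if (
        record.psa > definition["psa_high"]
        or record.grade_group >= definition["gg_high"]
        or rank >= 3
    ):
        value = 2
    elif (
        record.psa < definition["psa_low"]
        and record.grade_group == 1
        and rank <= 2
    ):
        value = 0
    else:
        value = 1
    return RiskGroupLabel(system="eau", value=value, label=EAU_LABELS[value])


def nccn_risk_group(
    record: PatientRecord, definition: Optional[Mapping] = None
) -> RiskGroupLabel:
    """Four-stratum table: low / intermediate / high / very-high.

    A documented approximation driven by PSA, grade group and stage only
    (the registry lacks core counts and PSA density, so finer strata
    collapse into these four).
    """
    definition = definition or default_schedule("nccn")
    _check_basics(record, need_age=False)
    rank = _effective_stage_rank(record.t_stage)
    if record.grade_group >= definition["gg_very_high"] or rank >= 4:
        value = 3
    elif (
        record.grade_group >= definition["gg_high"]
        or record.psa > definition["psa_high"]
        or rank >= 3
    ):
        value = 2
    elif (
        record.grade_group == 1
        and record.psa < definition["psa_low"]
        and rank <= 2
    ):
        value = 0
    else:
        value = 1
    return RiskGroupLabel(system="nccn", value=value, label=NCCN_LABELS[value])


_CLASSIFIERS = {
    "capra": capra_score,
    "eau": eau_risk_group,
    "nccn": nccn_risk_group,
}


def classify_cohort(
    cohort: Sequence[PatientRecord],
    system: str,
    schedule: Optional[Mapping] = None,
) -> list[RiskGroupLabel]:
    """Apply one comparator system to every patient."""
    if system not in _CLASSIFIERS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    fn = _CLASSIFIERS[system]
    return [fn(rec, schedule) for rec in cohort]
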