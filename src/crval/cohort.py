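"""Domain types for patient-level survival cohorts, inclusion filtering,
treatment grouping and cohort summary statistics.

The cohort model is deliberately registry-agnostic: a record carries the
covariates a two-cause prognostic model needs (age, PSA, T stage, grade
group, optional biopsy involvement, primary treatment, comorbidity flag)
plus follow-up time and a three-state outcome.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class Treatment(str, enum.Enum):
    CONSERVATIVE = "conservative"
    PROSTATECTOMY = "prostatectomy"
    RADIOTHERAPY = "radiotherapy"
    ADT = "adt"


class ConservativeSubtype(str, enum.Enum):
    ACTIVE_SURVEILLANCE = "active_surveillance"
    WATCHFUL_WAITING = "watchful_waiting"
    OTHER_CONSERVATIVE = "other_conservative"


class Event(str, enum.Enum):
    PCA_DEATH = "pca_death"
    OTHER_DEATH = "other_death"
    CENSORED = "censored"


#: Analysis-level treatment groups: radical pools surgery and radiotherapy.
ANALYSIS_GROUPS = ("conservative", "radical", "adt")

T_STAGES = ("T1", "T2", "T3", "T4")


@dataclass
class PatientRecord:
    """One diagnosed patient.

    Pre-filter records may carry ``None`` in any optional field; the
    inclusion filter enforces completeness of the mandatory ones.
    """

    patient_id: str
    age_dx: Optional[float] = None
    psa: Optional[float] = None
    t_stage: Optional[str] = None
    grade_group: Optional[int] = None
    ppc: Optional[float] = None
    treatment: Optional[Treatment] = None
    conservative_subtype: Optional[ConservativeSubtype] = None
    comorbid: Optional[bool] = None
    metastatic: Optional[bool] = None
    dx_date: Optional[datetime.date] = None
    followup_years: Optional[float] = None
    event: Optional[Event] = None

    def __post_init__(self) -> None:
        if self.treatment is not None:
            self.treatment = Treatment(self.treatment)
        if self.conservative_subtype is not None:
            self.conservative_subtype = ConservativeSubtype(self.conservative_subtype)
        if self.event is not None:
            self.event = Event(self.event)
        if self.t_stage is not None and self.t_stage not in T_STAGES:
            raise ValueError(
                f"patient {self.patient_id}: t_stage must be one of {T_STAGES}, "
                f"got {self.t_stage!r}"
            )
        if self.followup_years is not None and self.followup_years < 0:
            raise ValueError(
                f"patient {self.patient_id}: followup_years must be >= 0"
            )
        if self.ppc is not None and not (0.0 <= self.ppc <= 1.0):
            raise ValueError(f"patient {self.patient_id}: ppc must be in [0, 1]")
        if (
            self.conservative_subtype is not None
            and self.treatment is not Treatment.CONSERVATIVE
        ):
            raise ValueError(
                f"patient {self.patient_id}: conservative_subtype set but "
                f"treatment is {self.treatment}"
            )


#: Fields the prognostic model cannot run without.
DEFAULT_MANDATORY_FIELDS = frozenset(
    {"age_dx", "psa", "t_stage", "grade_group", "treatment", "comorbid"}
)


@dataclass(frozen=True)
class InclusionCriteria:
    """Inclusion window plus completeness requirements.

    ``missing_m_as_m0`` controls records with unknown metastatic status:
    by default they are excluded; when set, missingness is read as M0.
    """

    dx_window: Optional[tuple[datetime.date, datetime.date]] = None
    psa_max: float = 100.0
    require_nonmetastatic: bool = True
    mandatory_fields: frozenset[str] = DEFAULT_MANDATORY_FIELDS
    missing_m_as_m0: bool = False

    def __post_init__(self) -> None:
        if self.psa_max <= 0:
            raise ValueError("psa_max must be > 0")
        if self.dx_window is not None and not self.dx_window[0] < self.dx_window[1]:
            raise ValueError("dx_window start must precede end")


def exclusion_percentage(n_excluded: int, n_input: int) -> float:
    """Excluded share of the pre-filter cohort, in percent to one decimal."""
    if n_input <= 0:
        return 0.0
    return round(100.0 * n_excluded / n_input, 1)


@dataclass
class ExclusionLog:
    """Per-reason exclusion tallies for one filter pass.

    A record failing several checks contributes once to ``n_excluded`` but
    to every applicable reason tally; missing mandatory fields are also
    tallied per field in ``missing_field_counts``.
    """

    n_input: int = 0
    n_excluded: int = 0
    reasons: Counter = field(default_factory=Counter)
    missing_field_counts: Counter = field(default_factory=Counter)
    rejected_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    @property
    def excluded_percentage(self) -> float:
        return exclusion_percentage(self.n_excluded, self.n_input)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "excluded_percentage": self.excluded_percentage,
            "reasons": dict(self.reasons),
            "missing_field_counts": dict(self.missing_field_counts),
            "rejected_ids": list(self.rejected_ids),
        }


def _exclusion_reasons(rec: PatientRecord, criteria: InclusionCriteria) -> tuple[list[str], list[str]]:
    """Return (reasons, missing mandatory fields) for one record."""
    reasons: list[str] = []
    missing = [f for f in sorted(criteria.mandatory_fields) if getattr(rec, f) is None]
    if missing:
        reasons.append("missing_mandatory_field")
    if rec.psa is not None and not (0.0 < rec.psa < criteria.psa_max):
        reasons.append("psa_out_of_range")
    if criteria.require_nonmetastatic:
        if rec.metastatic is True:
            reasons.append("metastatic")
        elif rec.metastatic is None and not criteria.missing_m_as_m0:
            reasons.append("missing_metastatic_status")
    if criteria.dx_window is not None and rec.dx_date is not None:
        lo, hi = criteria.dx_window
        if not (lo <= rec.dx_date <= hi):  # window inclusive of both endpoints
            reasons.append("outside_dx_window")
    if rec.followup_years is None and rec.dx_date is None:
        reasons.append("missing_followup")
    return reasons, missing


def apply_inclusion_filters(
    records: Iterable[PatientRecord], criteria: InclusionCriteria
) -> tuple[list[PatientRecord], ExclusionLog]:
    """Filter a pre-cohort down to analysable records.

    Every retained record satisfies the criteria and has all mandatory
    fields present. The log reports one tally per exclusion reason; a
    record is counted once in the total regardless of how many checks it
    fails. Unparseable records are rejected with their id logged, never
    silently dropped.
    """
    cohort: list[PatientRecord] = []
    log = ExclusionLog()
    for rec in records:
        log.n_input += 1
        try:
            reasons, missing = _exclusion_reasons(rec, criteria)
        except (TypeError, AttributeError) as exc:  # malformed record object
            log.n_excluded += 1
            log.reasons["unparseable"] += 1
            log.rejected_ids.append(getattr(rec, "patient_id", "<unknown>"))
            continue
        if reasons:
            log.n_excluded += 1
            for r in reasons:
                log.reasons[r] += 1
            for f in missing:
                log.missing_field_counts[f] += 1
            log.rejected_ids.append(rec.patient_id)
        else:
            cohort.append(rec)
    return cohort, log


def assign_treatment_groups(cohort: Sequence[PatientRecord]) -> dict[str, str]:
    """Map each patient to an analysis group.

    Radical pools prostatectomy and radiotherapy delivered as primary
    treatment; conservative and ADT monotherapy stand alone. The result
    partitions the cohort.
    """
    groups: dict[str, str] = {}
    for rec in cohort:
        if rec.treatment in (Treatment.PROSTATECTOMY, Treatment.RADIOTHERAPY):
            groups[rec.patient_id] = "radical"
        elif rec.treatment is Treatment.CONSERVATIVE:
            groups[rec.patient_id] = "conservative"
        elif rec.treatment is Treatment.ADT:
            groups[rec.patient_id] = "adt"
        else:
            raise ValueError(
                f"patient {rec.patient_id}: unknown treatment code {rec.treatment!r}"
            )
    return groups


def crude_rate_per_100py(n_events: int, person_years: float) -> float:
    """Crude event rate per 100 person-years (unrounded)."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 100.0 * n_events / person_years


@dataclass
class CohortSummary:
    n: int
    person_years: float
    median_followup: float
    event_counts: dict[str, int]
    event_counts_10y: dict[str, int]
    covariate_distributions: dict[str, dict[str, tuple[int, float]]]
    crude_pcsm_rate: float
    crude_acm_rate: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _categorical_distribution(values: Sequence[str]) -> dict[str, tuple[int, float]]:
    counts = Counter(values)
    n = len(values)
    return {
        str(k): (c, round(100.0 * c / n, 1)) for k, c in sorted(counts.items())
    }


def summarize_cohort(cohort: Sequence[PatientRecord]) -> CohortSummary:
    """Cohort-level descriptive summary.

    Crude rates are events per 100 person-years, reported to two decimals
    (the conventional "per patient year" label understates the scale; the
    per-100 convention is what reproduces published magnitudes). Ten-year
    event counts keep events with follow-up <= 10 years.
    """
    n = len(cohort)
    if n == 0:
        return CohortSummary(0, 0.0, float("nan"), {}, {}, {}, 0.0, 0.0)
    fu = sorted(r.followup_years for r in cohort)
    person_years = float(sum(fu))
    if person_years <= 0:
        raise ValueError("cohort has patients but zero person-years of follow-up")
    mid = n // 2
    median_fu = fu[mid] if n % 2 else 0.5 * (fu[mid - 1] + fu[mid])

    counts = Counter(r.event.value for r in cohort)
    counts_10 = Counter(
        r.event.value for r in cohort if r.event is not Event.CENSORED and r.followup_years <= 10.0
    )
    event_counts = {e.value: counts.get(e.value, 0) for e in Event}
    event_counts["any_death"] = event_counts["pca_death"] + event_counts["other_death"]
    event_counts_10y = {
        "pca_death": counts_10.get("pca_death", 0),
        "other_death": counts_10.get("other_death", 0),
    }
    event_counts_10y["any_death"] = sum(event_counts_10y.values())

    dists = {
        "grade_group": _categorical_distribution([str(r.grade_group) for r in cohort]),
        "t_stage": _categorical_distribution([r.t_stage for r in cohort]),
        "treatment": _categorical_distribution([r.treatment.value for r in cohort]),
        "comorbid": _categorical_distribution(
            ["yes" if r.comorbid else "no" for r in cohort]
        ),
    }

    n_pca = event_counts["pca_death"]
    n_any = event_counts["any_death"]
    return CohortSummary(
        n=n,
        person_years=person_years,
        median_followup=median_fu,
        event_counts=event_counts,
        event_counts_10y=event_counts_10y,
        covariate_distributions=dists,
        crude_pcsm_rate=round(crude_rate_per_100py(n_pca, person_years), 2)
        if n_pca
        else 0.0,
        crude_acm_rate=round(crude_rate_per_100py(n_any, person_years), 2)
        if n_any
        else 0.0,
    )
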