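"""Discrimination and calibration analyses for the two-cause model.

Implements Harrell's concordance with jackknife standard errors and
paired score comparisons, observed-to-expected calibration ratios,
quintile calibration with a grouped chi-square goodness-of-fit statistic,
and subgroup calibration tables, all assembled by :func:`run_validation`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Event, PatientRecord, assign_treatment_groups
from .comparators import classify_cohort
from .engine import (
    CoefficientSet,
    CohortPredictions,
    cohort_frame,
    expected_events,
    predict_cohort,
)

OUTCOMES = ("pc", "npc", "acm")

_EVENT_FOR_OUTCOME = {
    "pc": (Event.PCA_DEATH,),
    "npc": (Event.OTHER_DEATH,),
    "acm": (Event.PCA_DEATH, Event.OTHER_DEATH),
}


# ---------------------------------------------------------------------------
# Harrell's c
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    c: float
    se: float
    ci95: tuple[float, float]
    n_pairs_comparable: int
    n_tied_score: int
    # per-patient pair contributions, kept for jackknife-based comparisons
    _pair_count: np.ndarray = field(repr=False, default=None)
    _pair_score: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "c": self.c,
            "se": self.se,
            "ci95": list(self.ci95),
            "n_pairs_comparable": self.n_pairs_comparable,
            "n_tied_score": self.n_tied_score,
        }


def _pair_contributions(
    score: np.ndarray, time: np.ndarray, event: np.ndarray, chunk: int = 512
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-patient comparable-pair counts and concordance scores.

    A pair is comparable when the patient with the earlier observed time
    has an event of the target cause (a censored patient with the same
    time as an event is known to have survived at least as long, so such
    tied-time pairs are comparable too; two events at the same time are
    not). The pair scores 1 when the earlier-event patient carries the
    higher risk score, 0.5 on a score tie.

    Returns (pair_count, pair_score, n_tied) where the arrays hold, for
    each patient, the sum over pairs involving that patient.
    """
    n = len(score)
    pair_count = np.zeros(n)
    pair_score = np.zeros(n)
    n_tied = 0
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti, di, si = time[sl, None], event[sl, None], score[sl, None]
        i_earlier = di & ((ti < time) | ((ti == time) & ~event))
        j_earlier = event & ((time < ti) | ((time == ti) & ~di))
        tie = si == score
        val = np.where(i_earlier, (si > score) + 0.5 * tie, 0.0) + np.where(
            j_earlier, (score > si) + 0.5 * tie, 0.0
        )
        comparable = i_earlier | j_earlier
        # zero the diagonal block
        idx = np.arange(sl.start, sl.stop)
        comparable[idx - sl.start, idx] = False
        val[idx - sl.start, idx] = 0.0
        pair_count[sl] += comparable.sum(axis=1)
        pair_score[sl] += val.sum(axis=1)
        n_tied += int((comparable & tie).sum())
    return pair_count, pair_score, n_tied // 2


def _jackknife_values(pair_count: np.ndarray, pair_score: np.ndarray) -> np.ndarray:
    """Leave-one-out c values from per-patient pair contributions."""
    total_pairs = pair_count.sum() / 2.0
    total_score = pair_score.sum() / 2.0
    p_loo = total_pairs - pair_count
    s_loo = total_score - pair_score
    c = total_score / total_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = np.where(p_loo > 0, s_loo / np.where(p_loo > 0, p_loo, 1.0), c)
    return c_loo


def harrell_c(
    score: Sequence[float], followup: Sequence[float], event: Sequence[bool]
) -> ConcordanceResult:
    """Harrell's concordance index for one target cause.

    ``event`` flags deaths from the target cause; censoring and
    competing-cause deaths both end observation without creating
    comparability at later times. Higher scores must mean higher risk.
    The standard error comes from a leave-one-out jackknife over patients.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(followup, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not (len(score) == len(time) == len(event)):
        raise ValueError("score, followup and event must have equal length")
    if np.any(time < 0):
        raise ValueError("negative follow-up time")
    pair_count, pair_score, n_tied = _pair_contributions(score, time, event)
    total_pairs = int(round(pair_count.sum() / 2.0))
    if total_pairs == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    c = pair_score.sum() / pair_count.sum()
    c_loo = _jackknife_values(pair_count, pair_score)
    n = len(score)
    se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    half = 1.959963984540054 * se
    return ConcordanceResult(
        c=float(c),
        se=se,
        ci95=(max(0.0, c - half), min(1.0, c + half)),
        n_pairs_comparable=total_pairs,
        n_tied_score=n_tied,
        _pair_count=pair_count,
        _pair_score=pair_score,
    )


@dataclass
class ConcordanceComparison:
    c_a: float
    c_b: float
    delta: float
    p: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_c(
    score_a: Sequence[float],
    score_b: Sequence[float],
    followup: Sequence[float],
    event: Sequence[bool],
) -> ConcordanceComparison:
    """Two-sided paired comparison of two risk scores' c-indices.

    The test statistic is the jackknife z-score of the per-patient
    leave-one-out differences (same patients, same comparable pairs
    weighting, different scores). Identical scores give delta 0 and p 1.
    """
    ra = harrell_c(score_a, followup, event)
    rb = harrell_c(score_b, followup, event)
    delta = ra.c - rb.c
    d_loo = _jackknife_values(ra._pair_count, ra._pair_score) - _jackknife_values(
        rb._pair_count, rb._pair_score
    )
    n = len(d_loo)
    se = float(np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return ConcordanceComparison(c_a=ra.c, c_b=rb.c, delta=float(delta), p=p)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class OERatio:
    observed: int
    expected: float
    oe: float          # observed / expected
    eo: float          # expected / observed
    label: str         # "1:x", x = expected/observed to three decimals

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def oe_ratio(observed: int, expected: float) -> OERatio:
    """Observed-to-expected calibration ratio, both ways round.

    The ``label`` normalises observed to 1 and prints expected/observed
    to three decimals; ``oe`` is the conventional observed/expected.
    """
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    if observed == 0:
        raise ValueError("observed count is 0: ratio undefined")
    eo = expected / observed
    return OERatio(
        observed=int(observed),
        expected=float(expected),
        oe=float(observed / expected),
        eo=float(eo),
        label=f"1:{eo:.3f}",
    )


@dataclass
class CalibrationRow:
    group: str
    outcome: str
    n: int
    observed: int
    expected: float
    oe: float
    percent_difference: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CalibrationTable:
    rows: list[CalibrationRow]
    chi_square: Optional[float] = None
    df: Optional[int] = None
    p: Optional[float] = None
    percent_diff_convention: str = "100*|E-O|/O"

    @property
    def total_observed(self) -> int:
        return sum(r.observed for r in self.rows)

    @property
    def total_expected(self) -> float:
        return sum(r.expected for r in self.rows)

    def as_dict(self) -> dict:
        return {
            "rows": [r.as_dict() for r in self.rows],
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p,
            "percent_diff_convention": self.percent_diff_convention,
        }


def percent_difference(observed: float, expected: float) -> float:
    """Absolute expected-vs-observed gap as a percentage of observed."""
    if observed == 0:
        return float("nan")
    return round(100.0 * abs(expected - observed) / observed, 1)


def grouped_gof(observed: np.ndarray, expected: np.ndarray, df: Optional[int] = None):
    """Grouped (O-E)^2/E chi-square statistic with df = G - 1 by default."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("every group needs expected > 0; merge groups")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = (len(observed) - 1) if df is None else df
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, df, p


def quintile_calibration(
    predictions: Sequence[float],
    observed_events: Sequence[bool],
    outcome: str = "acm",
    n_groups: int = 5,
    df: Optional[int] = None,
    ranking: Optional[Sequence[float]] = None,
) -> CalibrationTable:
    """Equal-count risk-group calibration with a chi-square GOF.

    Patients are ranked (stable sort, so ties at cut boundaries break by
    input order) and cut into ``n_groups`` near-equal groups; per group
    the observed event count is compared to the sum of the per-patient
    expected contributions in ``predictions``. The grouped statistic is
    sum (O-E)^2/E on G-1 degrees of freedom (configurable).

    ``ranking`` orders the patients; by default the expected contribution
    itself is used, but when contributions depend on observed follow-up,
    pass a fixed-horizon risk score instead — ranking by a follow-up-
    dependent quantity puts early deaths in the low groups and fabricates
    miscalibration.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observed_events, dtype=bool)
    if len(pred) != len(obs):
        raise ValueError("predictions and observed_events length mismatch")
    if len(pred) < n_groups:
        raise ValueError(f"need at least {n_groups} patients")
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictions must be finite")
    rank_key = pred if ranking is None else np.asarray(ranking, dtype=float)
    if len(rank_key) != len(pred):
        raise ValueError("ranking and predictions length mismatch")
    order = np.argsort(rank_key, kind="stable")
    rows = []
    o_list, e_list = [], []
    for g, idx in enumerate(np.array_split(order, n_groups)):
        o = int(obs[idx].sum())
        e = float(pred[idx].sum())
        if e <= 0:
            raise ValueError(
                f"group {g + 1} has expected count 0; merge groups or reduce n_groups"
            )
        o_list.append(o)
        e_list.append(e)
        rows.append(
            CalibrationRow(
                group=f"q{g + 1}",
                outcome=outcome,
                n=len(idx),
                observed=o,
                expected=e,
                oe=o / e,
                percent_difference=percent_difference(o, e),
            )
        )
    chi2, dof, p = grouped_gof(np.array(o_list), np.array(e_list), df=df)
    return CalibrationTable(rows=rows, chi_square=chi2, df=dof, p=p)


def subgroup_calibration(
    cohort: Sequence[PatientRecord],
    coefs: CoefficientSet,
    grouping: Optional[Mapping[str, str]] = None,
    horizon_cap: float = 15.0,
) -> CalibrationTable:
    """Observed vs expected deaths per subgroup and outcome.

    ``grouping`` maps patient_id to a subgroup label (defaults to the
    treatment analysis groups); it must cover the cohort. Empty groups
    are skipped with a warning.
    """
    grouping = grouping if grouping is not None else assign_treatment_groups(cohort)
    by_group: dict[str, list[PatientRecord]] = {}
    for rec in cohort:
        try:
            label = grouping[rec.patient_id]
        except KeyError:
            raise ValueError(f"patient {rec.patient_id} missing from grouping")
        by_group.setdefault(label, []).append(rec)

    rows = []
    for label in sorted(by_group):
        members = by_group[label]
        if not members:  # pragma: no cover - defensive
            warnings.warn(f"subgroup {label!r} is empty; skipped")
            continue
        exp = expected_events(members, coefs, horizon_cap=horizon_cap)
        obs = {
            "pc": sum(
                1
                for r in members
                if r.event is Event.PCA_DEATH and r.followup_years <= horizon_cap
            ),
            "npc": sum(
                1
                for r in members
                if r.event is Event.OTHER_DEATH and r.followup_years <= horizon_cap
            ),
        }
        obs["acm"] = obs["pc"] + obs["npc"]
        e_map = {"pc": exp.e_pc, "npc": exp.e_npc, "acm": exp.e_acm}
        for outcome in OUTCOMES:
            o, e = obs[outcome], e_map[outcome]
            rows.append(
                CalibrationRow(
                    group=label,
                    outcome=outcome,
                    n=len(members),
                    observed=o,
                    expected=e,
                    oe=(o / e) if e > 0 else float("nan"),
                    percent_difference=percent_difference(o, e),
                )
            )
    return CalibrationTable(rows=rows)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    n: int
    concordance: dict
    comparators: dict
    overall_oe: dict
    quintiles: dict
    subgroups: CalibrationTable
    observed_counts: dict
    observed_counts_untruncated: dict
    expected_counts: dict
    settings: dict

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "concordance": {
                oc: {grp: r.as_dict() for grp, r in d.items()}
                for oc, d in self.concordance.items()
            },
            "comparators": {
                sys: {oc: d.as_dict() for oc, d in per.items()}
                for sys, per in self.comparators.items()
            },
            "overall_oe": {oc: r.as_dict() for oc, r in self.overall_oe.items()},
            "quintiles": {oc: t.as_dict() for oc, t in self.quintiles.items()},
            "subgroups": self.subgroups.as_dict(),
            "observed_counts": self.observed_counts,
            "observed_counts_untruncated": self.observed_counts_untruncated,
            "expected_counts": self.expected_counts,
            "settings": self.settings,
        }


def _observed_flags(
    cohort: Sequence[PatientRecord], outcome: str, cap: Optional[float] = None
) -> np.ndarray:
    """Event indicators for one outcome, optionally truncated at ``cap``
    years (events later than the prediction horizon are not observable by
    a capped model and are excluded from calibration counts)."""
    targets = _EVENT_FOR_OUTCOME[outcome]
    flags = np.array([r.event in targets for r in cohort], dtype=bool)
    if cap is not None:
        fu = np.array([r.followup_years for r in cohort], dtype=float)
        flags &= fu <= cap
    return flags


def run_validation(
    cohort: Sequence[PatientRecord],
    coefs: CoefficientSet,
    comparator_systems: Sequence[str] = ("capra", "eau", "nccn"),
    comparator_schedules: Optional[Mapping[str, Mapping]] = None,
    n_groups: int = 5,
    horizon_cap: float = 15.0,
    include_as_subgroup: bool = True,
) -> ValidationReport:
    """Assemble the full discrimination + calibration report.

    The model's risk score for concordance is its as-treated predicted
    15-year cumulative risk of the target outcome; comparator systems are
    scored by their ordinal labels. Calibration uses expected deaths over
    each patient's available follow-up (capped at the horizon).
    """
    cohort = list(cohort)
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    groups = assign_treatment_groups(cohort)
    preds = predict_cohort(cohort, coefs)
    fu = np.array([r.followup_years for r in cohort], dtype=float)

    model_scores = {
        "pc": preds.risk_at_horizon("pc"),
        "acm": preds.risk_at_horizon("acm"),
    }
    flags = {oc: _observed_flags(cohort, oc) for oc in OUTCOMES}

    subgroup_masks = {"overall": np.ones(n, dtype=bool)}
    glabels = np.array([groups[r.patient_id] for r in cohort])
    for g in ("conservative", "radical"):
        subgroup_masks[g] = glabels == g
    if include_as_subgroup:
        as_mask = np.array(
            [
                r.conservative_subtype is not None
                and r.conservative_subtype.value == "active_surveillance"
                for r in cohort
            ]
        )
        if as_mask.any():
            subgroup_masks["active_surveillance"] = as_mask

    concordance: dict[str, dict] = {}
    for oc in ("pc", "acm"):
        concordance[oc] = {}
        for gname, mask in subgroup_masks.items():
            if mask.sum() < 2:
                continue
            try:
                concordance[oc][gname] = harrell_c(
                    model_scores[oc][mask], fu[mask], flags[oc][mask]
                )
            except ValueError:
                warnings.warn(f"no comparable pairs for {oc}/{gname}; skipped")

    comparators: dict[str, dict] = {}
    comparator_schedules = comparator_schedules or {}
    for system in comparator_systems:
        labels = classify_cohort(cohort, system, comparator_schedules.get(system))
        ordinal = np.array([lbl.value for lbl in labels], dtype=float)
        comparators[system] = {
            oc: compare_c(model_scores[oc], ordinal, fu, flags[oc])
            for oc in ("pc", "acm")
        }

    exp = expected_events(cohort, coefs, horizon_cap=horizon_cap)
    flags_cal = {oc: _observed_flags(cohort, oc, cap=horizon_cap) for oc in OUTCOMES}
    observed_counts = {oc: int(flags_cal[oc].sum()) for oc in OUTCOMES}
    observed_counts_untruncated = {oc: int(flags[oc].sum()) for oc in OUTCOMES}
    expected_counts = {"pc": exp.e_pc, "npc": exp.e_npc, "acm": exp.e_acm}
    overall_oe = {
        oc: oe_ratio(observed_counts[oc], expected_counts[oc])
        for oc in OUTCOMES
        if observed_counts[oc] > 0
    }

    per_patient = exp.per_patient
    horizon_risk = {
        "pc": preds.risk_at_horizon("pc"),
        "npc": preds.risk_at_horizon("npc"),
        "acm": preds.risk_at_horizon("acm"),
    }
    quintiles = {
        oc: quintile_calibration(
            per_patient[f"e_{oc}"].to_numpy(),
            flags_cal[oc],
            outcome=oc,
            n_groups=n_groups,
            ranking=horizon_risk[oc],
        )
        for oc in OUTCOMES
    }

    subgroups = subgroup_calibration(cohort, coefs, grouping=groups, horizon_cap=horizon_cap)

    return ValidationReport(
        n=n,
        concordance=concordance,
        comparators=comparators,
        overall_oe=overall_oe,
        quintiles=quintiles,
        subgroups=subgroups,
        observed_counts=observed_counts,
        observed_counts_untruncated=observed_counts_untruncated,
        expected_counts=expected_counts,
        settings={
            "n_groups": n_groups,
            "horizon_cap": horizon_cap,
            "comparators": list(comparator_systems),
            "percent_diff_convention": "100*|E-O|/O",
        },
    )
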