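import numpy as np
import pytest
from scipy import stats

from crval.cohort import Event
from crval.engine import default_coefficients, expected_events
from crval.synthetic import make_benchmark_cohort
from crval.validation import (
    compare_c,
    grouped_gof,
    harrell_c,
    oe_ratio,
    percent_difference,
    quintile_calibration,
    run_validation,
    subgroup_calibration,
)
from conftest import make_record


def brute_force_c(score, time, event):
    """Independent O(n^2) oracle: explicit pair enumeration."""
    n = len(score)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # is i the strictly earlier target-cause event of the pair?
            if event[i] and (time[i] < time[j] or (time[i] == time[j] and not event[j])):
                den += 1
                if score[i] > score[j]:
                    num += 1.0
                elif score[i] == score[j]:
                    num += 0.5
    return num / den if den else None


def random_survival(n, seed, tie_prob=0.2):
    rng = np.random.default_rng(seed)
    time = rng.integers(1, 10, size=n).astype(float)  # integer times force ties
    event = rng.random(n) < 0.6
    score = np.round(rng.random(n), 1 if rng.random() < tie_prob else 3)
    return score, time, event


class TestHarrellC:
    def test_perfect_ranking(self):
        r = harrell_c([0.9, 0.5, 0.1], [1, 2, 3], [True, True, True])
        assert r.c == 1.0
        assert r.n_pairs_comparable == 3

    def test_all_tied_scores(self):
        r = harrell_c([0.5] * 4, [1, 2, 3, 4], [True] * 4)
        assert r.c == 0.5
        assert r.n_tied_score == r.n_pairs_comparable == 6

    def test_censoring_example(self):
        # comparable pairs: (1,2) and (1,3) only; both concordant
        r = harrell_c([0.9, 0.1, 0.5], [2, 4, 6], [True, False, True])
        assert r.n_pairs_comparable == 2
        assert r.c == 1.0

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([0.1, 0.2], [1, 2], [False, False])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        score, time, event = random_survival(120, seed)
        r = harrell_c(score, time, event)
        assert r.c == pytest.approx(brute_force_c(score, time, event), abs=1e-12)

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(3)
        score = rng.random(80)
        time = rng.exponential(5, 80)
        event = rng.random(80) < 0.7
        c_pos = harrell_c(score, time, event).c
        c_neg = harrell_c(-score, time, event).c
        assert c_neg == pytest.approx(1.0 - c_pos, abs=1e-12)

    def test_ci_contains_c(self):
        score, time, event = random_survival(150, 9)
        r = harrell_c(score, time, event)
        assert r.ci95[0] <= r.c <= r.ci95[1]
        assert r.se >= 0

    def test_random_score_near_half(self, bench_cohort):
        cohort, _ = bench_cohort
        rng = np.random.default_rng(0)
        score = rng.random(len(cohort))
        fu = [r.followup_years for r in cohort]
        ev = [r.event is not Event.CENSORED for r in cohort]
        r = harrell_c(score, fu, ev)
        assert abs(r.c - 0.5) < 3 * r.se


class TestCompareC:
    def test_identical_scores(self):
        score, time, event = random_survival(100, 1)
        r = compare_c(score, score, time, event)
        assert r.delta == 0.0
        assert r.p == 1.0

    def test_negated_score_delta(self):
        rng = np.random.default_rng(2)
        score = rng.random(60)
        time = rng.exponential(5, 60)
        event = rng.random(60) < 0.7
        r = compare_c(score, -score, time, event)
        assert r.delta == pytest.approx(2 * r.c_a - 1.0, abs=1e-12)

    def test_true_score_beats_noise(self, bench_cohort, default_coefs):
        from crval.engine import predict_cohort

        cohort, truth = bench_cohort
        preds = predict_cohort(cohort, truth.coefs)
        score_true = preds.risk_at_horizon("pc")
        rng = np.random.default_rng(5)
        score_noise = rng.random(len(cohort))
        fu = [r.followup_years for r in cohort]
        ev = [r.event is Event.PCA_DEATH for r in cohort]
        r = compare_c(score_true, score_noise, fu, ev)
        assert r.delta > 0
        assert r.p < 0.05


class TestOERatio:
    def test_published_style_label(self):
        r = oe_ratio(observed=25_849, expected=25_925.0)
        assert r.label == "1:1.003"
        assert r.eo == pytest.approx(25_925 / 25_849)

    def test_equal_counts(self):
        assert oe_ratio(100, 100.0).label == "1:1.000"

    def test_oe_direction(self):
        # expected above observed -> O:E below 1
        r = oe_ratio(observed=8_151, expected=9_087.0)
        assert round(r.oe, 3) == 0.897

    def test_errors(self):
        with pytest.raises(ValueError):
            oe_ratio(10, 0.0)
        with pytest.raises(ValueError):
            oe_ratio(0, 5.0)


class TestQuintileCalibration:
    def test_two_group_hand_example(self):
        # groups: E = (10, 30), O = (15, 25) -> chi2 = 25/10 + 25/30
        pred = np.array([10 / 30] * 30 + [1.0] * 30)
        obs = np.array([True] * 15 + [False] * 15 + [True] * 25 + [False] * 5)
        table = quintile_calibration(pred, obs, n_groups=2)
        assert table.chi_square == pytest.approx(25 / 10 + 25 / 30, abs=1e-9)
        assert table.chi_square == pytest.approx(3.3333, abs=1e-4)
        assert table.df == 1
        assert table.p == pytest.approx(0.0679, abs=2e-4)

    def test_perfect_groups(self):
        chi2, df, p = grouped_gof([10, 20], [10.0, 20.0])
        assert chi2 == 0.0 and p == 1.0

    def test_totals_preserved(self, bench_cohort):
        cohort, truth = bench_cohort
        exp = expected_events(cohort, truth.coefs)
        obs = np.array(
            [r.event is not Event.CENSORED and r.followup_years <= 15 for r in cohort]
        )
        table = quintile_calibration(exp.per_patient["e_acm"].to_numpy(), obs)
        assert table.total_observed == int(obs.sum())
        assert table.total_expected == pytest.approx(exp.e_acm, rel=1e-12)
        assert len(table.rows) == 5

    def test_zero_expected_group_raises(self):
        pred = np.array([0.0] * 10 + [0.5] * 10)
        obs = np.zeros(20, dtype=bool)
        with pytest.raises(ValueError, match="merge"):
            quintile_calibration(pred, obs, n_groups=2)

    def test_self_simulated_quintiles_within_poisson_bounds(self):
        from crval.engine import predict_cohort

        cohort, truth = make_benchmark_cohort(30_000, seed=13)
        exp = expected_events(cohort, truth.coefs)
        obs = np.array(
            [r.event is Event.PCA_DEATH and r.followup_years <= 15 for r in cohort]
        )
        risk = predict_cohort(cohort, truth.coefs).risk_at_horizon("pc")
        table = quintile_calibration(
            exp.per_patient["e_pc"].to_numpy(), obs, outcome="pc", ranking=risk
        )
        for row in table.rows:
            assert abs(row.observed - row.expected) < 3 * np.sqrt(row.expected), row


class TestSubgroupCalibration:
    def test_percent_difference_formula(self):
        assert percent_difference(100, 103.0) == 3.0
        assert percent_difference(100, 100.0) == 0.0

    def test_rows_cover_groups_and_outcomes(self, bench_cohort):
        cohort, truth = bench_cohort
        table = subgroup_calibration(cohort, truth.coefs)
        groups = {r.group for r in table.rows}
        assert groups == {"conservative", "radical", "adt"}
        assert {r.outcome for r in table.rows} == {"pc", "npc", "acm"}

    def test_convergence_with_n(self):
        diffs = {}
        for n in (4000, 40_000):
            cohort, truth = make_benchmark_cohort(n, seed=3)
            table = subgroup_calibration(cohort, truth.coefs)
            acm_rows = [r for r in table.rows if r.outcome == "acm"]
            diffs[n] = np.mean([r.percent_difference for r in acm_rows])
        assert diffs[40_000] < diffs[4000]

    def test_missing_patient_in_grouping(self, bench_cohort):
        cohort, truth = bench_cohort
        with pytest.raises(ValueError, match="missing from grouping"):
            subgroup_calibration(cohort[:5], truth.coefs, grouping={})


@pytest.fixture(scope="module")
def report(bench_cohort):
    cohort, truth = bench_cohort
    return run_validation(cohort, truth.coefs)


class TestRunValidation:
    def test_deterministic(self, bench_cohort):
        import json

        cohort, truth = bench_cohort
        a = run_validation(cohort[:800], truth.coefs)
        b = run_validation(cohort[:800], truth.coefs)
        assert json.dumps(a.as_dict(), sort_keys=True) == json.dumps(
            b.as_dict(), sort_keys=True
        )

    def test_subgroup_observed_sums_to_overall(self, report):
        for oc in ("pc", "npc", "acm"):
            total = sum(r.observed for r in report.subgroups.rows if r.outcome == oc)
            assert total == report.observed_counts[oc]

    def test_truncated_counts_not_above_untruncated(self, report):
        for oc in ("pc", "npc", "acm"):
            assert report.observed_counts[oc] <= report.observed_counts_untruncated[oc]

    def test_model_beats_own_coarsening(self, bench_cohort):
        """Data-processing: the continuous true-model score discriminates
        at least as well as its own 3-stratum coarsening."""
        from crval.engine import predict_cohort

        cohort, truth = bench_cohort
        preds = predict_cohort(cohort, truth.coefs)
        score = preds.risk_at_horizon("pc")
        coarse = np.digitize(score, np.quantile(score, [1 / 3, 2 / 3]))
        fu = [r.followup_years for r in cohort]
        ev = [r.event is Event.PCA_DEATH for r in cohort]
        r = compare_c(score, coarse, fu, ev)
        assert r.delta > 0

    def test_comparator_block_structure(self, report):
        assert set(report.comparators) == {"capra", "eau", "nccn"}
        for per_oc in report.comparators.values():
            for cmp_res in per_oc.values():
                assert 0.0 <= cmp_res.p <= 1.0

    def test_overall_oe_close_to_one(self, report):
        for oc, r in report.overall_oe.items():
            se = 1.0 / np.sqrt(r.expected)  # Poisson SE on the log-ish scale
            assert abs(r.oe - 1.0) < 3 * se, (oc, r.oe)

    def test_empty_cohort_raises(self, default_coefs):
        with pytest.raises(ValueError, match="empty"):
            run_validation([], default_coefs)
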