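"""IRS scoring, dichotomization, association tests, survival comparison."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ppiscreen import (
    ClinicalInputError,
    CohortSimSpec,
    IHCScore,
    chi_square_test,
    crosstab,
    dichotomize,
    gen_cohort,
    irs,
    km_estimate,
    logrank_test,
    pct_category,
    read_cohort,
    spearman_rho,
    validate_markers,
    write_cohort,
)

from conftest import random_er_graph  # noqa: F401  (shared fixtures)


class TestPctCategory:
    @pytest.mark.parametrize(
        "pct,expected",
        [(0, 0), (0.5, 1), (1, 1), (7, 1), (10, 1), (10.5, 2), (11, 2),
         (50, 2), (50.5, 3), (55, 3), (100, 3)],
    )
    def test_banding(self, pct, expected):
        assert pct_category(pct) == expected

    @pytest.mark.parametrize("pct", [-1, 101])
    def test_out_of_range(self, pct):
        with pytest.raises(ClinicalInputError):
            pct_category(pct)


class TestIrs:
    @pytest.mark.parametrize("cat,inten,expected", [(3, 3, 9), (0, 3, 0), (2, 3, 6)])
    def test_product(self, cat, inten, expected):
        assert irs(cat, inten) == expected

    def test_out_of_range(self):
        with pytest.raises(ClinicalInputError):
            irs(4, 1)
        with pytest.raises(ClinicalInputError):
            irs(1, -1)

    @given(st.floats(0, 100), st.integers(0, 3))
    def test_score_always_in_range(self, pct, inten):
        s = IHCScore.from_raw(pct, inten)
        assert 0 <= s.irs <= 9
        assert s.irs == s.pct_category * s.intensity


class TestDichotomize:
    def test_median_split(self):
        assert dichotomize([1, 2, 3, 4, 9]) == ["low", "low", "low", "high", "high"]

    def test_all_equal_all_low(self):
        assert dichotomize([5, 5, 5, 5]) == ["low"] * 4

    def test_matches_brute_filter(self, rng):
        scores = rng.integers(0, 10, size=200).tolist()
        med = np.median(scores)
        expected = ["high" if s > med else "low" for s in scores]
        assert dichotomize(scores) == expected


class TestCrosstabAndChiSquare:
    def test_balanced_2x2(self):
        labels = {"p1": "high", "p2": "high", "p3": "low", "p4": "low"}
        cov = {"p1": "yes", "p2": "no", "p3": "yes", "p4": "no"}
        table = crosstab(labels, cov)
        assert (table.to_numpy() == 1).all()

    def test_margins_sum_to_n(self, rng):
        n = 200
        labels = {f"p{i}": rng.choice(["high", "low"]) for i in range(n)}
        cov = {f"p{i}": rng.choice(["a", "b", "c"]) for i in range(n)}
        table = crosstab(labels, cov)
        assert table.to_numpy().sum() == n

    def test_disjoint_ids_raise(self):
        with pytest.raises(ClinicalInputError):
            crosstab({"p1": "high"}, {"q1": "yes"})

    def test_null_table(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0 and df == 1 and p == pytest.approx(1.0)

    def test_2x2_closed_form_afp_counts(self):
        # GRB2-high by serum AFP status in a 130-patient series:
        # 47/72 positive vs 18/58 negative
        table = [[47, 25], [18, 40]]
        stat, df, p = chi_square_test(table)
        closed = 130 * (47 * 40 - 25 * 18) ** 2 / (72 * 58 * 65 * 65)
        assert stat == pytest.approx(closed, rel=1e-12)
        assert df == 1 and p < 0.001

    def test_3x2_matches_oe_summation(self, rng):
        arr = rng.integers(5, 40, size=(3, 2)).astype(float)
        stat, df, _ = chi_square_test(arr)
        expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
        assert stat == pytest.approx(((arr - expected) ** 2 / expected).sum())
        assert df == 2

    def test_invariant_under_permutation(self, rng):
        arr = rng.integers(5, 40, size=(3, 3)).astype(float)
        s1, _, _ = chi_square_test(arr)
        s2, _, _ = chi_square_test(arr[::-1, ::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_margin_raises(self):
        with pytest.raises(ClinicalInputError, match="row"):
            chi_square_test([[0, 0], [5, 5]])


class TestSpearman:
    def test_monotone_is_one(self):
        x = [1, 4, 2, 8, 5]
        assert spearman_rho(x, [v * 2 for v in x]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(0, 5, size=20).astype(float)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert spearman_rho(x, y) == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]))

    def test_constant_vector_signalled(self):
        with pytest.raises(ClinicalInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self, rng):
        times = np.sort(rng.exponential(10, size=25))
        km = km_estimate(times, [True] * 25)
        for t, s in zip(km["time"], km["survival"]):
            if t == 0:
                continue
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_all_censored_flat_one(self):
        km = km_estimate([3.0, 7.0, 9.0], [False, False, False])
        assert (km["survival"] == 1.0).all()

    def test_hand_worked_product_limit(self):
        # at t=5: 3 at risk, 1 event -> 2/3; censoring at 8 leaves 1 at risk,
        # so the event at t=12 drops the curve to 2/3 * (1 - 1/1) = 0
        km = km_estimate([5, 8, 12], [True, False, True])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[5.0] == pytest.approx(2 / 3)
        assert surv[8.0] == pytest.approx(2 / 3)
        assert surv[12.0] == pytest.approx(0.0)

    def test_hand_worked_product_limit_with_late_risk_set(self):
        # 4 subjects: events at 5 and 12, censorings at 8 and 15
        # S(5) = 3/4; at t=12 two at risk -> S = 3/4 * 1/2 = 3/8
        km = km_estimate([5, 8, 12, 15], [True, False, True, False])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[5.0] == pytest.approx(3 / 4)
        assert surv[12.0] == pytest.approx(3 / 8)

    def test_monotone_nonincreasing_and_starts_at_one(self, rng):
        t = rng.exponential(5, size=40)
        e = rng.random(40) < 0.7
        km = km_estimate(t, e)
        s = km["survival"].to_numpy()
        assert s[0] == 1.0 or km["time"].iloc[0] > 0
        assert (np.diff(s) <= 1e-12).all()

    def test_negative_time_raises(self):
        with pytest.raises(ClinicalInputError):
            km_estimate([-1.0, 2.0], [True, True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        stat, df, p = logrank_test([(t, e), (t, e)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_empty_group_raises(self):
        with pytest.raises(ClinicalInputError):
            logrank_test([([1.0], [True]), ([], [])])

    def test_matches_permutation_oracle(self, rng):
        na, nb = 12, 14
        ta = rng.exponential(5, size=na)
        tb = rng.exponential(12, size=nb)
        ea = rng.random(na) < 0.8
        eb = rng.random(nb) < 0.8
        stat_obs, _, _ = logrank_test([(ta, ea), (tb, eb)])
        # permutation null of the log-rank statistic
        all_t = np.concatenate([ta, tb])
        all_e = np.concatenate([ea, eb])
        n_perm, count = 2000, 0
        for _ in range(n_perm):
            idx = rng.permutation(na + nb)
            s, _, _ = logrank_test(
                [(all_t[idx[:na]], all_e[idx[:na]]), (all_t[idx[na:]], all_e[idx[na:]])]
            )
            if s >= stat_obs:
                count += 1
        p_perm = count / n_perm
        p_chi2 = float(stats.chi2.sf(stat_obs, 1))
        assert p_perm == pytest.approx(p_chi2, abs=0.03)

    def test_three_group_df(self):
        groups = [([1.0, 2.0], [True, True]), ([2.0, 3.0], [True, False]),
                  ([1.5, 4.0], [False, True])]
        _, df, _ = logrank_test(groups)
        assert df == 2


class TestValidateMarkers:
    def test_null_cohort_nothing_flagged_strongly(self):
        recs = gen_cohort(CohortSimSpec(n_patients=200, hazard_ratio=1.0, seed=11))
        report = validate_markers(recs, ("MARKER_A", "MARKER_B"))
        assert report["survival"]["os"]["four_group"]["p"] > 0.001

    def test_strong_hazard_detected(self):
        recs = gen_cohort(CohortSimSpec(n_patients=130, hazard_ratio=5.829, seed=5))
        report = validate_markers(recs, ("MARKER_A", "MARKER_B"))
        assert report["survival"]["os"]["combined_vs_rest"]["p"] < 0.05

    def test_four_group_composition_consistent(self):
        recs = gen_cohort(CohortSimSpec(n_patients=130, seed=2))
        report = validate_markers(recs, ("MARKER_A", "MARKER_B"))
        comp = report["group_composition"]
        assert sum(v["count"] for v in comp.values()) == 130
        high_a = sum(
            v["count"] for g, v in comp.items() if g.startswith("high")
        )
        assert high_a == sum(
            1 for r in recs if r.labels["MARKER_A"] == "high"
        )

    def test_report_structure(self):
        recs = gen_cohort(CohortSimSpec(n_patients=80, seed=3))
        report = validate_markers(recs, ("MARKER_A", "MARKER_B"), covariates=["afp", "stage"])
        assert set(report["associations"]) == {"afp", "stage"}
        assert -1 <= report["spearman_rho"] <= 1
        for which in ("os", "dfs"):
            assert set(report["survival"][which]) == {
                "MARKER_A", "MARKER_B", "combined_vs_rest", "four_group"
            }


def test_cohort_roundtrip(tmp_path):
    recs = gen_cohort(CohortSimSpec(n_patients=25, seed=9))
    p = tmp_path / "cohort.tsv"
    write_cohort(recs, p)
    back = read_cohort(p)
    assert len(back) == 25
    for a, b in zip(recs, back):
        assert a.patient_id == b.patient_id
        assert a.scores["MARKER_A"].irs == b.scores["MARKER_A"].irs
        assert a.time_os == pytest.approx(b.time_os)
        assert a.event_dfs == b.event_dfs
        assert a.covariates == b.covariates
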