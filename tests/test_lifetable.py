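import datetime
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwprisk.lifetable import (
    annual_average_incidence,
    build_life_table,
    cumulative_incidence_curve,
    pearson_chi2,
    peto_logrank,
    subgroup_rates,
)

from conftest import chain, exponential_cohort, worker


def censored_at(years, wid):
    days = int(years * 365.25)
    entry = datetime.date(1970, 1, 1)
    return worker(
        wid=wid,
        entry="1970-01-01",
        segments=chain(entry, ("mining", max(days, 400))),
        censor=(entry + datetime.timedelta(days=days)).isoformat(),
    )


def case_at(years, wid):
    days = int(years * 365.25)
    entry = datetime.date(1970, 1, 1)
    return worker(
        wid=wid,
        entry="1970-01-01",
        segments=chain(entry, ("mining", max(days, 400))),
        case=True,
        diagnosis=(entry + datetime.timedelta(days=days)).isoformat(),
        censor=None,
    )


class TestLifeTable:
    def test_no_events_zero_ci(self):
        workers = [censored_at(10.5, f"c{i}") for i in range(100)]
        lt = build_life_table(workers)
        assert lt.cumulative_incidence(10) == 0.0
        assert (lt.table["ci"] == 0).all()

    def test_without_withdrawals_equals_empirical_fraction(self):
        # 4 events by year 8 among 10 workers, all censoring after t
        workers = [case_at(t, f"d{t}") for t in (2.5, 3.5, 5.5, 7.5)]
        workers += [censored_at(20.5, f"c{i}") for i in range(6)]
        lt = build_life_table(workers)
        assert lt.cumulative_incidence(8) == pytest.approx(0.4)

    def test_structural_invariants(self):
        rng = np.random.default_rng(5)
        workers = exponential_cohort(rng, 400, hazard=0.03)
        lt = build_life_table(workers)
        t = lt.table
        assert ((t["q"] >= 0) & (t["q"] <= 1)).all()
        ci = t["ci"].to_numpy()
        assert (np.diff(ci) >= -1e-12).all() and ci[-1] <= 1.0
        # n_{k+1} = n_k - d_k - w_k
        assert np.allclose(t["n"].iloc[1:], (t["n"] - t["d"] - t["w"]).iloc[:-1])

    def test_constant_hazard_matches_exponential_closed_form(self):
        lam, T, n = 0.01, 40.0, 10_000
        rng = np.random.default_rng(42)
        lt = build_life_table(exponential_cohort(rng, n, lam, censor_years=T))
        expected = 1.0 - math.exp(-lam * T)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(lt.cumulative_incidence(40) - expected) < 3 * se


class TestCurve:
    def test_no_events_all_zero(self):
        curve = cumulative_incidence_curve(
            build_life_table([censored_at(5.5, "a"), censored_at(6.5, "b")])
        )
        assert (curve["ci"] == 0).all()

    def test_single_subject_event_jumps_to_one(self):
        curve = cumulative_incidence_curve(build_life_table([case_at(5.5, "x")]))
        assert curve.loc[curve["t"] == 5.0, "ci"].item() == 0.0
        assert curve.loc[curve["t"] == 6.0, "ci"].item() == 1.0

    def test_curve_equals_product_oracle(self):
        rng = np.random.default_rng(9)
        lt = build_life_table(exponential_cohort(rng, 300, 0.02))
        expected = 1.0 - np.cumprod(1.0 - lt.table["q"].to_numpy())
        assert np.allclose(cumulative_incidence_curve(lt)["ci"].to_numpy()[1:], expected)


class TestAnnualAverageIncidence:
    def test_zero_events(self):
        lt = build_life_table([censored_at(41.0, f"c{i}") for i in range(10)])
        assert annual_average_incidence(lt, 40) == 0.0

    def test_scale_of_published_rates(self):
        # CI(40) = 0.32 corresponds to 8.0 per 1000 per year
        workers = [case_at(t + 0.5, f"d{t}") for t in range(32)]
        workers += [censored_at(40.5, f"c{i}") for i in range(68)]
        lt = build_life_table(workers)
        assert lt.cumulative_incidence(40) == pytest.approx(0.32)
        assert annual_average_incidence(lt, 40) == pytest.approx(0.008)

    def test_follow_up_beyond_span_rejected(self):
        lt = build_life_table([censored_at(10.5, "a")])
        with pytest.raises(ValueError, match="span"):
            annual_average_incidence(lt, 50)


class TestPetoLogrank:
    def test_exchangeable_groups_null(self):
        rng = np.random.default_rng(3)
        group = exponential_cohort(rng, 200, 0.02)
        res = peto_logrank(group, list(group))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = exponential_cohort(rng, 150, 0.03)
        b = exponential_cohort(rng, 150, 0.01)
        assert peto_logrank(a, b).statistic == pytest.approx(
            peto_logrank(b, a).statistic
        )

    def test_unit_weights_match_hand_calculation(self):
        # 6 subjects: A events at 1, 3, censored 5; B event at 2, censored 4,
        # event at 6. Hand-computed classic log-rank: U = 0.6, V = 0.74,
        # chi2 = 0.36/0.74 = 0.486486 (also confirmed with lifelines).
        a = [case_at(1, "a1"), case_at(3, "a2"), censored_at(5, "a3")]
        b = [case_at(2, "b1"), censored_at(4, "b2"), case_at(6, "b3")]
        res = peto_logrank(a, b, weighting="logrank")
        assert res.statistic == pytest.approx(0.36 / 0.74, rel=1e-6)

    def test_peto_weights_match_hand_calculation(self):
        # same 6 subjects; survival-weighted: U = 0.4, V = 0.342778
        a = [case_at(1, "a1"), case_at(3, "a2"), censored_at(5, "a3")]
        b = [case_at(2, "b1"), censored_at(4, "b2"), case_at(6, "b3")]
        res = peto_logrank(a, b, weighting="peto")
        assert res.statistic == pytest.approx(0.16 / 0.342778, rel=1e-4)

    def test_unit_weights_match_lifelines_on_random_data(self):
        from lifelines import statistics as lifelines_stats

        from cwprisk.cohort import observation_window

        rng = np.random.default_rng(21)
        a = exponential_cohort(rng, 120, 0.03)
        b = exponential_cohort(rng, 150, 0.015)
        ours = peto_logrank(a, b, weighting="logrank")
        ref = lifelines_stats.logrank_test(
            [observation_window(w) for w in a],
            [observation_window(w) for w in b],
            event_observed_A=[w.cwp_status for w in a],
            event_observed_B=[w.cwp_status for w in b],
        )
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-6)

    def test_tenfold_hazard_ratio_detected(self):
        rng = np.random.default_rng(11)
        a = exponential_cohort(rng, 2000, 0.02)
        b = exponential_cohort(rng, 2000, 0.002)
        assert peto_logrank(a, b).p_value < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            peto_logrank([], [censored_at(5, "x")])


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "cases, noncases, expected",
        [
            ((248, 245, 259, 86), (1137, 2559, 2022, 10467), 1168.1),
            ((710, 112, 16), (5854, 5798, 4533), 806.0),
            ((27, 146, 435, 230), (2485, 3051, 5031, 5618), 200.2),
            ((88, 238, 512), (10513, 3237, 2435), 1383.0),
        ],
    )
    def test_characteristic_tables(self, cases, noncases, expected):
        res = pearson_chi2([cases, noncases])
        assert round(res.statistic, 1) == expected
        assert res.df == len(cases) - 1
        assert res.p_display() == "<0.001"

    def test_identical_row_proportions_zero(self):
        assert pearson_chi2([[10, 20, 30], [100, 200, 300]]).statistic == pytest.approx(
            0.0, abs=1e-9
        )

    def test_permutation_and_scaling_invariance(self):
        base = np.array([[12, 7, 31], [45, 3, 22]])
        s0 = pearson_chi2(base).statistic
        assert pearson_chi2(base[::-1]).statistic == pytest.approx(s0)
        assert pearson_chi2(base[:, [2, 0, 1]]).statistic == pytest.approx(s0)
        assert pearson_chi2(3 * base).statistic == pytest.approx(3 * s0)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            pearson_chi2([[1, 2]])


class TestSubgroupRates:
    def test_recovers_generated_rate(self):
        import datetime as dt

        from cwprisk.simulate import CohortSpec, generate_cohort

        rate = 2.1e-3
        spec = CohortSpec(
            n_workers=5000,
            era_mix=(1.0, 0.0, 0.0),
            category_mix=(0.0, 1.0, 0.0, 0.0),
            entry_windows={"1970-": (dt.date(1971, 1, 1), dt.date(1971, 12, 31))},
            subgroup_annual_rates={("1970-", "mining"): rate},
            seed=8,
        )
        records, _ = generate_cohort(spec)
        (sg,) = subgroup_rates(records, follow_up=40)
        ci = sg.ci_at_followup
        se = math.sqrt(max(ci, 1e-6) * (1 - ci) / 5000) / 40
        assert abs(sg.annual_rate - rate) < 3 * se
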