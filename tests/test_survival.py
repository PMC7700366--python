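"""Survival: median split, KM estimator, log-rank, hazard ratio, map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import aarspan as ap
from aarspan.diffexpr import Cohort, ExpressionMatrix
from aarspan.registry import CancerType
from aarspan.survival import (
    DegenerateSplitError,
    SurvivalTable,
    aggressiveness_correlation,
    hazard_ratio,
    km_estimate,
    logrank_test,
    median_split,
    survival_map,
)


def _table(times, events, prefix="s"):
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": [f"{prefix}{i}" for i in range(len(times))],
                "time_months": list(map(float, times)),
                "event": list(map(int, events)),
            }
        )
    )


def brute_force_km(times, events):
    """Risk-set recomputation of the product-limit curve, one step per time."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e})
    s, out = 1.0, []
    for t in event_times:
        n = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei)
        s *= 1 - d / n
        out.append((t, s))
    return out


def brute_force_logrank(t1, e1, t2, e2):
    """2x2-per-event-time tabulation of O-E and hypergeometric variance."""
    event_times = sorted({t for t, e in zip(t1, e1) if e}
                         | {t for t, e in zip(t2, e2) if e})
    O1 = E1 = O2 = E2 = V = 0.0
    for t in event_times:
        n1 = sum(1 for x in t1 if x >= t)
        n2 = sum(1 for x in t2 if x >= t)
        d1 = sum(1 for x, e in zip(t1, e1) if x == t and e)
        d2 = sum(1 for x, e in zip(t2, e2) if x == t and e)
        n, d = n1 + n2, d1 + d2
        O1 += d1
        O2 += d2
        E1 += d * n1 / n
        E2 += d * n2 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    hr = ((O1 / E1) / (O2 / E2)) if (O1 > 0 and O2 > 0) else None
    return chi2, hr


survival_tables = st.lists(
    st.tuples(
        st.integers(min_value=1, max_value=20),  # integer times force ties
        st.booleans(),
    ),
    min_size=1,
    max_size=12,
)


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1, 2, 3, 4], index=list("abcd"))
        labels = median_split(s)
        assert set(labels[labels == "high"].index) == {"c", "d"}
        assert set(labels[labels == "low"].index) == {"a", "b"}

    def test_ties_at_median_go_low(self):
        s = pd.Series([1, 2, 2, 5], index=list("abcd"))
        labels = median_split(s)
        assert set(labels[labels == "high"].index) == {"d"}
        assert set(labels[labels == "low"].index) == {"a", "b", "c"}

    def test_degenerate_all_equal(self):
        with pytest.raises(DegenerateSplitError):
            median_split(pd.Series([7.0] * 6))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([1.0, 2.0, 3.0]))


class TestKmEstimate:
    def test_three_deaths_no_censoring(self):
        curve = km_estimate(_table([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_censoring_between_deaths(self):
        # deaths at 1 and 3, censored at 2: S(1)=2/3, S(3)=2/3*(1-1/1)=0
        curve = km_estimate(_table([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        assert curve.probability_at(2.5) == pytest.approx(2 / 3)

    def test_all_censored(self):
        curve = km_estimate(_table([5, 6, 7], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.probability_at(100) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(_table([], []))

    @given(survival_tables)
    def test_matches_bruteforce_risk_sets(self, rows):
        times = [t for t, _ in rows]
        events = [e for _, e in rows]
        curve = km_estimate(_table(times, events))
        brute = brute_force_km(times, events)
        assert len(curve.times) == len(brute)
        for (t, s), ct, cs in zip(brute, curve.times, curve.survival):
            assert ct == t
            assert cs == pytest.approx(s, abs=1e-12)

    @given(survival_tables)
    def test_matches_lifelines(self, rows):
        from lifelines import KaplanMeierFitter

        times = [float(t) for t, _ in rows]
        events = [int(e) for _, e in rows]
        curve = km_estimate(_table(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-9)

    def test_survival_curve_monotone(self):
        rng = np.random.default_rng(5)
        curve = km_estimate(
            _table(rng.exponential(10, 50), rng.integers(0, 2, 50))
        )
        assert (np.diff(curve.survival) <= 1e-15).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()


class TestLogrank:
    def test_identical_groups(self):
        t = _table([1, 2, 3, 4], [1, 1, 0, 1])
        t2 = _table([1, 2, 3, 4], [1, 1, 0, 1], prefix="u")
        chi2, p = logrank_test(t, t2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation_on_fixture(self):
        hi = _table([2, 4, 4, 7, 9, 10], [1, 1, 1, 1, 0, 1])
        lo = _table([1, 3, 5, 5, 8, 12], [1, 1, 1, 0, 1, 0], prefix="u")
        chi2, p = logrank_test(hi, lo)
        brute_chi2, brute_hr = brute_force_logrank(
            [2, 4, 4, 7, 9, 10], [1, 1, 1, 1, 0, 1],
            [1, 3, 5, 5, 8, 12], [1, 1, 1, 0, 1, 0],
        )
        assert chi2 == pytest.approx(brute_chi2, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(brute_chi2, 1), abs=1e-12)
        assert hazard_ratio(hi, lo) == pytest.approx(brute_hr, abs=1e-10)

    def test_time_scaling_invariance(self):
        hi = _table([2, 4, 7, 9], [1, 1, 0, 1])
        lo = _table([1, 3, 5, 8], [1, 1, 1, 0], prefix="u")
        scaled_hi = _table([20, 40, 70, 90], [1, 1, 0, 1])
        scaled_lo = _table([10, 30, 50, 80], [1, 1, 1, 0], prefix="u")
        assert logrank_test(hi, lo) == logrank_test(scaled_hi, scaled_lo)

    def test_zero_events_convention(self):
        hi = _table([5, 6], [0, 0])
        lo = _table([7, 8], [0, 0], prefix="u")
        assert logrank_test(hi, lo) == (0.0, 1.0)

    def test_matches_lifelines_on_random_groups(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        for _ in range(5):
            t1 = rng.exponential(10, 30)
            t2 = rng.exponential(15, 25)
            e1 = rng.integers(0, 2, 30)
            e2 = rng.integers(0, 2, 25)
            if e1.sum() == 0 or e2.sum() == 0:
                continue
            chi2, p = logrank_test(_table(t1, e1), _table(t2, e2, prefix="u"))
            ll = ll_logrank(t1, t2, e1, e2)
            assert chi2 == pytest.approx(ll.test_statistic, abs=1e-9)
            assert p == pytest.approx(ll.p_value, abs=1e-9)


class TestHazardRatio:
    def test_identical_groups_unity(self):
        hi = _table([1, 2, 3, 4], [1, 1, 1, 0])
        lo = _table([1, 2, 3, 4], [1, 1, 1, 0], prefix="u")
        assert hazard_ratio(hi, lo) == pytest.approx(1.0)

    def test_zero_events_in_group_undefined(self):
        hi = _table([5, 6], [0, 0])
        lo = _table([1, 2], [1, 1], prefix="u")
        assert hazard_ratio(hi, lo) is None

    def test_label_swap_inverts(self):
        rng = np.random.default_rng(2)
        hi = _table(rng.exponential(5, 20), np.ones(20))
        lo = _table(rng.exponential(10, 20), np.ones(20), prefix="u")
        hr = hazard_ratio(hi, lo)
        assert hazard_ratio(lo, hi) == pytest.approx(1 / hr, abs=1e-10)
        chi_a, _ = logrank_test(hi, lo)
        chi_b, _ = logrank_test(lo, hi)
        assert chi_a == pytest.approx(chi_b, abs=1e-10)

    @given(survival_tables, survival_tables)
    def test_matches_bruteforce_tabulation(self, rows1, rows2):
        t1 = [t for t, _ in rows1]
        e1 = [int(e) for _, e in rows1]
        t2 = [t for t, _ in rows2]
        e2 = [int(e) for _, e in rows2]
        brute_chi2, brute_hr = brute_force_logrank(t1, e1, t2, e2)
        hi, lo = _table(t1, e1), _table(t2, e2, prefix="u")
        chi2, _ = logrank_test(hi, lo)
        assert chi2 == pytest.approx(brute_chi2, abs=1e-10)
        hr = hazard_ratio(hi, lo)
        if brute_hr is None:
            assert hr is None
        else:
            assert hr == pytest.approx(brute_hr, abs=1e-10)


class TestSurvivalMap:
    def test_single_cell_q_equals_p(self):
        rng = np.random.default_rng(4)
        samples = [f"t{i}" for i in range(20)]
        expr = {"X": ExpressionMatrix(
            pd.DataFrame(rng.gamma(3, 10, size=(1, 20)), index=["g"],
                         columns=samples), Cohort.TUMOR)}
        surv = {"X": _table(rng.exponential(20, 20),
                            rng.integers(0, 2, 20), prefix="t")}
        # align sample ids with the expression columns
        surv["X"].rows["sample_id"] = samples
        sm = survival_map(expr, surv, ["g"], [CancerType("X", "x", 10)])
        (res,) = sm.results
        assert res.q_value == pytest.approx(res.logrank_p)

    def test_planted_drivers_direction(self, paper_cohort):
        cfg = paper_cohort.config
        sm = survival_map(paper_cohort.expression_tumor, paper_cohort.survival,
                          cfg.genes, paper_cohort.cancer_types)
        for gene, arch in cfg.archetype.items():
            row = sm.totals.loc[gene]
            if arch == "oncogene_like":
                assert row["n_unfavorable"] >= 1
                assert row["n_favorable"] == 0
            else:
                # suppressor drivers must never be called unfavorable
                assert row["n_unfavorable"] == 0
        # most suppressor drivers reach a significant favorable call
        supp = [g for g, a in cfg.archetype.items() if a == "suppressor_like"]
        assert sum(sm.totals.loc[g, "n_favorable"] >= 1 for g in supp) >= 3

    def test_missing_survival_column_not_evaluable(self, small_cohort):
        cfg = small_cohort.config
        surv = dict(small_cohort.survival)
        dropped = small_cohort.cancers[-1]
        surv[dropped] = None
        sm = survival_map(small_cohort.expression_tumor, surv,
                          cfg.genes, small_cohort.cancer_types)
        assert sm.hazard_ratios[dropped].isna().all()


class TestAggressivenessCorrelation:
    def test_perfect_positive(self):
        cancers = [CancerType(f"C{i}", "x", float(i + 1)) for i in range(5)]
        counts = {f"C{i}": 2 * (i + 1) for i in range(5)}
        r, p = aggressiveness_correlation(cancers, counts)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        cancers = [CancerType(f"C{i}", "x", float(x)) for i, x in
                   enumerate([1, 2, 3])]
        counts = {"C0": 3, "C1": 2, "C2": 1}
        r, _ = aggressiveness_correlation(cancers, counts)
        assert r == pytest.approx(-1.0)

    def test_exclusion_list(self):
        cancers = [CancerType(f"C{i}", "x", float(i + 1)) for i in range(6)]
        counts = {f"C{i}": i for i in range(6)}
        counts["C5"] = 0  # outlier removed by exclusion
        r_all, _ = aggressiveness_correlation(cancers, counts)
        r_excl, _ = aggressiveness_correlation(cancers, counts, exclude=["C5"])
        assert r_excl == pytest.approx(1.0)
        assert r_all < r_excl

    def test_too_few_points(self):
        cancers = [CancerType("A", "x", 1.0), CancerType("B", "x", 2.0)]
        with pytest.raises(ValueError):
            aggressiveness_correlation(cancers, {"A": 1, "B": 2})

    def test_type_one_error_rate_under_null(self):
        # i.i.d. noise pairs, n=10: |r| should exceed the p<0.05 critical
        # value in about 5% of replicates
        rng = np.random.default_rng(123)
        n_sig = 0
        reps = 2000
        for _ in range(reps):
            os_months = rng.exponential(20, size=10) + 1
            counts = rng.integers(0, 40, size=10)
            cancers = [CancerType(f"C{i}", "x", float(t))
                       for i, t in enumerate(os_months)]
            _, p = aggressiveness_correlation(
                cancers, {f"C{i}": int(c) for i, c in enumerate(counts)}
            )
            n_sig += p < 0.05
        assert 0.04 <= n_sig / reps <= 0.06
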