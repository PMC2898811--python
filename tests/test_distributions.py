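import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from eventscan.distributions import (
    CompoundPoissonNull,
    EventClassMarginals,
    HypergeomCaseNull,
    MultipleHypergeomNull,
    OccupancyNull,
    ScenarioDistribution,
    StratifiedEventNull,
    StratifiedOccupancyNull,
    hypergeom_pmf,
    multiple_hypergeom_pmf,
    multiple_hypergeom_tail,
    occupancy_pmf,
    stratified_occupancy_pmf,
    stratified_pmf,
)
from oracles import (
    enum_occupancy_pmf,
    enum_sample_event_pmf,
    enum_stratified_event_pmf,
    enum_stratified_occupancy_pmf,
    members_from_classes,
)

TOL = 1e-10


# strategy: small class-count vectors with n <= 12, Y <= 3, V <= 8
@st.composite
def small_marginals(draw):
    c1 = draw(st.integers(0, 6))
    c2 = draw(st.integers(0, 3))
    c3 = draw(st.integers(0, 2))
    v = c1 + 2 * c2 + 3 * c3
    if v > 8:
        c3 = 0
        v = c1 + 2 * c2
    if v > 8:
        c2 = 0
        v = c1
    n = draw(st.integers(max(1, c1 + c2 + c3), 12))
    m = draw(st.integers(0, n))
    return (c1, c2, c3), n, m


class TestHypergeomCase:
    def test_sample_is_whole_population(self):
        assert hypergeom_pmf(2, 5, 2, 5) == pytest.approx(1.0)

    def test_subset_enumeration_value(self):
        # 20 subsets of size 3 from 6 individuals, 2 of them cases
        assert hypergeom_pmf(1, 3, 2, 6) == pytest.approx(0.6, abs=TOL)

    def test_normalization(self):
        null = HypergeomCaseNull(3, 9)
        assert null.pmf_array(4).sum() == pytest.approx(1.0, abs=TOL)

    def test_matches_scipy(self):
        null = HypergeomCaseNull(5, 11)
        for m in range(12):
            np.testing.assert_allclose(
                null.pmf_array(m),
                stats.hypergeom.pmf(np.arange(6), 11, 5, m),
                atol=TOL,
            )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            HypergeomCaseNull(-1, 5)
        with pytest.raises(ValueError):
            HypergeomCaseNull(6, 5)
        with pytest.raises(ValueError):
            HypergeomCaseNull(2, 5).pmf_array(6)
        with pytest.raises(ValueError):
            hypergeom_pmf(1.5, 3, 2, 6)


class TestMultipleHypergeom:
    def test_single_two_event_case(self):
        # n=4, one case with 2 events, sample half: case in sample w.p. 1/2
        marg = EventClassMarginals((0, 1), 4)
        assert multiple_hypergeom_pmf(2, 2, marg) == pytest.approx(0.5, abs=TOL)
        assert multiple_hypergeom_pmf(0, 2, marg) == pytest.approx(0.5, abs=TOL)

    def test_reduces_to_hypergeom_when_one_event_per_case(self):
        marg = EventClassMarginals((4,), 9)
        for m in range(10):
            for x in range(5):
                assert multiple_hypergeom_pmf(x, m, marg) == pytest.approx(
                    hypergeom_pmf(x, m, 4, 9), abs=TOL
                )

    def test_whole_population_mass_at_total_events(self):
        marg = EventClassMarginals((2, 1, 1), 7)
        null = MultipleHypergeomNull(marg)
        assert null.pmf(marg.total_events, 7) == pytest.approx(1.0, abs=TOL)

    def test_tail_trivia(self):
        marg = EventClassMarginals((2, 1), 6)
        assert multiple_hypergeom_tail(0, 3, marg) == pytest.approx(1.0)
        assert multiple_hypergeom_tail(marg.total_events + 1, 3, marg) == 0.0

    def test_tail_against_subset_enumeration(self):
        marg = EventClassMarginals((2, 1), 6)  # v = 4
        oracle = enum_sample_event_pmf(members_from_classes((2, 1), 6), 3)
        assert multiple_hypergeom_tail(2, 3, marg) == pytest.approx(
            oracle[2:].sum(), abs=TOL
        )

    @given(small_marginals())
    def test_pmf_matches_enumeration(self, case):
        counts, n, m = case
        marg = EventClassMarginals(counts, n)
        null = MultipleHypergeomNull(marg)
        oracle = enum_sample_event_pmf(members_from_classes(counts, n), m)
        np.testing.assert_allclose(null.pmf_array(m), oracle, atol=TOL)

    @given(small_marginals())
    def test_sums_to_one_and_mean_identity(self, case):
        counts, n, m = case
        null = MultipleHypergeomNull(EventClassMarginals(counts, n))
        pmf = null.pmf_array(m)
        assert pmf.sum() == pytest.approx(1.0, abs=TOL)
        assert (pmf * np.arange(pmf.size)).sum() == pytest.approx(
            m * null.v / n, abs=TOL
        )

    @given(small_marginals())
    def test_tail_monotone_in_k_and_m(self, case):
        counts, n, m = case
        null = MultipleHypergeomNull(EventClassMarginals(counts, n))
        tails = [null.tail(k, m) for k in range(null.v + 2)]
        assert all(a >= b - TOL for a, b in zip(tails, tails[1:]))
        if m < n:
            for k in range(null.v + 1):
                assert null.tail(k, m + 1) >= null.tail(k, m) - TOL

    def test_large_instance_is_stable(self):
        # population-scale marginals: pmf must still be a proper distribution.
        # log-gamma carries ~1e-9 absolute error at arguments this large, so
        # the normalization check is held to 1e-8 rather than the 1e-10 used
        # on enumerable instances.
        marg = EventClassMarginals((699, 130, 43), 544000)
        null = MultipleHypergeomNull(marg)
        pmf = null.pmf_array(8000)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-8)
        assert (pmf * np.arange(pmf.size)).sum() == pytest.approx(
            8000 * 1088 / 544000, rel=1e-8
        )


class TestCompoundPoisson:
    def test_degenerate_compounding_is_poisson(self):
        null = CompoundPoissonNull(ScenarioDistribution((1.0,)), 12.0, 100)
        lam = 30 * 12.0 / 100
        p = null.pmf_array(30)
        np.testing.assert_allclose(
            p, stats.poisson.pmf(np.arange(p.size), lam), atol=1e-12
        )

    def test_zero_events_probability(self):
        null = CompoundPoissonNull(ScenarioDistribution((0.6, 0.3, 0.1)), 9.0, 90)
        assert null.pmf(0, 30) == pytest.approx(np.exp(-3.0), abs=1e-12)

    def test_mean_identity_at_event_rate(self):
        # 2 events per 1000 population: mean events in m=1000 is 2.0
        q = ScenarioDistribution((0.6, 0.3, 0.1))
        null = CompoundPoissonNull(q, 136 / 1.5, 68000)
        p = null.pmf_array(1000)
        assert (p * np.arange(p.size)).sum() == pytest.approx(2.0, abs=1e-9)

    def test_truncation_tolerance(self):
        null = CompoundPoissonNull(
            ScenarioDistribution((0.5, 0.5)), 20.0, 200, tol=1e-12
        )
        assert 0 <= 1.0 - null.pmf_array(100).sum() < 1e-12

    def test_non_integer_case_total_allowed(self):
        CompoundPoissonNull(ScenarioDistribution((1.0,)), 90.67, 68000)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            CompoundPoissonNull(ScenarioDistribution((1.0,)), -1.0, 10)


class TestScenarioDistribution:
    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError):
            ScenarioDistribution((0.5, 0.4))  # sums to 0.9
        with pytest.raises(ValueError):
            ScenarioDistribution((-0.1, 1.1))

    def test_renormalizes_near_one_with_warning(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            s = ScenarioDistribution((0.929, 0.058, 0.008, 0.001, 0.001, 0.002))
        assert sum(s.probabilities) == pytest.approx(1.0, abs=1e-15)


class TestOccupancy:
    def test_uniform_on_three_configurations(self):
        # 2 events among 2 people: (2,0), (1,1), (0,2) equally likely
        null = OccupancyNull(2, 2)
        np.testing.assert_allclose(null.pmf_array(1), [1 / 3] * 3, atol=TOL)

    def test_whole_population(self):
        assert occupancy_pmf(3, 5, 3, 5) == pytest.approx(1.0, abs=TOL)

    def test_mean_identity(self):
        null = OccupancyNull(3, 5)
        p = null.pmf_array(2)
        assert (p * np.arange(4)).sum() == pytest.approx(3 * 2 / 5, abs=TOL)

    @pytest.mark.parametrize("n,V", [(3, 4), (5, 3), (12, 8), (7, 1)])
    def test_matches_enumeration(self, n, V):
        null = OccupancyNull(V, n)
        for m in range(n + 1):
            np.testing.assert_allclose(
                null.pmf_array(m), enum_occupancy_pmf(n, V, m), atol=TOL
            )

    def test_invalid(self):
        with pytest.raises(ValueError):
            OccupancyNull(-1, 5)
        with pytest.raises(ValueError):
            OccupancyNull(2, 5).pmf_array(6)


class TestStratified:
    def test_single_stratum_reduces_to_unstratified(self):
        marg = EventClassMarginals((2, 1), 6)
        strat = StratifiedEventNull([marg])
        plain = MultipleHypergeomNull(marg)
        for m in range(7):
            np.testing.assert_allclose(
                strat.pmf_array([m]), plain.pmf_array(m), atol=TOL
            )

    def test_two_strata_match_full_enumeration(self):
        counts_s = [(0, 1), (0, 1)]
        n_s = [4, 4]
        m_s = [2, 2]
        oracle = enum_stratified_event_pmf(counts_s, n_s, m_s)
        strat = StratifiedEventNull(
            [EventClassMarginals(c, n) for c, n in zip(counts_s, n_s)]
        )
        np.testing.assert_allclose(strat.pmf_array(m_s), oracle, atol=TOL)

    def test_heterogeneous_strata_against_enumeration(self):
        counts_s = [(2, 1), (1, 0, 1)]
        n_s = [6, 5]
        m_s = [3, 2]
        oracle = enum_stratified_event_pmf(counts_s, n_s, m_s)
        got = [
            stratified_pmf(
                x, m_s, [EventClassMarginals(c, n) for c, n in zip(counts_s, n_s)]
            )
            for x in range(oracle.size)
        ]
        np.testing.assert_allclose(got, oracle, atol=TOL)

    def test_full_sample_mass_at_total_events(self):
        margs = [EventClassMarginals((2, 1), 6), EventClassMarginals((1,), 3)]
        strat = StratifiedEventNull(margs)
        v = sum(m.total_events for m in margs)
        assert strat.pmf(v, [6, 3]) == pytest.approx(1.0, abs=TOL)

    def test_stratified_occupancy_reduces_and_convolves(self):
        plain = OccupancyNull(2, 2)
        strat = StratifiedOccupancyNull([2], [2])
        np.testing.assert_allclose(strat.pmf_array([1]), plain.pmf_array(1), atol=TOL)
        two = StratifiedOccupancyNull([2, 2], [2, 2])
        np.testing.assert_allclose(
            two.pmf_array([1, 1]),
            np.convolve([1 / 3] * 3, [1 / 3] * 3),
            atol=TOL,
        )

    def test_stratified_occupancy_against_enumeration(self):
        v_s, n_s, m_s = [3, 2], [4, 3], [2, 1]
        oracle = enum_stratified_occupancy_pmf(v_s, n_s, m_s)
        got = [stratified_occupancy_pmf(x, m_s, v_s, n_s) for x in range(6)]
        np.testing.assert_allclose(got, oracle, atol=TOL)

    def test_impossible_event_count_is_zero(self):
        assert stratified_occupancy_pmf(6, [1, 1], [2, 3], [2, 3]) == 0.0

    def test_mismatched_strata_rejected(self):
        with pytest.raises(ValueError):
            StratifiedOccupancyNull([1, 2], [5])
        with pytest.raises(ValueError):
            StratifiedEventNull([EventClassMarginals((1,), 4)]).pmf_array([2, 2])
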