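"""Indicator series, autocorrelation, correlation times, water exchange."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquabridge.contacts import HBond, WaterBridge
from aquabridge.errors import ContractViolationError, NoEventError
from aquabridge.lifetimes import (
    CorrelationResult,
    IndicatorSeries,
    aggregate_replicas,
    autocorrelation,
    correlation_time,
    indicator_from_categories,
    indicator_series,
    pooled_correlation,
    water_exchange,
)
from aquabridge.synthetic import GroundTruth, markov_indicator_series


def _leg(d=0, a=1):
    return HBond(donor_atom=d, acceptor_atom=a, distance_A=2.8)


def _bridge(water):
    return WaterBridge(
        ligand_atom=0, water_residue=water, target_atom=1,
        leg1=_leg(), leg2=_leg(2, 3),
    )


class TestIndicator:
    def test_direct_mode_from_bundles(self):
        bundles = [
            {"direct": [_leg()], "bridges": []},
            {"direct": [], "bridges": []},
            {"direct": [_leg()], "bridges": []},
        ]
        s = indicator_series(bundles, [0.0, 0.1, 0.2], "direct")
        assert s.h.tolist() == [1, 0, 1]

    def test_water_mediated_is_identity_agnostic(self):
        bundles = [
            {"direct": [], "bridges": [_bridge(501)]},
            {"direct": [], "bridges": [_bridge(733)]},
        ]
        s = indicator_series(bundles, [0.0, 0.1], "water_mediated")
        assert s.h.tolist() == [1, 1]

    def test_water_mediated_equals_or_over_per_water_indicators(self):
        rng = np.random.default_rng(0)
        waters = [500, 501, 502]
        bundles = []
        for _ in range(100):
            present = [w for w in waters if rng.random() < 0.3]
            bundles.append({"direct": [], "bridges": [_bridge(w) for w in present]})
        times = np.arange(100) * 0.1
        combined = indicator_series(bundles, times, "water_mediated").h
        per_water = np.zeros(100, dtype=int)
        for w in waters:
            hw = np.array(
                [any(b.water_residue == w for b in fc["bridges"]) for fc in bundles],
                dtype=int,
            )
            per_water |= hw
        np.testing.assert_array_equal(combined, per_water)

    def test_empty_table_gives_zeros(self):
        bundles = [{"direct": [], "bridges": []}] * 5
        s = indicator_series(bundles, np.arange(5) * 0.1, "any_polar")
        assert s.h.tolist() == [0] * 5

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            indicator_series([], [], "direct")

    def test_from_categories(self):
        cats = ["DIRECT_INTERACTION", "NO_POLAR_CONTACT", "WATER_MEDIATED_ONLY"]
        assert indicator_from_categories(cats, [0, 0.1, 0.2], "direct").h.tolist() == [1, 0, 0]
        assert indicator_from_categories(cats, [0, 0.1, 0.2], "any_polar").h.tolist() == [1, 0, 1]


class TestAutocorrelation:
    def test_constant_one_stays_one(self):
        s = IndicatorSeries(0, np.arange(50) * 0.1, np.ones(50))
        c = autocorrelation(s)
        np.testing.assert_allclose(c.C, 1.0)

    def test_period_two_alternation(self):
        h = np.tile([1, 0], 50)
        s = IndicatorSeries(0, np.arange(100) * 1.0, h)
        c = autocorrelation(s)
        assert c.C[0] == pytest.approx(1.0)
        assert c.C[1] == pytest.approx(0.0, abs=1e-12)
        assert c.C[2] == pytest.approx(1.0, rel=0.05)

    def test_all_zero_raises_no_event(self):
        s = IndicatorSeries(0, np.arange(10) * 0.1, np.zeros(10))
        with pytest.raises(NoEventError) as exc:
            autocorrelation(s)
        assert exc.value.mean_occupancy == 0.0

    def test_max_lag_beyond_half_duration_rejected(self):
        s = IndicatorSeries(0, np.arange(10) * 0.1, np.ones(10))
        with pytest.raises(ValueError):
            autocorrelation(s, max_lag_ns=0.8)

    def test_matches_analytic_two_state_form(self):
        truth = GroundTruth(k_on=0.1, k_off=0.1, seed=20, n_replicas=8,
                            n_frames=5000, dt_ns=0.1)
        curves = [autocorrelation(markov_indicator_series(truth, r)) for r in range(8)]
        pooled = pooled_correlation(curves)
        lam = 0.2
        mask = pooled.lags_ns <= 3.0 / lam  # early lags, where decay lives
        expect = 0.5 + 0.5 * np.exp(-lam * pooled.lags_ns[mask])
        # cross-replica SE of the pooled curve at these lags is ~0.01-0.02
        np.testing.assert_allclose(pooled.C[mask], expect, atol=0.08)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=200).filter(sum))
    def test_bounds_and_normalisation(self, bits):
        s = IndicatorSeries(0, np.arange(len(bits)) * 0.1, np.array(bits))
        c = autocorrelation(s)
        assert c.C[0] == pytest.approx(1.0)
        assert np.all(c.C >= -1e-12) and np.all(c.C <= 1 + 1e-12)
        assert c.mean_occupancy == pytest.approx(np.mean(bits))


class TestCorrelationTime:
    def make_exp(self, tau=5.0, tmax=50.0, dt=0.1, c_inf=0.0):
        lags = np.arange(0.0, tmax + dt / 2, dt)
        C = c_inf + (1 - c_inf) * np.exp(-lags / tau)
        return CorrelationResult(lags_ns=lags, C=C, mean_occupancy=c_inf)

    @pytest.mark.parametrize("method", ["integral", "exponential_fit"])
    def test_closed_form_exponential_within_2pct(self, method):
        corr = self.make_exp()
        out = correlation_time(corr, method)
        assert out.tau_ns == pytest.approx(5.0, rel=0.02)
        assert not out.censored
        assert out.tau_method == method

    @pytest.mark.parametrize("method", ["integral", "exponential_fit"])
    def test_plateaued_exponential_within_2pct(self, method):
        corr = self.make_exp(c_inf=0.5)
        out = correlation_time(corr, method)
        assert out.tau_ns == pytest.approx(5.0, rel=0.02)

    def test_constant_curve_is_censored(self):
        lags = np.arange(0.0, 10.0, 0.1)
        corr = CorrelationResult(lags_ns=lags, C=np.ones_like(lags),
                                 mean_occupancy=1.0)
        out = correlation_time(corr, "integral")
        assert out.censored and out.tau_ns == pytest.approx(lags[-1])

    def test_bad_c0_violates_contract(self):
        lags = np.arange(0.0, 5.0, 0.1)
        corr = CorrelationResult(lags_ns=lags, C=np.full_like(lags, 0.4),
                                 mean_occupancy=0.4)
        with pytest.raises(ContractViolationError):
            correlation_time(corr, "integral")

    def test_markov_relaxation_time_recovered_within_20pct(self):
        truth = GroundTruth(k_on=0.1, k_off=0.1, seed=20, n_replicas=8,
                            n_frames=5000, dt_ns=0.1)
        curves = [autocorrelation(markov_indicator_series(truth, r)) for r in range(8)]
        pooled = correlation_time(pooled_correlation(curves), "integral")
        assert pooled.tau_ns == pytest.approx(truth.relax_time_ns, rel=0.2)
        # per-replica estimates are individually noisy (few tens of
        # on/off events each); their mean must still bracket the truth
        # within its own standard error
        per = [correlation_time(c, "integral").tau_ns for c in curves]
        agg = aggregate_replicas(per)
        assert abs(agg.mean - truth.relax_time_ns) < 4 * agg.sem
        assert agg.sem > 0


class TestAggregate:
    def test_worked_example(self):
        agg = aggregate_replicas([4, 5, 6, 5, 5, 4, 6, 5])
        assert agg.mean == pytest.approx(5.0)
        assert agg.sem == pytest.approx(0.267, abs=5e-4)
        assert agg.n == 8

    def test_equal_values_sem_zero(self):
        assert aggregate_replicas([3.3, 3.3, 3.3]).sem == pytest.approx(0.0, abs=1e-12)

    def test_single_value_sem_undefined(self):
        agg = aggregate_replicas([7.0])
        assert agg.mean == 7.0 and np.isnan(agg.sem)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_replicas([])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a, b = aggregate_replicas(values), aggregate_replicas(shuffled)
        assert a.mean == pytest.approx(b.mean, rel=1e-12, abs=1e-12)
        assert a.sem == pytest.approx(b.sem, rel=1e-9, abs=1e-12)


class TestWaterExchange:
    def test_counting_example(self):
        records = [[_bridge(501)], [_bridge(501)], [_bridge(733)], [_bridge(733)]]
        ex = water_exchange(records)
        assert ex.n_bridge_frames == 4
        assert ex.n_identity_switches == 1
        assert ex.distinct_waters == 2

    def test_no_bridges_all_zero(self):
        ex = water_exchange([[], [], []])
        assert (ex.n_bridge_frames, ex.n_identity_switches, ex.distinct_waters) == (
            0, 0, 0,
        )

    def test_switch_count_bounded_by_bridge_frames(self):
        rng = np.random.default_rng(3)
        records = []
        for _ in range(200):
            if rng.random() < 0.6:
                records.append([_bridge(int(rng.integers(500, 505)))])
            else:
                records.append([])
        ex = water_exchange(records)
        assert ex.n_identity_switches <= max(0, ex.n_bridge_frames - 1)
        assert ex.distinct_waters >= 1

    def test_configured_swap_probability_recovered(self):
        """Frozen-unbound, always-bridged scene: switch fraction ~ 0.5."""
        from aquabridge.contacts import detect_water_bridges
        from aquabridge.synthetic import generate_frames
        from aquabridge.topology import Frame, select_atoms

        truth = GroundTruth(k_on=0.0, k_off=1.0, p_bridge=1.0,
                            water_swap_prob=0.5, seed=9, n_replicas=1,
                            n_frames=400, dt_ns=0.1, start_state=0)
        top, frames, log = generate_frames(truth, 0)
        lig = select_atoms(top, resname="LIG")
        focal = select_atoms(top, chain="A", resid=95)
        records = [
            detect_water_bridges(Frame(index=i, time_ns=0.0, coords=c), top,
                                 lig, focal)
            for i, c in enumerate(frames)
        ]
        ex = water_exchange(records)
        assert ex.n_bridge_frames == 400
        # 4-sigma binomial band around 0.5 with n = 399
        assert ex.switch_fraction == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(399))
        # identity-agnostic indicator is unaffected by the swapping
        s = indicator_series(
            [{"direct": [], "bridges": r} for r in records],
            np.arange(400) * 0.1, "water_mediated",
        )
        assert s.h.tolist() == [1] * 400
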