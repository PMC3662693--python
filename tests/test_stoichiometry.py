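"""Nitrogen/electron bookkeeping: closure, electron ledger, CE, gas split."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from denitcath import stoichiometry as st


class TestCurrentAndSupply:
    @pytest.mark.parametrize(
        "density,volume,expected",
        [(15.0, 145e-6, 2.175e-3), (0.0, 145e-6, 0.0), (14.1, 145e-6, 2.0445e-3)],
    )
    def test_current_from_density(self, density, volume, expected):
        assert st.current_from_density(density, volume) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "current,expected",
        [(2.175e-3, 2.175e-3 * 86400 / 96485), (0.0, 0.0), (96485 / 86400, 1.0)],
    )
    def test_electron_supply(self, current, expected):
        assert st.electron_supply(current) == pytest.approx(expected)
        if current == 2.175e-3:
            assert expected == pytest.approx(1.9477e-3, rel=1e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.current_from_density(-1.0, 145e-6)
        with pytest.raises(ValueError):
            st.electron_supply(-0.1)


class TestNitrogenBalance:
    def test_removal_period1(self, reference_periods):
        balance = st.nitrogen_removed(reference_periods["period1"])
        assert balance.removed_concentration == pytest.approx(4.1)
        assert balance.removed_n == pytest.approx(8.2)

    def test_removal_period3_includes_consumed_nitrite(self, reference_periods):
        balance = st.nitrogen_removed(reference_periods["period3"])
        assert balance.delta_no2 < 0  # nitrite consumed, not produced
        assert balance.removed_concentration == pytest.approx(18.6)

    def test_no_change_means_no_removal(self):
        p = st.OperatingPeriod(
            "x", flow=2.0, no3_in=5.0, no3_out=5.0, no2_in=1.0, no2_out=1.0
        )
        assert st.nitrogen_removed(p).removed_n == 0.0

    def test_missing_species_named_in_error(self):
        p = st.OperatingPeriod("x", flow=1.0, no3_in=5.0, no3_out=1.0)
        with pytest.raises(ValueError, match="no2_in"):
            st.nitrogen_removed(p)

    def test_no_is_pinned_to_zero(self, reference_periods):
        assert st.nitrogen_removed(reference_periods["period1"]).delta_no == 0.0

    @pytest.mark.parametrize(
        "period_id,n2o,expected_n2",
        [("period1", 0.6, 3.5), ("period2", 4.0, 3.8), ("period3", 13.0, 5.6)],
    )
    def test_closure_reproduces_effluent_n2(
        self, reference_periods, period_id, n2o, expected_n2
    ):
        n2 = st.estimate_n2_by_closure(reference_periods[period_id], n2o)
        assert n2 == pytest.approx(expected_n2, abs=1e-9)

    def test_closure_residual_exactly_zero(self, reference_periods):
        for p in reference_periods.values():
            balance = st.close_balance(p, p.n2o_out)
            assert balance.closure_residual == pytest.approx(0.0, abs=1e-12)

    def test_n2o_equal_to_removed_gives_zero_n2(self, reference_periods):
        p = reference_periods["period1"]
        assert st.estimate_n2_by_closure(p, 4.1) == pytest.approx(0.0)

    def test_infeasible_n2o_rejected(self, reference_periods):
        with pytest.raises(ValueError, match="infeasible"):
            st.estimate_n2_by_closure(reference_periods["period1"], 10.0)


class TestElectronDemand:
    def test_period1_hand_value(self):
        balance = st.NitrogenBalance(
            delta_no3=8.0, delta_no2=-0.2, delta_n2o=1.2, delta_n2=7.0
        )
        demand = st.electron_demand(balance)
        # (2*8.0 + 2*8.2 + 1*7.0) mg N/d over 14.007 g/mol
        assert sum(demand.values()) == pytest.approx(39.4 / 14007.0, rel=1e-12)
        assert sum(demand.values()) == pytest.approx(2.813e-3, rel=1e-3)

    def test_zero_balance_zero_demand(self):
        balance = st.NitrogenBalance(delta_no3=0.0, delta_no2=0.0)
        assert sum(st.electron_demand(balance).values()) == 0.0

    def test_five_electrons_per_nitrate_to_n2(self):
        balance = st.NitrogenBalance(
            delta_no3=14.007, delta_no2=0.0, delta_n2o=0.0, delta_n2=14.007
        )
        assert sum(st.electron_demand(balance).values()) == pytest.approx(5.0e-3)

    def test_three_electrons_per_nitrite_to_n2(self):
        balance = st.NitrogenBalance(
            delta_no3=0.0, delta_no2=-14.007, delta_n2o=0.0, delta_n2=14.007
        )
        assert sum(st.electron_demand(balance).values()) == pytest.approx(3.0e-3)

    def test_unclosed_balance_rejected(self):
        balance = st.NitrogenBalance(delta_no3=10.0, delta_no2=0.0)
        with pytest.raises(ValueError, match="not closed"):
            st.electron_demand(balance)

    @given(scale=st_.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_demand_homogeneous_in_loads(self, scale):
        base = st.NitrogenBalance(
            delta_no3=8.0, delta_no2=-0.2, delta_n2o=1.2, delta_n2=7.0
        )
        scaled = st.NitrogenBalance(
            delta_no3=8.0 * scale, delta_no2=-0.2 * scale,
            delta_n2o=1.2 * scale, delta_n2=7.0 * scale,
        )
        assert sum(st.electron_demand(scaled).values()) == pytest.approx(
            scale * sum(st.electron_demand(base).values())
        )


class TestGasSplit:
    def test_supply_at_lower_boundary_all_n2o(self):
        split = st.split_gas_by_electron_balance(1.0, supply=4.0, pre_gas_demand=2.0)
        assert (split.n2o, split.n2) == (1.0, 0.0)

    def test_supply_at_upper_boundary_all_n2(self):
        split = st.split_gas_by_electron_balance(1.0, supply=5.0, pre_gas_demand=2.0)
        assert (split.n2o, split.n2) == (0.0, 1.0)

    def test_interpolates_between_boundaries(self):
        split = st.split_gas_by_electron_balance(1.0, supply=4.5, pre_gas_demand=2.0)
        assert split.n2o == pytest.approx(0.5)
        assert split.n2 == pytest.approx(0.5)
        assert not split.clamped

    def test_clamping_sets_flag(self):
        low = st.split_gas_by_electron_balance(1.0, supply=0.0, pre_gas_demand=2.0)
        high = st.split_gas_by_electron_balance(1.0, supply=50.0, pre_gas_demand=2.0)
        assert low.clamped and high.clamped
        assert low.n2 == 0.0 and high.n2 == 1.0

    @given(
        gas=st_.floats(0.01, 10.0),
        s1=st_.floats(0.0, 50.0),
        s2=st_.floats(0.0, 50.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_supply_and_conserves_gas(self, gas, s1, s2):
        lo, hi = sorted((s1, s2))
        a = st.split_gas_by_electron_balance(gas, lo, pre_gas_demand=1.0)
        b = st.split_gas_by_electron_balance(gas, hi, pre_gas_demand=1.0)
        assert b.n2 >= a.n2 - 1e-12
        for split in (a, b):
            assert split.n2o + split.n2 == pytest.approx(gas)
            assert 0.0 <= split.n2 <= gas


class TestCoulombicEfficiencyAndShares:
    def test_period1_derived_value(self):
        assert st.coulombic_efficiency(1.948e-3, 2.8129e-3) == pytest.approx(
            69.25, abs=0.1
        )

    @pytest.mark.parametrize("supply,demand,expected", [(1.0, 1.0, 100.0), (1.0, 4.0, 25.0)])
    def test_simple_ratios(self, supply, demand, expected):
        assert st.coulombic_efficiency(supply, demand) == expected

    def test_zero_demand_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            st.coulombic_efficiency(1.0, 0.0)

    @given(
        supply=st_.floats(1e-6, 10.0),
        demand=st_.floats(1e-6, 10.0),
        scale=st_.floats(0.01, 1000.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_ce_scale_invariant(self, supply, demand, scale):
        assert st.coulombic_efficiency(supply, demand) == pytest.approx(
            st.coulombic_efficiency(supply * scale, demand * scale)
        )

    def test_n2o_share_period3(self, reference_periods):
        balance = st.close_balance(reference_periods["period3"], 13.0)
        share = st.n2o_share(balance.delta_n2o, balance.removed_n)
        assert share == pytest.approx(69.9, abs=0.05)

    @pytest.mark.parametrize("n2o,removed,expected", [(0.0, 5.0, 0.0), (5.0, 5.0, 100.0)])
    def test_share_bounds(self, n2o, removed, expected):
        assert st.n2o_share(n2o, removed) == expected

    def test_share_undefined_without_removal(self):
        with pytest.raises(ValueError):
            st.n2o_share(0.0, 0.0)


class TestOperatingPeriodValidation:
    def test_rejects_nonpositive_flow(self):
        with pytest.raises(ValueError, match="flow"):
            st.OperatingPeriod("x", flow=0.0)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError, match="no3_in"):
            st.OperatingPeriod("x", flow=1.0, no3_in=-1.0)

    def test_summary_shares_bounded_when_closed(self, reference_periods):
        for p in reference_periods.values():
            summary = st.summarize_period(p)
            assert 0.0 <= summary.n2o_share_of_removed <= 100.0
            assert 0.0 <= summary.n2o_share_of_gas <= 100.0
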