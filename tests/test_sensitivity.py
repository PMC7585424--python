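"""Tests for scenario construction and the sensitivity sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lakecarbon.boxmodel import balance_residuals, forward_delta_dic
from lakecarbon.sensitivity import (
    Scenario,
    baseline_network,
    build_network,
    scenario_suite,
    sweep_escape,
    sweep_remineralization,
)

X_GRID = np.linspace(0.0, 1.0, 21)


class TestBaseline:
    def test_chain_values(self, chain_baseline):
        b = chain_baseline
        assert b.partition.f_co2_meth == pytest.approx(120.3125)
        assert b.partition.f_oxy == pytest.approx(43.3125)
        assert b.f_nc == pytest.approx(151.275, abs=1e-9)
        assert b.f_det + b.f_mag == pytest.approx(b.f_nc)

    def test_baseline_reproduces_measured_dic_exactly(self, chain_baseline):
        assert forward_delta_dic(chain_baseline.spec) == pytest.approx(
            12.1, abs=1e-9
        )

    def test_identity_scenario_is_bitwise_baseline(self, chain_baseline):
        spec, feasible = build_network(Scenario(), chain_baseline)
        assert feasible
        by_name = {t.name: t for t in spec.terms}
        for t in chain_baseline.spec.terms:
            other = by_name[t.name]
            assert other.flux == t.flux
            assert other.epsilon == t.epsilon
            assert other.delta == t.delta


class TestBuildNetwork:
    def test_no_methanogenesis_limit(self, chain_baseline):
        spec, feasible = build_network(
            Scenario(remin_meth_frac=0.0), chain_baseline
        )
        assert feasible
        names = {t.name for t in spec.terms}
        assert "co2_methanogenic" not in names and "ch4_oxidation" not in names
        assert spec.term("respiration").flux == pytest.approx(
            chain_baseline.remin_total
        )

    def test_full_escape_drops_the_oxidation_term(self, chain_baseline):
        spec, feasible = build_network(
            Scenario(remin_meth_frac=0.5, escape_frac=1.0), chain_baseline
        )
        assert feasible
        assert "ch4_oxidation" not in {t.name for t in spec.terms}

    @given(
        x=st.floats(0.0, 1.0),
        e=st.floats(0.0, 0.85),
        r=st.sampled_from([1.0, 1.2, 1 / 1.2]),
        s=st.sampled_from([0.8, 1.0, 1.2]),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_scenario_networks_are_balanced_at_their_solution(
        self, x, e, r, s
    ):
        base = baseline_network()
        spec, feasible = build_network(
            Scenario(remin_meth_frac=x, escape_frac=e, ratio_co2_ch4=r, ph_scale=s),
            base,
        )
        if not feasible:
            return
        delta = forward_delta_dic(spec)
        mass, iso = balance_residuals(spec, delta)
        scale = sum(t.flux for t in spec.terms)
        assert abs(mass) <= 1e-9 * scale
        assert abs(iso) <= 1e-9 * scale * 100

    def test_infeasible_point_flagged_not_raised(self, chain_baseline):
        # scaled-up production with zero methane escape returns more carbon
        # than the outputs remove: no nonnegative detrital/magmatic input
        # can close the balance
        spec, feasible = build_network(
            Scenario(remin_meth_frac=0.5, escape_frac=0.0, ph_scale=3.0),
            chain_baseline,
        )
        assert not feasible and spec is None


class TestSweeps:
    def test_baseline_curve_crosses_measured_band(self, chain_baseline):
        """The 64% escape curve passes through 12.1 +- 0.6 at the baseline
        remineralization partition."""
        sw = sweep_remineralization(
            [chain_baseline.remin_meth_frac], Scenario(), chain_baseline
        )
        value = sw.table["delta_dic_permil"].iloc[0]
        assert 12.1 - 0.6 <= value <= 12.1 + 0.6

    def test_strictly_increasing_in_x_with_escape(self, chain_baseline):
        sw = sweep_remineralization(X_GRID, Scenario(), chain_baseline)
        d = sw.table["delta_dic_permil"].to_numpy()
        assert np.all(np.diff(d) > 0)

    def test_zero_escape_curve_lies_below(self, chain_baseline):
        on = sweep_remineralization(X_GRID, Scenario(), chain_baseline)
        off = sweep_remineralization(
            X_GRID, Scenario(escape_frac=0.0), chain_baseline
        )
        gap = on.table["delta_dic_permil"] - off.table["delta_dic_permil"]
        assert gap.iloc[0] == pytest.approx(0.0, abs=1e-9)  # x = 0: no methane
        assert np.all(gap.iloc[1:] > 0)

    def test_monotone_in_escape_fraction(self, chain_baseline):
        sw = sweep_escape(
            np.linspace(0.0, 0.85, 18),
            Scenario(remin_meth_frac=0.5),
            chain_baseline,
        )
        d = sw.table["delta_dic_permil"].to_numpy()
        assert np.all(np.diff(d) >= 0)
        assert d.argmin() == 0

    def test_escape_grid_bounds_enforced(self, chain_baseline):
        with pytest.raises(ValueError):
            sweep_escape([0.9], Scenario(remin_meth_frac=0.5), chain_baseline)

    def test_single_point_grid_equals_scenario_evaluation(self, chain_baseline):
        x = chain_baseline.remin_meth_frac
        sw = sweep_escape([0.64], Scenario(remin_meth_frac=x), chain_baseline)
        assert sw.table["delta_dic_permil"].iloc[0] == pytest.approx(12.1, abs=1e-9)


@pytest.fixture(scope="module")
def suite(chain_baseline):
    return scenario_suite(chain_baseline, x_grid=X_GRID).table


class TestScenarioSuite:
    def test_photosynthesis_pair_brackets_baseline(self, suite):
        base = suite[suite.scenario == "baseline"].delta_dic_permil.to_numpy()
        lo = suite[suite.scenario == "photosynthesis_-20"].delta_dic_permil.to_numpy()
        hi = suite[suite.scenario == "photosynthesis_+20"].delta_dic_permil.to_numpy()
        ok = ~(np.isnan(lo) | np.isnan(hi) | np.isnan(base))
        # the pair brackets the baseline everywhere; which member sits on
        # top flips with x (at low x the photosynthesis-output effect
        # dominates, at high x the scaled methane-escape effect does)
        assert np.all(np.minimum(lo[ok], hi[ok]) <= base[ok] + 1e-9)
        assert np.all(np.maximum(lo[ok], hi[ok]) >= base[ok] - 1e-9)

    def test_burial_scenario_only_reallocates_remineralization(
        self, chain_baseline
    ):
        spec_b, _ = build_network(
            Scenario(remin_meth_frac=0.5, burial_frac_gpp=0.07), chain_baseline
        )
        spec_0, _ = build_network(Scenario(remin_meth_frac=0.5), chain_baseline)
        for name in ("photosynthesis", "co2_degassing", "carbonate"):
            assert spec_b.term(name).flux == spec_0.term(name).flux
        assert spec_b.term("respiration").flux < spec_0.term("respiration").flux

    def test_alternative_detmag_split_preserves_total(self, chain_baseline):
        spec_alt, _ = build_network(
            Scenario(det_mag_split=(0.68, 0.32)), chain_baseline
        )
        spec_0, _ = build_network(Scenario(), chain_baseline)
        total_alt = spec_alt.term("detrital").flux + spec_alt.term("magmatic").flux
        total_0 = spec_0.term("detrital").flux + spec_0.term("magmatic").flux
        assert total_alt == pytest.approx(total_0, rel=1e-12)
        assert spec_alt.term("detrital").flux != spec_0.term("detrital").flux

    def test_all_curves_coincide_without_methanogenesis(self, suite):
        at_zero = suite[(suite.x == 0.0) & (suite.scenario.isin(
            ["baseline", "escape_0", "escape_30", "escape_85"]))]
        values = at_zero.delta_dic_permil.to_numpy()
        assert np.allclose(values, values[0], atol=1e-9)
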