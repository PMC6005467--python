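"""Unit conversions, the 15N balance rows, their uncertainty model, and the
steady-state delta solution (the transcription-correctness oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isolim.isotopes import (DEFAULT_EPSILONS, R_N2_DEFAULT,
                             UNKNOWN_DELTA_ORDER, IsotopeSpec,
                             build_isotope_rows, delta_to_ratio,
                             frac_coefficient, isotope_sigma, ratio_to_delta,
                             steady_state_deltas)

ZERO_EPS = {k: 0.0 for k in DEFAULT_EPSILONS}


def _spec(**kw):
    base = dict(delta_known={"upno3": 5.70, "MES": 7.68, "DOM": 4.87,
                             "DET": 4.42})
    base.update(kw)
    return IsotopeSpec(**base)


class TestConversions:
    def test_zero_delta_gives_air_ratio(self):
        assert delta_to_ratio(0.0) == R_N2_DEFAULT

    def test_positive_delta_scales_ratio(self):
        assert delta_to_ratio(5.70) == pytest.approx(R_N2_DEFAULT * 1.00570)

    @given(st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, d):
        assert ratio_to_delta(delta_to_ratio(d)) == pytest.approx(d, abs=1e-12)

    @pytest.mark.parametrize("eps,expected", [
        (0.0, 1.0), (-5.0, np.exp(-0.005)), (-10.0, np.exp(-0.010))])
    def test_fractionation_coefficient(self, eps, expected):
        assert frac_coefficient(eps) == pytest.approx(expected, abs=1e-12)


class TestRowCoefficients:
    def test_nitrate_row_matches_mixing_equation(self, model):
        spec = _spec(delta_unknown={**{k: 0.0 for k in UNKNOWN_DELTA_ORDER},
                                    "NO3": 9.92})
        A = build_isotope_rows(model, spec).matrix()
        r = list(build_isotope_rows(model, spec).names).index("iso_NO3")
        assert A[r, model.flow_id("EXT", "NO3")] == pytest.approx(
            delta_to_ratio(5.70))
        expected = -delta_to_ratio(9.92) * frac_coefficient(-5.0)
        assert A[r, model.flow_id("NO3", "CYA")] == pytest.approx(expected)
        assert A[r, model.flow_id("NO3", "DTM")] == pytest.approx(expected)

    def test_system_row_exports_carry_known_deltas(self, model):
        rows = build_isotope_rows(model, _spec())
        A = rows.matrix()
        r = rows.names.index("iso_system")
        assert A[r, model.flow_id("MES", "HTL")] == pytest.approx(
            -delta_to_ratio(7.68))
        assert A[r, model.flow_id("DET", "SNK")] == pytest.approx(
            -delta_to_ratio(4.42))

    def test_self_carnivory_absent_from_all_rows(self, model):
        A = build_isotope_rows(model, _spec()).matrix()
        assert np.allclose(A[:, model.flow_id("MES", "MES")], 0.0)

    def test_zero_fractionation_rows_vanish_on_balanced_flows(
            self, model, random_balanced_flows):
        """With no fractionation and a single common delta, each row is that
        common ratio times a mass-balance row, so it annihilates any
        mass-balanced x."""
        spec = IsotopeSpec(
            epsilons=dict(ZERO_EPS), delta_nfix=3.0,
            delta_known={"upno3": 3.0, "MES": 3.0, "DOM": 3.0, "DET": 3.0},
            delta_unknown={k: 3.0 for k in UNKNOWN_DELTA_ORDER})
        res = build_isotope_rows(model, spec).residuals(random_balanced_flows)
        assert np.abs(res).max() < 1e-12

    def test_rows_linear_in_flows(self, model, random_balanced_flows):
        rows = build_isotope_rows(model, _spec())
        r1 = rows.residuals(random_balanced_flows)
        r3 = rows.residuals(3.0 * random_balanced_flows)
        assert r3 == pytest.approx(3.0 * r1)


class TestIsotopeSigma:
    def test_zero_reference_floors(self, model):
        rows = build_isotope_rows(model, _spec())
        sig = isotope_sigma(rows, np.zeros(model.n_flows))
        assert np.all(sig == 1e-4 * R_N2_DEFAULT)

    def test_single_flow_formula(self, model):
        """Only EXT->NO3 and the NO3 uptake flows touch the nitrate row; with
        x on NO3->CYA alone, sigma = 0.1 * |R_NO3 * (1 - alpha_no3)|."""
        spec = _spec(delta_unknown={k: 0.0 for k in UNKNOWN_DELTA_ORDER})
        rows = build_isotope_rows(model, spec)
        x = np.zeros(model.n_flows)
        x[model.flow_id("NO3", "CYA")] = 1.0
        sig = isotope_sigma(rows, x)
        r = rows.names.index("iso_NO3")
        expected = 0.10 * R_N2_DEFAULT * (1 - np.exp(-0.005))
        assert sig[r] == pytest.approx(expected)

    def test_linear_in_reference_above_floor(self, model, random_balanced_flows):
        rows = build_isotope_rows(model, _spec())
        s1 = isotope_sigma(rows, random_balanced_flows)
        s2 = isotope_sigma(rows, 2.0 * random_balanced_flows)
        above = s1 > 1e-4 * R_N2_DEFAULT
        assert np.any(above)
        assert s2[above] == pytest.approx(2.0 * s1[above])


class TestSteadyStateDeltas:
    def test_no_fractionation_propagates_source_delta(
            self, model, random_balanced_flows):
        d = steady_state_deltas(model, random_balanced_flows,
                                delta_upno3=5.0, delta_nfix=5.0,
                                epsilons=ZERO_EPS)
        for v in d.values():
            assert v == pytest.approx(5.0, abs=1e-9)

    def test_consumers_enrich_when_excretion_fractionates(
            self, model, random_balanced_flows):
        """Preferential loss of light N via excretion leaves the consumer
        heavier than its flow-weighted diet."""
        eps = dict(ZERO_EPS, exc=-5.0)
        d = steady_state_deltas(model, random_balanced_flows,
                                delta_upno3=5.0, delta_nfix=5.0, epsilons=eps)
        x = random_balanced_flows
        mes_diet = (
            d["DTM"] * x[model.flow_id("DTM", "MES")]
            + d["HNF"] * x[model.flow_id("HNF", "MES")]
            + d["MIC"] * x[model.flow_id("MIC", "MES")]
            + d["DET"] * x[model.flow_id("DET", "MES")]
        ) / (x[model.flow_id("DTM", "MES")] + x[model.flow_id("HNF", "MES")]
             + x[model.flow_id("MIC", "MES")] + x[model.flow_id("DET", "MES")])
        assert d["MES"] > mes_diet

    def test_self_consistency_closes_all_ten_rows(
            self, model, random_balanced_flows):
        """Core transcription check: the steady-state deltas must make every
        balance row vanish on the flows that generated them."""
        x = random_balanced_flows
        d = steady_state_deltas(model, x, delta_upno3=8.0)
        spec = IsotopeSpec(
            delta_known={"upno3": 8.0, "MES": d["MES"], "DOM": d["DOM"],
                         "DET": d["DET"]},
            delta_unknown={k: d[k] for k in UNKNOWN_DELTA_ORDER})
        res = build_isotope_rows(model, spec).residuals(x)
        assert np.abs(res).max() <= 1e-10

    def test_zero_throughput_is_singular(self, model):
        with pytest.raises(np.linalg.LinAlgError):
            steady_state_deltas(model, np.zeros(model.n_flows), delta_upno3=5.0)
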