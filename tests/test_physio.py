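"""Unit and property tests for the isotope → iWUE equation chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isowue import physio as ph
from isowue.constants import (
    AtmosphericState,
    Formulation,
    FractionationConstants,
    Pathway,
)
from isowue.physio import (
    ConfigurationError,
    DegenerateConstantsError,
    InvalidInputError,
    IsotopeSample,
    compute_iwue,
)

K = FractionationConstants()


class TestElementaryOps:
    @pytest.mark.parametrize(
        "r_sample, r_standard, expected",
        [
            (0.0112372, 0.0112372, 0.0),          # identity
            (1.01, 1.0, 10.0),                    # forced by the formula
            (0.98993, 1.0, -10.07),               # direct arithmetic
        ],
    )
    def test_ratio_to_delta(self, r_sample, r_standard, expected):
        assert ph.ratio_to_delta(r_sample, r_standard) == pytest.approx(
            expected, abs=1e-9
        )

    def test_ratio_to_delta_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            ph.ratio_to_delta(-1.0, 1.0)
        with pytest.raises(InvalidInputError):
            ph.ratio_to_delta(1.0, 0.0)

    @pytest.mark.parametrize(
        "da, dp, expected",
        [
            (0.0, 0.0, 0.0),
            (-8.5, -30.07, 22.239),   # hand arithmetic on the Δ definition
            (-8.5, -13.72, 5.293),
        ],
    )
    def test_discrimination(self, da, dp, expected):
        assert ph.discrimination(da, dp) == pytest.approx(expected, abs=1e-3)

    def test_discrimination_pole(self):
        with pytest.raises(InvalidInputError):
            ph.discrimination(-8.5, -1000.0)

    def test_discrimination_inverts(self):
        dd = ph.discrimination(-8.5, -27.3)
        assert ph.delta_plant_from_discrimination(-8.5, dd) == pytest.approx(
            -27.3, abs=1e-12
        )

    def test_barometric_sea_level_and_altitude(self):
        assert ph.barometric_pressure(0.0) == pytest.approx(101325.0)
        # standard-atmosphere value at the transect ceiling
        assert ph.barometric_pressure(3800.0) == pytest.approx(63.3e3, rel=2e-3)

    def test_barometric_monotone_decreasing(self):
        z = np.linspace(0, 5000, 200)
        p = ph.barometric_pressure(z)
        assert np.all(np.diff(p) < 0)

    def test_barometric_rejects_deep_depression(self):
        with pytest.raises(InvalidInputError):
            ph.barometric_pressure(-600.0)

    def test_gamma_star_reference_point(self, constants):
        assert ph.gamma_star(298.0, constants.p0) == pytest.approx(
            constants.gamma_star_25, abs=0.0
        )

    def test_gamma_star_arrhenius_at_308(self):
        # independent evaluation: 42.75 * exp(37830*10/(8.314*308*298))
        assert ph.gamma_star(308.0, K.p0) == pytest.approx(70.18, abs=0.02)

    def test_gamma_star_linear_in_pressure(self):
        full = ph.gamma_star(290.0, K.p0)
        half = ph.gamma_star(290.0, K.p0 / 2)
        assert half == pytest.approx(full / 2, rel=1e-12)


class TestC3Inversions:
    @pytest.mark.parametrize(
        "dd, ca, expected",
        [
            (K.a, 415.0, 0.0),                    # numerator vanishes
            (K.b, 415.0, 415.0),                  # ratio equals one
            (22.239, 415.0, 300.95),              # hand arithmetic
        ],
    )
    def test_ci_simple(self, dd, ca, expected):
        assert ph.ci_simple_c3(dd, ca) == pytest.approx(expected, abs=0.01)

    def test_ci_simple_degenerate(self):
        with pytest.raises(DegenerateConstantsError):
            ph.ci_simple_c3(10.0, 415.0, FractionationConstants(a=29.0, b=29.0))

    def test_photoresp_collapses_when_fprime_zero(self):
        k0 = FractionationConstants(f_prime=0.0)
        ci = ph.ci_photoresp_c3(20.0, 415.0, 42.75, 42.0, k0)
        assert ci == pytest.approx(ph.ci_simple_c3(20.0, 415.0, k0), rel=1e-14)

    def test_photoresp_collapses_when_gamma_star_zero(self):
        ci = ph.ci_photoresp_c3(20.0, 415.0, 0.0, 42.0, K)
        assert ci == pytest.approx(ph.ci_simple_c3(20.0, 415.0, K), rel=1e-14)

    def test_photoresp_rejects_nonpositive_pca(self):
        with pytest.raises(InvalidInputError):
            ph.ci_photoresp_c3(20.0, 415.0, 42.75, 0.0, K)

    def test_photoresp_printed_sign_switch(self):
        forward = ph.ci_photoresp_c3(20.0, 415.0, 42.75, 42.0, K)
        printed = ph.ci_photoresp_c3(
            20.0, 415.0, 42.75, 42.0, FractionationConstants(photoresp_sign="printed")
        )
        # the two sign conventions straddle the uncorrected inversion
        simple = ph.ci_simple_c3(20.0, 415.0, K)
        assert printed < simple < forward

    def test_mesophyll_collapses_when_ratio_zero(self):
        k0 = FractionationConstants(gsc_over_gm=0.0)
        cc = ph.cc_mesophyll_c3(20.0, 415.0, 42.75, 42.0, k0)
        assert cc == pytest.approx(ph.ci_photoresp_c3(20.0, 415.0, 42.75, 42.0, k0), rel=1e-14)

    def test_mesophyll_cc_below_its_ci(self):
        cc = ph.cc_mesophyll_c3(20.0, 415.0, 42.75, 42.0, K)
        ci = ph.ci_from_cc(cc, 415.0, K)
        assert cc < ci < 415.0


class TestC4Inversion:
    def test_delta_a_gives_zero_ci(self):
        ci, ok = ph.ci_c4(K.a, 415.0)
        assert ci == pytest.approx(0.0, abs=1e-12)
        assert ok

    def test_forward_at_unit_ratio(self):
        # b4 + (b3 − s)·φ at defaults: −5.7 + 28.2·0.21 = 0.222 ‰
        assert ph.forward_c4(415.0, 415.0) == pytest.approx(0.222, abs=1e-9)

    def test_hand_arithmetic_example(self):
        ci, ok = ph.ci_c4(3.0, 415.0)
        assert ci == pytest.approx(139.1, abs=0.1)
        assert ok

    def test_out_of_range_flagged_not_clamped(self):
        ci, ok = ph.ci_c4(5.293, 415.0)
        assert not ok
        assert ci < 0.0  # never silently clamped

    def test_degenerate_slope(self):
        k = FractionationConstants(b4=4.4, phi=0.0)
        with pytest.raises(DegenerateConstantsError):
            ph.ci_c4(3.0, 415.0, k)


class TestIwue:
    @pytest.mark.parametrize(
        "ca, ci, expected",
        [(415.0, 415.0, 0.0), (415.0, 0.0, 259.375), (415.0, 300.96, 71.275)],
    )
    def test_values(self, ca, ci, expected):
        assert ph.iwue(ca, ci) == pytest.approx(expected, abs=1e-2)

    def test_strictly_decreasing_in_ci(self):
        ci = np.linspace(0, 415, 100)
        w = ph.iwue(415.0, ci)
        assert np.all(np.diff(w) < 0)

    def test_inverse(self):
        assert ph.ci_from_iwue(415.0, ph.iwue(415.0, 212.3)) == pytest.approx(212.3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(x=st.floats(0.01, 0.99), ca=st.floats(300, 500), t=st.floats(270, 310),
       z=st.floats(0, 4000))
def test_round_trip_all_formulations(x, ca, t, z):
    """forward(invert(Δ)) and invert(forward(C)) agree to 1e-9 relative."""
    patm = ph.barometric_pressure(z)
    gs = ph.gamma_star(t, patm)
    p_ca = ca * 1e-6 * patm
    c = x * ca
    for fwd, inv in [
        (lambda c_: ph.forward_simple_c3(c_, ca), lambda d: ph.ci_simple_c3(d, ca)),
        (lambda c_: ph.forward_photoresp_c3(c_, ca, gs, p_ca),
         lambda d: ph.ci_photoresp_c3(d, ca, gs, p_ca)),
        (lambda c_: ph.forward_mesophyll_c3(c_, ca, gs, p_ca),
         lambda d: ph.cc_mesophyll_c3(d, ca, gs, p_ca)),
        (lambda c_: ph.forward_c4(c_, ca), lambda d: ph.ci_c4(d, ca)[0]),
    ]:
        assert inv(fwd(c)) == pytest.approx(c, rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(x=st.floats(0.05, 0.95), ca=st.floats(350, 450))
def test_c3_c4_monotonicity_in_delta(x, ca):
    """C3 iWUE falls with Δ (b > a); C4 iWUE rises with Δ (negative slope)."""
    eps = 0.01
    d3 = ph.forward_simple_c3(x * ca, ca)
    w3_lo = ph.iwue(ca, ph.ci_simple_c3(d3, ca))
    w3_hi = ph.iwue(ca, ph.ci_simple_c3(d3 + eps, ca))
    assert w3_hi < w3_lo
    d4 = ph.forward_c4(x * ca, ca)
    w4_lo = ph.iwue(ca, ph.ci_c4(d4, ca)[0])
    w4_hi = ph.iwue(ca, ph.ci_c4(d4 + eps, ca)[0])
    assert w4_hi > w4_lo


class TestComposedChain:
    def _sample(self, d13c=-28.0, pathway=Pathway.C3, sid="x1"):
        return IsotopeSample(
            sample_id=sid, site_id="s", species_id="sp",
            pathway=pathway, delta13c_leaf=d13c,
        )

    def test_simple_formulation_equals_manual_chain(self):
        atm = AtmosphericState(elevation=1200.0, temperature=290.0)
        res = compute_iwue(self._sample(), atm, formulation=Formulation.SIMPLE)
        dd = ph.discrimination(atm.delta13c_air, -28.0)
        ci = ph.ci_simple_c3(dd, atm.ca)
        assert res.ci == pytest.approx(ci, rel=1e-14)
        assert res.iwue == pytest.approx(ph.iwue(atm.ca, ci), rel=1e-14)
        assert res.in_range

    def test_c4_mean_level_leaf_is_out_of_model_range(self):
        """δ13C = −13.72 with δa = −8.5 gives Δ = 5.29 ‰, above the C4
        model's attainable band [0.222, 4.4] ‰ — flagged, not clamped."""
        atm = AtmosphericState()
        res = compute_iwue(
            self._sample(d13c=-13.72, pathway=Pathway.C4),
            atm, formulation=Formulation.C4,
        )
        assert not res.in_range
        assert res.ci < 0

    def test_pathway_formulation_mismatch(self):
        atm = AtmosphericState()
        with pytest.raises(ConfigurationError):
            compute_iwue(self._sample(pathway=Pathway.C3), atm,
                         formulation=Formulation.C4)
        with pytest.raises(ConfigurationError):
            compute_iwue(self._sample(pathway=Pathway.C4), atm,
                         formulation=Formulation.PHOTORESP)

    def test_mesophyll_result_populates_cc_and_uses_it(self):
        atm = AtmosphericState(elevation=500.0, temperature=295.0)
        res = compute_iwue(self._sample(), atm, formulation=Formulation.MESOPHYLL)
        assert res.cc is not None and res.cc < res.ci
        assert res.iwue == pytest.approx(ph.iwue(atm.ca, res.cc), rel=1e-14)

    def test_implausible_delta13c_warns(self):
        with pytest.warns(UserWarning, match="plausible"):
            self._sample(d13c=-55.0)

    def test_batch_order_preserved(self, iwue_table, default_transect):
        table, _ = default_transect
        assert len(iwue_table) == len(table)
        assert (iwue_table["sample_id"] == table["sample_id"]).all()
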