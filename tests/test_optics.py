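"""Forward model, absorbance gradients, and the two-wavelength inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsbundle import (
    ExtinctionTable,
    OpticalModelParams,
    absorbance,
    absorbance_gradient,
    forward_intensity,
    invert_concentrations,
    mbll_delta,
    scattering_coefficient,
)
from nirsbundle.errors import ConfigError, DataError, GeometryError

conc = st.floats(min_value=0.01, max_value=50.0, allow_nan=False)


def _roundtrip(c_hbo, c_hbr, ext, params, l_short=5.0, l_long=30.0):
    """Forward both pairs of a homogeneous medium, then invert the gradient."""
    i_long = forward_intensity(c_hbo, c_hbr, l_long, ext, params)
    i_short = forward_intensity(c_hbo, c_hbr, l_short, ext, params)
    grads = [
        absorbance_gradient(
            absorbance(1.0, i_short[wl]), absorbance(1.0, i_long[wl]), l_long - l_short
        )
        for wl in ext.wavelengths
    ]
    return invert_concentrations(grads[0], grads[1], ext, params)


class TestScattering:
    def test_values_at_default_wavelengths(self, params):
        assert scattering_coefficient(760, params) == pytest.approx(0.9541, abs=1e-4)
        assert scattering_coefficient(830, params) == pytest.approx(0.9084, abs=1e-4)

    def test_zero_gamma2_gives_flat_spectrum(self):
        p = OpticalModelParams(gamma2=0.0)
        assert scattering_coefficient(760, p) == p.gamma1
        assert scattering_coefficient(830, p) == p.gamma1

    def test_nonpositive_mus_rejected(self):
        with pytest.raises(ConfigError):
            OpticalModelParams(gamma2=2e-3)  # gamma2*lambda > 1 at 760 nm


class TestAbsorbance:
    def test_unit_ratio_gives_zero(self):
        assert absorbance(2.0, 2.0) == 0.0

    def test_e_minus_ten_gives_ten(self):
        assert absorbance(1.0, np.exp(-10.0)) == pytest.approx(10.0)

    def test_half_ratio_gives_ln_two(self):
        assert absorbance(1.0, 0.5) == pytest.approx(np.log(2))

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(DataError):
            absorbance(1.0, np.array([1.0, 0.0, 1.0]))
        with pytest.raises(DataError):
            absorbance(0.0, 1.0)


class TestGradient:
    def test_equal_series_zero_gradient(self):
        a = np.array([0.1, 0.2, 0.3])
        assert np.all(absorbance_gradient(a, a, 10.0) == 0)

    def test_homogeneous_medium_recovers_mu(self):
        # A = mu*l on both pairs -> gradient == mu regardless of delta_l
        mu = 0.96
        for delta in (5.0, 12.5, 25.0):
            a_s = mu * 5.0 * np.ones(4)
            a_l = mu * (5.0 + delta) * np.ones(4)
            assert absorbance_gradient(a_s, a_l, delta) == pytest.approx(mu)

    def test_common_additive_component_cancels(self, rng):
        a_s = rng.normal(size=50)
        a_l = rng.normal(size=50)
        s = rng.normal(size=50)
        base = absorbance_gradient(a_s, a_l, 25.0)
        shifted = absorbance_gradient(a_s + s, a_l + s, 25.0)
        assert np.allclose(base, shifted, atol=1e-12)

    def test_zero_delta_l_rejected(self):
        with pytest.raises(GeometryError):
            absorbance_gradient(np.zeros(3), np.zeros(3), 0.0)


class TestInversion:
    def test_gradient_equal_mus_gives_zero_concentrations(self, ext, params):
        mus = [scattering_coefficient(wl, params) for wl in ext.wavelengths]
        cs = invert_concentrations(
            np.full(5, mus[0]), np.full(5, mus[1]), ext, params
        )
        assert np.allclose(cs.hbo, 0, atol=1e-12)
        assert np.allclose(cs.hbr, 0, atol=1e-12)

    def test_identity_extinction_passthrough(self):
        ident = ExtinctionTable(wavelengths=(760.0, 830.0), eps=((1.0, 0.0), (0.0, 1.0)))
        cs = invert_concentrations(
            np.array([2.0]), np.array([3.0]), ident, mus=(0.0, 0.0)
        )
        assert cs.hbo[0] == pytest.approx(2.0)
        assert cs.hbr[0] == pytest.approx(3.0)

    def test_singular_extinction_rejected(self):
        bad = ExtinctionTable(wavelengths=(760.0, 830.0), eps=((1.0, 2.0), (2.0, 4.0)))
        with pytest.raises(ConfigError, match="condition"):
            invert_concentrations(np.zeros(2), np.zeros(2), bad)

    @settings(max_examples=50, deadline=None)
    @given(c_hbo=conc, c_hbr=conc)
    def test_forward_inverse_round_trip(self, c_hbo, c_hbr, ext, params):
        cs = _roundtrip(np.full(3, c_hbo), np.full(3, c_hbr), ext, params)
        assert np.allclose(cs.hbo, c_hbo, rtol=1e-9)
        assert np.allclose(cs.hbr, c_hbr, rtol=1e-9)

    def test_linearity_in_gradient_deviation(self, ext, params):
        mus = np.array([scattering_coefficient(wl, params) for wl in ext.wavelengths])
        dev = np.array([1e-3, 2e-3])
        c1 = invert_concentrations(
            np.array([mus[0] + dev[0]]), np.array([mus[1] + dev[1]]), ext, params
        )
        c2 = invert_concentrations(
            np.array([mus[0] + 2 * dev[0]]), np.array([mus[1] + 2 * dev[1]]), ext, params
        )
        assert c2.hbo[0] == pytest.approx(2 * c1.hbo[0])
        assert c2.hbr[0] == pytest.approx(2 * c1.hbr[0])


class TestForward:
    def test_pure_scattering_attenuation(self, ext, params):
        l = 10.0 / scattering_coefficient(760.0, params)  # mus*l = 10
        out = forward_intensity(np.zeros(1), np.zeros(1), l, ext, params)
        assert out[760.0][0] == pytest.approx(np.exp(-10.0))

    def test_forward_then_absorbance_is_mu_l(self, ext, params):
        c_hbo, c_hbr, l = np.full(3, 5.0), np.full(3, 3.4), 30.0
        out = forward_intensity(c_hbo, c_hbr, l, ext, params)
        for wl in ext.wavelengths:
            e_hbo, e_hbr = ext.eps_for(wl)
            mu = e_hbo * 5.0 + e_hbr * 3.4 + scattering_coefficient(wl, params)
            assert absorbance(1.0, out[wl]) == pytest.approx(mu * l)

    def test_monotone_in_hbo(self, ext, params):
        lo = forward_intensity(np.array([1.0]), np.array([3.0]), 30.0, ext, params)
        hi = forward_intensity(np.array([2.0]), np.array([3.0]), 30.0, ext, params)
        for wl in ext.wavelengths:
            assert hi[wl][0] < lo[wl][0]


class TestMBLL:
    def test_constant_intensity_gives_zero_delta(self, ext):
        i_out = {wl: np.full(10, 0.8) for wl in ext.wavelengths}
        cs = mbll_delta(i_out, 30.0, ext)
        assert cs.mode == "differential"
        assert np.allclose(cs.hbo, 0)
        assert np.allclose(cs.hbr, 0)

    def test_doubling_dpf_halves_delta(self, ext, rng):
        i_out = {wl: 0.5 + 0.1 * rng.random(20) for wl in ext.wavelengths}
        c6 = mbll_delta(i_out, 30.0, ext, dpf=6.0)
        c12 = mbll_delta(i_out, 30.0, ext, dpf=12.0)
        assert np.allclose(c12.hbo, c6.hbo / 2)
        assert np.allclose(c12.hbr, c6.hbr / 2)

    def test_step_in_hbo_recovered_shape(self, ext, params):
        # forward a pure HbO step with unit-pathlength DPF: exact recovery
        step = np.concatenate([np.zeros(10), np.full(10, 0.5)])
        c_hbo, c_hbr, l = 5.0 + step, np.full(20, 3.4), 30.0
        out = forward_intensity(c_hbo, c_hbr, l, ext, params)
        cs = mbll_delta(out, l, ext, dpf=1.0, reference="first")
        assert np.allclose(cs.hbo, step, atol=1e-9)
        assert np.allclose(cs.hbr, 0, atol=1e-9)

    def test_extinction_table_condition_number(self, ext):
        assert 1 < ext.condition_number < 10


class TestShapeAgreement:
    def test_bundled_and_mbll_agree_on_response_shape(self, ext, params):
        """Noise-free single-compartment response: correlation 1 after mean removal."""
        t = np.arange(200) / 1.81
        resp = 0.4 * np.exp(-0.5 * ((t - 40) / 8.0) ** 2)
        c_hbo, c_hbr = 5.0 + resp, 3.4 - 0.3 * resp
        l_s, l_l = 5.0, 30.0
        i_l = forward_intensity(c_hbo, c_hbr, l_l, ext, params)
        i_s = forward_intensity(c_hbo, c_hbr, l_s, ext, params)
        grads = [
            absorbance_gradient(
                absorbance(1.0, i_s[wl]), absorbance(1.0, i_l[wl]), l_l - l_s
            )
            for wl in ext.wavelengths
        ]
        bundled = invert_concentrations(grads[0], grads[1], ext, params).hbo
        mbll = mbll_delta(i_l, l_l, ext, dpf=6.0, reference="first").hbo
        a = bundled - bundled.mean()
        b = mbll - mbll.mean()
        r = np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b))
        assert r == pytest.approx(1.0, abs=1e-9)
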