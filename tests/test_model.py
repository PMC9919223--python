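"""The exact layer model, its limits, and the Taylor approximations."""

import mpmath as mp
import numpy as np
import pytest
from scipy.integrate import quad

from qcmfilm import (BulkMedium, Layer, OvertoneShiftSet, PowerLawMaterial,
                     acoustic_ratio, dissipation_to_bandwidth, kanazawa,
                     predict_film, predict_multilayer, sauerbrey,
                     sauerbrey_mass, shift_set_from_model, taylor_air,
                     taylor_liquid)
from qcmfilm.model import bandwidth_to_dissipation


# ---------------------------------------------------------------- Sauerbrey

def test_sauerbrey_sensitivity_and_inverse(res):
    """1 nm at 1 g/cm^3 on a 5 MHz crystal shifts -Delta f/n by 5.7 Hz."""
    m = 1e-9 * 1000.0
    assert -sauerbrey(res, m) == pytest.approx(5.7, rel=0.01)
    assert sauerbrey(res, 0.0) == 0.0
    rng = np.random.default_rng(7)
    for m in rng.uniform(1e-8, 1e-3, 10):
        assert sauerbrey_mass(sauerbrey(res, m), res) == pytest.approx(m, rel=1e-12)


def test_rigid_film_in_vacuum_is_sauerbrey_exactly(res, overtones):
    layer = Layer(PowerLawMaterial.rigid(rho=1200.0), 4e-9)
    shift = predict_film(res, layer, BulkMedium.vacuum(), overtones)
    per_n = shift / overtones
    assert per_n.imag == pytest.approx(0.0, abs=1e-12)
    assert per_n.real == pytest.approx(sauerbrey(res, layer.areal_mass), rel=1e-12)


def test_zero_thickness_in_vacuum_is_zero(res, soft_material):
    shift = predict_film(res, Layer(soft_material, 0.0), BulkMedium.vacuum(), 3)
    assert shift == 0


# ---------------------------------------------------------------- Kanazawa

def test_kanazawa_matches_closed_form(res, water):
    """Delta f(n=1) = -f0^(3/2) sqrt(rho eta / pi) / Zq for a Newtonian bulk,
    with Delta Gamma = -Delta f exactly (independent closed-form oracle from
    Z = (1+i) sqrt(omega rho eta / 2))."""
    shift = kanazawa(res, water, 1)
    oracle = -res.f0**1.5 * np.sqrt(1000.0 * 1e-3 / np.pi) / res.Zq
    assert shift.real == pytest.approx(oracle, rel=1e-12)
    assert shift.imag == pytest.approx(-oracle, rel=1e-12)


def test_kanazawa_properties(res, water, overtones):
    shift = kanazawa(res, water, overtones)
    per_n = shift / overtones
    # Delta Gamma = -Delta f on every overtone; Delta f/n ~ n^(-1/2)
    np.testing.assert_allclose(per_n.imag, -per_n.real, rtol=1e-12)
    np.testing.assert_allclose(per_n.real * np.sqrt(overtones),
                               per_n.real[0] * np.sqrt(3.0), rtol=1e-12)
    assert np.all(per_n.real < 0)
    # vacuum and zero viscosity give zero
    assert kanazawa(res, BulkMedium.vacuum(), 3) == 0
    assert kanazawa(res, BulkMedium.newtonian(1000.0, 0.0), 3) == 0


def test_film_at_zero_thickness_reduces_to_kanazawa(res, water, soft_material):
    layer = Layer(soft_material, 0.0)
    shift = predict_film(res, layer, water, 5)
    assert shift == pytest.approx(kanazawa(res, water, 5), rel=1e-12)
    # and the bulk-referenced shift vanishes
    assert predict_film(res, layer, water, 5, reference="bulk") == \
        pytest.approx(0.0, abs=1e-9)


# --------------------------------------------------- exact model vs oracle

def _film_shift_mpmath(f0, Zq, rho_f, d_f, J1c, J2c, b1, b2, f_cen,
                       rho_b, eta_b, n):
    """Independent high-precision evaluation of the single-film load."""
    with mp.workdps(50):
        f = mp.mpf(n) * f0
        omega = 2 * mp.pi * f
        scale = f / mp.mpf(f_cen)
        J = J1c * scale**mp.mpf(b1) - 1j * J2c * scale**mp.mpf(b2)
        G = 1 / J
        Zf = mp.sqrt(rho_f * G)
        if mp.re(Zf) < 0:
            Zf = -Zf
        k = omega * rho_f / Zf
        Zb = mp.sqrt(1j * omega * rho_b * eta_b)
        if mp.re(Zb) < 0:
            Zb = -Zb
        t = mp.tan(k * d_f)
        Zload = Zf * (Zb + 1j * Zf * t) / (Zf + 1j * Zb * t)
        shift = 1j * f0 * Zload / (mp.pi * Zq)
        return complex(shift)


@pytest.mark.parametrize("n", [3, 5, 7, 9, 11])
def test_exact_model_matches_high_precision_oracle(res, water, soft_material, n):
    """The polymer-brush parameter set in water against 50-digit arithmetic."""
    layer = Layer(soft_material, 9.8e-9)
    ours = complex(predict_film(res, layer, water, n))
    oracle = _film_shift_mpmath(res.f0, res.Zq, 1000.0, 9.8e-9,
                                0.29e-6, 1.68e-6, -1.61, -0.91, 30e6,
                                1000.0, 1e-3, n)
    assert ours.real == pytest.approx(oracle.real, rel=1e-10)
    assert ours.imag == pytest.approx(oracle.imag, rel=1e-10)


def test_thick_film_saturates_to_bulk_of_film_material(res, soft_material):
    """Far beyond the film's penetration depth the shift equals the
    semi-infinite response of the film material, regardless of what
    terminates the stack -- and stays finite (no tan overflow)."""
    semi_inf = kanazawa(res, BulkMedium.viscoelastic(soft_material), 3)
    for bulk in (BulkMedium.vacuum(), BulkMedium.water()):
        for d in (5e-6, 5e-3):
            shift = predict_film(res, Layer(soft_material, d), bulk, 3)
            assert np.isfinite(shift)
            assert shift == pytest.approx(semi_inf, rel=1e-6)


# ---------------------------------------------------------------- Taylor

def test_taylor_air_plain_variant_rigid_film_is_exact_sauerbrey(res):
    layer = Layer(PowerLawMaterial.rigid(), 50e-9)
    shift = taylor_air(res, layer, 3, variant="plain")
    assert shift.imag == 0
    assert shift.real / 3 == pytest.approx(sauerbrey(res, layer.areal_mass))


def test_taylor_air_fourth_order_convergence(res, soft_material):
    """Halving the thickness shrinks the relative deviation ~16x."""
    vac = BulkMedium.vacuum()
    prev = None
    for d in (8e-9, 4e-9, 2e-9):
        approx = taylor_air(res, Layer(soft_material, d), 3, variant="plain")
        exact = predict_film(res, Layer(soft_material, d), vac, 3)
        rel = abs(approx - exact) / abs(exact)
        if prev is not None:
            assert prev / rel == pytest.approx(16.0, rel=0.2)
        prev = rel


def test_taylor_liquid_second_order_convergence(res, water, soft_material):
    """Absolute error is O(d^2): halving d halves the relative deviation."""
    prev = None
    for d in (8e-9, 4e-9, 2e-9):
        approx = taylor_liquid(res, Layer(soft_material, d), water, 3)
        exact = predict_film(res, Layer(soft_material, d), water, 3,
                             reference="bulk")
        rel = abs(approx - exact) / abs(exact)
        if prev is not None:
            assert prev / rel == pytest.approx(2.0, rel=0.1)
        prev = rel


def test_taylor_liquid_rigid_film_is_sauerbrey_and_soft_film_below(res, water):
    rigid = Layer(PowerLawMaterial.rigid(rho=1000.0), 5e-9)
    s_rigid = taylor_liquid(res, rigid, water, 3) / 3
    assert s_rigid.real == pytest.approx(sauerbrey(res, rigid.areal_mass))
    # a soft film shows the missing-mass effect: -Delta f/n below Sauerbrey
    soft = Layer(PowerLawMaterial.from_compliance(1e-6, 3e-6, rho=1000.0), 5e-9)
    s_soft = taylor_liquid(res, soft, water, 3) / 3
    assert -s_soft.real < -s_rigid.real


def test_taylor_requires_matching_bulk(res, soft_material):
    with pytest.raises(ValueError, match="Newtonian"):
        taylor_liquid(res, Layer(soft_material, 1e-9), BulkMedium.vacuum(), 3)


# ------------------------------------------------------------- multilayer

def test_single_layer_multilayer_equals_film(res, water, soft_material, overtones):
    layer = Layer(soft_material, 7e-9)
    a = predict_film(res, layer, water, overtones)
    b = predict_multilayer(res, [layer], water, overtones)
    np.testing.assert_array_equal(a, b)


def test_sublayer_splitting_invariance(res, water, soft_material):
    """Transfer through the stack is associative: splitting a layer into
    sublayers of the same material leaves the prediction unchanged."""
    d = 12e-9
    whole = predict_film(res, Layer(soft_material, d), water, 5)
    for splits in (2, 7):
        parts = [Layer(soft_material, d / splits)] * splits
        split = predict_multilayer(res, parts, water, 5)
        assert split == pytest.approx(whole, rel=1e-10)


def test_zero_layers_is_bulk_only(res, water):
    assert predict_multilayer(res, [], water, 3) == pytest.approx(
        kanazawa(res, water, 3), rel=1e-14)


def test_thin_staircase_approaches_integral_form(res, water):
    """A staircase of thin sublayers approximating a continuous compliance
    profile J(z) approaches the integral form
    (Delta f + i Delta Gamma)/n = -(2 f0^2/Zq) rho Int [1 - i w eta J(z)] dz
    in the thin limit (numerical quadrature as the independent oracle;
    the deviation is second order in the total profile depth)."""
    n = 3
    J1_0, J2_0 = 0.25e-6, 1.0e-6

    def rel_dev(L):
        def J_of_z(z):  # linearly decaying profile
            w = 1.0 - z / L
            return (J1_0 * w) - 1j * (J2_0 * w)

        m = 50
        layers = []
        for i in range(m):
            z = (i + 0.5) * L / m
            Jz = J_of_z(z)
            mat = PowerLawMaterial.from_compliance(Jz.real, -Jz.imag, rho=1000.0)
            layers.append(Layer(mat, L / m))
        ours = predict_multilayer(res, layers, water, n, reference="bulk")

        omega = 2 * np.pi * n * res.f0
        integrand_re = lambda z: (1.0 - 1j * omega * water.eta * J_of_z(z)).real
        integrand_im = lambda z: (1.0 - 1j * omega * water.eta * J_of_z(z)).imag
        I = quad(integrand_re, 0, L)[0] + 1j * quad(integrand_im, 0, L)[0]
        oracle = n * (-2 * res.f0**2 / res.Zq) * 1000.0 * I
        return abs(ours - oracle) / abs(oracle)

    d2, d1 = rel_dev(2e-9), rel_dev(1e-9)
    assert d1 < 0.01
    # absolute deviation is O(L^2), so the relative deviation halves with L
    assert d2 / d1 == pytest.approx(2.0, rel=0.15)


# ------------------------------------------------- ratios and conversions

def test_acoustic_ratio_limits(res, water, overtones):
    # Sauerbrey film in air: ratio 0
    rigid = shift_set_from_model(res, Layer(PowerLawMaterial.rigid(), 3e-9),
                                 BulkMedium.vacuum(), overtones,
                                 reference="bare")
    np.testing.assert_allclose(acoustic_ratio(rigid), 0.0, atol=1e-15)
    # Newtonian bulk alone: ratio 1 on all overtones
    k = kanazawa(res, water, overtones)
    bulk_only = OvertoneShiftSet(overtones, (k / overtones).real,
                                 (k / overtones).imag, reference="bare")
    np.testing.assert_allclose(acoustic_ratio(bulk_only), 1.0, rtol=1e-12)


def test_acoustic_ratio_undefined_flagged_per_overtone():
    s = OvertoneShiftSet([3, 5], [0.0, -1.0], [1.0, 1.0], reference="bulk")
    r = acoustic_ratio(s)
    assert np.isnan(r[0]) and r[1] == 1.0


def test_dissipation_conversion(res, overtones):
    """Delta Gamma/n = Delta D f0/2: 2.5 Hz per ppm at 5 MHz, any overtone."""
    assert dissipation_to_bandwidth(0.0, res) == 0.0
    assert dissipation_to_bandwidth(1.0, res, units="ppm") == pytest.approx(2.5)
    assert dissipation_to_bandwidth(2.0, res, units="ppm") == pytest.approx(5.0)
    assert dissipation_to_bandwidth(1e-6, res, units="absolute") == \
        pytest.approx(2.5)
    assert bandwidth_to_dissipation(2.5, res) == pytest.approx(1.0)


def test_overtone_validation():
    with pytest.raises(ValueError):
        OvertoneShiftSet([2, 4], [-1, -1], [0, 0])
    with pytest.raises(ValueError):
        OvertoneShiftSet([5, 3], [-1, -1], [0, 0])
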