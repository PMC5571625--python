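"""Corneal optics: surface powers, TNP/TCP, plane conversions, vergence."""

import math

import numpy as np
import pytest

from toricpred.config import OpticsConfig
from toricpred.double_angle import Astigmatism, vec_add
from toricpred.optics import (
    SurfaceGeometry,
    VergenceContext,
    iol_cyl_to_corneal,
    refraction_to_corneal_plane,
    refraction_to_spectacle_plane,
    spectacle_to_corneal,
    srkt_elp,
    surface_astigmatism,
    surface_power,
    tcp,
    tnp,
    vector_modality,
)


@pytest.mark.parametrize(
    "radius, n_in, n_out, expected",
    [
        (7.5, 1.0, 1.3375, 45.0),
        (6.0, 1.376, 1.336, -6.667),
        (7.5, 1.0, 1.376, 50.133),
    ],
)
def test_surface_power_examples(radius, n_in, n_out, expected):
    assert surface_power(radius, n_in, n_out) == pytest.approx(expected, abs=5e-4)


def test_surface_power_domain_and_antisymmetry(rng):
    with pytest.raises(ValueError):
        surface_power(0.0, 1.0, 1.3375)
    for r in rng.uniform(5.0, 9.0, 20):
        assert surface_power(r, 1.0, 1.376) == pytest.approx(-surface_power(r, 1.376, 1.0))


def test_surface_astigmatism_anterior():
    g = SurfaceGeometry(7.5, 7.8, 90.0)
    a = surface_astigmatism(g, 1.0, 1.3375)
    assert a.magnitude == pytest.approx(0.3375 * (1000 / 7.5 - 1000 / 7.8), abs=1e-9)
    assert a.magnitude == pytest.approx(1.731, abs=5e-4)
    assert a.axis == 90.0


def test_surface_astigmatism_posterior_axis_flip():
    # steep posterior curvature at 90° contributes an ATR-directed (axis 0) effect
    g = SurfaceGeometry(5.8, 6.1, 90.0)
    a = surface_astigmatism(g, 1.376, 1.336)
    assert a.magnitude == pytest.approx(abs(-40 / 5.8 + 40 / 6.1), abs=1e-9)
    assert a.magnitude == pytest.approx(0.339, abs=5e-4)
    assert a.axis == pytest.approx(0.0)


def test_surface_astigmatism_spherical_is_zero():
    g = SurfaceGeometry(7.7, 7.7, 0.0)
    assert surface_astigmatism(g, 1.0, 1.376).magnitude == 0.0


def test_vector_modality_matches_double_angle_sum():
    ant = SurfaceGeometry(7.5, 7.8, 90.0)
    post = SurfaceGeometry(5.8, 6.1, 90.0)
    got = vector_modality(ant, post)
    expected = vec_add(
        surface_astigmatism(ant, 1.0, 1.376), surface_astigmatism(post, 1.376, 1.336)
    )
    assert got.isclose(expected, tol=1e-9)


def test_vector_modality_zero_posterior_and_triangle_bound():
    ant = SurfaceGeometry(7.5, 7.8, 95.0)
    post_sph = SurfaceGeometry(6.2, 6.2, 0.0)
    assert vector_modality(ant, post_sph).isclose(surface_astigmatism(ant, 1.0, 1.376))
    post = SurfaceGeometry(5.9, 6.3, 40.0)
    total = vector_modality(ant, post)
    bound = (
        surface_astigmatism(ant, 1.0, 1.376).magnitude
        + surface_astigmatism(post, 1.376, 1.336).magnitude
    )
    assert total.magnitude <= bound + 1e-12


def test_tnp_meridional_thick_lens_arithmetic():
    """Hand check of F1 + F2 − (d/n)·F1·F2 per principal meridian."""
    ant = SurfaceGeometry(7.5, 7.8, 90.0)
    post = SurfaceGeometry(6.4, 6.4, 0.0)
    cct = 550.0
    d_over_n = 550e-6 / 1.376
    f1_steep, f1_flat = 376.0 / 7.5, 376.0 / 7.8
    f2 = -40.0 / 6.4
    f_steep = f1_steep + f2 - d_over_n * f1_steep * f2
    f_flat = f1_flat + f2 - d_over_n * f1_flat * f2
    got = tnp(ant, post, cct)
    assert got.magnitude == pytest.approx(f_steep - f_flat, abs=1e-9)
    assert got.axis == pytest.approx(90.0)


def test_tnp_thin_lens_limit_and_spherical_case():
    ant = SurfaceGeometry(7.4, 7.8, 80.0)
    post = SurfaceGeometry(5.9, 6.2, 100.0)
    thin = tnp(ant, post, 1e-6)
    expected = vec_add(
        surface_astigmatism(ant, 1.0, 1.376), surface_astigmatism(post, 1.376, 1.336)
    )
    assert thin.isclose(expected, tol=1e-6)
    sph = tnp(SurfaceGeometry(7.7, 7.7, 0.0), SurfaceGeometry(6.3, 6.3, 0.0), 550.0)
    assert sph.magnitude == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        tnp(ant, post, -5.0)


def test_tcp_paraxial_limit_agrees_with_tnp():
    ant = SurfaceGeometry(7.5, 7.8, 90.0)
    post = SurfaceGeometry(6.0, 6.0, 0.0)
    t_tnp = tnp(ant, post, 550.0)
    t_tcp = tcp(ant, post, 550.0, zone_mm=0.05)
    assert abs(t_tcp.magnitude - t_tnp.magnitude) < 0.01
    assert t_tcp.isclose(t_tnp, tol=0.01)


def test_tcp_spherical_cornea_is_zero_and_4mm_regression():
    sph = tcp(SurfaceGeometry(7.7, 7.7, 0.0), SurfaceGeometry(6.3, 6.3, 0.0), 550.0, 4.0)
    assert sph.magnitude == pytest.approx(0.0, abs=1e-9)
    got = tcp(SurfaceGeometry(7.5, 7.8, 90.0), SurfaceGeometry(6.0, 6.0, 0.0), 550.0, 4.0)
    ref = tnp(SurfaceGeometry(7.5, 7.8, 90.0), SurfaceGeometry(6.0, 6.0, 0.0), 550.0)
    assert abs(got.magnitude - ref.magnitude) < 0.2  # finite-zone trace near the Gaussian value
    assert got.axis == pytest.approx(90.0, abs=0.1)


def test_tcp_ray_miss_raises():
    with pytest.raises(ValueError):
        tcp(SurfaceGeometry(1.5, 1.5, 0.0), SurfaceGeometry(6.0, 6.0, 0.0), 550.0, 4.0)


def test_spectacle_to_corneal_examples():
    a = spectacle_to_corneal(-2.0, -1.0, 180.0, 12.0)
    expected = abs(-2.0 / 1.024 - (-3.0) / 1.036)
    assert a.magnitude == pytest.approx(expected, abs=1e-9)
    assert a.magnitude == pytest.approx(0.943, abs=5e-4)
    assert a.axis == pytest.approx(90.0)  # minus-cyl axis 180 → steep meridian 90

    assert spectacle_to_corneal(-2.0, 0.0, 0.0, 12.0).magnitude == 0.0
    assert spectacle_to_corneal(1.0, -1.5, 30.0, 0.0).magnitude == pytest.approx(1.5)


def test_vertex_round_trip_and_monotonicity():
    s, c, a = -1.25, -2.0, 40.0
    sc, cc, ac = refraction_to_corneal_plane(s, c, a, 12.0)
    s2, c2, a2 = refraction_to_spectacle_plane(sc, cc, ac, 12.0)
    assert (s2, c2, a2) == pytest.approx((s, c, a), abs=1e-12)
    # corneal-plane cylinder of a myopic refraction shrinks with distance
    mags = [spectacle_to_corneal(-4.0, -2.0, 0.0, d).magnitude for d in (0.0, 6.0, 12.0, 18.0)]
    assert all(m1 > m2 for m1, m2 in zip(mags, mags[1:]))


def test_srkt_elp_plausible_range():
    elp = srkt_elp(23.98, 43.5, 118.5)
    assert 4.0 < elp < 7.0
    assert srkt_elp(26.0, 43.5, 118.5) > elp  # longer eye → deeper ELP


def _vergence_oracle(p_iol, elp_mm, al_mm, k):
    """Independent two-meridian back-solve written out longhand."""
    n = 1.336
    elp, al = elp_mm / 1000.0, al_mm / 1000.0
    v2 = n / (al - elp) - p_iol
    v1 = n / (n / v2 + elp)
    return v1 - k


def test_iol_cyl_to_corneal_against_vergence_oracle():
    ctx = VergenceContext(12.0, 5.0, 23.98, 43.5, 118.5)
    cyl = 2.25
    expected = abs(
        _vergence_oracle(19.4 - cyl / 2, 5.0, 23.98, 43.5)
        - _vergence_oracle(19.4 + cyl / 2, 5.0, 23.98, 43.5)
    )
    got = iol_cyl_to_corneal(cyl, 19.4, ctx)
    assert got == pytest.approx(expected, abs=1e-12)
    assert 0.6 <= got / cyl <= 0.75


def test_iol_cyl_ratio_properties():
    assert iol_cyl_to_corneal(0.0, 19.4, VergenceContext(12.0, 5.0, 23.98, 43.5, 118.5)) == 0.0
    # ratio → 1 as the lens approaches the cornea, and decreases with depth
    ratios = []
    for elp in (1e-6, 2.0, 4.0, 6.0):
        ctx = VergenceContext(12.0, max(elp, 1e-6), 23.98, 43.5, 118.5)
        ratios.append(iol_cyl_to_corneal(1.5, 19.4, ctx) / 1.5)
    assert ratios[0] == pytest.approx(1.0, abs=1e-3)
    assert all(r1 > r2 for r1, r2 in zip(ratios, ratios[1:]))
    assert all(r < 1.0 + 1e-9 for r in ratios)


def test_surface_geometry_validation():
    with pytest.raises(ValueError):
        SurfaceGeometry(7.8, 7.5, 0.0)  # steep radius must be the smaller
    with pytest.raises(ValueError):
        SurfaceGeometry(-7.5, 7.8, 0.0)
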