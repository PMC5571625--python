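"""Double-angle astigmatism algebra: examples, oracle checks, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toricpred.double_angle import (
    Astigmatism,
    AxisClass,
    centroid,
    classify_axis,
    components,
    from_double_angle,
    to_double_angle,
    vec_add,
    vec_sub,
)

astigs = st.builds(
    Astigmatism,
    magnitude=st.floats(0.0, 6.0),
    axis=st.floats(0.0, 179.999),
)


def profile_sum_oracle(a: Astigmatism, b: Astigmatism) -> Astigmatism:
    """Independent oracle: sum the sinusoidal meridional power profiles
    P(φ) = (M/2)(1 − cos 2(φ−θ)) on a fine grid and re-fit magnitude/axis."""
    phi = np.arange(0.0, 180.0, 1.0)
    total = np.zeros_like(phi)
    for ast in (a, b):
        total += (ast.magnitude / 2.0) * (1.0 - np.cos(np.radians(2.0 * (phi - ast.axis))))
    t = np.radians(2.0 * phi)
    design = np.column_stack([np.ones_like(t), np.cos(t), np.sin(t)])
    _, bc, cc = np.linalg.lstsq(design, total, rcond=None)[0]
    # profile (M/2)(1 − cos2(φ−θ)) has double-angle amplitude M/2, minimum at θ
    mag = 2.0 * math.hypot(bc, cc)
    axis = (math.degrees(math.atan2(-cc, -bc)) / 2.0) % 180.0
    return Astigmatism(mag, axis if mag > 1e-12 else 0.0)


@pytest.mark.parametrize(
    "mag, axis, x, y",
    [
        (1.0, 90.0, -1.0, 0.0),
        (0.5, 45.0, 0.0, 0.5),
        (0.0, 0.0, 0.0, 0.0),
    ],
)
def test_to_double_angle_examples(mag, axis, x, y):
    v = to_double_angle(Astigmatism(mag, axis))
    assert v.x == pytest.approx(x, abs=1e-12)
    assert v.y == pytest.approx(y, abs=1e-12)


@pytest.mark.parametrize(
    "x, y, mag, axis",
    [
        (0.56, 0.0, 0.56, 0.0),
        (-1.0, 0.0, 1.0, 90.0),
        (0.0, -0.5, 0.5, 135.0),
    ],
)
def test_from_double_angle_examples(x, y, mag, axis):
    a = from_double_angle((x, y))
    assert a.magnitude == pytest.approx(mag, abs=1e-12)
    assert a.axis == pytest.approx(axis, abs=1e-9)


def test_vec_add_against_meridional_profile_oracle():
    a, b = Astigmatism(2.25, 90.0), Astigmatism(0.56, 0.0)
    expected = profile_sum_oracle(a, b)
    got = vec_add(a, b)
    assert got.magnitude == pytest.approx(expected.magnitude, abs=1e-9)
    assert got.magnitude == pytest.approx(1.69, abs=1e-12)
    assert got.axis == pytest.approx(90.0, abs=1e-9)


def test_vec_add_cancellation_and_identity():
    z = vec_add(Astigmatism(1.0, 90.0), Astigmatism(1.0, 0.0))
    assert z.magnitude == pytest.approx(0.0, abs=1e-12)
    a = Astigmatism(1.3, 37.0)
    assert vec_add(a, Astigmatism(0.0, 123.0)).isclose(a)


def test_vec_sub_examples():
    d = vec_sub(Astigmatism(0.5, 90.0), Astigmatism(1.0, 90.0))
    assert d.isclose(Astigmatism(0.5, 0.0))
    d2 = vec_sub(Astigmatism(1.69, 90.0), Astigmatism(2.25, 90.0))
    assert d2.isclose(Astigmatism(0.56, 0.0))
    a = Astigmatism(0.8, 12.0)
    assert vec_sub(a, Astigmatism(0.0, 66.0)).isclose(a)


def test_centroid_examples():
    c, mean_abs = centroid([Astigmatism(1.0, 90.0), Astigmatism(1.0, 0.0)])
    assert c.magnitude == pytest.approx(0.0, abs=1e-12)
    assert mean_abs == pytest.approx(1.0)

    v = Astigmatism(0.7, 34.0)
    c2, m2 = centroid([v] * 5)
    assert c2.isclose(v, tol=1e-12)
    assert m2 == pytest.approx(0.7)

    c3, m3 = centroid([Astigmatism(0.5, 90.0)] * 2 + [Astigmatism(0.5, 0.0)])
    assert c3.magnitude == pytest.approx(0.5 / 3.0, abs=1e-12)
    assert c3.axis == pytest.approx(90.0)
    assert m3 == pytest.approx(0.5)


def test_centroid_empty_raises():
    with pytest.raises(ValueError):
        centroid([])


@pytest.mark.parametrize(
    "mag, axis, wtr_atr, oblique",
    [
        (1.0, 90.0, -1.0, 0.0),
        (1.0, 135.0, 0.0, 1.0),  # 135°-directed is positive by convention
        (0.59, 103.0, -0.530, 0.259),  # centroid error of the WTR anterior-only modality
    ],
)
def test_components_sign_convention(mag, axis, wtr_atr, oblique):
    c = components(Astigmatism(mag, axis))
    assert c.wtr_atr == pytest.approx(wtr_atr, abs=5e-4)
    assert c.oblique == pytest.approx(oblique, abs=5e-4)


@pytest.mark.parametrize(
    "axis, klass",
    [
        (103.0, AxisClass.WTR),
        (171.0, AxisClass.ATR),
        (45.0, AxisClass.OBLIQUE),
        (60.0, AxisClass.WTR),
        (120.0, AxisClass.WTR),
        (30.0, AxisClass.ATR),
        (150.0, AxisClass.ATR),
        (0.0, AxisClass.ATR),
        (30.5, AxisClass.OBLIQUE),
        (149.5, AxisClass.OBLIQUE),
        (183.0, AxisClass.ATR),  # folded mod 180 before classification
        (-10.0, AxisClass.ATR),
    ],
)
def test_classify_axis_bands(axis, klass):
    assert classify_axis(axis) is klass


def test_astigmatism_invariants():
    with pytest.raises(ValueError):
        Astigmatism(-0.1, 90.0)
    assert Astigmatism(0.0, 77.0).axis == 0.0  # zero magnitude canonicalizes
    assert Astigmatism(1.0, 200.0).axis == pytest.approx(20.0)


@settings(derandomize=True, max_examples=300)
@given(astigs)
def test_round_trip_identity(a):
    assert from_double_angle(to_double_angle(a)).isclose(a, tol=1e-9)


@settings(derandomize=True, max_examples=200)
@given(astigs, astigs, astigs)
def test_group_structure(a, b, c):
    assert vec_add(a, b).isclose(vec_add(b, a), tol=1e-9)
    assert vec_add(vec_add(a, b), c).isclose(vec_add(a, vec_add(b, c)), tol=1e-9)
    inverse = Astigmatism(a.magnitude, a.axis + 90.0)
    assert vec_add(a, inverse).magnitude <= 1e-9


@settings(derandomize=True, max_examples=300)
@given(astigs)
def test_components_preserve_norm(a):
    c = components(a)
    assert math.hypot(c.wtr_atr, c.oblique) == pytest.approx(a.magnitude, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(st.lists(astigs, min_size=1, max_size=12))
def test_centroid_jensen_bound(vs):
    c, mean_abs = centroid(vs)
    assert c.magnitude <= mean_abs + 1e-12


@settings(derandomize=True, max_examples=300)
@given(st.floats(-360.0, 720.0))
def test_classification_is_a_partition(axis):
    assert classify_axis(axis) in (AxisClass.WTR, AxisClass.ATR, AxisClass.OBLIQUE)
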