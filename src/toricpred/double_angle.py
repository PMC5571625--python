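"""Double-angle vector algebra for corneal astigmatism.

Astigmatism is the universal currency of this package: a magnitude in
diopters attached to a steep-meridian axis in degrees.  Because meridians
repeat every 180°, astigmatisms do not add like ordinary vectors; mapping
``M @ θ`` to the plane vector ``(M·cos 2θ, M·sin 2θ)`` (the *double-angle*
representation) makes addition, subtraction and averaging linear.  All of
the Alpins-style vector analysis in this package — surgically induced
astigmatism, prediction errors, centroids — happens in that space.

Conventions
-----------
* Axes are in degrees on ``[0, 180)`` and always denote the *steep*
  (highest-power) meridian.
* A zero-magnitude astigmatism carries the canonical axis 0.
* The clinically reported WTR/ATR and oblique error components apply a sign
  flip to the second double-angle coordinate (``oblique = −M·sin 2θ``), so
  that errors directed along 135° are positive and along 45° negative;
  internal vector algebra always uses the unflipped ``(x, y)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Astigmatism",
    "DoubleAngleVector",
    "ComponentPair",
    "AxisClass",
    "to_double_angle",
    "from_double_angle",
    "vec_add",
    "vec_sub",
    "centroid",
    "components",
    "classify_axis",
    "normalize_axis",
]

#: default tolerance (diopters, double-angle space) for equality testing
DEFAULT_TOL = 1e-9


def normalize_axis(axis_deg: float) -> float:
    """Fold an axis in degrees into ``[0, 180)``."""
    a = math.fmod(float(axis_deg), 180.0)
    if a < 0.0:
        a += 180.0
    return a


@dataclass(frozen=True)
class Astigmatism:
    """Magnitude (D, ≥ 0) at a steep-meridian axis (degrees, ``[0, 180)``).

    The constructor normalizes the axis modulo 180 and canonicalizes the
    axis of a zero-magnitude value to 0.  Negative magnitudes are rejected:
    an astigmatism "of −M at θ" is the same physical quantity as ``M`` at
    ``θ + 90`` and must be written that way.
    """

    magnitude: float
    axis: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude) or not math.isfinite(self.axis):
            raise ValueError("Astigmatism requires finite magnitude and axis")
        if self.magnitude < 0.0:
            raise ValueError(f"magnitude must be >= 0, got {self.magnitude}")
        axis = 0.0 if self.magnitude == 0.0 else normalize_axis(self.axis)
        object.__setattr__(self, "magnitude", float(self.magnitude))
        object.__setattr__(self, "axis", axis)

    def isclose(self, other: "Astigmatism", tol: float = DEFAULT_TOL) -> bool:
        """Equality in double-angle space within ``tol`` diopters."""
        a, b = to_double_angle(self), to_double_angle(other)
        return math.hypot(a.x - b.x, a.y - b.y) <= tol

    def __str__(self) -> str:  # clinical "M @ A" notation
        return f"{self.magnitude:.2f} @ {self.axis:.0f}"


@dataclass(frozen=True)
class DoubleAngleVector:
    """Cartesian form ``(M·cos 2θ, M·sin 2θ)`` of an astigmatism, in D."""

    x: float
    y: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class ComponentPair:
    """Signed clinical error components of an astigmatism vector.

    ``wtr_atr``  — component along the 90°/0° axis pair; negative values
    point toward 90° (over-correction of WTR / under-correction of ATR
    astigmatism when applied to prediction errors).

    ``oblique`` — component along the 135°/45° pair; positive toward 135°,
    negative toward 45°.

    ``wtr_atr² + oblique²`` equals the squared magnitude of the source
    vector exactly.
    """

    wtr_atr: float
    oblique: float


class AxisClass(str, Enum):
    """Exhaustive steep-meridian classification of ``[0, 180)``."""

    WTR = "WTR"
    ATR = "ATR"
    OBLIQUE = "OBLIQUE"


def to_double_angle(a: Astigmatism) -> DoubleAngleVector:
    """Map ``M @ θ`` to ``(M·cos 2θ, M·sin 2θ)``."""
    t = math.radians(2.0 * a.axis)
    return DoubleAngleVector(a.magnitude * math.cos(t), a.magnitude * math.sin(t))


def from_double_angle(v: DoubleAngleVector | tuple[float, float]) -> Astigmatism:
    """Inverse of :func:`to_double_angle`; ``(0, 0)`` maps to ``0 @ 0``."""
    x, y = (v.x, v.y) if isinstance(v, DoubleAngleVector) else v
    mag = math.hypot(x, y)
    if mag == 0.0:
        return Astigmatism(0.0, 0.0)
    axis = normalize_axis(math.degrees(math.atan2(y, x)) / 2.0)
    return Astigmatism(mag, axis)


def vec_add(a: Astigmatism, b: Astigmatism) -> Astigmatism:
    """Alpins vector summation: componentwise sum in double-angle space."""
    va, vb = to_double_angle(a), to_double_angle(b)
    return from_double_angle((va.x + vb.x, va.y + vb.y))


def vec_sub(a: Astigmatism, b: Astigmatism) -> Astigmatism:
    """Double-angle difference ``a − b``; ``vec_sub(a, a)`` is ``0 @ 0``."""
    va, vb = to_double_angle(a), to_double_angle(b)
    return from_double_angle((va.x - vb.x, va.y - vb.y))


def centroid(vs: Sequence[Astigmatism] | Iterable[Astigmatism]) -> tuple[Astigmatism, float]:
    """Vector mean of astigmatisms, plus the arithmetic mean of magnitudes.

    Returns ``(centroid, mean_abs)``.  The centroid magnitude never exceeds
    ``mean_abs`` (Jensen's inequality), with equality only when all axes
    coincide.

    Raises
    ------
    ValueError
        If the input is empty.
    """
    vs = list(vs)
    if not vs:
        raise ValueError("centroid of an empty list is undefined")
    xs, ys, mags = zip(*((dv.x, dv.y, a.magnitude) for a in vs for dv in (to_double_angle(a),)))
    c = from_double_angle((sum(xs) / len(vs), sum(ys) / len(vs)))
    return c, sum(mags) / len(vs)


def components(a: Astigmatism) -> ComponentPair:
    """Decompose into signed WTR/ATR and oblique reporting components.

    ``wtr_atr = M·cos 2θ`` and ``oblique = −M·sin 2θ``; the sign flip on the
    oblique term makes 135°-directed vectors positive and 45°-directed
    vectors negative.
    """
    v = to_double_angle(a)
    return ComponentPair(wtr_atr=v.x, oblique=-v.y)


def classify_axis(axis_deg: float) -> AxisClass:
    """Classify a steep meridian as WTR, ATR or OBLIQUE.

    WTR on ``[60, 120]``; ATR on ``[0, 30] ∪ [150, 180)``; OBLIQUE on the
    open bands in between.  Inputs outside ``[0, 180)`` are folded first.
    """
    a = normalize_axis(axis_deg)
    if 60.0 <= a <= 120.0:
        return AxisClass.WTR
    if a <= 30.0 or a >= 150.0:
        return AxisClass.ATR
    return AxisClass.OBLIQUE


# ---------------------------------------------------------------------------
# Array helpers — vectorized double-angle algebra for cohort-scale work.
# These mirror the scalar API on numpy arrays (magnitudes in D, axes in deg).

def axes_to_xy(mag: np.ndarray, axis_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.radians(2.0 * np.asarray(axis_deg, dtype=float))
    m = np.asarray(mag, dtype=float)
    return m * np.cos(t), m * np.sin(t)


def xy_to_axes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mag = np.hypot(x, y)
    axis = np.degrees(np.arctan2(y, x)) / 2.0
    axis = np.mod(axis, 180.0)
    axis = np.where(mag == 0.0, 0.0, axis)
    return mag, axis
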