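"""Meridional corneal power computations and plane conversions.

Implements the corneal-power modalities that take the posterior surface
into account, plus the optical plumbing of the accuracy analysis:

* :func:`surface_power` / :func:`surface_astigmatism` — single refracting
  surface, ``P = (n_out − n_in)/r``;
* :func:`vector_modality` — Alpins vector sum of anterior (1.0→1.376) and
  posterior (1.376→1.336) surface astigmatisms;
* :func:`tnp` — true net power from the Gaussian thick-lens formula
  ``F = F1 + F2 − (d/n)·F1·F2`` per meridian;
* :func:`tcp` — total corneal refractive power by exact meridional Snell
  ray tracing through both spherical (per-meridian) surfaces over a pupil
  zone, averaged over ray height;
* spectacle↔corneal-plane refraction conversion (per-meridian vertex
  formula ``P' = P/(1 − d·P)``);
* :func:`iol_cyl_to_corneal` — IOL-plane toric cylinder to corneal-plane
  cylinder through a two-meridian refractive vergence chain with the SRK/T
  effective lens position.

Surfaces whose steep meridians are not co-axial are combined by sampling
the meridional power profiles on a degree grid, summing, and re-fitting the
``a + b·cos 2φ + c·sin 2φ`` sinusoid — the continuous analogue of the
double-angle vector sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import OpticsConfig
from .double_angle import Astigmatism, from_double_angle, normalize_axis

__all__ = [
    "SurfaceGeometry",
    "VergenceContext",
    "surface_power",
    "surface_astigmatism",
    "vector_modality",
    "tnp",
    "tcp",
    "spectacle_to_corneal",
    "refraction_to_corneal_plane",
    "refraction_to_spectacle_plane",
    "srkt_elp",
    "iol_cyl_to_corneal",
]


@dataclass(frozen=True)
class SurfaceGeometry:
    """Per-meridian spherical description of one corneal surface.

    Radii are stored positive for the cornea-convex orientation; the sign of
    the optical power comes from the refractive-index ordering.  The steep
    meridian is the one of smaller radius (greater curvature).
    """

    r_steep_mm: float
    r_flat_mm: float
    steep_axis_deg: float

    def __post_init__(self) -> None:
        if self.r_steep_mm <= 0 or self.r_flat_mm <= 0:
            raise ValueError("surface radii must be positive")
        if self.r_flat_mm < self.r_steep_mm:
            raise ValueError("flat-meridian radius must be >= steep-meridian radius")
        object.__setattr__(self, "steep_axis_deg", normalize_axis(self.steep_axis_deg))

    def curvature_profile(self, phi_deg: np.ndarray) -> np.ndarray:
        """Normal curvature (1/mm) at each meridian ``phi`` of a toric surface."""
        c_steep = 1.0 / self.r_steep_mm
        c_flat = 1.0 / self.r_flat_mm
        d = np.radians(np.asarray(phi_deg, dtype=float) - self.steep_axis_deg)
        return c_flat + (c_steep - c_flat) * np.cos(d) ** 2


@dataclass(frozen=True)
class VergenceContext:
    """Geometry of the pseudophakic eye for vergence calculations."""

    vertex_distance_mm: float
    elp_mm: float
    axial_length_mm: float
    mean_k_d: float
    a_constant: float

    def __post_init__(self) -> None:
        for name in ("vertex_distance_mm", "elp_mm", "axial_length_mm", "mean_k_d", "a_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.elp_mm >= self.axial_length_mm:
            raise ValueError("effective lens position must be anterior to the retina")


def surface_power(radius_mm: float, n_in: float, n_out: float) -> float:
    """Paraxial power (D) of a single spherical refracting surface."""
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    return (n_out - n_in) / (radius_mm / 1000.0)


def surface_astigmatism(g: SurfaceGeometry, n_in: float, n_out: float) -> Astigmatism:
    """Astigmatism contributed by one surface.

    Magnitude is the absolute meridional power difference; the axis is the
    meridian of the more *positive* power.  For the posterior surface
    (``n_out < n_in``) the powers are negative, so the more positive total
    contribution lies on the flat-curvature meridian: a posterior surface
    steep at 90° produces an against-the-rule (axis 0) effect.
    """
    p_steep = surface_power(g.r_steep_mm, n_in, n_out)
    p_flat = surface_power(g.r_flat_mm, n_in, n_out)
    diff = p_steep - p_flat
    if diff >= 0:
        return Astigmatism(diff, g.steep_axis_deg)
    return Astigmatism(-diff, g.steep_axis_deg + 90.0)


def _fit_meridional_profile(phi_deg: np.ndarray, power: np.ndarray) -> tuple[float, Astigmatism]:
    """Least-squares fit ``P(φ) ≈ a + b·cos 2φ + c·sin 2φ``.

    A pure astigmatism ``M @ θ`` has profile ``P_flat + M·cos²(φ−θ)``, i.e.
    double-angle amplitude ``M/2``; the fit therefore returns magnitude
    ``2·√(b²+c²)`` at the axis of maximum power, together with the mean
    power ``a``.
    """
    t = np.radians(2.0 * phi_deg)
    design = np.column_stack([np.ones_like(t), np.cos(t), np.sin(t)])
    coef, *_ = np.linalg.lstsq(design, power, rcond=None)
    a, b, c = coef
    return float(a), from_double_angle((2.0 * b, 2.0 * c))


def _meridian_grid(step_deg: float) -> np.ndarray:
    n = max(int(round(180.0 / step_deg)), 4)
    return np.arange(n) * (180.0 / n)


def vector_modality(
    anterior: SurfaceGeometry,
    posterior: SurfaceGeometry,
    cfg: OpticsConfig | None = None,
) -> Astigmatism:
    """Two-surface vector modality: Alpins sum of the surface astigmatisms."""
    cfg = cfg or OpticsConfig()
    from .double_angle import vec_add

    ant = surface_astigmatism(anterior, cfg.n_air, cfg.n_cornea)
    post = surface_astigmatism(posterior, cfg.n_cornea, cfg.n_aqueous)
    return vec_add(ant, post)


def tnp(
    anterior: SurfaceGeometry,
    posterior: SurfaceGeometry,
    cct_um: float,
    cfg: OpticsConfig | None = None,
) -> Astigmatism:
    """True net power astigmatism from the Gaussian thick-lens formula.

    Per meridian ``φ``: ``F(φ) = F1(φ) + F2(φ) − (d/n)·F1(φ)·F2(φ)`` with
    ``d`` the central corneal thickness in metres and ``n`` the stromal
    index.  Non-co-axial surfaces are handled by profile sampling and
    sinusoid re-fit.
    """
    if cct_um <= 0:
        raise ValueError("central corneal thickness must be positive")
    cfg = cfg or OpticsConfig()
    phi = _meridian_grid(cfg.meridian_step_deg)
    f1 = (cfg.n_cornea - cfg.n_air) * anterior.curvature_profile(phi) * 1000.0
    f2 = (cfg.n_aqueous - cfg.n_cornea) * posterior.curvature_profile(phi) * 1000.0
    d_over_n = (cct_um * 1e-6) / cfg.n_cornea
    f_total = f1 + f2 - d_over_n * f1 * f2
    _, astig = _fit_meridional_profile(phi, f_total)
    return astig


# ---------------------------------------------------------------------------
# TCP: exact meridional ray trace through two spherical surfaces.

def _refract_2d(dz, dy, nz, ny, n1: float, n2: float):
    """Snell refraction of unit direction (dz, dy) at unit normal (nz, ny).

    The normal must oppose the incident direction (d·n < 0).  Raises on
    total internal reflection.
    """
    mu = n1 / n2
    cos_i = -(dz * nz + dy * ny)
    sin_t2 = mu**2 * (1.0 - cos_i**2)
    if np.any(sin_t2 > 1.0):
        raise ValueError("total internal reflection in corneal ray trace")
    cos_t = np.sqrt(1.0 - sin_t2)
    k = mu * cos_i - cos_t
    return mu * dz + k * nz, mu * dy + k * ny


def _trace_meridional_power(r1_mm, r2_mm, cct_mm: float, heights_mm, cfg: OpticsConfig):
    """Equivalent power seen by parallel rays at the given heights.

    ``r1_mm``/``r2_mm`` may be arrays (one radius per meridian); heights is
    a 1-D array.  Returns an array of shape (n_meridians, n_heights) of
    per-ray equivalent powers ``F = −n'·tan(u′)/h``, which converges to the
    Gaussian thick-lens power as h → 0.
    """
    r1 = np.asarray(r1_mm, dtype=float)[:, None]
    r2 = np.asarray(r2_mm, dtype=float)[:, None]
    h = np.asarray(heights_mm, dtype=float)[None, :]
    if np.any(h >= r1):
        raise ValueError("ray height exceeds anterior radius of curvature (ray misses surface)")

    # Surface 1: vertex at z=0, center (r1, 0); parallel ray y = h.
    z1 = r1 - np.sqrt(r1**2 - h**2)
    y1 = np.broadcast_to(h, z1.shape)
    # outward unit normal opposing the incident (+z) ray
    nz1 = (z1 - r1) / r1
    ny1 = y1 / r1
    dz, dy = _refract_2d(1.0, 0.0, nz1, ny1, cfg.n_air, cfg.n_cornea)

    # Surface 2: vertex at z=cct, center (cct + r2, 0).
    cz = cct_mm + r2
    pz = z1 - cz
    py = y1
    b = dz * pz + dy * py
    disc = b**2 - (pz**2 + py**2 - r2**2)
    if np.any(disc < 0):
        raise ValueError("ray misses the posterior corneal surface")
    s = -b - np.sqrt(disc)
    z2 = z1 + s * dz
    y2 = y1 + s * dy
    nz2 = (z2 - cz) / r2
    ny2 = y2 / r2
    dz2, dy2 = _refract_2d(dz, dy, nz2, ny2, cfg.n_cornea, cfg.n_aqueous)

    slope = dy2 / dz2  # tan of the exit angle; negative for converging rays
    return -cfg.n_aqueous * slope / h * 1000.0  # heights in mm → power in D


def tcp(
    anterior: SurfaceGeometry,
    posterior: SurfaceGeometry,
    cct_um: float,
    zone_mm: float | None = None,
    cfg: OpticsConfig | None = None,
) -> Astigmatism:
    """Total corneal refractive power astigmatism by Snell-law ray tracing.

    For each meridian of a degree grid, parallel rays are traced at heights
    uniform in ``(0, zone/2]`` through the anterior and posterior spherical
    (per-meridian) surfaces; the per-ray equivalent powers are averaged over
    the zone and the meridional profile is re-fit to a sinusoid.  In the
    small-zone limit this agrees with :func:`tnp` (paraxial equivalence).
    """
    cfg = cfg or OpticsConfig()
    zone = cfg.tcp_zone_mm if zone_mm is None else zone_mm
    if zone <= 0:
        raise ValueError("zone diameter must be positive")
    if cct_um <= 0:
        raise ValueError("central corneal thickness must be positive")
    phi = _meridian_grid(cfg.meridian_step_deg)
    r1 = 1.0 / anterior.curvature_profile(phi)
    r2 = 1.0 / posterior.curvature_profile(phi)
    n_h = max(int(cfg.tcp_n_heights), 1)
    heights = (np.arange(1, n_h + 1) / n_h) * (zone / 2.0)
    powers = _trace_meridional_power(r1, r2, cct_um * 1e-3, heights, cfg)
    _, astig = _fit_meridional_profile(phi, powers.mean(axis=1))
    return astig


# ---------------------------------------------------------------------------
# Refraction plane conversions.

def _vertex_transform(power_d: float, distance_m: float) -> float:
    denom = 1.0 - distance_m * power_d
    if abs(denom) < 1e-9:
        raise ValueError("vergence diverges in vertex transform (1 − d·P ≈ 0)")
    return power_d / denom


def refraction_to_corneal_plane(
    sphere_d: float, cyl_d: float, axis_deg: float, vertex_distance_mm: float
) -> tuple[float, float, float]:
    """Move a spectacle refraction to the corneal plane, per meridian.

    Returns ``(sphere, cyl, axis)`` in the same cylinder-sign convention as
    the input (the axis is unchanged; each principal meridian power is
    transformed by ``P' = P/(1 − d·P)``).
    """
    d = vertex_distance_mm / 1000.0
    p_axis = _vertex_transform(sphere_d, d)           # power at the cyl axis meridian
    p_cross = _vertex_transform(sphere_d + cyl_d, d)  # power 90° away
    return p_axis, p_cross - p_axis, normalize_axis(axis_deg)


def refraction_to_spectacle_plane(
    sphere_d: float, cyl_d: float, axis_deg: float, vertex_distance_mm: float
) -> tuple[float, float, float]:
    """Inverse of :func:`refraction_to_corneal_plane` (``P = P'/(1 + d·P')``)."""
    d = -vertex_distance_mm / 1000.0
    p_axis = _vertex_transform(sphere_d, d)
    p_cross = _vertex_transform(sphere_d + cyl_d, d)
    return p_axis, p_cross - p_axis, normalize_axis(axis_deg)


def spectacle_to_corneal(
    sphere_d: float, cyl_d: float, axis_deg: float, vertex_distance_mm: float
) -> Astigmatism:
    """Corneal-plane cylinder of a spectacle refraction, as an astigmatism.

    The steep meridian is the one of more *negative* corneal-plane
    refraction (a steeper cornea is more myopic along that meridian), so a
    minus-cylinder refraction maps to steep axis ``axis + 90``.
    """
    _, cyl_c, axis = refraction_to_corneal_plane(sphere_d, cyl_d, axis_deg, vertex_distance_mm)
    if cyl_c == 0.0:
        return Astigmatism(0.0, 0.0)
    steep = axis + 90.0 if cyl_c < 0 else axis
    return Astigmatism(abs(cyl_c), steep)


# ---------------------------------------------------------------------------
# SRK/T effective lens position and the IOL→corneal cylinder ratio.

def srkt_elp(axial_length_mm: float, mean_k_d: float, a_constant: float) -> float:
    """SRK/T effective lens position (mm) from biometry and the A-constant."""
    al = axial_length_mm
    k = mean_k_d
    r = 337.5 / k
    lcor = al if al <= 24.2 else -3.446 + 1.716 * al - 0.0237 * al**2
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    h = r - math.sqrt(max(r**2 - cw**2 / 4.0, 0.0))
    acd_const = 0.62467 * a_constant - 68.747
    return h + (acd_const - 3.336)


def _corneal_refraction_for_iol(p_iol_d: float, ctx: VergenceContext, n: float) -> float:
    """Corneal-plane refraction that focuses an eye with the given IOL power.

    Back-solves the vergence chain: corneal power ``mean_k`` at the corneal
    plane, IOL of power ``p_iol`` at depth ``elp``, retina at ``axial_length``
    (aqueous/vitreous index ``n``).
    """
    elp = ctx.elp_mm / 1000.0
    al = ctx.axial_length_mm / 1000.0
    v_after_iol = n / (al - elp)
    v_before_iol = v_after_iol - p_iol_d
    if abs(v_before_iol) < 1e-9:
        raise ValueError("non-physical vergence: zero vergence at the IOL plane")
    denom = n / v_before_iol + elp
    if abs(denom) < 1e-12:
        raise ValueError("non-physical vergence in the corneal-plane back-solve")
    v_at_cornea = n / denom
    return v_at_cornea - ctx.mean_k_d


def iol_cyl_to_corneal(
    toric_cyl_iol_plane_d: float, iol_sphere_d: float, ctx: VergenceContext
) -> float:
    """Corneal-plane cylinder (D) equivalent to an IOL-plane toric cylinder.

    Runs the refractive vergence chain for the two IOL principal meridians
    ``iol_sphere ± toric_cyl/2`` and differences the corneal-plane
    refractions.  The ratio to the IOL-plane cylinder is < 1 for any
    physiologic effective lens position and decreases as the IOL sits
    deeper.
    """
    if toric_cyl_iol_plane_d == 0.0:
        return 0.0
    n = 1.336
    r_hi = _corneal_refraction_for_iol(iol_sphere_d + toric_cyl_iol_plane_d / 2.0, ctx, n)
    r_lo = _corneal_refraction_for_iol(iol_sphere_d - toric_cyl_iol_plane_d / 2.0, ctx, n)
    return abs(r_lo - r_hi)
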