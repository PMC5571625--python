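"""Synthetic eye-cohort generator for the toric-IOL accuracy analysis.

Generates self-consistent cohorts of pseudophakic eyes in which every
downstream quantity — device readings, Scheimpflug radii, implanted IOL,
observed alignment, follow-up manifest refraction — is a (optionally noisy)
view of an explicit per-eye truth record.  The truth is composed *forward*
through the very same estimation equation the analysis pipeline inverts:

    postop manifest cylinder = true preop total ⊕ corneal-plane IOL
                               cylinder (at the implanted axis) ⊕ true SICA

so that with all noise channels at zero the pipeline recovers the truth to
floating-point precision (the generator's master closure property).

Truth model
-----------
* ``A`` — true anterior keratometric astigmatism (what anterior-only
  devices read); drawn per subgroup from calibrated truncated normals.
* ``P`` — true posterior-surface effect vector; magnitude drawn per
  subgroup, steep curvature meridian near vertical in both subgroups, so
  the effect is against-the-rule-directed.
* ``T = A ⊕ P`` — true total corneal astigmatism (what the corneal
  wavefront channel reads, and what the two-surface Vector modality
  computes from the synthesized radii).
* true SICA — flattening at the temporal incision meridian: the induced
  astigmatism vector carries steep axis ``incision + 90``, magnitude drawn
  around the surgeon's assumed 0.50 D.

Anterior radii are synthesized so that the 1.0→1.376 anterior surface
astigmatism equals ``A`` exactly, posterior radii so the 1.376→1.336
surface effect equals ``P``; device channels are modelled directly in
astigmatism space.  Truncated-normal magnitude channels are *mean
calibrated*: the underlying normal location is solved so the truncated
mean equals the configured mean (the nominal SD is kept, so the realized
SD sits slightly below it — a truncated normal cannot always match both).
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.optimize import brentq

from .config import AnalysisConfig, OpticsConfig, _load_mapping
from .double_angle import Astigmatism, from_double_angle, to_double_angle, vec_add, vec_sub
from .optics import (
    VergenceContext,
    iol_cyl_to_corneal,
    refraction_to_spectacle_plane,
    srkt_elp,
)

__all__ = [
    "TruncNormalSpec",
    "SubgroupSpec",
    "NoiseConfig",
    "CohortConfig",
    "generate_cohort",
    "select_toricity",
    "sample_truncnorm",
]


class TruncNormalSpec(BaseModel):
    """A truncated-normal channel ``N(mean, sd²)`` restricted to ``[lo, hi]``.

    With ``calibrate_mean`` (the default for magnitude channels) the
    location of the parent normal is solved so that the *truncated* mean
    equals ``mean``.
    """

    mean: float
    sd: float = Field(ge=0.0)
    lo: float
    hi: float
    calibrate_mean: bool = True

    @model_validator(mode="after")
    def _check(self) -> "TruncNormalSpec":
        if self.lo >= self.hi:
            raise ValueError(f"infeasible truncation [{self.lo}, {self.hi}]")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean {self.mean} outside truncation [{self.lo}, {self.hi}]")
        return self


@lru_cache(maxsize=256)
def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of the parent normal whose truncation to [lo, hi] has the
    requested mean (monotone in the location; solved by bisection)."""

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    span = 8.0 * sd
    return float(brentq(lambda mu: trunc_mean(mu) - mean, lo - span, hi + span, xtol=1e-12))


def sample_truncnorm(spec: TruncNormalSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.sd == 0.0:
        return np.full(n, spec.mean)
    loc = _calibrated_loc(spec.mean, spec.sd, spec.lo, spec.hi) if spec.calibrate_mean else spec.mean
    a, b = (spec.lo - loc) / spec.sd, (spec.hi - loc) / spec.sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=spec.sd, size=n, random_state=rng)


class SubgroupSpec(BaseModel):
    """Per-subgroup (WTR or ATR) astigmatism distributions."""

    anterior_mag: TruncNormalSpec
    anterior_axis: TruncNormalSpec  # steep meridian, deg (folded mod 180 on use)
    posterior_mag: TruncNormalSpec


class NoiseConfig(BaseModel):
    """Per-channel device/refraction noise (all SDs ≥ 0).

    Astigmatism channels are perturbed per double-angle component (D);
    radii in mm; manifest refraction at the spectacle plane.
    """

    iolmaster_sd_d: float = Field(0.10, ge=0)
    simk_sd_d: float = Field(0.15, ge=0)
    wavefront_sd_d: float = Field(0.20, ge=0)
    radius_sd_mm: float = Field(0.015, ge=0)
    manifest_cyl_sd_d: float = Field(0.25, ge=0)
    manifest_sphere_sd_d: float = Field(0.25, ge=0)


def _default_wtr() -> SubgroupSpec:
    return SubgroupSpec(
        anterior_mag=TruncNormalSpec(mean=2.25, sd=1.04, lo=1.00, hi=4.54),
        anterior_axis=TruncNormalSpec(mean=90.0, sd=8.0, lo=60.0, hi=120.0, calibrate_mean=False),
        posterior_mag=TruncNormalSpec(mean=0.56, sd=0.21, lo=0.20, hi=1.00),
    )


def _default_atr() -> SubgroupSpec:
    return SubgroupSpec(
        anterior_mag=TruncNormalSpec(mean=1.39, sd=0.56, lo=1.00, hi=2.19),
        anterior_axis=TruncNormalSpec(mean=0.0, sd=8.0, lo=-30.0, hi=30.0, calibrate_mean=False),
        posterior_mag=TruncNormalSpec(mean=0.26, sd=0.20, lo=0.10, hi=0.70),
    )


class CohortConfig(BaseModel):
    """Study conditions of a synthetic cohort.

    Defaults emulate the baseline characteristics of a 41-eye toric-IOL
    series: 24/41 WTR eyes; anterior keratometric astigmatism 2.25 ± 1.04 D
    (WTR) and 1.39 ± 0.56 D (ATR); posterior astigmatism 0.56 ± 0.21 D
    (WTR, range 0.20–1.0) and 0.26 ± 0.20 D (ATR, range 0.10–0.70) with a
    vertically aligned posterior steep meridian; AL 23.98 ± 0.97 mm, ACD
    2.80 ± 0.42 mm, IOL sphere 19.4 ± 3.8 D; surgeon-assumed SICA 0.50 D at
    a temporal incision.
    """

    n_eyes: int = Field(41, ge=1)
    seed: int
    wtr_fraction: float = Field(24.0 / 41.0, ge=0.0, le=1.0)
    wtr: SubgroupSpec = Field(default_factory=_default_wtr)
    atr: SubgroupSpec = Field(default_factory=_default_atr)
    posterior_axis: TruncNormalSpec = TruncNormalSpec(
        mean=90.0, sd=10.0, lo=45.0, hi=135.0, calibrate_mean=False
    )
    mean_k_d: TruncNormalSpec = TruncNormalSpec(
        mean=43.5, sd=1.4, lo=40.0, hi=47.0, calibrate_mean=False
    )
    posterior_mean_radius_mm: TruncNormalSpec = TruncNormalSpec(
        mean=6.35, sd=0.25, lo=5.60, hi=7.10, calibrate_mean=False
    )
    axial_length_mm: TruncNormalSpec = TruncNormalSpec(mean=23.98, sd=0.97, lo=22.01, hi=25.57)
    acd_mm: TruncNormalSpec = TruncNormalSpec(mean=2.80, sd=0.42, lo=1.91, hi=3.42)
    cct_um: TruncNormalSpec = TruncNormalSpec(
        mean=550.0, sd=35.0, lo=480.0, hi=620.0, calibrate_mean=False
    )
    iol_sphere_d: TruncNormalSpec = TruncNormalSpec(mean=19.4, sd=3.8, lo=15.5, hi=25.5)
    sica_magnitude_d: TruncNormalSpec = TruncNormalSpec(mean=0.50, sd=0.25, lo=0.0, hi=1.50)
    sica_axis_jitter_sd_deg: float = Field(30.0, ge=0)
    incision_meridian_deg: float = 180.0
    assumed_sica_d: float = 0.50
    alignment_error_sd_deg: float = Field(3.0, ge=0)
    preop_se_mean_d: float = -0.50
    preop_se_sd_d: float = Field(1.50, ge=0)
    postop_se_mean_d: float = -0.20
    postop_se_sd_d: float = Field(0.25, ge=0)
    toricity_steps_d: list[float] = Field(
        default_factory=lambda: [1.0 + 0.5 * i for i in range(14)]
    )
    quantize_manifest: bool = False
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)

    def noise_free(self) -> "CohortConfig":
        """Copy with every noise/error channel silenced.

        Device and refraction noise, IOL alignment error, and the SICA
        magnitude/axis dispersion are zeroed; biological heterogeneity
        (astigmatism magnitudes, axes, biometry) is retained.
        """
        out = self.model_copy(deep=True)
        out.noise = NoiseConfig(
            iolmaster_sd_d=0, simk_sd_d=0, wavefront_sd_d=0,
            radius_sd_mm=0, manifest_cyl_sd_d=0, manifest_sphere_sd_d=0,
        )
        out.alignment_error_sd_deg = 0.0
        out.sica_axis_jitter_sd_deg = 0.0
        out.sica_magnitude_d = TruncNormalSpec(
            mean=self.sica_magnitude_d.mean, sd=0.0,
            lo=self.sica_magnitude_d.lo, hi=self.sica_magnitude_d.hi,
        )
        out.postop_se_sd_d = 0.0
        out.preop_se_sd_d = 0.0
        out.quantize_manifest = False
        return out

    def analysis_config(self) -> AnalysisConfig:
        """Analysis configuration sharing this cohort's optical constants."""
        return AnalysisConfig(optics=self.optics.model_copy(deep=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        return cls.model_validate(_load_mapping(path))

    def sha256(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def select_toricity(
    predicted: Astigmatism,
    iol_sphere_d: float,
    ctx: VergenceContext,
    cfg: CohortConfig,
) -> tuple[float, float]:
    """Choose the IOL toricity step and intended axis for one eye.

    The corneal-plane target is the predicted astigmatism minus the
    surgeon-assumed SICA expressed at the incision meridian; the available
    step whose corneal-plane equivalent is nearest the target magnitude is
    chosen (ties break toward the lower toricity).  Returns
    ``(iol_toric_cyl_d, intended_axis_deg)``.
    """
    if not cfg.toricity_steps_d:
        raise ValueError("toricity step list is empty")
    target = vec_sub(predicted, Astigmatism(cfg.assumed_sica_d, cfg.incision_meridian_deg))
    best_step, best_dist = None, None
    for step in sorted(cfg.toricity_steps_d):
        dist = abs(iol_cyl_to_corneal(step, iol_sphere_d, ctx) - target.magnitude)
        if best_dist is None or dist < best_dist:
            best_step, best_dist = step, dist
    return float(best_step), target.axis


# ---------------------------------------------------------------------------

def _anterior_radii(mean_k: float, mag: float, optics: OpticsConfig) -> tuple[float, float]:
    """Radii (steep, flat) whose true-surface astigmatism equals ``mag``."""
    scale = (optics.n_cornea - optics.n_air) / (optics.keratometric_index - optics.n_air)
    p_mean = mean_k * scale
    dn = (optics.n_cornea - optics.n_air) * 1000.0
    return dn / (p_mean + mag / 2.0), dn / (p_mean - mag / 2.0)


def _posterior_radii(mean_radius: float, mag: float, optics: OpticsConfig) -> tuple[float, float]:
    """Radii (steep, flat) whose posterior surface effect magnitude is ``mag``."""
    dn = (optics.n_cornea - optics.n_aqueous) * 1000.0  # positive, e.g. 40
    p_abs_mean = dn / mean_radius
    return dn / (p_abs_mean + mag / 2.0), dn / (p_abs_mean - mag / 2.0)


def _noisy_surface(r_steep: float, r_flat: float, axis: float, e1: float, e2: float):
    rs, rf = r_steep + e1, r_flat + e2
    if rs <= rf:
        return rs, rf, axis % 180.0
    return rf, rs, (axis + 90.0) % 180.0


def _spectacle_manifest(
    se_corneal: float,
    cyl_vec: Astigmatism,
    vertex_mm: float,
    noise_xy: tuple[float, float],
    noise_sphere: float,
    quantize: bool,
) -> tuple[float, float, float]:
    """Corneal-plane SE + cylinder vector → (possibly noisy) spectacle Rx.

    Minus-cylinder convention: the steep corneal meridian carries the more
    negative refraction, so the cylinder axis is ``steep − 90``.
    """
    mag = cyl_vec.magnitude
    sphere_c = se_corneal + mag / 2.0
    cyl_c = -mag
    axis_c = (cyl_vec.axis - 90.0) % 180.0
    s, c, a = refraction_to_spectacle_plane(sphere_c, cyl_c, axis_c, vertex_mm)
    # perturb at the spectacle plane: SE and double-angle cylinder components
    se_spec = s + c / 2.0
    dv = to_double_angle(Astigmatism(-c, a + 90.0))
    noisy = from_double_angle((dv.x + noise_xy[0], dv.y + noise_xy[1]))
    se_spec += noise_sphere
    mag_n = noisy.magnitude
    s_n = se_spec + mag_n / 2.0
    c_n = -mag_n
    a_n = (noisy.axis - 90.0) % 180.0
    if quantize:
        s_n = round(s_n * 4.0) / 4.0
        c_n = round(c_n * 4.0) / 4.0
        a_n = (round(a_n / 5.0) * 5.0) % 180.0
    return s_n, c_n, a_n


def generate_cohort(
    cfg: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(cohort_df, truth_df)``; deterministic given the seed.

    ``cohort_df`` follows the eye-record CSV schema
    (:data:`toricpred.io.COLUMN_DICTIONARY`); ``truth_df`` carries the
    parallel per-eye truth (true astigmatism vectors, true SICA, true
    postoperative composition) used by closure tests.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_eyes
    noise = cfg.noise
    optics = cfg.optics

    is_wtr = rng.random(n) < cfg.wtr_fraction

    def per_subgroup(attr: str) -> np.ndarray:
        w = sample_truncnorm(getattr(cfg.wtr, attr), rng, n)
        a = sample_truncnorm(getattr(cfg.atr, attr), rng, n)
        return np.where(is_wtr, w, a)

    ant_mag = per_subgroup("anterior_mag")
    ant_axis = per_subgroup("anterior_axis") % 180.0
    post_mag = per_subgroup("posterior_mag")
    post_axis = sample_truncnorm(cfg.posterior_axis, rng, n) % 180.0

    mean_k = sample_truncnorm(cfg.mean_k_d, rng, n)
    post_mean_r = sample_truncnorm(cfg.posterior_mean_radius_mm, rng, n)
    al = sample_truncnorm(cfg.axial_length_mm, rng, n)
    acd = sample_truncnorm(cfg.acd_mm, rng, n)
    cct = sample_truncnorm(cfg.cct_um, rng, n)
    iol_sphere = sample_truncnorm(cfg.iol_sphere_d, rng, n)

    sica_mag = {tp: sample_truncnorm(cfg.sica_magnitude_d, rng, n) for tp in ("1m", "3m")}
    sica_jit = {tp: rng.normal(0.0, cfg.sica_axis_jitter_sd_deg, n) for tp in ("1m", "3m")}
    align_err = {tp: rng.normal(0.0, cfg.alignment_error_sd_deg, n) for tp in ("1m", "3m")}
    se_pre = rng.normal(cfg.preop_se_mean_d, cfg.preop_se_sd_d, n)
    se_post = {tp: rng.normal(cfg.postop_se_mean_d, cfg.postop_se_sd_d, n) for tp in ("1m", "3m")}

    dev_noise = {
        name: rng.normal(0.0, sd, (n, 2))
        for name, sd in (
            ("iolmaster", noise.iolmaster_sd_d),
            ("simk", noise.simk_sd_d),
            ("wavefront", noise.wavefront_sd_d),
        )
    }
    man_noise = {tp: rng.normal(0.0, noise.manifest_cyl_sd_d, (n, 2)) for tp in ("pre", "1m", "3m")}
    man_s_noise = {tp: rng.normal(0.0, noise.manifest_sphere_sd_d, n) for tp in ("pre", "1m", "3m")}
    radius_noise = rng.normal(0.0, noise.radius_sd_mm, (n, 12))

    k_factor = (optics.keratometric_index - 1.0) * 1000.0
    rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(n):
        A = Astigmatism(float(ant_mag[i]), float(ant_axis[i]))
        post_steep = float(post_axis[i])
        P = Astigmatism(float(post_mag[i]), post_steep + 90.0)  # effect vector
        T = vec_add(A, P)

        ant_rs, ant_rf = _anterior_radii(float(mean_k[i]), A.magnitude, optics)
        post_rs, post_rf = _posterior_radii(float(post_mean_r[i]), P.magnitude, optics)

        # vergence context from the *synthesized* radii, mirroring the
        # pipeline's mean-keratometry computation exactly
        mk = 0.5 * (k_factor / ant_rs + k_factor / ant_rf)
        ctx = VergenceContext(
            vertex_distance_mm=optics.vertex_distance_mm,
            elp_mm=srkt_elp(float(al[i]), mk, optics.a_constant),
            axial_length_mm=float(al[i]),
            mean_k_d=mk,
            a_constant=optics.a_constant,
        )
        step, intended_axis = select_toricity(T, float(iol_sphere[i]), ctx, cfg)
        c_corneal = iol_cyl_to_corneal(step, float(iol_sphere[i]), ctx)

        per_tp: dict[str, dict] = {}
        for j, tp in enumerate(("1m", "3m")):
            s_axis = (cfg.incision_meridian_deg + 90.0 + sica_jit[tp][i]) % 180.0
            S = Astigmatism(float(sica_mag[tp][i]), s_axis)
            observed = (intended_axis + align_err[tp][i]) % 180.0
            ivec = Astigmatism(c_corneal, observed + 90.0)
            postop_cyl = vec_add(vec_add(T, ivec), S)
            A_post = vec_add(A, S)
            apost_rs, apost_rf = _anterior_radii(float(mean_k[i]), A_post.magnitude, optics)
            manifest = _spectacle_manifest(
                float(se_post[tp][i]), postop_cyl, optics.vertex_distance_mm,
                (float(man_noise[tp][i, 0]), float(man_noise[tp][i, 1])),
                float(man_s_noise[tp][i]), cfg.quantize_manifest,
            )
            per_tp[tp] = dict(
                S=S, observed=observed, postop_cyl=postop_cyl, A_post=A_post,
                apost_radii=(apost_rs, apost_rf), manifest=manifest,
            )

        manifest_pre = _spectacle_manifest(
            float(se_pre[i]), T, optics.vertex_distance_mm,
            (float(man_noise["pre"][i, 0]), float(man_noise["pre"][i, 1])),
            float(man_s_noise["pre"][i]), cfg.quantize_manifest,
        )

        def noisy_astig(truth: Astigmatism, channel: str) -> Astigmatism:
            dv = to_double_angle(truth)
            dx, dy = dev_noise[channel][i]
            return from_double_angle((dv.x + dx, dv.y + dy))

        iolm = noisy_astig(A, "iolmaster")
        simk = noisy_astig(A, "simk")
        wavef = noisy_astig(T, "wavefront")

        rn = radius_noise[i]
        a_rs, a_rf, a_ax = _noisy_surface(ant_rs, ant_rf, A.axis, rn[0], rn[1])
        p_rs, p_rf, p_ax = _noisy_surface(post_rs, post_rf, post_steep, rn[2], rn[3])
        s1 = per_tp["1m"]
        s3 = per_tp["3m"]
        a1_rs, a1_rf, a1_ax = _noisy_surface(*s1["apost_radii"], s1["A_post"].axis, rn[4], rn[5])
        p1_rs, p1_rf, p1_ax = _noisy_surface(post_rs, post_rf, post_steep, rn[6], rn[7])
        a3_rs, a3_rf, a3_ax = _noisy_surface(*s3["apost_radii"], s3["A_post"].axis, rn[8], rn[9])
        p3_rs, p3_rf, p3_ax = _noisy_surface(post_rs, post_rf, post_steep, rn[10], rn[11])

        eye_id = f"eye{i:05d}"
        rows.append(
            {
                "eye_id": eye_id,
                "subgroup_axis_deg": iolm.axis,
                "ant_r_steep_mm": a_rs, "ant_r_flat_mm": a_rf, "ant_axis_deg": a_ax,
                "post_r_steep_mm": p_rs, "post_r_flat_mm": p_rf, "post_axis_deg": p_ax,
                "ant_r_steep_1m_mm": a1_rs, "ant_r_flat_1m_mm": a1_rf, "ant_axis_1m_deg": a1_ax,
                "post_r_steep_1m_mm": p1_rs, "post_r_flat_1m_mm": p1_rf, "post_axis_1m_deg": p1_ax,
                "ant_r_steep_3m_mm": a3_rs, "ant_r_flat_3m_mm": a3_rf, "ant_axis_3m_deg": a3_ax,
                "post_r_steep_3m_mm": p3_rs, "post_r_flat_3m_mm": p3_rf, "post_axis_3m_deg": p3_ax,
                "axial_length_mm": al[i], "acd_mm": acd[i], "cct_um": cct[i],
                "iol_sphere_d": iol_sphere[i], "iol_toric_cyl_d": step,
                "intended_axis_deg": intended_axis,
                "observed_axis_1m_deg": s1["observed"],
                "observed_axis_3m_deg": s3["observed"],
                "manifest_pre_sphere_d": manifest_pre[0],
                "manifest_pre_cyl_d": manifest_pre[1],
                "manifest_pre_axis_deg": manifest_pre[2],
                "manifest_1m_sphere_d": s1["manifest"][0],
                "manifest_1m_cyl_d": s1["manifest"][1],
                "manifest_1m_axis_deg": s1["manifest"][2],
                "manifest_3m_sphere_d": s3["manifest"][0],
                "manifest_3m_cyl_d": s3["manifest"][1],
                "manifest_3m_axis_deg": s3["manifest"][2],
                "iolmaster_mag_d": iolm.magnitude, "iolmaster_axis_deg": iolm.axis,
                "simk_mag_d": simk.magnitude, "simk_axis_deg": simk.axis,
                "wavefront_mag_d": wavef.magnitude, "wavefront_axis_deg": wavef.axis,
            }
        )
        truth_rows.append(
            {
                "eye_id": eye_id,
                "subgroup": "WTR" if is_wtr[i] else "ATR",
                "true_anterior_mag_d": A.magnitude, "true_anterior_axis_deg": A.axis,
                "true_posterior_mag_d": P.magnitude, "true_posterior_axis_deg": P.axis,
                "true_total_mag_d": T.magnitude, "true_total_axis_deg": T.axis,
                "iol_corneal_cyl_d": c_corneal,
                "intended_axis_deg": intended_axis,
                "true_sica_1m_mag_d": s1["S"].magnitude, "true_sica_1m_axis_deg": s1["S"].axis,
                "true_sica_3m_mag_d": s3["S"].magnitude, "true_sica_3m_axis_deg": s3["S"].axis,
                "true_postop_cyl_1m_mag_d": s1["postop_cyl"].magnitude,
                "true_postop_cyl_1m_axis_deg": s1["postop_cyl"].axis,
                "true_postop_cyl_3m_mag_d": s3["postop_cyl"].magnitude,
                "true_postop_cyl_3m_axis_deg": s3["postop_cyl"].axis,
                "true_postop_se_1m_d": se_post["1m"][i],
                "true_postop_se_3m_d": se_post["3m"][i],
            }
        )

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
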