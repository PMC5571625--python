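"""The accuracy analysis: SICA, back-calculated preoperative astigmatism,
per-modality prediction error, and per-stratum aggregation.

The estimation chain per eye and timepoint:

1. **SICA** — surgically induced astigmatism change, the double-angle
   difference of the post- and pre-operative two-surface (Vector-modality)
   corneal astigmatisms from the Scheimpflug radii:
   ``SICA = post ⊖ pre``.
2. **Estimated preoperative corneal astigmatism** — inverts the
   composition ``postop manifest cylinder = preop + IOL cylinder (steepest
   meridian, corneal plane, at the observed axis) + SICA``:
   ``estimated = postop ⊖ IOL ⊖ SICA``.  The manifest cylinder is moved to
   the corneal plane by the per-meridian vertex formula; the IOL-plane
   toric cylinder is moved there through the SRK/T + refractive-vergence
   chain.
3. **Prediction error** — per modality, ``measured (or calculated)
   preoperative astigmatism ⊖ estimated preoperative astigmatism``, with
   its signed WTR/ATR and oblique reporting components.
4. **Aggregation** — centroid, component means/SDs, proportions of eyes
   with |error| within thresholds, ICC against the estimated astigmatism,
   and Shapiro-gated one-sample tests with Bonferroni correction, per
   modality × subgroup (WTR/ATR) × timepoint.

Eyes with an oblique preoperative steep meridian are excluded up front;
eyes never change subgroup postoperatively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import ICCEstimate, TestResult, icc_agreement, mean_component_test
from .config import AnalysisConfig
from .double_angle import (
    Astigmatism,
    AxisClass,
    ComponentPair,
    centroid,
    classify_axis,
    components,
    vec_sub,
)
from .modalities import Modality, ModalityEstimate, EyeRecord, compute_modalities
from .optics import (
    VergenceContext,
    iol_cyl_to_corneal,
    spectacle_to_corneal,
    srkt_elp,
    vector_modality,
)

logger = logging.getLogger(__name__)

TIMEPOINTS = ("1M", "3M")


def compute_sica(pre_vector: Astigmatism, post_vector: Astigmatism) -> Astigmatism:
    """Per-case surgically induced astigmatism change: ``post ⊖ pre``."""
    return vec_sub(post_vector, pre_vector)


def estimate_preop(
    postop_manifest_corneal: Astigmatism,
    iol_cyl_corneal: Astigmatism,
    sica: Astigmatism,
) -> Astigmatism:
    """Back-calculate the preoperative corneal astigmatism.

    Exact algebraic inverse of the composition equation: for any triple,
    ``estimate_preop(t ⊕ i ⊕ s, i, s) = t``.
    """
    return vec_sub(vec_sub(postop_manifest_corneal, iol_cyl_corneal), sica)


def prediction_error(
    estimate: ModalityEstimate | Astigmatism, estimated_preop: Astigmatism
) -> tuple[Astigmatism, ComponentPair]:
    """Vector prediction error and its signed reporting components."""
    astig = estimate.astig if isinstance(estimate, ModalityEstimate) else estimate
    err = vec_sub(astig, estimated_preop)
    return err, components(err)


def mean_keratometry(rec: EyeRecord, keratometric_index: float) -> float:
    """Mean keratometric power (D) of the preoperative anterior surface."""
    k = (keratometric_index - 1.0) * 1000.0
    return 0.5 * (k / rec.anterior.r_steep_mm + k / rec.anterior.r_flat_mm)


def vergence_context(rec: EyeRecord, cfg: AnalysisConfig) -> VergenceContext:
    """SRK/T-derived vergence geometry of one pseudophakic eye."""
    mean_k = mean_keratometry(rec, cfg.optics.keratometric_index)
    elp = srkt_elp(rec.axial_length_mm, mean_k, cfg.optics.a_constant)
    return VergenceContext(
        vertex_distance_mm=cfg.optics.vertex_distance_mm,
        elp_mm=elp,
        axial_length_mm=rec.axial_length_mm,
        mean_k_d=mean_k,
        a_constant=cfg.optics.a_constant,
    )


def iol_corneal_vector(rec: EyeRecord, observed_axis_deg: float, cfg: AnalysisConfig) -> Astigmatism:
    """Corneal-plane IOL cylinder vector at the observed alignment.

    An IOL physically aligned at axis ``θ`` adds corrective power along the
    perpendicular meridian, so the vector carries axis ``θ + 90``; its
    magnitude is the corneal-plane equivalent of the IOL-plane toricity.
    """
    c = iol_cyl_to_corneal(rec.iol_toric_cyl_d, rec.iol_sphere_d, vergence_context(rec, cfg))
    return Astigmatism(c, observed_axis_deg + 90.0)


@dataclass
class CaseResult:
    """One eye × timepoint pass through the estimation chain."""

    eye_id: str
    timepoint: str
    subgroup: AxisClass
    sica: Astigmatism
    estimated_preop: Astigmatism
    estimates: dict[Modality, Astigmatism]
    errors: dict[Modality, tuple[Astigmatism, ComponentPair]]


@dataclass
class PredictionErrorSummary:
    modality: Modality
    subgroup: AxisClass
    timepoint: str
    n: int
    centroid: Astigmatism
    mean_abs: float
    mean_wtr_atr: float
    sd_wtr_atr: float
    mean_oblique: float
    sd_oblique: float
    pct_within_050: float
    pct_within_100: float
    icc_wtr_atr: ICCEstimate
    icc_oblique: ICCEstimate
    test_wtr_atr: Optional[TestResult] = None
    test_oblique: Optional[TestResult] = None


@dataclass
class StudyResults:
    per_eye: pd.DataFrame
    summary: pd.DataFrame
    sica: pd.DataFrame
    cases: list[CaseResult] = field(repr=False, default_factory=list)
    summaries: list[PredictionErrorSummary] = field(repr=False, default_factory=list)
    exclusions: list[str] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)


def analyze_case(rec: EyeRecord, timepoint: str, cfg: AnalysisConfig,
                 estimates: Sequence[ModalityEstimate]) -> Optional[CaseResult]:
    """Run the estimation chain for one eye at one timepoint."""
    manifest = rec.manifest_1m if timepoint == "1M" else rec.manifest_3m
    observed = rec.observed_axis_1m_deg if timepoint == "1M" else rec.observed_axis_3m_deg
    ant_post = rec.anterior_post_1m if timepoint == "1M" else rec.anterior_post_3m
    post_post = rec.posterior_post_1m if timepoint == "1M" else rec.posterior_post_3m
    if manifest is None or observed is None or ant_post is None or post_post is None:
        return None

    pre_vec = vector_modality(rec.anterior, rec.posterior, cfg.optics)
    post_vec = vector_modality(ant_post, post_post, cfg.optics)
    sica = compute_sica(pre_vec, post_vec)

    postop_corneal = spectacle_to_corneal(*manifest, cfg.optics.vertex_distance_mm)
    iol_vec = iol_corneal_vector(rec, observed, cfg)
    est_preop = estimate_preop(postop_corneal, iol_vec, sica)

    errors = {e.modality: prediction_error(e, est_preop) for e in estimates}
    return CaseResult(
        eye_id=rec.eye_id,
        timepoint=timepoint,
        subgroup=rec.subgroup,
        sica=sica,
        estimated_preop=est_preop,
        estimates={e.modality: e.astig for e in estimates},
        errors=errors,
    )


def summarize(
    errors: Sequence[tuple[Astigmatism, ComponentPair]],
    modality: Modality,
    subgroup: AxisClass,
    timepoint: str,
    pairs_wtr_atr: Sequence[tuple[float, float]],
    pairs_oblique: Sequence[tuple[float, float]],
    m_comparisons: int,
    cfg: AnalysisConfig,
) -> PredictionErrorSummary:
    """Aggregate one modality × subgroup × timepoint stratum."""
    if not errors:
        raise ValueError("summarize called with no prediction errors")
    vecs = [e for e, _ in errors]
    comps = [c for _, c in errors]
    cent, mean_abs = centroid(vecs)
    mags = np.array([v.magnitude for v in vecs])
    wtr = np.array([c.wtr_atr for c in comps])
    obl = np.array([c.oblique for c in comps])
    lo, hi = cfg.thresholds
    n = len(vecs)
    tests: dict[str, Optional[TestResult]] = {"wtr_atr": None, "oblique": None}
    if n >= 3:
        tests["wtr_atr"] = mean_component_test(wtr, m_comparisons, cfg.alpha)
        tests["oblique"] = mean_component_test(obl, m_comparisons, cfg.alpha)
    return PredictionErrorSummary(
        modality=modality,
        subgroup=subgroup,
        timepoint=timepoint,
        n=n,
        centroid=cent,
        mean_abs=mean_abs,
        mean_wtr_atr=float(wtr.mean()),
        sd_wtr_atr=float(wtr.std(ddof=1)) if n > 1 else 0.0,
        mean_oblique=float(obl.mean()),
        sd_oblique=float(obl.std(ddof=1)) if n > 1 else 0.0,
        pct_within_050=float((mags <= lo).mean() * 100.0),
        pct_within_100=float((mags <= hi).mean() * 100.0),
        icc_wtr_atr=icc_agreement(pairs_wtr_atr),
        icc_oblique=icc_agreement(pairs_oblique),
        test_wtr_atr=tests["wtr_atr"],
        test_oblique=tests["oblique"],
    )


def run_study(cohort: Iterable[EyeRecord], cfg: AnalysisConfig | None = None) -> StudyResults:
    """End-to-end accuracy analysis over a cohort of eye records.

    Oblique-steep-meridian eyes are excluded; per-eye validation failures
    are collected and the run continues on the remaining eyes.  The result
    is deterministic given the cohort and configuration.
    """
    cfg = cfg or AnalysisConfig()
    cases: list[CaseResult] = []
    exclusions: list[str] = []
    failures: list[str] = []

    for rec in cohort:
        subgroup = rec.subgroup
        if subgroup is AxisClass.OBLIQUE:
            exclusions.append(
                f"eye {rec.eye_id}: oblique preoperative steep meridian "
                f"({rec.subgroup_axis_deg:.1f} deg) excluded"
            )
            continue
        try:
            estimates = compute_modalities(rec, cfg)
            for tp in TIMEPOINTS:
                case = analyze_case(rec, tp, cfg, estimates)
                if case is not None:
                    cases.append(case)
        except Exception as exc:  # pragma: no cover - defensive per-eye guard
            failures.append(f"eye {rec.eye_id}: {exc}")
            logger.warning("eye %s failed: %s", rec.eye_id, exc)

    summaries: list[PredictionErrorSummary] = []
    for subgroup in (AxisClass.WTR, AxisClass.ATR):
        for tp in TIMEPOINTS:
            stratum = [c for c in cases if c.subgroup is subgroup and c.timepoint == tp]
            if not stratum:
                continue
            modalities = sorted(
                {m for c in stratum for m in c.errors}, key=lambda m: list(Modality).index(m)
            )
            m_comp = len(modalities)
            for modality in modalities:
                sub = [c for c in stratum if modality in c.errors]
                errs = [c.errors[modality] for c in sub]
                pw = [(components(c.estimated_preop).wtr_atr,
                       components(c.estimates[modality]).wtr_atr) for c in sub]
                po = [(components(c.estimated_preop).oblique,
                       components(c.estimates[modality]).oblique) for c in sub]
                summaries.append(
                    summarize(errs, modality, subgroup, tp, pw, po, m_comp, cfg)
                )

    return StudyResults(
        per_eye=per_eye_frame(cases),
        summary=summary_frame(summaries),
        sica=sica_frame(cases),
        cases=cases,
        summaries=summaries,
        exclusions=exclusions,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Tidy frames.

def per_eye_frame(cases: Sequence[CaseResult]) -> pd.DataFrame:
    rows = []
    for c in cases:
        for modality, (err, comp) in c.errors.items():
            est = c.estimates[modality]
            rows.append(
                {
                    "eye_id": c.eye_id,
                    "subgroup": c.subgroup.value,
                    "timepoint": c.timepoint,
                    "modality": modality.value,
                    "estimate_mag_d": est.magnitude,
                    "estimate_axis_deg": est.axis,
                    "estimated_preop_mag_d": c.estimated_preop.magnitude,
                    "estimated_preop_axis_deg": c.estimated_preop.axis,
                    "sica_mag_d": c.sica.magnitude,
                    "sica_axis_deg": c.sica.axis,
                    "error_mag_d": err.magnitude,
                    "error_axis_deg": err.axis,
                    "error_wtr_atr_d": comp.wtr_atr,
                    "error_oblique_d": comp.oblique,
                }
            )
    return pd.DataFrame(rows)


def sica_frame(cases: Sequence[CaseResult]) -> pd.DataFrame:
    seen: dict[tuple[str, str], CaseResult] = {}
    for c in cases:
        seen.setdefault((c.eye_id, c.timepoint), c)
    rows = []
    for subgroup in (AxisClass.WTR, AxisClass.ATR):
        for tp in TIMEPOINTS:
            sel = [c.sica for c in seen.values() if c.subgroup is subgroup and c.timepoint == tp]
            if not sel:
                continue
            cent, mean_abs = centroid(sel)
            mags = [s.magnitude for s in sel]
            rows.append(
                {
                    "subgroup": subgroup.value,
                    "timepoint": tp,
                    "n": len(sel),
                    "sica_centroid_mag_d": cent.magnitude,
                    "sica_centroid_axis_deg": cent.axis,
                    "sica_mean_abs_d": mean_abs,
                    "sica_sd_abs_d": float(np.std(mags, ddof=1)) if len(mags) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def summary_frame(summaries: Sequence[PredictionErrorSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "modality": s.modality.value,
                "subgroup": s.subgroup.value,
                "timepoint": s.timepoint,
                "n": s.n,
                "centroid_mag_d": s.centroid.magnitude,
                "centroid_axis_deg": s.centroid.axis,
                "mean_abs_error_d": s.mean_abs,
                "mean_wtr_atr_d": s.mean_wtr_atr,
                "sd_wtr_atr_d": s.sd_wtr_atr,
                "mean_oblique_d": s.mean_oblique,
                "sd_oblique_d": s.sd_oblique,
                "pct_within_050": s.pct_within_050,
                "pct_within_100": s.pct_within_100,
                "icc_wtr_atr": np.nan if s.icc_wtr_atr.value is None else s.icc_wtr_atr.value,
                "icc_oblique": np.nan if s.icc_oblique.value is None else s.icc_oblique.value,
                "icc_variant": "ICC(A,1) two-way single-measures absolute agreement",
                "p_adj_wtr_atr": np.nan if s.test_wtr_atr is None else s.test_wtr_atr.adjusted_p,
                "sig_wtr_atr": None if s.test_wtr_atr is None else s.test_wtr_atr.significant,
                "test_wtr_atr": None if s.test_wtr_atr is None else s.test_wtr_atr.test_used,
                "p_adj_oblique": np.nan if s.test_oblique is None else s.test_oblique.adjusted_p,
                "sig_oblique": None if s.test_oblique is None else s.test_oblique.significant,
                "test_oblique": None if s.test_oblique is None else s.test_oblique.test_used,
            }
        )
    return pd.DataFrame(rows)
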