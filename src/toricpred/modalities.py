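"""Per-eye preoperative corneal astigmatism under the ten named modalities.

Three families of modalities are produced from one :class:`EyeRecord`:

* **anterior-only device readings** — IOLMaster and Pentacam SimK, plus the
  Pentacam corneal wavefront (all pass-throughs of device columns);
* **adjusted values** — the Baylor nomogram applied to IOLMaster or SimK,
  and the Barrett toric calculator outputs (proprietary: accepted only as
  pass-through columns with provenance ``external``);
* **two-surface computations** — true net power (TNP), total corneal
  refractive power (TCP) and the Alpins vector sum, computed from the
  Pentacam anterior/posterior radii and pachymetry by
  :mod:`toricpred.optics`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .config import AnalysisConfig, NomogramTable
from .double_angle import Astigmatism, AxisClass, classify_axis
from .optics import SurfaceGeometry, tcp, tnp, vector_modality

logger = logging.getLogger(__name__)


class Modality(str, Enum):
    IOLMASTER = "IOLMaster"
    SIMK = "SimK"
    BAYLOR_IOLMASTER = "Baylor-IOLMaster"
    BAYLOR_SIMK = "Baylor-SimK"
    BARRETT_IOLMASTER = "Barrett-IOLMaster"
    BARRETT_SIMK = "Barrett-SimK"
    WAVEFRONT = "Wavefront"
    TNP = "TNP"
    TCP = "TCP"
    VECTOR = "Vector"


#: modality whose reading emulates the full (two-surface) corneal astigmatism
TOTAL_CORNEAL_MODALITIES = (Modality.WAVEFRONT, Modality.TNP, Modality.TCP, Modality.VECTOR)
#: anterior-surface-only device modalities
ANTERIOR_ONLY_MODALITIES = (Modality.IOLMASTER, Modality.SIMK)


@dataclass
class EyeRecord:
    """One eye's biometry, device measurements, surgery and follow-up."""

    eye_id: str
    subgroup_axis_deg: float
    anterior: SurfaceGeometry
    posterior: SurfaceGeometry
    anterior_post_1m: Optional[SurfaceGeometry]
    posterior_post_1m: Optional[SurfaceGeometry]
    anterior_post_3m: Optional[SurfaceGeometry]
    posterior_post_3m: Optional[SurfaceGeometry]
    axial_length_mm: float
    acd_mm: float
    cct_um: Optional[float]
    iol_sphere_d: float
    iol_toric_cyl_d: float
    intended_axis_deg: float
    observed_axis_1m_deg: Optional[float]
    observed_axis_3m_deg: Optional[float]
    manifest_pre: Optional[tuple[float, float, float]]
    manifest_1m: Optional[tuple[float, float, float]]
    manifest_3m: Optional[tuple[float, float, float]]
    device_iolmaster: Optional[Astigmatism]
    device_simk: Optional[Astigmatism]
    device_wavefront: Optional[Astigmatism]
    barrett_iolmaster: Optional[Astigmatism] = None
    barrett_simk: Optional[Astigmatism] = None

    @property
    def subgroup(self) -> AxisClass:
        return classify_axis(self.subgroup_axis_deg)


@dataclass(frozen=True)
class ModalityEstimate:
    eye_id: str
    modality: Modality
    astig: Astigmatism
    provenance: str = "computed"  # "device", "computed" or "external"


def baylor_adjust(measured: Astigmatism, table: NomogramTable) -> Astigmatism:
    """Apply a toric-nomogram adjustment to an anterior keratometric reading.

    The row is selected by the measured steep-meridian class (WTR rows
    reduce the effective magnitude, ATR rows increase it) and the magnitude
    interval.  Oblique axes are outside the nomogram's domain and raise.
    The adjusted value keeps the measured axis (``axis_rule = "keep"``).
    """
    klass = classify_axis(measured.axis)
    row = table.row_for(klass, measured.magnitude)  # raises for OBLIQUE / gaps
    adjusted = row.adjust(measured.magnitude)
    return Astigmatism(adjusted, measured.axis if adjusted > 0 else 0.0)


def compute_modalities(rec: EyeRecord, cfg: AnalysisConfig | None = None) -> list[ModalityEstimate]:
    """All available preoperative-astigmatism modalities for one eye.

    Modalities whose inputs are missing are omitted with a logged notice;
    a failure in one modality never suppresses the others.
    """
    cfg = cfg or AnalysisConfig()
    out: list[ModalityEstimate] = []

    def emit(modality: Modality, astig: Optional[Astigmatism], provenance: str) -> None:
        if astig is None:
            logger.info("eye %s: %s omitted (input not present)", rec.eye_id, modality.value)
            return
        out.append(ModalityEstimate(rec.eye_id, modality, astig, provenance))

    emit(Modality.IOLMASTER, rec.device_iolmaster, "device")
    emit(Modality.SIMK, rec.device_simk, "device")
    emit(Modality.WAVEFRONT, rec.device_wavefront, "device")

    for modality, source in (
        (Modality.BAYLOR_IOLMASTER, rec.device_iolmaster),
        (Modality.BAYLOR_SIMK, rec.device_simk),
    ):
        if source is None:
            logger.info("eye %s: %s omitted (no source reading)", rec.eye_id, modality.value)
            continue
        try:
            out.append(ModalityEstimate(rec.eye_id, modality, baylor_adjust(source, cfg.nomogram)))
        except ValueError as exc:
            logger.warning("eye %s: %s failed: %s", rec.eye_id, modality.value, exc)

    emit(Modality.BARRETT_IOLMASTER, rec.barrett_iolmaster, "external")
    emit(Modality.BARRETT_SIMK, rec.barrett_simk, "external")

    cct = rec.cct_um if rec.cct_um is not None else cfg.optics.default_cct_um
    if rec.cct_um is None:
        logger.info("eye %s: pachymetry missing, using default CCT %.0f µm",
                    rec.eye_id, cfg.optics.default_cct_um)
    for modality, fn in (
        (Modality.TNP, lambda: tnp(rec.anterior, rec.posterior, cct, cfg.optics)),
        (Modality.TCP, lambda: tcp(rec.anterior, rec.posterior, cct, cfg=cfg.optics)),
        (Modality.VECTOR, lambda: vector_modality(rec.anterior, rec.posterior, cfg.optics)),
    ):
        try:
            out.append(ModalityEstimate(rec.eye_id, modality, fn()))
        except ValueError as exc:
            logger.warning("eye %s: %s failed: %s", rec.eye_id, modality.value, exc)

    return out
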