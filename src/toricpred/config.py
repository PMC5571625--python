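"""Run configuration: optical constants, vergence context, nomogram tables.

Everything a clinician-configurable run needs lives here as pydantic models
so that YAML/JSON config files validate loudly.  Defaults follow the usual
conventions of keratometry and IOL-power work:

* SimK keratometric index 1.3375 (the fictitious single-surface index);
* physical indices 1.376 (stroma) and 1.336 (aqueous) for true anterior and
  posterior surface powers;
* vertex distance 12 mm for spectacle↔corneal-plane conversion;
* SRK/T effective lens position from a configurable A-constant.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .double_angle import Astigmatism, AxisClass, classify_axis


class OpticsConfig(BaseModel):
    """Optical constants for the corneal-power modalities."""

    n_air: float = 1.0
    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    keratometric_index: float = 1.3375  # SimK fictitious index
    vertex_distance_mm: float = 12.0
    default_cct_um: float = 550.0  # used when a record omits pachymetry
    tcp_zone_mm: float = 4.0
    tcp_n_heights: int = 50  # ray heights per semi-meridian
    meridian_step_deg: float = 1.0  # grid for meridional-profile combination
    a_constant: float = 118.5  # SRK/T A-constant of the implanted IOL line


class NomogramRow(BaseModel):
    """One magnitude interval ``[lo, hi)`` of a nomogram class row.

    The adjusted effective astigmatism is ``magnitude + offset`` (or ``set``
    when given), floored at ``floor``.
    """

    lo: float = 0.0
    hi: Optional[float] = None  # None = open-ended
    offset: float = 0.0
    set: Optional[float] = None
    floor: float = 0.0

    def contains(self, magnitude: float) -> bool:
        return magnitude >= self.lo and (self.hi is None or magnitude < self.hi)

    def adjust(self, magnitude: float) -> float:
        out = self.set if self.set is not None else magnitude + self.offset
        return max(out, self.floor)


class NomogramTable(BaseModel):
    """Toric-nomogram lookup adjusting anterior keratometric astigmatism.

    Compensates the population-mean posterior astigmatism that anterior-only
    keratometry cannot see: with-the-rule readings are reduced,
    against-the-rule readings increased.  The published nomogram cells are a
    third-party table; the default shipped here is an approximate ±0.7 D
    rule and real analyses should supply their own table file.

    ``axis_rule`` currently supports only ``"keep"`` (adjusted value keeps
    the measured steep axis).
    """

    wtr: list[NomogramRow] = Field(default_factory=lambda: [NomogramRow(offset=-0.7)])
    atr: list[NomogramRow] = Field(default_factory=lambda: [NomogramRow(offset=+0.7)])
    axis_rule: Literal["keep"] = "keep"

    @model_validator(mode="after")
    def _validate_rows(self) -> "NomogramTable":
        for name, rows in (("wtr", self.wtr), ("atr", self.atr)):
            ordered = sorted(rows, key=lambda r: r.lo)
            for prev, nxt in zip(ordered, ordered[1:]):
                if prev.hi is None or nxt.lo < prev.hi:
                    raise ValueError(f"nomogram {name} rows overlap or are unordered")
        return self

    def row_for(self, axis_class: AxisClass, magnitude: float) -> NomogramRow:
        if axis_class is AxisClass.WTR:
            rows = self.wtr
        elif axis_class is AxisClass.ATR:
            rows = self.atr
        else:
            raise ValueError("nomogram is undefined for oblique astigmatism")
        for row in rows:
            if row.contains(magnitude):
                return row
        raise ValueError(
            f"nomogram {axis_class.value} rows do not cover magnitude {magnitude:.2f} D"
        )


def identity_nomogram() -> NomogramTable:
    """A nomogram that returns every measurement unchanged (for testing)."""
    return NomogramTable(wtr=[NomogramRow()], atr=[NomogramRow()])


class AnalysisConfig(BaseModel):
    """Configuration of the accuracy-analysis pipeline."""

    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    nomogram: NomogramTable = Field(default_factory=NomogramTable)
    #: thresholds (D) for the within-|error| proportions
    thresholds: tuple[float, float] = (0.5, 1.0)
    #: significance level for normality gating and hypothesis tests
    alpha: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.model_validate(_load_mapping(path))

    def sha256(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _load_mapping(path: str | Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def baylor_axis_class(astig: Astigmatism) -> AxisClass:
    """Axis class used for nomogram row selection."""
    return classify_axis(astig.axis)
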