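"""Per-sample MRD key metrics: tumor load, limit of detection, limit of quantification.

Every bone-marrow sample carries its own detection and quantification
limits because both scale inversely with the number of cells (NGS: cell
equivalents from DNA input) or nucleated events (MFC: flow cytometry)
actually assayed.  The assay-specific numerator constants are:

* NGS: LOD = 1.9 / cells, LOQ = 2.39 / cells.  The 1.9 corresponds to a
  5% risk of falsely claiming absence of disease under Poisson sampling;
  2.39 is the experimentally determined quantification factor (70% total
  error).
* MFC: LOD = 30 / events, LOQ = 50 / events, per the consensus guidelines
  on plasma-cell myeloma MRD analysis and reporting.

Tumor load (TL) is simply the detected clonal-sequence or
aberrant-plasma-cell count divided by the cells assayed.  All values are
unitless fractions in [0, 1]; "per million" scaling is presentation only.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Assay",
    "AssayMeasurement",
    "AssayConstants",
    "MRDKeyMetrics",
    "compute_lod",
    "compute_loq",
    "compute_tl",
    "compute_metrics",
    "format_per_million",
    "round_sig",
    "ValidationError",
    "DEFAULT_CONSTANTS",
]


class Assay(str, enum.Enum):
    """MRD measurement technology."""

    NGS = "NGS"
    MFC = "MFC"


class ValidationError(ValueError):
    """Raised when a measurement or configuration violates its invariants."""


@dataclass(frozen=True)
class AssayMeasurement:
    """One raw per-sample, per-assay observation.

    Parameters
    ----------
    patient_id
        Opaque identifier; never interpreted.
    assay
        ``Assay.NGS`` (immunosequencing of Ig rearrangements) or
        ``Assay.MFC`` (multicolor flow cytometry).
    cells_assayed
        NGS: number of cell equivalents derived from DNA input.
        MFC: total nucleated events acquired.  Must be >= 1.
    tumor_count
        NGS: clonal sequence count.  MFC: aberrant plasma-cell events.
        Zero is a legitimate value (no clone detected), not missing data.
    tumor_load_override
        Optional directly-reported TL fraction, used when a source reports
        TL rather than raw counts.  Takes precedence over the count ratio.
    """

    patient_id: str
    assay: Assay
    cells_assayed: int
    tumor_count: Optional[int] = None
    tumor_load_override: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        if self.cells_assayed < 1:
            raise ValidationError(
                f"cells_assayed must be >= 1, got {self.cells_assayed}"
            )
        if self.tumor_count is None and self.tumor_load_override is None:
            raise ValidationError(
                "measurement needs tumor_count or tumor_load_override"
            )
        if self.tumor_count is not None:
            if self.tumor_count < 0:
                raise ValidationError(
                    f"tumor_count must be >= 0, got {self.tumor_count}"
                )
            if self.tumor_count > self.cells_assayed:
                raise ValidationError(
                    f"tumor_count ({self.tumor_count}) exceeds cells_assayed "
                    f"({self.cells_assayed})"
                )
        if self.tumor_load_override is not None and not (
            0.0 <= self.tumor_load_override <= 1.0
        ):
            raise ValidationError(
                f"tumor_load_override must lie in [0, 1], got "
                f"{self.tumor_load_override}"
            )


@dataclass(frozen=True)
class AssayConstants:
    """Numerator constants of the per-sample limit formulas.

    Defaults are the published values; ``ngs_lod_factor`` /
    ``ngs_loq_factor`` are exposed so that a laboratory applying a
    rearrangement-uniqueness correction can supply adjusted multipliers.
    """

    ngs_lod_factor: float = 1.9
    ngs_loq_factor: float = 2.39
    mfc_lod_events: float = 30.0
    mfc_loq_events: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "ngs_lod_factor",
            "ngs_loq_factor",
            "mfc_lod_events",
            "mfc_loq_events",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.ngs_loq_factor < self.ngs_lod_factor:
            raise ValidationError("NGS LOQ factor must be >= LOD factor")
        if self.mfc_loq_events < self.mfc_lod_events:
            raise ValidationError("MFC LOQ factor must be >= LOD factor")

    def lod_factor(self, assay: Assay) -> float:
        return self.ngs_lod_factor if assay is Assay.NGS else self.mfc_lod_events

    def loq_factor(self, assay: Assay) -> float:
        return self.ngs_loq_factor if assay is Assay.NGS else self.mfc_loq_events


DEFAULT_CONSTANTS = AssayConstants()


@dataclass(frozen=True)
class MRDKeyMetrics:
    """TL/LOD/LOQ triple for one measurement (unitless fractions)."""

    tumor_load: float
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_load <= 1.0):
            raise ValidationError(f"tumor_load out of [0,1]: {self.tumor_load}")
        if not (0.0 < self.lod <= self.loq <= 1.0):
            raise ValidationError(
                f"need 0 < lod <= loq <= 1, got lod={self.lod}, loq={self.loq}"
            )


def _limit(cells_assayed: int, factor: float) -> float:
    # Limits above 1 can only arise for pathologically tiny samples
    # (e.g. < 30 MFC events); clamp since a fraction cannot exceed 1.
    value = factor / cells_assayed
    if value > 1.0:
        logger.warning(
            "limit %g/%d = %g exceeds 1; clamping", factor, cells_assayed, value
        )
        return 1.0
    return value


def compute_lod(m: AssayMeasurement, c: AssayConstants = DEFAULT_CONSTANTS) -> float:
    """Per-sample limit of detection: lod_factor(assay) / cells_assayed."""
    return _limit(m.cells_assayed, c.lod_factor(m.assay))


def compute_loq(m: AssayMeasurement, c: AssayConstants = DEFAULT_CONSTANTS) -> float:
    """Per-sample limit of quantification: loq_factor(assay) / cells_assayed."""
    return _limit(m.cells_assayed, c.loq_factor(m.assay))


def compute_tl(m: AssayMeasurement) -> float:
    """Tumor load: tumor_count / cells_assayed, or the reported override."""
    if m.tumor_load_override is not None:
        return m.tumor_load_override
    assert m.tumor_count is not None  # enforced by AssayMeasurement
    return m.tumor_count / m.cells_assayed


def compute_metrics(
    m: AssayMeasurement, c: AssayConstants = DEFAULT_CONSTANTS
) -> MRDKeyMetrics:
    """Bundle TL, LOD and LOQ for one measurement."""
    return MRDKeyMetrics(
        tumor_load=compute_tl(m), lod=compute_lod(m, c), loq=compute_loq(m, c)
    )


def format_per_million(fraction: float, digits: int = 2) -> str:
    """Render a fraction in the field's exponential notation, e.g. '1.7e-06'.

    Rounds to ``digits`` significant figures.  Zero renders as '0'.
    """
    if fraction == 0:
        return "0"
    exponent = math.floor(math.log10(abs(fraction)))
    mantissa = round(fraction / 10**exponent, digits - 1)
    if abs(mantissa) >= 10:  # rounding pushed the mantissa over a decade
        mantissa /= 10
        exponent += 1
    return f"{mantissa:g}e{exponent:+03d}"


def round_sig(value: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, digits - 1 - exponent)
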