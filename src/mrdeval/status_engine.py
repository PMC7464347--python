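"""MRD status decision engine.

Given a sample's key metrics (TL, LOD, LOQ) and a study-wide MRD cut-off,
the engine assigns exactly one of six rules:

* B1 branch — TL at or above the cut-off:
    * B1a: TL >= LOD and TL >= LOQ  -> positive, TL quantifiable
    * B1b: TL >= LOD and TL <  LOQ  -> positive, TL not quantifiable
    * B1c: TL <  LOD                -> nonassessable (only reachable when
      LOD > cut-off, since TL >= cut-off)
* B2 branch — TL below the cut-off:
    * B2a/B2b: LOD <= cut-off       -> negative (a/b split mirrors the
      TL-vs-LOQ position, recorded for audit only)
    * B2c: LOD >  cut-off           -> nonassessable; the sample cannot
      demonstrate negativity at a cut-off its own LOD undercuts

Tie-breaking is inclusive on the favorable side: TL equal to the cut-off
is positive-branch, LOD equal to the cut-off is assessable, TL equal to
LOQ is quantifiable.  Comparisons use a relative tolerance of 1e-9 so
that quotients such as 30/3e6 compare cleanly against literal cut-offs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .core_metrics import (
    AssayConstants,
    AssayMeasurement,
    DEFAULT_CONSTANTS,
    MRDKeyMetrics,
    ValidationError,
    compute_metrics,
)

__all__ = [
    "MRDStatus",
    "TLQuantifiability",
    "Rule",
    "MRDCutoff",
    "MRDCall",
    "PRESET_CUTOFFS",
    "assign_status",
    "assess_tl_statement",
    "call_sample",
]

#: Relative tolerance for boundary comparisons between metrics and cut-offs.
REL_TOL = 1e-9


class MRDStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONASSESSABLE = "nonassessable"


class TLQuantifiability(str, enum.Enum):
    QUANTIFIABLE = "quantifiable"
    NONQUANTIFIABLE = "nonquantifiable"
    NOT_APPLICABLE = "not_applicable"


class Rule(str, enum.Enum):
    B1a = "B1a"
    B1b = "B1b"
    B1c = "B1c"
    B2a = "B2a"
    B2b = "B2b"
    B2c = "B2c"


@dataclass(frozen=True)
class MRDCutoff:
    """A study-wide tumor-load threshold, e.g. 1e-5."""

    value: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise ValidationError(f"cut-off must lie in (0, 1], got {self.value}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.value:g}")


#: The consensus / EMA cut-offs evaluated in the cut-off sweep.
PRESET_CUTOFFS = (
    MRDCutoff(1e-4),
    MRDCutoff(2e-5),
    MRDCutoff(1e-5),
    MRDCutoff(1e-6),
)


@dataclass(frozen=True)
class MRDCall:
    """Outcome of the decision algorithm for one measurement at one cut-off."""

    status: MRDStatus
    tl_quantifiable: TLQuantifiability
    rule_fired: Rule
    cutoff: MRDCutoff
    metrics: MRDKeyMetrics
    patient_id: Optional[str] = None
    assay: Optional[str] = None

    def __post_init__(self) -> None:
        applicable = self.status is MRDStatus.POSITIVE
        if applicable == (self.tl_quantifiable is TLQuantifiability.NOT_APPLICABLE):
            raise ValidationError(
                "tl_quantifiable must be not_applicable exactly for "
                "non-positive calls"
            )


def _ge(a: float, b: float) -> bool:
    """a >= b, with ties resolved by relative tolerance."""
    return a >= b or math.isclose(a, b, rel_tol=REL_TOL)


def assign_status(metrics: MRDKeyMetrics, cutoff: MRDCutoff) -> MRDCall:
    """Assign MRD status (first decision step).

    The returned call has ``tl_quantifiable`` already filled in via
    :func:`assess_tl_statement`, so exactly one of the six rules fires.
    """
    tl, lod = metrics.tumor_load, metrics.lod
    if _ge(tl, cutoff.value):  # B1: TL above cut-off
        if _ge(tl, lod):
            status = MRDStatus.POSITIVE
            rule = Rule.B1a if _ge(tl, metrics.loq) else Rule.B1b
        else:
            status, rule = MRDStatus.NONASSESSABLE, Rule.B1c
    else:  # B2: TL below cut-off
        if _ge(cutoff.value, lod):
            status = MRDStatus.NEGATIVE
            rule = Rule.B2a if _ge(tl, metrics.loq) else Rule.B2b
        else:
            status, rule = MRDStatus.NONASSESSABLE, Rule.B2c
    call = MRDCall(
        status=status,
        tl_quantifiable=TLQuantifiability.NOT_APPLICABLE
        if status is not MRDStatus.POSITIVE
        else TLQuantifiability.QUANTIFIABLE,  # provisional; refined below
        rule_fired=rule,
        cutoff=cutoff,
        metrics=metrics,
    )
    return assess_tl_statement(call)


def assess_tl_statement(call: MRDCall) -> MRDCall:
    """Second decision step: may the TL of a positive sample be stated?

    Positive samples with TL >= LOQ are quantifiable; positive samples
    below the LOQ are reported positive but their TL cannot be stated.
    Non-positive samples are not applicable.
    """
    if call.status is not MRDStatus.POSITIVE:
        quant = TLQuantifiability.NOT_APPLICABLE
    elif _ge(call.metrics.tumor_load, call.metrics.loq):
        quant = TLQuantifiability.QUANTIFIABLE
    else:
        quant = TLQuantifiability.NONQUANTIFIABLE
    return MRDCall(
        status=call.status,
        tl_quantifiable=quant,
        rule_fired=call.rule_fired,
        cutoff=call.cutoff,
        metrics=call.metrics,
        patient_id=call.patient_id,
        assay=call.assay,
    )


def call_sample(
    m: AssayMeasurement,
    cutoff: MRDCutoff,
    c: AssayConstants = DEFAULT_CONSTANTS,
) -> MRDCall:
    """Full per-sample evaluation: metrics -> status -> TL statement."""
    call = assign_status(compute_metrics(m, c), cutoff)
    return MRDCall(
        status=call.status,
        tl_quantifiable=call.tl_quantifiable,
        rule_fired=call.rule_fired,
        cutoff=call.cutoff,
        metrics=call.metrics,
        patient_id=m.patient_id,
        assay=m.assay.value,
    )
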