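"""Cohort-level MRD analytics.

Four analyses over a cohort of paired NGS/MFC bone-marrow measurements:

* **Cut-off sweep** — status counts per assay at each candidate MRD
  cut-off, showing how lower cut-offs trade MRD-negative calls for
  nonassessable ones as per-sample LODs are undercut.
* **Concordance** — cross-tabulation of paired NGS vs MFC calls at one
  cut-off; pairs where either method is nonassessable (LOD undercut) are
  set aside, and Cohen's kappa is computed on the remaining 2x2 table.
* **Response stratification** — MRD-negativity rates by serological
  remission category, plus the aggregate rate among patients at VGPR or
  better (CR + nCR + VGPR).
* **Tumor-load comparison** — Pearson correlation and a paired t-test of
  log10 TLs among concordant MRD-positive pairs, with optional removal
  of the most extreme off-line outliers.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core_metrics import (
    Assay,
    AssayConstants,
    AssayMeasurement,
    DEFAULT_CONSTANTS,
    ValidationError,
    compute_tl,
)
from .status_engine import MRDCall, MRDCutoff, MRDStatus, call_sample

logger = logging.getLogger(__name__)

__all__ = [
    "Response",
    "Timepoint",
    "PatientRecord",
    "SweepResult",
    "ConcordanceResult",
    "TLComparison",
    "sweep_cutoffs",
    "concordance",
    "cohen_kappa",
    "stratify_by_response",
    "compare_tl",
    "VGPR_OR_BETTER",
]


class Response(str, enum.Enum):
    """Serological remission category (IMWG criteria)."""

    CR = "CR"
    nCR = "nCR"
    VGPR = "VGPR"
    PR = "PR"
    MR = "MR"
    baseline = "baseline"
    NA = "NA"


#: Strata counted in the "VGPR or better" aggregate negativity rate.
VGPR_OR_BETTER = (Response.CR, Response.nCR, Response.VGPR)


class Timepoint(str, enum.Enum):
    baseline = "baseline"
    post_induction = "post_induction"
    post_mobilization = "post_mobilization"
    post_ASCT1 = "post_ASCT1"
    post_ASCT2 = "post_ASCT2"
    post_consolidation = "post_consolidation"
    NA = "NA"


@dataclass(frozen=True)
class PatientRecord:
    """Paired NGS + MFC measurements for one patient at one timepoint."""

    patient_id: str
    ngs: Optional[AssayMeasurement] = None
    mfc: Optional[AssayMeasurement] = None
    response: Response = Response.NA
    timepoint: Timepoint = Timepoint.NA

    def __post_init__(self) -> None:
        object.__setattr__(self, "response", Response(self.response))
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        if self.ngs is None and self.mfc is None:
            raise ValidationError(
                f"patient {self.patient_id}: at least one assay required"
            )
        if self.ngs is not None and self.ngs.assay is not Assay.NGS:
            raise ValidationError(f"patient {self.patient_id}: ngs slot holds {self.ngs.assay}")
        if self.mfc is not None and self.mfc.assay is not Assay.MFC:
            raise ValidationError(f"patient {self.patient_id}: mfc slot holds {self.mfc.assay}")

    def measurement(self, assay: Assay) -> Optional[AssayMeasurement]:
        return self.ngs if assay is Assay.NGS else self.mfc


@dataclass(frozen=True)
class SweepResult:
    """Status counts and cohort proportions per (assay, cut-off)."""

    n_cohort: Dict[Assay, int]
    counts: Dict[Tuple[Assay, float], Dict[MRDStatus, int]]

    def proportion(self, assay: Assay, cutoff: float, status: MRDStatus) -> float:
        return self.counts[(assay, cutoff)][status] / self.n_cohort[assay]


@dataclass(frozen=True)
class ConcordanceResult:
    """Paired NGS/MFC agreement at one cut-off.

    ``lod_discordant`` pairs (either call nonassessable) are excluded
    from the 2x2 table underlying kappa; ``kappa_n`` reports the size of
    that table so the exclusion stays transparent.
    """

    n_total: int
    concordant_pos: int
    concordant_neg: int
    discordant_ngs_pos: int
    discordant_mfc_pos: int
    lod_discordant: int
    kappa: float
    kappa_n: int
    cutoff: float

    @property
    def overall_concordance(self) -> float:
        return (self.concordant_pos + self.concordant_neg) / self.n_total

    @property
    def overall_discordance(self) -> float:
        return (self.discordant_ngs_pos + self.discordant_mfc_pos) / self.n_total

    @property
    def lod_discordance(self) -> float:
        return self.lod_discordant / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "cutoff": self.cutoff,
            "counts": {
                "concordant_pos": self.concordant_pos,
                "concordant_neg": self.concordant_neg,
                "discordant_ngs_pos": self.discordant_ngs_pos,
                "discordant_mfc_pos": self.discordant_mfc_pos,
                "lod_discordant": self.lod_discordant,
            },
            "proportions": {
                "overall_concordance": self.overall_concordance,
                "overall_discordance": self.overall_discordance,
                "lod_discordance": self.lod_discordance,
            },
            "kappa": self.kappa,
            "kappa_n": self.kappa_n,
        }


@dataclass(frozen=True)
class TLComparison:
    """Paired tumor-load comparison among concordant MRD-positive pairs."""

    n_pairs: int
    pearson_r: float
    pearson_p: float
    pearson_r_outliers_removed: float
    pearson_p_outliers_removed: float
    n_outliers_removed: int
    outlier_patient_ids: Tuple[str, ...]
    t_statistic: float
    p_value: float
    scale: str  # "log10" | "linear"

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "pearson_r_outliers_removed": self.pearson_r_outliers_removed,
            "pearson_p_outliers_removed": self.pearson_p_outliers_removed,
            "n_outliers_removed": self.n_outliers_removed,
            "outlier_patient_ids": list(self.outlier_patient_ids),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "scale": self.scale,
        }


def _calls_for_assay(
    cohort: Sequence[PatientRecord],
    assay: Assay,
    cutoff: MRDCutoff,
    c: AssayConstants,
) -> List[MRDCall]:
    calls = []
    for rec in cohort:
        m = rec.measurement(assay)
        if m is not None:
            calls.append(call_sample(m, cutoff, c))
    return calls


def sweep_cutoffs(
    cohort: Sequence[PatientRecord],
    cutoffs: Sequence[MRDCutoff],
    c: AssayConstants = DEFAULT_CONSTANTS,
) -> SweepResult:
    """Call every present measurement at every cut-off and tabulate statuses."""
    if not cohort:
        raise ValidationError("empty cohort")
    if not cutoffs:
        raise ValidationError("no cut-offs supplied")
    n_cohort: Dict[Assay, int] = {}
    counts: Dict[Tuple[Assay, float], Dict[MRDStatus, int]] = {}
    for assay in Assay:
        n_cohort[assay] = sum(1 for r in cohort if r.measurement(assay) is not None)
        for cutoff in cutoffs:
            tally = {s: 0 for s in MRDStatus}
            for call in _calls_for_assay(cohort, assay, cutoff, c):
                tally[call.status] += 1
            counts[(assay, cutoff.value)] = tally
    return SweepResult(n_cohort=n_cohort, counts=counts)


def cohen_kappa(table: Sequence[Sequence[float]]) -> float:
    """Cohen's kappa for a 2x2 agreement table ``[[a, b], [c, d]]``.

    Rows index the first rater's call, columns the second's; ``a`` and
    ``d`` are the agreement cells.  kappa = (p_o - p_e) / (1 - p_e) with
    marginal-product expected agreement p_e.  A degenerate table with
    p_e = 1 (all mass in one cell) has perfect observed agreement and
    returns 1.0.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("table counts must be non-negative")
    n = t.sum()
    if n == 0:
        raise ValidationError("all-zero agreement table")
    po = (t[0, 0] + t[1, 1]) / n
    pe = (t[0].sum() * t[:, 0].sum() + t[1].sum() * t[:, 1].sum()) / n**2
    if math.isclose(pe, 1.0):
        return 1.0
    return float((po - pe) / (1 - pe))


def concordance(
    cohort: Sequence[PatientRecord],
    cutoff: MRDCutoff,
    c: AssayConstants = DEFAULT_CONSTANTS,
) -> ConcordanceResult:
    """Cross-tabulate paired NGS vs MFC calls at one cut-off.

    Records missing either assay are excluded with a warning.  Pairs in
    which either call is nonassessable are counted as ``lod_discordant``
    and excluded from the kappa table.
    """
    cells = {
        "concordant_pos": 0,
        "concordant_neg": 0,
        "discordant_ngs_pos": 0,
        "discordant_mfc_pos": 0,
        "lod_discordant": 0,
    }
    n_total = 0
    for rec in cohort:
        if rec.ngs is None or rec.mfc is None:
            logger.warning(
                "patient %s lacks a paired measurement; excluded from "
                "concordance", rec.patient_id,
            )
            continue
        n_total += 1
        s_ngs = call_sample(rec.ngs, cutoff, c).status
        s_mfc = call_sample(rec.mfc, cutoff, c).status
        if MRDStatus.NONASSESSABLE in (s_ngs, s_mfc):
            cells["lod_discordant"] += 1
        elif s_ngs is MRDStatus.POSITIVE and s_mfc is MRDStatus.POSITIVE:
            cells["concordant_pos"] += 1
        elif s_ngs is MRDStatus.NEGATIVE and s_mfc is MRDStatus.NEGATIVE:
            cells["concordant_neg"] += 1
        elif s_ngs is MRDStatus.POSITIVE:
            cells["discordant_ngs_pos"] += 1
        else:
            cells["discordant_mfc_pos"] += 1
    if n_total == 0:
        raise ValidationError("no fully paired records in cohort")
    table = [
        [cells["concordant_pos"], cells["discordant_ngs_pos"]],
        [cells["discordant_mfc_pos"], cells["concordant_neg"]],
    ]
    kappa_n = n_total - cells["lod_discordant"]
    kappa = cohen_kappa(table) if kappa_n > 0 else float("nan")
    return ConcordanceResult(
        n_total=n_total,
        kappa=kappa,
        kappa_n=kappa_n,
        cutoff=cutoff.value,
        **cells,
    )


def stratify_by_response(
    cohort: Sequence[PatientRecord],
    cutoff: MRDCutoff,
    c: AssayConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Status counts and within-stratum proportions per (assay, response).

    Returns a dict with per-stratum tallies and, per assay, the aggregate
    MRD-negativity rate among patients at VGPR or better.  Empty strata
    report proportions as None rather than 0.
    """
    strata: Dict[Tuple[Assay, Response], Dict[MRDStatus, int]] = {
        (a, r): {s: 0 for s in MRDStatus} for a in Assay for r in Response
    }
    for rec in cohort:
        for assay in Assay:
            m = rec.measurement(assay)
            if m is None:
                continue
            call = call_sample(m, cutoff, c)
            strata[(assay, rec.response)][call.status] += 1

    out: dict = {"cutoff": cutoff.value, "strata": {}, "vgpr_or_better": {}}
    for (assay, resp), tally in strata.items():
        n = sum(tally.values())
        out["strata"][(assay, resp)] = {
            "n": n,
            "counts": dict(tally),
            "proportions": (
                {s: tally[s] / n for s in MRDStatus} if n > 0 else None
            ),
        }
    for assay in Assay:
        n_agg = sum(
            out["strata"][(assay, r)]["n"] for r in VGPR_OR_BETTER
        )
        neg_agg = sum(
            out["strata"][(assay, r)]["counts"][MRDStatus.NEGATIVE]
            for r in VGPR_OR_BETTER
        )
        out["vgpr_or_better"][assay] = {
            "n": n_agg,
            "n_negative": neg_agg,
            "negativity_rate": neg_agg / n_agg if n_agg else None,
        }
    return out


def _concordant_positive_pairs(
    cohort: Sequence[PatientRecord],
    cutoff: MRDCutoff,
    c: AssayConstants,
) -> Tuple[List[str], np.ndarray, np.ndarray]:
    ids: List[str] = []
    ngs_tl: List[float] = []
    mfc_tl: List[float] = []
    for rec in cohort:
        if rec.ngs is None or rec.mfc is None:
            continue
        if (
            call_sample(rec.ngs, cutoff, c).status is MRDStatus.POSITIVE
            and call_sample(rec.mfc, cutoff, c).status is MRDStatus.POSITIVE
        ):
            ids.append(rec.patient_id)
            ngs_tl.append(compute_tl(rec.ngs))
            mfc_tl.append(compute_tl(rec.mfc))
    return ids, np.asarray(ngs_tl), np.asarray(mfc_tl)


def compare_tl(
    cohort: Sequence[PatientRecord],
    cutoff: MRDCutoff,
    c: AssayConstants = DEFAULT_CONSTANTS,
    scale: str = "log10",
    n_outliers: int = 2,
) -> TLComparison:
    """Correlate and test paired TLs among concordant MRD-positive pairs.

    TLs span several orders of magnitude, so the default working scale is
    log10.  Outlier handling refits after dropping the ``n_outliers``
    pairs with the largest absolute residuals from the least-squares line
    of MFC on NGS — the pairs farthest off the agreement trend.
    """
    if scale not in ("log10", "linear"):
        raise ValidationError(f"unknown scale {scale!r}")
    ids, x, y = _concordant_positive_pairs(cohort, cutoff, c)
    if len(ids) < 3:
        raise ValidationError(
            f"need >= 3 concordant MRD-positive pairs, found {len(ids)}"
        )
    if scale == "log10":
        # concordant positives have TL >= cutoff > 0 on both assays
        x, y = np.log10(x), np.log10(y)
    r, p_r = stats.pearsonr(x, y)
    if np.allclose(x - y, 0.0):  # identical pairs: zero difference by convention
        t_stat, p_t = 0.0, 1.0
    else:
        t_stat, p_t = stats.ttest_rel(x, y)

    n_out = min(n_outliers, len(ids) - 3)
    if n_out > 0:
        slope, intercept = np.polyfit(x, y, 1)
        resid = np.abs(y - (slope * x + intercept))
        drop = np.argsort(resid)[-n_out:]
        keep = np.setdiff1d(np.arange(len(ids)), drop)
        r_clean, p_clean = stats.pearsonr(x[keep], y[keep])
        outlier_ids = tuple(ids[i] for i in sorted(drop))
    else:
        r_clean, p_clean, outlier_ids = r, p_r, ()
    return TLComparison(
        n_pairs=len(ids),
        pearson_r=float(r),
        pearson_p=float(p_r),
        pearson_r_outliers_removed=float(r_clean),
        pearson_p_outliers_removed=float(p_clean),
        n_outliers_removed=len(outlier_ids),
        outlier_patient_ids=outlier_ids,
        t_statistic=float(t_stat),
        p_value=float(p_t),
        scale=scale,
    )
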