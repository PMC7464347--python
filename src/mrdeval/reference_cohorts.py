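"""Deterministic reconstruction cohorts built from published marginals.

The per-patient trial data are not deposited, so these builders
reconstruct *synthetic* 125-patient cohorts whose cell counts and status
marginals match the published summary figures exactly.  They exercise
the full pipeline end to end: each builder emits raw measurements
(cells assayed + tumor counts) chosen so that the decision engine, run
at the stated cut-off, reproduces the published table — the statuses
themselves are never hard-coded downstream.

Shared building blocks (cut-off 1e-5 unless noted):

* NGS, 1.1e6 cell equivalents (the cohort median): LOD 1.7e-6.
  count 0 -> negative; count 45 -> TL 4.1e-5, positive (the published
  median detected NGS TL).
* NGS, 1.8e5 cell equivalents (the cohort minimum): LOD 1.06e-5 > 1e-5,
  count 0 -> nonassessable.
* MFC, 5.0e6 events (median): LOD 6.0e-6.  count 0 -> negative;
  count 500 -> TL 1.0e-4, positive (published median MFC-positive TL).
* MFC, 1.0e6 events (minimum): LOD 3.0e-5 > 1e-5, count 0 ->
  nonassessable.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .core_metrics import Assay, AssayMeasurement
from .cohort_analysis import PatientRecord, Response

__all__ = [
    "concordance_cohort",
    "stratified_cohort",
    "sweep_cohort_ngs",
    "tl_correlation_cohort",
]

_NGS_MEDIAN_CELLS = 1_100_000
_NGS_MIN_CELLS = 180_000
_MFC_MEDIAN_EVENTS = 5_000_000
_MFC_MIN_EVENTS = 1_000_000


def _ngs(pid: str, status: str) -> AssayMeasurement:
    cells, count = {
        "pos": (_NGS_MEDIAN_CELLS, 45),
        "neg": (_NGS_MEDIAN_CELLS, 0),
        "nonassessable": (_NGS_MIN_CELLS, 0),
    }[status]
    return AssayMeasurement(pid, Assay.NGS, cells, count)


def _mfc(pid: str, status: str) -> AssayMeasurement:
    cells, count = {
        "pos": (_MFC_MEDIAN_EVENTS, 500),
        "neg": (_MFC_MEDIAN_EVENTS, 0),
        "nonassessable": (_MFC_MIN_EVENTS, 0),
    }[status]
    return AssayMeasurement(pid, Assay.MFC, cells, count)


def concordance_cohort() -> List[PatientRecord]:
    """125 paired records reproducing the published concordance table.

    42 concordant positive, 43 concordant negative, 14 discordant in
    each direction, and 12 pairs nonassessable by one method (2 NGS,
    10 MFC) at cut-off 1e-5.
    """
    spec = (
        [("pos", "pos")] * 42
        + [("neg", "neg")] * 43
        + [("pos", "neg")] * 14
        + [("neg", "pos")] * 14
        + [("nonassessable", "neg")] * 2
        + [("neg", "nonassessable")] * 10
    )
    return [
        PatientRecord(
            patient_id=f"C{i + 1:03d}",
            ngs=_ngs(f"C{i + 1:03d}", s_ngs),
            mfc=_mfc(f"C{i + 1:03d}", s_mfc),
        )
        for i, (s_ngs, s_mfc) in enumerate(spec)
    ]


# Per-stratum (n, NGS-negative, MFC-negative) counts of the published
# response-stratified MRD rates at cut-off 1e-5; remaining patients in a
# stratum are positive by that assay.
_STRATA = (
    (Response.CR, 54, 37, 37),
    (Response.nCR, 31, 19, 12),
    (Response.VGPR, 24, 4, 5),
    (Response.PR, 7, 0, 0),
    (Response.MR, 1, 0, 0),
    (Response.baseline, 1, 0, 0),
    (Response.NA, 7, 0, 0),
)


def stratified_cohort() -> List[PatientRecord]:
    """125 paired records reproducing the published response-stratified rates."""
    records: List[PatientRecord] = []
    i = 0
    for response, n, n_ngs_neg, n_mfc_neg in _STRATA:
        for j in range(n):
            pid = f"S{i + 1:03d}"
            records.append(
                PatientRecord(
                    patient_id=pid,
                    ngs=_ngs(pid, "neg" if j < n_ngs_neg else "pos"),
                    mfc=_mfc(pid, "neg" if j < n_mfc_neg else "pos"),
                    response=response,
                )
            )
            i += 1
    return records


def sweep_cohort_ngs() -> List[PatientRecord]:
    """125 NGS-only records reproducing the published cut-off sweep endpoint.

    At cut-off 1e-6: 80 positive, 1 negative (2.0e6 cell equivalents,
    LOD 0.95e-6), 44 nonassessable (median cell input, LOD 1.7e-6
    undercut by the cut-off).
    """
    records: List[PatientRecord] = []
    for i in range(125):
        pid = f"W{i + 1:03d}"
        if i < 80:
            m = AssayMeasurement(pid, Assay.NGS, _NGS_MEDIAN_CELLS, 45)
        elif i == 80:
            m = AssayMeasurement(pid, Assay.NGS, 2_000_000, 0)
        else:
            m = AssayMeasurement(pid, Assay.NGS, _NGS_MEDIAN_CELLS, 0)
        records.append(PatientRecord(patient_id=pid, ngs=m))
    return records


def tl_correlation_cohort(
    seed: int = 0,
    n_pairs: int = 42,
    n_outliers: int = 2,
    assay_log10_sd: float = 0.4,
) -> List[PatientRecord]:
    """Concordant MRD-positive pairs with planted correlation and outliers.

    Shared log10 TL is drawn from N(-3.5, 0.8) truncated to
    [-4.4, -1.5] so every pair stays MRD-positive on both assays at
    cut-off 1e-5; independent per-assay noise of ``assay_log10_sd``
    decades sets the attainable correlation.  The last ``n_outliers``
    pairs have their MFC TL displaced two decades off the trend line,
    mimicking extreme disagreement between methods.  Counts are the
    rounded expected values, so calls are deterministic.
    """
    rng = np.random.default_rng(seed)
    records: List[PatientRecord] = []
    for i in range(n_pairs):
        pid = f"T{i + 1:03d}"
        log_tl = float(np.clip(rng.normal(-3.5, 0.8), -4.4, -1.5))
        log_ngs = np.clip(log_tl + rng.normal(0, assay_log10_sd), -4.4, -1.3)
        log_mfc = np.clip(log_tl + rng.normal(0, assay_log10_sd), -4.4, -1.3)
        if i >= n_pairs - n_outliers:
            log_mfc = np.clip(log_mfc + 2.0, None, -1.3)
        ngs_count = max(1, round(10**log_ngs * _NGS_MEDIAN_CELLS))
        mfc_count = max(1, round(10**log_mfc * _MFC_MEDIAN_EVENTS))
        records.append(
            PatientRecord(
                patient_id=pid,
                ngs=AssayMeasurement(pid, Assay.NGS, _NGS_MEDIAN_CELLS, ngs_count),
                mfc=AssayMeasurement(pid, Assay.MFC, _MFC_MEDIAN_EVENTS, mfc_count),
            )
        )
    return records
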