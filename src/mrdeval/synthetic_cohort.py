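"""Seeded synthetic paired NGS/MFC cohorts.

The trial data behind the analyses (GMMG-HD6 MRD pairs) are not publicly
deposited, so a generator emulates the sampling situation the pipeline
assumes:

1. draw a serological response category per patient;
2. draw a residual-disease indicator; MRD-negative patients carry a true
   tumor load of exactly zero (no contamination/background is modelled);
3. for residual-disease patients, draw log10 true TL from a
   response-specific normal, clamped at 5e-2 (plasma-cell infiltration
   levels beyond that are diagnostic, not residual, disease);
4. perturb the shared true TL independently per assay in log10 space
   (``cross_assay_log10_sd``) — the knob that sets the achievable
   NGS-vs-MFC TL correlation;
5. draw cells assayed log-uniformly over the per-assay observed range;
6. draw the detected tumor count binomially: Binomial(cells, effective
   TL).  Binomial (not Poisson) keeps tumor_count <= cells_assayed.

Everything is deterministic under a fixed seed.  The default
configuration mirrors the published cohort's marginals: n = 125,
response frequencies 54/31/24/7/1/1/7 (CR/nCR/VGPR/PR/MR/baseline/NA),
NGS cell equivalents 1.8e5-2.3e6, MFC events 1.0e6-1.4e7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_metrics import (
    Assay,
    AssayConstants,
    AssayMeasurement,
    DEFAULT_CONSTANTS,
    ValidationError,
    compute_loq,
    compute_metrics,
    compute_tl,
)
from .cohort_analysis import PatientRecord, Response, Timepoint

__all__ = [
    "SimulationConfig",
    "TruePatientState",
    "simulate_cohort",
    "recover_parameters",
    "DEFAULT_RESPONSE_PROBS",
]

#: Serological response frequencies of the published 125-patient cohort.
DEFAULT_RESPONSE_PROBS: Dict[Response, float] = {
    Response.CR: 54 / 125,
    Response.nCR: 31 / 125,
    Response.VGPR: 24 / 125,
    Response.PR: 7 / 125,
    Response.MR: 1 / 125,
    Response.baseline: 1 / 125,
    Response.NA: 7 / 125,
}

# Calibration constants: chance of a truly MRD-negative marrow, and the
# center of the log10 residual tumor-load distribution, by serological
# response.  Deeper serological responses have more truly negative
# marrows and lower residual loads; baseline samples carry frank disease.
DEFAULT_P_MRD_NEGATIVE: Dict[Response, float] = {
    Response.CR: 0.65,
    Response.nCR: 0.50,
    Response.VGPR: 0.18,
    Response.PR: 0.05,
    Response.MR: 0.0,
    Response.baseline: 0.0,
    Response.NA: 0.40,
}
DEFAULT_TL_LOG10_MEAN: Dict[Response, float] = {
    Response.CR: -4.5,
    Response.nCR: -4.2,
    Response.VGPR: -3.8,
    Response.PR: -3.2,
    Response.MR: -3.0,
    Response.baseline: -1.5,
    Response.NA: -4.0,
}

#: Residual TL ceiling: 5% plasma-cell fraction.
TL_CEILING = 5e-2


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults mirror the published cohort."""

    n_patients: int = 125
    seed: int = 0
    response_probs: Dict[Response, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_PROBS)
    )
    p_mrd_negative_by_response: Dict[Response, float] = field(
        default_factory=lambda: dict(DEFAULT_P_MRD_NEGATIVE)
    )
    tl_log10_mean_by_response: Dict[Response, float] = field(
        default_factory=lambda: dict(DEFAULT_TL_LOG10_MEAN)
    )
    tl_log10_sd: float = 0.8
    ngs_cells_range: Tuple[int, int] = (180_000, 2_300_000)
    mfc_events_range: Tuple[int, int] = (1_000_000, 14_000_000)
    cross_assay_log10_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        total = sum(self.response_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValidationError(
                f"response probabilities must sum to 1, got {total}"
            )
        if any(p < 0 for p in self.response_probs.values()):
            raise ValidationError("response probabilities must be >= 0")
        for name in ("ngs_cells_range", "mfc_events_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValidationError(f"{name} must satisfy 1 <= min <= max")
        if self.tl_log10_sd <= 0:
            raise ValidationError("tl_log10_sd must be positive")
        if self.cross_assay_log10_sd < 0:
            raise ValidationError("cross_assay_log10_sd must be >= 0")
        for resp, p in self.p_mrd_negative_by_response.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"p_mrd_negative[{resp}] out of [0,1]")


@dataclass(frozen=True)
class TruePatientState:
    """Latent truth behind one simulated patient."""

    patient_id: str
    response: Response
    true_tl: float  # 0 for truly MRD-negative marrow
    effective_tl_ngs: float
    effective_tl_mfc: float


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(10 ** rng.uniform(math.log10(lo), math.log10(hi))))


def simulate_cohort(
    cfg: SimulationConfig,
) -> Tuple[List[PatientRecord], List[TruePatientState]]:
    """Generate a paired cohort plus its latent truth table."""
    rng = np.random.default_rng(cfg.seed)
    responses = list(cfg.response_probs)
    probs = np.array([cfg.response_probs[r] for r in responses])
    probs = probs / probs.sum()  # renormalize away float slack

    records: List[PatientRecord] = []
    truth: List[TruePatientState] = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        response = responses[rng.choice(len(responses), p=probs)]
        if rng.random() < cfg.p_mrd_negative_by_response.get(response, 0.0):
            true_tl = eff_ngs = eff_mfc = 0.0
        else:
            log_tl = rng.normal(
                cfg.tl_log10_mean_by_response[response], cfg.tl_log10_sd
            )
            log_tl = min(log_tl, math.log10(TL_CEILING))
            true_tl = 10**log_tl
            eff_ngs = min(
                10 ** (log_tl + rng.normal(0.0, cfg.cross_assay_log10_sd)),
                TL_CEILING,
            )
            eff_mfc = min(
                10 ** (log_tl + rng.normal(0.0, cfg.cross_assay_log10_sd)),
                TL_CEILING,
            )
        ngs_cells = _log_uniform_int(rng, *cfg.ngs_cells_range)
        mfc_events = _log_uniform_int(rng, *cfg.mfc_events_range)
        ngs = AssayMeasurement(
            patient_id=pid,
            assay=Assay.NGS,
            cells_assayed=ngs_cells,
            tumor_count=int(rng.binomial(ngs_cells, eff_ngs)),
        )
        mfc = AssayMeasurement(
            patient_id=pid,
            assay=Assay.MFC,
            cells_assayed=mfc_events,
            tumor_count=int(rng.binomial(mfc_events, eff_mfc)),
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                ngs=ngs,
                mfc=mfc,
                response=response,
                timepoint=Timepoint.NA,
            )
        )
        truth.append(
            TruePatientState(
                patient_id=pid,
                response=response,
                true_tl=true_tl,
                effective_tl_ngs=eff_ngs,
                effective_tl_mfc=eff_mfc,
            )
        )
    return records, truth


def recover_parameters(
    records: Sequence[PatientRecord],
    truth: Sequence[TruePatientState],
    c: AssayConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Estimator diagnostics on paired generator output.

    For samples whose true effective TL reaches the per-sample LOQ, the
    log10 bias and RMSE of the count-ratio estimator are reported; for
    all samples the empirical detection rate (count > 0) is compared to
    the Poisson approximation 1 - exp(-TL * cells).
    """
    truth_by_id = {t.patient_id: t for t in truth}
    log_errors: List[float] = []
    detected = 0
    n_meas = 0
    expected_detection = 0.0
    false_pos = 0
    n_zero_truth = 0
    for rec in records:
        t = truth_by_id[rec.patient_id]
        for assay, eff in (
            (Assay.NGS, t.effective_tl_ngs),
            (Assay.MFC, t.effective_tl_mfc),
        ):
            m = rec.measurement(assay)
            if m is None:
                continue
            n_meas += 1
            est = compute_tl(m)
            if est > 0:
                detected += 1
            expected_detection += 1.0 - math.exp(-eff * m.cells_assayed)
            if eff == 0.0:
                n_zero_truth += 1
                if m.tumor_count:
                    false_pos += 1
            elif eff >= compute_loq(m, c) and est > 0:
                log_errors.append(math.log10(est) - math.log10(eff))
    errs = np.asarray(log_errors)
    return {
        "n_measurements": n_meas,
        "n_quantifiable": len(errs),
        "log10_bias": float(errs.mean()) if errs.size else float("nan"),
        "log10_rmse": float(np.sqrt((errs**2).mean())) if errs.size else float("nan"),
        "detection_rate": detected / n_meas if n_meas else float("nan"),
        "poisson_expected_detection_rate": (
            expected_detection / n_meas if n_meas else float("nan")
        ),
        "n_zero_truth_measurements": n_zero_truth,
        "false_positive_detections": false_pos,
    }
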