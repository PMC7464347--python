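"""Synthetic paired-cohort generator: determinism, marginals, recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from mrdeval import (
    Assay,
    MRDCutoff,
    Response,
    ValidationError,
    compute_lod,
    compute_loq,
    compute_tl,
)
from mrdeval.synthetic_cohort import (
    DEFAULT_RESPONSE_PROBS,
    SimulationConfig,
    recover_parameters,
    simulate_cohort,
)


def all_negative_config(**kwargs):
    return SimulationConfig(
        p_mrd_negative_by_response={r: 1.0 for r in Response}, **kwargs
    )


def test_same_seed_identical_output():
    cfg = SimulationConfig(n_patients=50, seed=123)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    assert a == b
    c = simulate_cohort(SimulationConfig(n_patients=50, seed=124))
    assert a != c


def test_all_negative_cohort_has_zero_counts():
    records, truth = simulate_cohort(all_negative_config(n_patients=30, seed=1))
    for rec in records:
        assert rec.ngs.tumor_count == 0
        assert rec.mfc.tumor_count == 0
    assert all(t.true_tl == 0.0 for t in truth)


def test_zero_truth_never_detected():
    """No background/contamination term: truly negative marrows yield 0 counts."""
    records, truth = simulate_cohort(SimulationConfig(n_patients=200, seed=2))
    report = recover_parameters(records, truth)
    assert report["false_positive_detections"] == 0
    assert report["n_zero_truth_measurements"] > 0


def test_response_frequencies_match_probs():
    records, _ = simulate_cohort(SimulationConfig(n_patients=4000, seed=3))
    counts = {r: 0 for r in Response}
    for rec in records:
        counts[rec.response] += 1
    observed = [counts[r] for r in DEFAULT_RESPONSE_PROBS]
    expected = [4000 * p for p in DEFAULT_RESPONSE_PROBS.values()]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    # 6 df; reject only at p < 1e-4
    assert chi2 < stats.chi2.ppf(1 - 1e-4, df=len(observed) - 1)


def test_cell_counts_within_configured_ranges():
    cfg = SimulationConfig(n_patients=300, seed=4)
    records, _ = simulate_cohort(cfg)
    ngs_cells = [r.ngs.cells_assayed for r in records]
    mfc_cells = [r.mfc.cells_assayed for r in records]
    assert min(ngs_cells) >= cfg.ngs_cells_range[0]
    assert max(ngs_cells) <= cfg.ngs_cells_range[1]
    assert min(mfc_cells) >= cfg.mfc_events_range[0]
    assert max(mfc_cells) <= cfg.mfc_events_range[1]


def test_median_limits_land_in_published_ranges():
    """Default generator puts median per-assay LOD/LOQ inside the printed ranges."""
    records, _ = simulate_cohort(SimulationConfig(n_patients=300, seed=5))
    ngs_lod = np.median([compute_lod(r.ngs) for r in records])
    ngs_loq = np.median([compute_loq(r.ngs) for r in records])
    mfc_lod = np.median([compute_lod(r.mfc) for r in records])
    mfc_loq = np.median([compute_loq(r.mfc) for r in records])
    assert 8.1e-7 <= ngs_lod <= 1.9e-4
    assert 1.0e-6 <= ngs_loq <= 2.4e-4
    assert 2.2e-6 <= mfc_lod <= 3.0e-5
    assert 3.7e-6 <= mfc_loq <= 5.0e-5


def test_correlation_monotone_in_cross_assay_noise():
    """More cross-assay noise -> lower NGS/MFC log-TL correlation."""
    rs = []
    for sd in (0.0, 0.4, 1.0):
        cfg = SimulationConfig(
            n_patients=400,
            seed=6,
            p_mrd_negative_by_response={r: 0.0 for r in Response},
            tl_log10_mean_by_response={r: -3.0 for r in Response},
            cross_assay_log10_sd=sd,
            ngs_cells_range=(2_000_000, 2_300_000),
            mfc_events_range=(10_000_000, 14_000_000),
        )
        records, _ = simulate_cohort(cfg)
        x, y = [], []
        for rec in records:
            tn, tm = compute_tl(rec.ngs), compute_tl(rec.mfc)
            if tn >= compute_loq(rec.ngs) and tm >= compute_loq(rec.mfc):
                x.append(math.log10(tn))
                y.append(math.log10(tm))
        rs.append(stats.pearsonr(x, y)[0])
    assert rs[0] > rs[1] > rs[2]
    assert rs[0] > 0.98  # noise-free limit with large cell counts


def test_log10_bias_near_zero_in_large_cells_regime():
    cfg = SimulationConfig(
        n_patients=300,
        seed=7,
        ngs_cells_range=(2_000_000, 2_300_000),
        mfc_events_range=(10_000_000, 14_000_000),
    )
    records, truth = simulate_cohort(cfg)
    report = recover_parameters(records, truth)
    assert report["n_quantifiable"] > 100
    assert abs(report["log10_bias"]) < 0.05
    assert report["log10_rmse"] < 0.25


def test_detection_rate_matches_poisson_approximation():
    """For rare clones the chance of >=1 detected cell is ~1 - exp(-TL*cells)."""
    cfg = SimulationConfig(
        n_patients=500,
        seed=8,
        p_mrd_negative_by_response={r: 0.0 for r in Response},
        tl_log10_mean_by_response={r: -6.3 for r in Response},
        tl_log10_sd=0.3,
        cross_assay_log10_sd=0.0,
    )
    records, truth = simulate_cohort(cfg)
    report = recover_parameters(records, truth)
    n = report["n_measurements"]
    p = report["poisson_expected_detection_rate"]
    se = math.sqrt(p * (1 - p) / n)
    assert abs(report["detection_rate"] - p) < 4 * se + 0.01


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_patients=0),
        dict(response_probs={Response.CR: 0.5}),
        dict(tl_log10_sd=0.0),
        dict(cross_assay_log10_sd=-0.1),
        dict(ngs_cells_range=(100, 10)),
        dict(p_mrd_negative_by_response={r: 1.5 for r in Response}),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValidationError):
        SimulationConfig(**kwargs)
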