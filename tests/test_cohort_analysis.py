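"""Cohort analytics: sweep, concordance/kappa, stratification, TL comparison."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrdeval import (
    Assay,
    AssayMeasurement,
    MRDCutoff,
    MRDStatus,
    PatientRecord,
    Response,
    ValidationError,
    cohen_kappa,
    compare_tl,
    concordance,
    stratify_by_response,
    sweep_cutoffs,
)
from mrdeval.cohort_analysis import VGPR_OR_BETTER
from mrdeval.reference_cohorts import (
    concordance_cohort,
    stratified_cohort,
    sweep_cohort_ngs,
    tl_correlation_cohort,
)
from mrdeval.status_engine import PRESET_CUTOFFS
from mrdeval.synthetic_cohort import SimulationConfig, simulate_cohort


class TestCohenKappa:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[10, 0], [0, 10]], 1.0),  # perfect agreement
            ([[5, 5], [5, 5]], 0.0),  # agreement equals chance
            ([[42, 14], [14, 43]], 0.5044),  # hand-computed: po=85/113, pe=6385/113^2
        ],
    )
    def test_closed_form_values(self, table, expected):
        assert cohen_kappa(table) == pytest.approx(expected, abs=1e-4)

    def test_degenerate_tables(self):
        assert cohen_kappa([[7, 0], [0, 0]]) == 1.0  # p_e = 1 guard
        with pytest.raises(ValidationError):
            cohen_kappa([[0, 0], [0, 0]])
        with pytest.raises(ValidationError):
            cohen_kappa([[1, -1], [0, 0]])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=4, max_size=4))
    def test_agrees_with_sklearn_on_random_tables(self, counts):
        """Definition-level kappa vs scikit-learn's on label expansions."""
        a, b, c, d = counts
        if a + b + c + d == 0:
            return  # all-zero table raises; covered above
        from sklearn.metrics import cohen_kappa_score

        r1 = [0] * (a + b) + [1] * (c + d)
        r2 = [0] * a + [1] * b + [0] * c + [1] * d
        expected = cohen_kappa_score(r1, r2)
        if np.isnan(expected):
            return
        assert cohen_kappa([[a, b], [c, d]]) == pytest.approx(expected, abs=1e-12)


class TestConcordance:
    def test_published_partition_reproduced(self, cutoff_1e5):
        res = concordance(concordance_cohort(), cutoff_1e5)
        assert res.n_total == 125
        assert (res.concordant_pos, res.concordant_neg) == (42, 43)
        assert (res.discordant_ngs_pos, res.discordant_mfc_pos) == (14, 14)
        assert res.lod_discordant == 12
        assert res.overall_concordance == pytest.approx(0.680)
        assert res.overall_discordance == pytest.approx(0.224)
        assert res.lod_discordance == pytest.approx(0.096)
        assert res.kappa_n == 113
        assert res.kappa == pytest.approx(0.5044, abs=1e-4)

    def test_proportions_partition_unity(self, cutoff_1e5):
        res = concordance(concordance_cohort(), cutoff_1e5)
        total = (
            res.overall_concordance + res.overall_discordance + res.lod_discordance
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_perfect_agreement_gives_kappa_one(self, cutoff_1e5):
        cohort = [
            PatientRecord(
                f"p{i}",
                ngs=AssayMeasurement(f"p{i}", Assay.NGS, 10**6, 0 if i % 2 else 100),
                mfc=AssayMeasurement(f"p{i}", Assay.MFC, 5 * 10**6, 0 if i % 2 else 500),
            )
            for i in range(20)
        ]
        assert concordance(cohort, cutoff_1e5).kappa == pytest.approx(1.0)

    def test_unpaired_records_excluded_with_warning(self, cutoff_1e5, caplog):
        cohort = concordance_cohort()[:10] + [
            PatientRecord("solo", ngs=AssayMeasurement("solo", Assay.NGS, 10**6, 0))
        ]
        with caplog.at_level(logging.WARNING):
            res = concordance(cohort, cutoff_1e5)
        assert res.n_total == 10
        assert any("solo" in r.message for r in caplog.records)


class TestSweep:
    def test_published_nonassessable_endpoint(self):
        sweep = sweep_cutoffs(sweep_cohort_ngs(), [MRDCutoff(1e-6)])
        tally = sweep.counts[(Assay.NGS, 1e-6)]
        assert tally[MRDStatus.NONASSESSABLE] == 44
        assert sweep.proportion(Assay.NGS, 1e-6, MRDStatus.NONASSESSABLE) == (
            pytest.approx(0.352)
        )

    def test_counts_conserved_at_every_cutoff(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_patients=40, seed=5))
        sweep = sweep_cutoffs(cohort, list(PRESET_CUTOFFS))
        for (assay, _), tally in sweep.counts.items():
            assert sum(tally.values()) == sweep.n_cohort[assay] == 40

    def test_single_sample_trajectory(self):
        # LOD 1.9e-6, TL 0: negative at 1e-4/1e-5, nonassessable at 1e-6
        rec = PatientRecord("p", ngs=AssayMeasurement("p", Assay.NGS, 10**6, 0))
        sweep = sweep_cutoffs([rec], list(PRESET_CUTOFFS))
        get = lambda cut, s: sweep.counts[(Assay.NGS, cut)][s]
        assert get(1e-4, MRDStatus.NEGATIVE) == 1
        assert get(1e-5, MRDStatus.NEGATIVE) == 1
        assert get(1e-6, MRDStatus.NONASSESSABLE) == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            sweep_cutoffs([], [MRDCutoff(1e-5)])

    def test_monotonicity_across_cutoffs(self):
        """Lowering the cut-off never decreases positives nor increases negatives."""
        for seed in range(10):
            cohort, _ = simulate_cohort(SimulationConfig(n_patients=60, seed=seed))
            sweep = sweep_cutoffs(cohort, list(PRESET_CUTOFFS))
            for assay in Assay:
                cuts = sorted((c.value for c in PRESET_CUTOFFS), reverse=True)
                pos = [sweep.counts[(assay, c)][MRDStatus.POSITIVE] for c in cuts]
                neg = [sweep.counts[(assay, c)][MRDStatus.NEGATIVE] for c in cuts]
                assert pos == sorted(pos)
                assert neg == sorted(neg, reverse=True)


class TestStratification:
    def test_published_vgpr_or_better_rates(self, cutoff_1e5):
        out = stratify_by_response(stratified_cohort(), cutoff_1e5)
        ngs = out["vgpr_or_better"][Assay.NGS]
        mfc = out["vgpr_or_better"][Assay.MFC]
        assert (ngs["n"], ngs["n_negative"]) == (109, 60)
        assert ngs["negativity_rate"] == pytest.approx(60 / 109, abs=1e-12)
        assert (mfc["n"], mfc["n_negative"]) == (109, 54)
        assert mfc["negativity_rate"] == pytest.approx(54 / 109, abs=1e-12)

    def test_per_stratum_counts(self, cutoff_1e5):
        out = stratify_by_response(stratified_cohort(), cutoff_1e5)
        cr = out["strata"][(Assay.NGS, Response.CR)]
        assert cr["n"] == 54
        assert cr["counts"][MRDStatus.NEGATIVE] == 37
        assert cr["proportions"][MRDStatus.NEGATIVE] == pytest.approx(37 / 54)

    def test_empty_stratum_reports_none_not_zero(self, cutoff_1e5):
        cohort = stratified_cohort()
        cohort = [r for r in cohort if r.response is not Response.MR]
        out = stratify_by_response(cohort, cutoff_1e5)
        assert out["strata"][(Assay.NGS, Response.MR)]["proportions"] is None

    def test_aggregate_strata_set(self):
        assert set(VGPR_OR_BETTER) == {Response.CR, Response.nCR, Response.VGPR}


class TestTLComparison:
    def test_identical_tls_give_unit_correlation(self, cutoff_1e5):
        cohort = [
            PatientRecord(
                f"p{i}",
                ngs=AssayMeasurement(f"p{i}", Assay.NGS, 10**6, 20 * (i + 1)),
                mfc=AssayMeasurement(f"p{i}", Assay.MFC, 10**6, 20 * (i + 1)),
            )
            for i in range(10)
        ]
        res = compare_tl(cohort, cutoff_1e5, n_outliers=0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_outlier_removal_raises_correlation(self, cutoff_1e5):
        cohort = tl_correlation_cohort(seed=0, n_pairs=42, n_outliers=2)
        res = compare_tl(cohort, cutoff_1e5, n_outliers=2)
        assert res.n_pairs == 42
        assert res.n_outliers_removed == 2
        assert res.pearson_r_outliers_removed > res.pearson_r
        # the planted outliers are the ones identified
        assert set(res.outlier_patient_ids) == {"T041", "T042"}

    def test_planted_correlation_recovered(self, cutoff_1e5):
        """Cross-assay noise sd 0.4 on top of TL sd 0.8 plants r = 0.8."""
        cfg = SimulationConfig(
            n_patients=42,
            seed=11,
            p_mrd_negative_by_response={r: 0.0 for r in Response},
            tl_log10_mean_by_response={r: -3.0 for r in Response},
            tl_log10_sd=0.8,
            cross_assay_log10_sd=0.4,
        )
        cohort, _ = simulate_cohort(cfg)
        res = compare_tl(cohort, cutoff_1e5, n_outliers=0)
        r_true = 0.8**2 / (0.8**2 + 0.4**2)
        se = (1 - r_true**2) / np.sqrt(res.n_pairs - 1)
        assert res.n_pairs >= 35
        assert abs(res.pearson_r - r_true) < 3 * se

    def test_too_few_pairs_rejected(self, cutoff_1e5):
        with pytest.raises(ValidationError):
            compare_tl(concordance_cohort()[:2], cutoff_1e5)

    def test_linear_scale_option(self, cutoff_1e5):
        cohort = tl_correlation_cohort(seed=1, n_pairs=20, n_outliers=0)
        res = compare_tl(cohort, cutoff_1e5, scale="linear", n_outliers=0)
        assert res.scale == "linear"
        assert -1.0 <= res.pearson_r <= 1.0
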