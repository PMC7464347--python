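#!/usr/bin/env python
"""Cut-off sweep: how the MRD cut-off choice redistributes statuses.

Calls every measurement at cut-offs 1e-4, 2e-5, 1e-5 and 1e-6, both for
the synthetic cohort from step 01 and for the published-marginal sweep
reconstruction (where 44/125 NGS samples become nonassessable at 1e-6).
Lowering the cut-off converts negatives into nonassessables whenever a
sample's own LOD exceeds the cut-off.
"""

from pathlib import Path

from mrdeval import Assay, MRDStatus, read_measurements, sweep_cutoffs, write_report
from mrdeval.reference_cohorts import sweep_cohort_ngs
from mrdeval.status_engine import PRESET_CUTOFFS

IN = Path("results/synthetic/measurements.csv")


def describe(sweep, assay):
    for cutoff in sorted((c.value for c in PRESET_CUTOFFS), reverse=True):
        t = sweep.counts[(assay, cutoff)]
        n = sweep.n_cohort[assay]
        print(
            f"  {assay.value} @ {cutoff:g}: "
            f"pos {t[MRDStatus.POSITIVE]}, neg {t[MRDStatus.NEGATIVE]}, "
            f"nonassessable {t[MRDStatus.NONASSESSABLE]} "
            f"({100 * t[MRDStatus.NONASSESSABLE] / n:.1f}%)"
        )


def main() -> None:
    cohort = read_measurements(IN)
    sweep = sweep_cutoffs(cohort, list(PRESET_CUTOFFS))
    write_report("results", sweep=sweep, config={"input": str(IN)})
    print("synthetic cohort:")
    for assay in Assay:
        describe(sweep, assay)

    ref = sweep_cutoffs(sweep_cohort_ngs(), list(PRESET_CUTOFFS))
    write_report("results/reference_sweep", sweep=ref, config={"input": "reconstruction"})
    print("published-marginal reconstruction (NGS only):")
    describe(ref, Assay.NGS)


if __name__ == "__main__":
    main()
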