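import pytest

from mrdeval import (
    Assay,
    AssayConstants,
    AssayMeasurement,
    MRDCutoff,
)


@pytest.fixture(scope="session")
def constants():
    return AssayConstants()


@pytest.fixture(scope="session")
def cutoff_1e5():
    return MRDCutoff(1e-5)


@pytest.fixture
def ngs_median_sample():
    """NGS sample at the cohort-median cell input with a detected clone."""
    return AssayMeasurement("p1", Assay.NGS, 1_100_000, 45)


@pytest.fixture
def mfc_median_sample():
    """MFC sample at the cohort-median event count with no aberrant cells."""
    return AssayMeasurement("p1", Assay.MFC, 5_000_000, 0)
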