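import numpy as np
import pandas as pd
import pytest

from kinoproteo.io_formats import PsmTable, SampleDesign
from kinoproteo.preprocess import preprocess_pipeline
from kinoproteo.synthetic import generate_psm_dataset


@pytest.fixture(scope="session")
def design11() -> SampleDesign:
    return SampleDesign.default_tmt11()


@pytest.fixture(scope="session")
def two_group_design() -> SampleDesign:
    """3 vs 3 two-group design (vehicle vs top dose)."""
    return SampleDesign(
        channels=("126", "127N", "127C", "128N", "128C", "129N"),
        groups=("vehicle",) * 3 + ("10uM",) * 3,
        doses=(0.0,) * 3 + (10.0,) * 3,
    )


@pytest.fixture(scope="session")
def small_dataset(design11):
    """300-protein synthetic dataset with planted effects (seed-fixed)."""
    return generate_psm_dataset(n_proteins=300, design=design11, seed=123)


@pytest.fixture(scope="session")
def imputed_small(small_dataset):
    psms, _ = small_dataset
    matrix, qc = preprocess_pipeline(psms, seed=5)
    return matrix, qc


def make_psm_frame(design, rows):
    """Build a PSM table from (psm_id, protein, fdr, intensities) tuples."""
    records = []
    for psm_id, protein, fdr, intens in rows:
        rec = {"psm_id": psm_id, "protein": protein, "psm_fdr": fdr}
        rec.update(dict(zip(design.channels, intens)))
        records.append(rec)
    return PsmTable(frame=pd.DataFrame(records), design=design)


@pytest.fixture
def tiny_psms(design11):
    ones = [100.0] * 11
    return make_psm_frame(design11, [
        ("p1", "PROT1", 0.001, ones),
        ("p2", "PROT1", 0.002, [200.0] * 11),
        ("p3", "PROT2", 0.005, [50.0] * 6 + [0.0] * 5),
    ])
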