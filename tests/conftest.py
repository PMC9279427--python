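import numpy as np
import pytest

import scexhaust as sx


@pytest.fixture(scope="session")
def small_config() -> sx.CohortConfig:
    """A desk-scale cohort: 7 patients x 60 cells, 300 genes."""
    return sx.CohortConfig(cells_per_patient=60, n_genes=600, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> sx.SyntheticCohort:
    return sx.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def qc_cohort(small_cohort):
    """QC-filtered counts, row-aligned annotation and normalized matrix."""
    counts, report = sx.qc_filter(small_cohort.counts)
    kept = set(counts.barcodes)
    ann = small_cohort.annotation[small_cohort.annotation["barcode"].isin(kept)]
    ann = ann.set_index("barcode").loc[counts.barcodes].reset_index()
    norm = sx.log_normalize(counts)
    return counts, ann, norm


@pytest.fixture(scope="session")
def cytokine_panel():
    panel, effects = sx.simulate_cytokine_panel(sx.PanelConfig(seed=13))
    return panel, effects


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
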