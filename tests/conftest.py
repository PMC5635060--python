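import numpy as np
import pandas as pd
import pytest

from cnvmet import (
    CohortConfig,
    generate_cohort,
    strong_signal_config,
)
from cnvmet.preprocess import tumor_fold_difference


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal validation cohort: balanced subtypes, no missingness."""
    return generate_cohort(strong_signal_config(seed=9))


@pytest.fixture(scope="session")
def strong_folds(strong_cohort):
    """Tumor-only fold-difference matrices of the strong cohort."""
    c = strong_cohort
    return {
        tag: tumor_fold_difference(getattr(c, tag), c.normal_ids).subset_samples(c.tumor_ids)
        for tag in ("cnv", "met", "exp")
    }


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-regime cohort with the study-like design (with MCAR)."""
    return generate_cohort(CohortConfig(seed=11, n_tumor=60, n_normal=20, n_genes=400))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
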