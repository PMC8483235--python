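import warnings

import numpy as np
import pandas as pd
import pytest

from endomix.synthetic import default_config, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast structural checks (~90 samples)."""
    return generate_cohort(default_config(n_patients=30, seed=42, sequencing_depth=5000))


@pytest.fixture(scope="session")
def medium_cohort():
    """Cohort large enough for community typing recovery (~250 samples),
    at the discovery-emulation sequencing depth."""
    return generate_cohort(default_config(n_patients=80, seed=7))


@pytest.fixture(scope="session")
def typing_cohort():
    """Study-scale cohort (~1,350 samples) for community-type recovery: the
    k-selection margin for the two small dominated clusters only stabilises
    near the size of the cohorts being emulated."""
    return generate_cohort(default_config(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Cohort with long visit series for the time-series modules."""
    cfg = default_config(n_patients=60, seed=11, visit_geometric_p=0.12, sequencing_depth=10_000)
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_tables(tmp_path):
    """Three-sample abundance + metadata TSV pair on disk."""
    abundance = pd.DataFrame(
        [[10, 5, 5], [2, 8, 10], [7, 7, 6]],
        index=["s1", "s2", "s3"],
        columns=["Haemophilus", "Veillonella", "Prevotella"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "patient_id": ["p1", "p1", "p2"],
            "visit_index": [1, 2, 1],
            "day_offset": [0, 35, 0],
            "visit_type": ["stable", "exacerbation", "stable"],
            "neutrophil_pct": [70.0, 50.0, 80.0],
            "eosinophil_pct": [1.0, 5.0, np.nan],
        }
    )
    a_path, m_path = tmp_path / "abundance.tsv", tmp_path / "metadata.tsv"
    abundance.to_csv(a_path, sep="\t", index_label="sample_id")
    meta.to_csv(m_path, sep="\t", index=False)
    return a_path, m_path
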