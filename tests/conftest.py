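import numpy as np
import pandas as pd
import pytest

from astrovar.simulate import null_config, generate_cohort
from astrovar.normalize import normalize_counts, size_factors_median_ratio
from astrovar.tables import FeatureTable


@pytest.fixture(scope="session")
def small_null_cohort():
    """A 300-analyte null cohort (no spikes), normalized; session-cached."""
    tables, samples, _ = generate_cohort(null_config(300, seed=42))
    table = tables["rna_counts"]
    normed = normalize_counts(table, size_factors_median_ratio(table))
    return normed, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_table():
    """A deterministic 5-analyte x 4-sample raw table with its sample sheet
    (two pre-flight, two post-flight samples)."""
    gen = np.random.default_rng(7)
    data = pd.DataFrame(
        gen.uniform(1.0, 100.0, size=(5, 4)),
        index=[f"A{i}" for i in range(5)],
        columns=["C001_L-3", "C002_L-3", "C001_R+1", "C002_R+1"],
    )
    samples = pd.DataFrame({
        "sample_id": data.columns,
        "subject_id": ["C001", "C002", "C001", "C002"],
        "timepoint_label": ["L-3", "L-3", "R+1", "R+1"],
        "day_offset": [-3, -3, 4, 4],
    })
    return FeatureTable(data, modality="rna_counts", normalized=True), samples
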