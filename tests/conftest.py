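import numpy as np
import pandas as pd
import pytest

from rfharmonize import StudyConfig, generate_study
from rfharmonize.qa_normalization import (apply_qa_filters,
                                          normalize_to_internal_standard)
from rfharmonize.response_factors import build_logrf_table


def small_config(**overrides) -> StudyConfig:
    """A reduced study design used throughout the unit tests."""
    base = dict(n_datasets=12, n_calibrants=20, n_suspects=12)
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config(), seed=11)


@pytest.fixture(scope="session")
def small_logrf(small_study):
    peaks, meta, pred, truth = small_study
    normalized = normalize_to_internal_standard(peaks)
    qa_report, filtered = apply_qa_filters(normalized)
    logrf, ranges = build_logrf_table(filtered)
    return logrf, ranges, qa_report, truth


def toy_peaks(rows):
    """Build a minimal valid peak DataFrame from (ds, comp, role, matrix,
    level, conc_molar, area) tuples."""
    df = pd.DataFrame(rows, columns=[
        "dataset_id", "compound_id", "role", "sample_matrix", "spike_level",
        "concentration", "peak_area"])
    df["ion_species"] = "[M+H]+"
    df["retention_time"] = np.nan
    df["detected"] = df["peak_area"].notna() & (df["peak_area"] > 0)
    return df
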