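import numpy as np
import pandas as pd
import pytest

import trflptools as t
from trflptools.io_profiles import build_profile_matrix


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (fixed seed) shared across tests."""
    spec = t.StudyDesignSpec(seed=20240901)
    peaks, meta, truth = t.generate_study(spec)
    return peaks, meta, truth


@pytest.fixture(scope="session")
def pot_matrix(study):
    peaks, meta, _ = study
    _, pots = build_profile_matrix(peaks, meta)
    return pots


@pytest.fixture(scope="session")
def extraction_matrix(study):
    peaks, meta, _ = study
    ext, _ = build_profile_matrix(peaks, meta)
    return ext


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_meta():
    """Balanced 2x2 design with 3 replicates per cell."""
    rows = []
    i = 0
    for season in ("spring", "summer"):
        for treatment in ("ambient", "ozone"):
            for r in range(3):
                rows.append((f"s{i}", f"p{i}", season, treatment, 1))
                i += 1
    return pd.DataFrame(rows, columns=["sample_id", "pot_id", "season", "treatment",
                                       "extraction_replicate"])
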