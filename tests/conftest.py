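import numpy as np
import pandas as pd
import pytest

from uropep import CohortDesign, PeakMatrix, SampleRecord, simulate_cohort, table2_models


def make_peak_matrix(rng, n_samples=6, n_peptides=8, zero_fraction=0.3):
    amp = rng.lognormal(mean=4.0, sigma=1.0, size=(n_samples, n_peptides))
    amp[rng.random(amp.shape) < zero_fraction] = 0.0
    amplitudes = pd.DataFrame(
        amp,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"P{j}" for j in range(n_peptides)],
    )
    info = pd.DataFrame(
        {
            "mass": rng.uniform(800, 3500, n_peptides),
            "ce_time": rng.uniform(19, 45, n_peptides),
        },
        index=amplitudes.columns,
    )
    return PeakMatrix(amplitudes, info)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    return make_peak_matrix(rng)


@pytest.fixture(scope="session")
def marker_models():
    return table2_models()


@pytest.fixture(scope="session")
def discovery_cohort(marker_models):
    """One Table-2-calibrated discovery-sized cohort with background nulls."""
    design = CohortDesign(seed=11, n_background_peptides=200)
    return simulate_cohort(design, marker_models)


def separable_cohort(n_per_class=10, gap=8.0, seed=5, n_features=4):
    """Two well-separated clouds wrapped as a PeakMatrix + records."""
    rng = np.random.default_rng(seed)
    cases = rng.lognormal(np.log(50.0 + gap * 10), 0.2, size=(n_per_class, n_features))
    ctrls = rng.lognormal(np.log(5.0), 0.2, size=(n_per_class, n_features))
    amp = np.vstack([cases, ctrls])
    ids = [f"S{i}" for i in range(2 * n_per_class)]
    amplitudes = pd.DataFrame(amp, index=ids, columns=[f"P{j}" for j in range(n_features)])
    info = pd.DataFrame(
        {"mass": 1000.0 + 10 * np.arange(n_features), "ce_time": 25.0 + np.arange(n_features)},
        index=amplitudes.columns,
    )
    records = [
        SampleRecord(sample_id=ids[i], group="HCC" if i < n_per_class else "LC",
                     age=60.0, sex="M")
        for i in range(2 * n_per_class)
    ]
    return PeakMatrix(amplitudes, info), records
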