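import numpy as np
import pandas as pd
import pytest

from thiolife import halflife as hl
from thiolife import normalization as nz
from thiolife import synthetic as sy


@pytest.fixture(scope="session")
def kinetics_small() -> pd.DataFrame:
    """2000 features with log-normal half-lives around the study median."""
    return sy.simulate_true_halflives(2000, 1998.0, 1.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_matrix(kinetics_small):
    """Noise- and contamination-free three-fraction array set."""
    return sy.simulate_fraction_intensities(
        kinetics_small,
        contam=sy.ContaminationModel.off(),
        noise=sy.NoiseModel.off(),
    )


@pytest.fixture(scope="session")
def noiseless_normalized(noiseless_matrix):
    matrix, truth = noiseless_matrix
    combined = nz.combine_replicates(matrix)
    ratios = nz.compute_raw_ratios(combined)
    normalized, fit, removal_log = nz.normalize_iterative(ratios)
    return normalized, fit, removal_log, truth


@pytest.fixture(scope="session")
def noiseless_halflives(noiseless_normalized):
    normalized, _, _, _ = noiseless_normalized
    return hl.estimate_halflives(normalized)


def make_ratios(n_raw, p_raw, prefix="F") -> pd.DataFrame:
    idx = pd.Index([f"{prefix}{i}" for i in range(len(n_raw))], name="feature_id")
    return pd.DataFrame(
        {"n_raw": np.asarray(n_raw, float), "p_raw": np.asarray(p_raw, float)},
        index=idx,
    )
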