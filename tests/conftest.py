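import numpy as np
import pytest

from ficss.spectra import SpectralDataset, split_calibration_prediction
from ficss.synthetic import Band, SyntheticScenario, generate, make_reference_scenario


def make_small_scenario(noise_sd: float = 0.004, n_samples: int = 48) -> SyntheticScenario:
    """Compact two-region scenario: 200 channels, 3 analytes, fast to run."""
    return SyntheticScenario(
        n_samples=n_samples,
        wn_start=4000.0,
        wn_stop=5600.0,
        wn_step=8.0,
        analyte_names=["A", "B", "C"],
        bands={
            "A": [Band(4400, 40, 1.0)],
            "B": [Band(4700, 40, 0.5)],
            "C": [Band(5200, 40, 0.8)],
        },
        conc_mean=np.array([1.0, 2.0, 1.5]),
        conc_sd=np.array([0.35, 0.7, 0.5]),
        conc_corr=np.array(
            [[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]]
        ),
        baseline_coeffs=(0.02, 0.01, 0.0),
        noise_sd=noise_sd,
        saturation=1.0,
        seed=4242,
    )


@pytest.fixture(scope="session")
def small_scenario():
    return make_small_scenario()


@pytest.fixture(scope="session")
def small_split_dataset(small_scenario):
    """Small generated dataset with a 2:1 calibration/prediction split."""
    ds, truth = generate(small_scenario, seed=11)
    ds = split_calibration_prediction(ds, ratio=2 / 3, seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def reference_scenario():
    return make_reference_scenario()


@pytest.fixture
def toy_dataset():
    """Hand-sized dataset for I/O and preprocessing tests."""
    rng = np.random.default_rng(7)
    wn = np.arange(4000.0, 4000.0 + 5 * 4, 4.0)
    return SpectralDataset(
        wavenumbers=wn,
        absorbance=rng.uniform(0.1, 1.0, size=(3, 5)),
        targets=rng.uniform(0.5, 2.0, size=(3, 2)),
        analyte_names=["EC", "ECG"],
        sample_ids=["s1", "s2", "s3"],
    )
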