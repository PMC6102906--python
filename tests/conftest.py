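import numpy as np
import pytest

from neurochair.p300_decoder import train_swlda
from neurochair.calibrate import generate_calibration_trials
from neurochair.synth_signals import ERPModel


@pytest.fixture(scope="session")
def default_erp():
    return ERPModel()


@pytest.fixture(scope="session")
def noisy_erp():
    # low-SNR user so trial accuracy is informative (not saturated at 1.0)
    return ERPModel(p300_amplitude=2.0, noise_std=20.0)


@pytest.fixture(scope="session")
def trained_model(default_erp):
    """SWLDA model trained once on a 36-trial synthetic session."""
    trials = generate_calibration_trials(36, default_erp, seed=101)
    X = [f for feats, _, _ in trials for f in feats]
    y = np.concatenate([lab for _, lab, _ in trials])
    return train_swlda(X, y)
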