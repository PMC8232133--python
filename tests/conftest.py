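import numpy as np
import pytest

import ccecg
from ccecg.training import StopAtValidationBac, TrainConfig, train

# Study-scale synthetic conditions: class mix mirrors the OHCA rhythm
# prevalence (~14% VF, ~36% OR, ~50% asystole), compressions around the
# 110/min metronome rate, weak artifacts (SNR >= -3 dB) for the easily
# separable training scenario.
EASY_SNR = (-3.0, 5.0)


@pytest.fixture(scope="session")
def easy_train_ds():
    return ccecg.make_dataset(
        {"VF": 82, "OR": 218, "ASYSTOLE": 300}, snr_distribution=EASY_SNR, seed=101
    )


@pytest.fixture(scope="session")
def easy_val_ds():
    return ccecg.make_dataset(
        {"VF": 41, "OR": 109, "ASYSTOLE": 150}, snr_distribution=EASY_SNR, seed=202
    )


@pytest.fixture(scope="session")
def tiny_train_ds():
    return ccecg.make_dataset(
        {"VF": 5, "OR": 10, "ASYSTOLE": 15}, snr_distribution=EASY_SNR, seed=303
    )


@pytest.fixture(scope="session")
def tiny_val_ds():
    return ccecg.make_dataset(
        {"VF": 3, "OR": 6, "ASYSTOLE": 9}, snr_distribution=EASY_SNR, seed=404
    )


@pytest.fixture(scope="session")
def trained_preset(easy_train_ds, easy_val_ds):
    """Preset model fitted on the easy scenario (seed 0), with its history."""
    model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=0)
    cfg = TrainConfig(max_epochs=100, early_stop_patience=99, seed=0)
    result = train(
        model, easy_train_ds, easy_val_ds, cfg,
        callbacks=[StopAtValidationBac(0.90)],
    )
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
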