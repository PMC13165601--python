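"""Shared fixtures: the tiny study profile and its trained artifacts.

The expensive artifacts (simulated measurement sets, the overfit tiny
model, the transfer-vs-scratch epoch counts) are session-scoped so the
learning-signal checks and the acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from quct.model import build_model
from quct.phantoms import make_dataset
from quct.profiles import get_profile
from quct.training import TrainConfig, simulate_pairs, train, transfer_learn

OVERFIT_LR = 1e-3
FINETUNE_LR = 3e-4              # gentler rate for adapting trained weights
OVERFIT_EPOCHS = 200
DICE_TARGET = 0.9
TRANSFER_THRESHOLD = 0.65       # validation Dice bar for the epoch race
SCRATCH_EPOCH_CAP = 40
TRANSFER_EPOCH_CAP = 12


@pytest.fixture(scope="session")
def tiny_profile():
    return get_profile("tiny")


@pytest.fixture(scope="session")
def tiny_phantoms(tiny_profile):
    return make_dataset("original", 8, 42, tiny_profile.disc_config)


@pytest.fixture(scope="session")
def clean_pairs(tiny_profile, tiny_phantoms):
    return simulate_pairs(tiny_profile, tiny_phantoms)


@pytest.fixture(scope="session")
def noisy_sets(tiny_profile, tiny_phantoms):
    """Noisy re-acquisitions of the same phantoms (the phase-2 protocol):
    fine-tuning data and validation carry independent noise realizations."""
    return (simulate_pairs(tiny_profile, tiny_phantoms, snr_db=20.0,
                           noise_seed=100),
            simulate_pairs(tiny_profile, tiny_phantoms, snr_db=20.0,
                           noise_seed=900))


@pytest.fixture(scope="session")
def overfit_run(tiny_profile, clean_pairs):
    """Train the tiny small-variant model until it memorizes 8 phantoms."""
    model = build_model(tiny_profile.model_config("small"), seed=0)
    cfg = TrainConfig(learning_rate=OVERFIT_LR, epochs=OVERFIT_EPOCHS,
                      batch_size=8, seed=0, patience=OVERFIT_EPOCHS,
                      stop_train_dice=DICE_TARGET)
    state, hist = train(model, clean_pairs, clean_pairs, cfg)
    return {"state": state, "history": hist, "model": model}


def _epochs_to_threshold(history, threshold, cap):
    for i, d in enumerate(history.val_dice):
        if d >= threshold:
            return i + 1
    return cap + 1


@pytest.fixture(scope="session")
def transfer_race(tiny_profile, overfit_run, noisy_sets):
    """Epochs to reach the validation-Dice bar on noisy data, per seed,
    for transfer-initialized vs from-scratch training."""
    noisy_tr, noisy_va = noisy_sets
    results = {}
    for seed in (1, 2, 3):
        m = build_model(tiny_profile.model_config("small"), seed=seed)
        cfg = TrainConfig(learning_rate=FINETUNE_LR, epochs=TRANSFER_EPOCH_CAP,
                          batch_size=8, seed=seed, patience=TRANSFER_EPOCH_CAP)
        _, h_t = transfer_learn(m, overfit_run["state"], noisy_tr, noisy_va,
                                cfg)
        m2 = build_model(tiny_profile.model_config("small"), seed=seed)
        cfg2 = TrainConfig(learning_rate=FINETUNE_LR, epochs=SCRATCH_EPOCH_CAP,
                           batch_size=8, seed=seed, patience=SCRATCH_EPOCH_CAP)
        _, h_s = train(m2, noisy_tr, noisy_va, cfg2)
        results[seed] = {
            "transfer": _epochs_to_threshold(h_t, TRANSFER_THRESHOLD,
                                             TRANSFER_EPOCH_CAP),
            "scratch": _epochs_to_threshold(h_s, TRANSFER_THRESHOLD,
                                            SCRATCH_EPOCH_CAP),
            "transfer_first_val": h_t.val_dice[0] if h_t.val_dice else None,
            "transfer_best_val": max(h_t.val_dice) if h_t.val_dice else None,
        }
    return results
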