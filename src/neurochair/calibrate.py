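"""Decoder calibration: synthesize a training session (five sets of 12
trials by default), train SWLDA, and report cross-validated accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .p300_decoder import (SWLDAModel, bandpass_filter,
                           extract_epochs_and_featurize, label_features,
                           score_and_classify, train_swlda)
from .synth_signals import ERPModel, make_stimulus_schedule, synth_eeg_session


@dataclass
class CalibrationReport:
    n_trials: int
    n_features: int
    n_selected: int
    cv_trial_accuracy: float
    chance_level: float


def generate_calibration_trials(
    n_trials: int = 60,
    erp: ERPModel | None = None,
    seed=None,
    n_sequences: int = 3,
    band=(2.0, 25.0),
    decim: int = 25,
):
    """Per-trial feature/label sets for a synthetic calibration session.

    Attended targets cycle through the six stimuli so classes stay balanced.
    """
    erp = erp or ERPModel()
    rng = np.random.default_rng(seed)
    trials = []
    for k in range(n_trials):
        attended = k % 6
        sched = make_stimulus_schedule(range(6), n_sequences=n_sequences,
                                       seed=int(rng.integers(2**31)),
                                       trial_id=k)
        rec = synth_eeg_session(sched, attended, erp,
                                seed=int(rng.integers(2**31)))
        feats = extract_epochs_and_featurize(bandpass_filter(rec, *band),
                                             sched, decim)
        trials.append((feats, label_features(feats, attended), attended))
    return trials


def calibrate(
    n_trials: int = 60,
    erp: ERPModel | None = None,
    seed=None,
    n_sequences: int = 3,
    band=(2.0, 25.0),
    decim: int = 25,
    p_enter: float = 0.10,
    p_remove: float = 0.15,
    max_features: int = 60,
    cv_folds: int = 5,
) -> tuple[SWLDAModel, CalibrationReport]:
    """Train the SWLDA decoder on synthetic data with k-fold trial CV."""
    trials = generate_calibration_trials(n_trials, erp, seed, n_sequences,
                                         band, decim)

    def fit(subset):
        X = [f for feats, _, _ in subset for f in feats]
        y = np.concatenate([lab for _, lab, _ in subset])
        return train_swlda(X, y, p_enter, p_remove, max_features)

    folds = np.array_split(np.arange(n_trials), cv_folds)
    hits = 0
    for fold in folds:
        train = [trials[i] for i in range(n_trials) if i not in fold]
        model_k = fit(train)
        for i in fold:
            feats, _, attended = trials[i]
            _, best = score_and_classify(model_k, feats, range(6))
            hits += int(best == attended)

    model = fit(trials)
    report = CalibrationReport(
        n_trials=n_trials,
        n_features=len(trials[0][0][0].values),
        n_selected=len(model.selected),
        cv_trial_accuracy=hits / n_trials,
        chance_level=1.0 / 6.0,
    )
    return model, report
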