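"""P300 decoding pipeline: band-pass filter, 800 ms epochs, block-mean
features, SWLDA training, epoch scoring and candidate-restricted trial
classification.

SWLDA (stepwise linear discriminant analysis) is ordinary stepwise
regression of the +1/-1 class label on the epoch features: a forward step
adds the candidate with the smallest partial-F p-value when it is below
``p_enter``; after every addition, backward steps remove any included
feature whose p-value exceeds ``p_remove``; selection stops when no move is
possible or ``max_features`` is reached.  The resulting weight vector scores
each epoch, scores are summed per stimulus across sequences, and the trial
output is the argmax over the *currently available* candidate set - with
fewer than six detected targets the argmax runs over fewer alternatives,
which is what improves online accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .synth_signals import EEGRecord, StimulusSchedule

EPOCH_SECONDS = 0.8
DEFAULT_BAND = (2.0, 25.0)
DEFAULT_DECIM = 25
DEFAULT_P_ENTER = 0.10
DEFAULT_P_REMOVE = 0.15
DEFAULT_MAX_FEATURES = 60


def bandpass_filter(record: EEGRecord, low: float, high: float, order: int = 4) -> EEGRecord:
    """Causal Butterworth band-pass, applied per channel.

    Causality matters online: the filtered value at time t must depend only
    on samples at or before t, so epochs can be cut as soon as 800 ms of
    signal has arrived.
    """
    nyq = record.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq} Hz"
        )
    sos = signal.butter(order, (low, high), btype="bandpass",
                        fs=record.sample_rate, output="sos")
    return EEGRecord(
        record.sample_rate,
        record.channel_names,
        signal.sosfilt(sos, record.samples, axis=-1),
        record.start_time,
    )


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    trial_id: int
    stimulus_index: int
    sequence_index: int


def extract_epochs_and_featurize(
    record: EEGRecord,
    schedule: StimulusSchedule,
    decim: int = DEFAULT_DECIM,
) -> list[FeatureVector]:
    """One feature vector per stimulus event.

    The 800 ms post-onset window is cut per event; features are the means of
    ``decim``-sample blocks, concatenated channel-major.  Consecutive epochs
    overlap (onsets every 0.2 s) and are used as-is.
    """
    fs = record.sample_rate
    n_epoch = int(round(EPOCH_SECONDS * fs))
    if decim < 1 or n_epoch % decim:
        raise ValueError(f"decim must divide the {n_epoch}-sample epoch")
    out = []
    for ev in schedule.events:
        i0 = int(round((ev.onset - record.start_time) * fs))
        if i0 < 0 or i0 + n_epoch > record.n_samples:
            raise ValueError(
                f"record too short for event at {ev.onset:.3f} s "
                f"(stimulus {ev.stimulus_index}, sequence {ev.sequence_index})"
            )
        epoch = record.samples[:, i0:i0 + n_epoch]
        feats = epoch.reshape(epoch.shape[0], -1, decim).mean(axis=2)
        out.append(FeatureVector(
            feats.ravel(), schedule.trial_id, ev.stimulus_index, ev.sequence_index,
        ))
    return out


def label_features(features, attended_index: int) -> np.ndarray:
    """+1 for attended-stimulus epochs, -1 otherwise."""
    return np.array([1.0 if f.stimulus_index == attended_index else -1.0
                     for f in features])


@dataclass
class SWLDAModel:
    selected: list[int]
    weights: np.ndarray
    intercept: float
    p_enter: float = DEFAULT_P_ENTER
    p_remove: float = DEFAULT_P_REMOVE
    max_features: int = DEFAULT_MAX_FEATURES

    def score(self, values: np.ndarray) -> float:
        return float(np.dot(self.weights, np.asarray(values)[self.selected])
                     + self.intercept)

    def to_json(self) -> str:
        return json.dumps({
            "selected": [int(i) for i in self.selected],
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
            "max_features": self.max_features,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SWLDAModel":
        d = json.loads(text)
        return cls(
            selected=list(d["selected"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            p_enter=d.get("p_enter", DEFAULT_P_ENTER),
            p_remove=d.get("p_remove", DEFAULT_P_REMOVE),
            max_features=d.get("max_features", DEFAULT_MAX_FEATURES),
        )


def _ols_rss(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept; returns (coef incl. intercept, RSS)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid), rank


def train_swlda(
    X,
    y,
    p_enter: float = DEFAULT_P_ENTER,
    p_remove: float = DEFAULT_P_REMOVE,
    max_features: int = DEFAULT_MAX_FEATURES,
) -> SWLDAModel:
    """Stepwise forward/backward feature selection + OLS weights.

    ``X`` may be an (n, p) array or a list of :class:`FeatureVector`;
    ``y`` holds +-1 labels (anything sign-coded works).
    """
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], FeatureVector):
        X = np.array([f.values for f in X])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")

    selected: list[int] = []
    seen: set[frozenset[int]] = set()
    while True:
        moved = False
        # forward: candidate with the smallest partial-F p-value
        if len(selected) < max_features:
            pvals = _forward_pvalues(X, y, selected)
            if pvals:
                j, pj = min(pvals.items(), key=lambda kv: (kv[1], kv[0]))
                if pj < p_enter:
                    selected.append(j)
                    moved = True
        # backward: repeatedly drop the worst included feature above p_remove
        while selected:
            pv = _included_pvalues(X, y, selected)
            j, pj = max(pv.items(), key=lambda kv: (kv[1], kv[0]))
            if pj > p_remove:
                selected.remove(j)
                moved = True
            else:
                break
        key = frozenset(selected)
        if not moved or key in seen:
            break
        seen.add(key)

    if selected:
        coef, _, _ = _ols_rss(X[:, selected], y)
        intercept, weights = float(coef[0]), coef[1:]
    else:
        intercept, weights = float(y.mean()), np.zeros(0)
    return SWLDAModel(selected, weights, intercept, p_enter, p_remove, max_features)


def _forward_pvalues(X, y, selected) -> dict[int, float]:
    """Partial-F p-value for adding each remaining candidate.

    Residualizes y and every candidate column against the current design in
    one multi-RHS least-squares solve; exactly collinear candidates (zero
    residual norm) are skipped.
    """
    n, p = X.shape
    rest = [j for j in range(p) if j not in selected]
    if not rest:
        return {}
    A = np.column_stack([np.ones(n), X[:, selected]])
    Q, _ = np.linalg.qr(A)
    ey = y - Q @ (Q.T @ y)
    rss0 = float(ey @ ey)
    E = X[:, rest] - Q @ (Q.T @ X[:, rest])
    dfe = n - (len(selected) + 1) - 1
    if dfe <= 0:
        return {}
    out = {}
    col_scale = np.linalg.norm(X[:, rest], axis=0) + 1e-300
    for k, j in enumerate(rest):
        e = E[:, k]
        ee = float(e @ e)
        if np.sqrt(ee) <= 1e-10 * col_scale[k]:
            continue  # exactly collinear with current design
        gain = (float(e @ y)) ** 2 / ee
        rss1 = max(rss0 - gain, 0.0)
        if rss1 <= 1e-12 * max(rss0, 1.0):
            out[j] = 0.0
        else:
            F = gain / (rss1 / dfe)
            out[j] = float(stats.f.sf(F, 1, dfe))
    return out


def _included_pvalues(X, y, selected) -> dict[int, float]:
    """Partial-F p-value of each currently included feature (drop test).

    Computed as the squared t-statistic of each coefficient in the single
    full fit, which equals the drop-one partial F exactly.
    """
    n = len(y)
    A = np.column_stack([np.ones(n), X[:, selected]])
    Q, R = np.linalg.qr(A)
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - A @ coef
    rss = float(resid @ resid)
    dfe = n - A.shape[1]
    if dfe <= 0 or rss <= 1e-12:
        return {j: 0.0 for j in selected}
    Rinv = np.linalg.inv(R)
    diag = np.sum(Rinv * Rinv, axis=1)  # diag of (A'A)^-1
    sigma2 = rss / dfe
    out = {}
    for k, j in enumerate(selected, start=1):
        se2 = sigma2 * diag[k]
        F = coef[k] ** 2 / se2 if se2 > 0 else np.inf
        out[j] = float(stats.f.sf(F, 1, dfe))
    return out


@dataclass(frozen=True)
class TrialScores:
    """Per-stimulus aggregated discriminant scores for one trial."""

    scores: dict[int, float]


def score_and_classify(model: SWLDAModel, features, candidate_set):
    """Score every epoch, sum per stimulus, argmax over the candidate set.

    Ties break toward the lowest stimulus index.  Restricting
    ``candidate_set`` to the detected targets implements the online rule
    that only displayed targets can be selected.
    """
    candidates = sorted(set(int(c) for c in candidate_set))
    if not candidates:
        raise ValueError("candidate_set must be non-empty")
    totals: dict[int, float] = {c: 0.0 for c in candidates}
    for f in features:
        if f.stimulus_index in totals:
            totals[f.stimulus_index] += model.score(f.values)
    best = max(candidates, key=lambda c: (totals[c], -c))
    return TrialScores(totals), best


def decode_trial(
    model: SWLDAModel,
    record: EEGRecord,
    schedule: StimulusSchedule,
    candidate_set=None,
    band=DEFAULT_BAND,
    decim: int = DEFAULT_DECIM,
):
    """Full online path for one trial: filter, featurize, classify."""
    filtered = bandpass_filter(record, *band)
    feats = extract_epochs_and_featurize(filtered, schedule, decim)
    cands = candidate_set if candidate_set is not None else schedule.active_set
    return score_and_classify(model, feats, cands)
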