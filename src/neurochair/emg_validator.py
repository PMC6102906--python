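"""Jaw-clench validation-command detector.

The single EMG channel is cut into contiguous 200 ms windows; each window is
band-pass filtered to 55-77 Hz and its variance compared against a fixed
threshold (1500) to yield a binary clench decision.  The last four decisions
sit in a FIFO queue (oldest first); the pattern [1, 1, 0, 0] - a sustained
clench followed by two quiet windows - fires the validation command, so the
command is confirmed two windows (0.4 s) after the clench ceases.  Requiring
cessation debounces the detector against signal fluctuations and prevents a
long clench from firing repeatedly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .synth_signals import EEGRecord


@dataclass(frozen=True)
class ValidatorConfig:
    window: float = 0.2
    band: tuple[float, float] = (55.0, 77.0)
    threshold: float = 1500.0
    pattern: tuple[int, ...] = (1, 1, 0, 0)  # oldest -> newest
    channel_name: str = "FCz"
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if len(self.pattern) != 4 or any(b not in (0, 1) for b in self.pattern):
            raise ValueError("pattern must be a binary 4-tuple")


@dataclass(frozen=True)
class ValidatorState:
    """FIFO of the last (up to 4) binary clench decisions, oldest first."""

    fifo: tuple[int, ...] = ()
    last_fire_time: float | None = None


def validator_step(
    state: ValidatorState,
    window_samples: np.ndarray,
    t_end: float,
    cfg: ValidatorConfig,
    sample_rate: float | None = None,
) -> tuple[ValidatorState, bool]:
    """Process one window; return the new state and whether the command fired.

    If ``sample_rate`` is given the window is band-pass filtered here
    (causally, within the window); otherwise the samples are assumed already
    filtered.  A fire empties the FIFO so one clench cannot fire twice on
    overlapping patterns.
    """
    w = np.asarray(window_samples, dtype=float)
    if sample_rate is not None:
        expect = int(round(cfg.window * sample_rate))
        if w.size != expect:
            raise ValueError(f"window has {w.size} samples, expected {expect}")
        sos = signal.butter(cfg.filter_order, cfg.band, btype="bandpass",
                            fs=sample_rate, output="sos")
        w = signal.sosfilt(sos, w)
    decision = 1 if float(np.var(w)) > cfg.threshold else 0
    fifo = (state.fifo + (decision,))[-len(cfg.pattern):]
    fired = fifo == tuple(cfg.pattern)
    if fired:
        return ValidatorState(fifo=(), last_fire_time=t_end), True
    return replace(state, fifo=fifo), False


def detect_validations(trace: EEGRecord, cfg: ValidatorConfig | None = None) -> list[float]:
    """Fire times for a whole single-channel trace.

    Windows are contiguous, non-overlapping and aligned to the trace start;
    the fire time is the end time of the window completing the pattern, so a
    clench ending on the window grid at time t fires at exactly t + 2
    windows = t + 0.4 s with the defaults.
    """
    cfg = cfg or ValidatorConfig()
    if trace.samples.shape[0] != 1:
        raise ValueError("validator expects a single-channel trace")
    fs = trace.sample_rate
    wlen = int(round(cfg.window * fs))
    if trace.n_samples < wlen:
        raise ValueError("trace shorter than one analysis window")
    x = trace.samples[0]
    state = ValidatorState()
    fires = []
    for k in range(trace.n_samples // wlen):
        seg = x[k * wlen:(k + 1) * wlen]
        t_end = trace.start_time + (k + 1) * wlen / fs
        state, fired = validator_step(state, seg, t_end, cfg, sample_rate=fs)
        if fired:
            fires.append(t_end)
    return fires
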