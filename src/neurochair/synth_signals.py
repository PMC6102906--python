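"""Seeded synthetic EEG and EMG generators.

The decoder and validator in this package assume specific statistical
structure in their inputs: an oddball stimulation stream in which the
attended stimulus elicits a P300-like potential ~300 ms after onset, and a
single EMG channel whose 55-77 Hz power jumps by orders of magnitude during
a jaw clench.  This module produces signals with exactly that structure,
bit-reproducibly under a seed, so the whole control stack can be exercised
closed-loop without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: 500 Hz amplifier rate used throughout.
DEFAULT_SAMPLE_RATE = 500.0

#: Signal electrodes, frontal to parietal.
DEFAULT_CHANNELS = (
    "F3", "F4", "FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4",
)

#: Oddball timing: 120 ms intensification, 80 ms inter-stimulus interval.
T_INTENSIFY = 0.12
T_INTERVAL = 0.08

#: Sequences aggregated per trial; 6 stimuli x 0.2 s x 3 = 3.6 s per trial.
DEFAULT_N_SEQUENCES = 3


@dataclass(frozen=True)
class StimEvent:
    onset: float
    stimulus_index: int
    sequence_index: int


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed sequence of stimulus intensifications for one selection trial.

    Within each sequence every stimulus in ``active_set`` is intensified
    exactly once, in seeded-random order; consecutive onsets are separated
    by ``t_intensify + t_interval``.
    """

    trial_id: int
    events: tuple[StimEvent, ...]
    n_sequences: int
    t_intensify: float = T_INTENSIFY
    t_interval: float = T_INTERVAL
    active_set: frozenset[int] = frozenset(range(6))

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony in seconds."""
        return self.t_intensify + self.t_interval

    @property
    def span(self) -> float:
        """Total trial span: one SOA per event."""
        return len(self.events) * self.soa

    @property
    def start(self) -> float:
        return self.events[0].onset if self.events else 0.0


@dataclass
class EEGRecord:
    """Multichannel signal block (channels x time), in microvolts."""

    sample_rate: float
    channel_names: tuple[str, ...]
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows for "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


def _default_channel_gains(channel_names) -> np.ndarray:
    """Gain profile peaking at Pz and decaying with list distance.

    Any smooth topography peaking over parietal cortex is adequate for a
    synthetic P300; the exact profile only sets per-channel SNR.
    """
    names = list(channel_names)
    peak = names.index("Pz") if "Pz" in names else len(names) - 1
    idx = np.arange(len(names))
    return np.clip(1.0 - 0.08 * np.abs(idx - peak), 0.2, 1.0)


@dataclass
class ERPModel:
    """Gaussian-bump P300 template plus stationary background noise."""

    p300_amplitude: float = 5.0
    p300_latency: float = 0.3
    p300_width: float = 0.06
    channel_gains: np.ndarray | None = None
    noise_std: float = 10.0
    noise_spectrum: str = "white"  # or "one_over_f"
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if min(self.p300_amplitude, self.p300_width, self.noise_std) < 0:
            raise ValueError("amplitude, width and noise_std must be >= 0")
        if self.channel_gains is None:
            self.channel_gains = _default_channel_gains(self.channel_names)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if len(self.channel_gains) != len(self.channel_names):
            raise ValueError("channel_gains length must equal channel count")
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise spectrum {self.noise_spectrum!r}")


@dataclass
class EMGModel:
    """Band-limited Gaussian EMG: quiet at rest, ~60x louder in-band when
    the jaw is clenched.

    Defaults are calibrated so that the variance of a 200 ms window of the
    55-77 Hz filtered signal stays below 100 at rest and above 1500 during a
    clench with very wide margin.  The window variance is chi-square-like
    with only ~2*B*T = 8.8 effective degrees of freedom, so the margins must
    absorb a heavy-tailed distribution: rest 5 uV gives mean variance ~17
    (99.99th pct < 100) and clench 300 uV gives mean ~6e4 (0.01th pct >
    1500).
    """

    rest_inband_std: float = 5.0
    clench_inband_std: float = 300.0
    band: tuple[float, float] = (55.0, 77.0)
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if not self.clench_inband_std > self.rest_inband_std > 0:
            raise ValueError("need clench_inband_std > rest_inband_std > 0")


def make_stimulus_schedule(
    active_set=range(6),
    n_sequences: int = DEFAULT_N_SEQUENCES,
    t_intensify: float = T_INTENSIFY,
    t_interval: float = T_INTERVAL,
    seed=None,
    trial_id: int = 0,
    start_time: float = 0.0,
) -> StimulusSchedule:
    """Randomly ordered intensification schedule for one trial.

    Each of ``n_sequences`` sequences intensifies every stimulus in
    ``active_set`` exactly once in an independent seeded-random permutation.
    """
    active = sorted(set(int(i) for i in active_set))
    if not active:
        raise ValueError("active_set must be non-empty")
    if any(i < 0 or i > 5 for i in active):
        raise ValueError("stimulus indices must lie in 0..5")
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    soa = t_intensify + t_interval
    events = []
    for s in range(n_sequences):
        order = rng.permutation(active)
        for k, stim in enumerate(order):
            onset = start_time + (s * len(active) + k) * soa
            events.append(StimEvent(onset, int(stim), s))
    return StimulusSchedule(
        trial_id=trial_id,
        events=tuple(events),
        n_sequences=n_sequences,
        t_intensify=t_intensify,
        t_interval=t_interval,
        active_set=frozenset(active),
    )


def _noise(shape, std, spectrum, rng) -> np.ndarray:
    if std == 0:
        return np.zeros(shape)
    w = rng.standard_normal(shape)
    if spectrum == "white":
        return std * w
    # 1/f amplitude shaping in the frequency domain, renormalised to std.
    f = np.fft.rfftfreq(shape[-1], d=1.0)
    scale = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, f[1])), 0.0)
    shaped = np.fft.irfft(np.fft.rfft(w, axis=-1) * scale, n=shape[-1], axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return std * shaped / sd


def synth_eeg_session(
    schedule: StimulusSchedule,
    attended_index: int,
    erp: ERPModel | None = None,
    seed=None,
) -> EEGRecord:
    """Simulated multichannel EEG for one oddball trial.

    Epochs following onsets of ``attended_index`` contain the P300 bump
    (scaled per channel by ``erp.channel_gains``); all other epochs contain
    background noise only.  The record covers the schedule span plus an
    0.8 s tail so the last epoch is complete.
    """
    erp = erp or ERPModel()
    if attended_index not in schedule.active_set:
        raise ValueError(
            f"attended_index {attended_index} not in active set "
            f"{sorted(schedule.active_set)}"
        )
    rng = np.random.default_rng(seed)
    fs = DEFAULT_SAMPLE_RATE
    n_ch = len(erp.channel_names)
    start = schedule.start
    n = int(round((schedule.span + 0.8) * fs))
    x = _noise((n_ch, n), erp.noise_std, erp.noise_spectrum, rng)

    t = np.arange(n) / fs  # relative to record start
    for ev in schedule.events:
        if ev.stimulus_index != attended_index:
            continue
        centre = (ev.onset - start) + erp.p300_latency
        if erp.p300_width > 0:
            bump = erp.p300_amplitude * np.exp(
                -0.5 * ((t - centre) / erp.p300_width) ** 2
            )
        else:
            bump = np.where(t == centre, erp.p300_amplitude, 0.0)
        x += erp.channel_gains[:, None] * bump[None, :]
    return EEGRecord(fs, tuple(erp.channel_names), x, start_time=start)


def _bandlimited_noise(n, band, fs, std, rng) -> np.ndarray:
    """Gaussian noise confined to ``band`` with exact in-band std."""
    if std == 0:
        return np.zeros(n)
    pad = 1000
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    sd = x.std()
    return x * (std / sd) if sd > 0 else x


def synth_emg_trace(
    duration: float,
    clench_intervals=(),
    model: EMGModel | None = None,
    seed=None,
) -> EEGRecord:
    """Single-channel EMG with resting noise and jaw-clench bursts.

    Clench intervals are rectangular amplitude envelopes: the in-band std is
    ``rest_inband_std`` outside every interval and rises to (approximately)
    ``clench_inband_std`` inside, with no energy leakage outside the
    interval boundaries.
    """
    model = model or EMGModel()
    fs = model.sample_rate
    intervals = sorted((float(a), float(b)) for a, b in clench_intervals)
    for a, b in intervals:
        if not (0 <= a < b <= duration):
            raise ValueError(f"clench interval ({a}, {b}) outside [0, {duration}]")
    for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
        if a1 < b0:
            raise ValueError(f"overlapping clench intervals ({a0},{b0}) and ({a1},{b1})")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = _bandlimited_noise(n, model.band, fs, model.rest_inband_std, rng)
    if intervals:
        burst_std = np.sqrt(
            max(model.clench_inband_std**2 - model.rest_inband_std**2, 0.0)
        )
        burst = _bandlimited_noise(n, model.band, fs, burst_std, rng)
        t = np.arange(n) / fs
        env = np.zeros(n)
        for a, b in intervals:
            env[(t >= a) & (t < b)] = 1.0
        x = x + env * burst
    return EEGRecord(fs, ("FCz",), x[None, :])
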