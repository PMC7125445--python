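"""Synthetic self-paced movement sessions with known ground truth.

Each session emulates a seated subject performing self-paced ballistic ankle
dorsiflexions: multichannel EEG sampled together with one surface EMG
channel.  Every trial contributes

* a movement-related cortical potential (MRCP): a slow negative deflection
  on the EEG that ramps down over ``mrcp_duration`` seconds, reaches its
  trough at movement onset, and rebounds to baseline shortly after.  The
  deflection is focused on one electrode (``focus_channel``, Cz by default)
  and attenuated over the rest of the scalp by per-channel spread weights;
* an EMG burst spanning movement onset to offset, riding on a quiet
  baseline, which is what real recordings are labelled from.

Idle gaps between consecutive trials are drawn uniformly from
``idle_range`` (3-7 s by default, as in a self-paced protocol).  Background
EEG noise is white or 1/f ("pink"); ``noise_sd = 0`` produces a fully
deterministic, noise-free session (EMG baseline included) so that exact
recovery can be asserted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal.windows import hann

from .montage import CHANNELS_1020, Montage, default_montage

__all__ = [
    "SynthConfig",
    "Session",
    "generate_session",
    "generate_cohort",
    "detect_emg_events",
    "pink_noise",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic session generator.

    All amplitudes are dimensionless (the pipeline z-normalizes epochs, so
    only ratios matter).  ``spatial_spread`` maps channel name -> weight in
    [0, 1]; when omitted it defaults to 1.0 at the focus channel, 0.6 at its
    montage neighbours and 0.3 elsewhere.
    """

    n_channels: int = 19
    channel_names: Sequence[str] = field(default_factory=lambda: list(CHANNELS_1020))
    fs: float = 1024.0
    n_trials: int = 30
    idle_range: tuple[float, float] = (3.0, 7.0)
    mrcp_amplitude: float = 2.0
    mrcp_duration: float = 2.0
    mrcp_shape: Literal["ramp", "halfcos"] = "ramp"
    rebound_duration: float = 0.5
    focus_channel: str = "Cz"
    spatial_spread: dict[str, float] | None = None
    noise_model: Literal["white", "pink"] = "pink"
    noise_sd: float = 0.5
    emg_burst_duration: float = 0.4
    emg_burst_amplitude: float = 1.0
    emg_baseline_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 < self.idle_range[0] <= self.idle_range[1]):
            raise ValueError("idle_range must satisfy 0 < min <= max")
        if self.mrcp_duration <= 0:
            raise ValueError("mrcp_duration must be positive")
        if self.n_channels != len(self.channel_names):
            raise ValueError("n_channels must match channel_names length")
        if self.focus_channel not in self.channel_names:
            raise ValueError(f"focus_channel {self.focus_channel!r} not in montage")
        # Shorter gaps would overlay one trial's pre-movement ramp onto the
        # previous trial's rebound; trials closer than the 4 s labelling rule
        # are instead dropped later, at segmentation.
        if self.idle_range[0] < self.mrcp_duration + self.rebound_duration:
            raise ValueError(
                "idle_range min must be >= mrcp_duration + rebound_duration "
                "(consecutive MRCP waveforms would overlap)"
            )
        weights = self.spread_weights()
        for ch, w in weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"spread weight for {ch} outside [0, 1]")
        if weights[self.focus_channel] != 1.0:
            raise ValueError("spread weight at focus_channel must be 1.0")

    def spread_weights(self, montage: Montage | None = None) -> dict[str, float]:
        """Per-channel MRCP attenuation weights (focus 1.0 / neighbours 0.6 / rest 0.3)."""
        if self.spatial_spread is not None:
            return {ch: self.spatial_spread.get(ch, 0.0) for ch in self.channel_names}
        if montage is None and list(self.channel_names) == CHANNELS_1020:
            montage = default_montage()
        nbrs = (
            montage.neighbors.get(self.focus_channel, frozenset())
            if montage is not None
            else frozenset()
        )
        out = {}
        for ch in self.channel_names:
            if ch == self.focus_channel:
                out[ch] = 1.0
            elif ch in nbrs:
                out[ch] = 0.6
            else:
                out[ch] = 0.3
        return out


@dataclass
class Session:
    """One recording run: EEG + EMG + movement events.

    ``events`` holds (onset_sample, offset_sample) pairs, sorted and
    non-overlapping; for synthetic data ``ground_truth`` is identical.
    """

    eeg: np.ndarray  # (n_channels, n_samples)
    emg: np.ndarray  # (n_samples,)
    fs: float
    channel_names: list[str]
    events: list[tuple[int, int]]
    ground_truth: list[tuple[int, int]] = field(default_factory=list)
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(self.channel_names):
            raise ValueError("eeg must be (n_channels, n_samples) matching channel_names")
        prev_off = -1
        for on, off in self.events:
            if not on < off:
                raise ValueError("each event must have onset < offset")
            if on <= prev_off:
                raise ValueError("events must be sorted and non-overlapping")
            prev_off = off

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _mrcp_waveform(cfg: SynthConfig) -> np.ndarray:
    """Negativity of length round((mrcp_duration + rebound) * fs), trough at onset."""
    n_ramp = int(round(cfg.mrcp_duration * cfg.fs))
    n_reb = int(round(cfg.rebound_duration * cfg.fs))
    t = np.arange(n_ramp) / max(n_ramp, 1)
    if cfg.mrcp_shape == "ramp":
        ramp = -cfg.mrcp_amplitude * t
    elif cfg.mrcp_shape == "halfcos":
        ramp = -cfg.mrcp_amplitude * 0.5 * (1.0 - np.cos(np.pi * t))
    else:
        raise ValueError(f"unknown mrcp_shape {cfg.mrcp_shape!r}")
    if n_reb > 0:
        u = np.arange(1, n_reb + 1) / n_reb
        rebound = -cfg.mrcp_amplitude * (1.0 - u)
    else:
        rebound = np.empty(0)
    return np.concatenate([ramp, rebound])


def _emg_burst(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Rectified-noise burst under a floored Hann envelope.

    The envelope is clipped below at 20% and the noise carrier at 25% of its
    scale so that every sample of the burst has strictly positive amplitude:
    burst edges then coincide with the labelled onset/offset to the sample,
    which is what makes noise-free event recovery exact.
    """
    env = np.maximum(hann(n), 0.2)
    carrier = 0.25 + 0.75 * np.abs(rng.standard_normal(n))
    return amplitude * env * carrier


def generate_session(cfg: SynthConfig, subject_id: str = "S0") -> Session:
    """Generate one synthetic session; deterministic for a fixed ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n_burst = int(round(cfg.emg_burst_duration * fs))
    n_pre = int(round(cfg.mrcp_duration * fs))

    # Event layout: first onset after one idle gap (>= ramp length), then
    # gap ~ U(idle_range) between each offset and the next onset.
    gaps = rng.uniform(cfg.idle_range[0], cfg.idle_range[1], size=cfg.n_trials)
    events: list[tuple[int, int]] = []
    onset = max(int(round(gaps[0] * fs)), n_pre)
    for i in range(cfg.n_trials):
        if i > 0:
            onset = events[-1][1] + int(round(gaps[i] * fs))
        events.append((onset, onset + n_burst))
    tail = int(round((cfg.idle_range[1] + 2.5) * fs))
    n_samples = events[-1][1] + tail

    names = list(cfg.channel_names)
    if cfg.noise_sd > 0:
        if cfg.noise_model == "white":
            eeg = cfg.noise_sd * rng.standard_normal((cfg.n_channels, n_samples))
        elif cfg.noise_model == "pink":
            eeg = np.stack(
                [cfg.noise_sd * pink_noise(n_samples, rng) for _ in range(cfg.n_channels)]
            )
        else:
            raise ValueError(f"unknown noise_model {cfg.noise_model!r}")
    else:
        eeg = np.zeros((cfg.n_channels, n_samples))

    wave = _mrcp_waveform(cfg)
    weights = np.array([cfg.spread_weights()[ch] for ch in names])
    for on, _off in events:
        a = on - n_pre
        b = a + wave.size
        seg = wave[max(0, -a):]
        a = max(a, 0)
        eeg[:, a:b] += weights[:, None] * seg[: b - a]

    emg = np.zeros(n_samples)
    if cfg.noise_sd > 0 and cfg.emg_baseline_sd > 0:
        emg += cfg.emg_baseline_sd * rng.standard_normal(n_samples)
    for on, off in events:
        emg[on:off] += _emg_burst(off - on, cfg.emg_burst_amplitude, rng)

    return Session(
        eeg=eeg,
        emg=emg,
        fs=fs,
        channel_names=names,
        events=list(events),
        ground_truth=list(events),
        subject_id=subject_id,
    )


def generate_cohort(cfg: SynthConfig, n_subjects: int) -> list[Session]:
    """Generate ``n_subjects`` sessions with per-subject seeds spawned from cfg.seed."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_subjects)]
    return [
        generate_session(replace(cfg, seed=seeds[i]), subject_id=f"S{i + 1}")
        for i in range(n_subjects)
    ]


def detect_emg_events(
    emg: np.ndarray,
    fs: float,
    threshold: float,
    min_gap_s: float = 0.5,
    smooth_s: float = 0.05,
) -> list[tuple[int, int]]:
    """Amplitude-threshold burst detection on a single EMG channel.

    The signal is rectified and smoothed with a ``smooth_s``-second moving
    average; maximal runs above ``threshold`` become candidate bursts, runs
    closer than ``min_gap_s`` are merged, and each burst edge is then
    refined outward/inward to the extent of contiguous raw rectified
    samples above threshold (so a clean burst is recovered to the sample).

    Returns a possibly empty list of (onset_sample, offset_sample) pairs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.abs(np.asarray(emg, dtype=float))
    w = max(int(round(smooth_s * fs)), 1)
    smooth = np.convolve(x, np.ones(w) / w, mode="same")
    above = smooth > threshold
    if not above.any():
        return []
    # maximal runs of the smoothed detection function
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size)
    runs = list(zip(starts, ends))
    # merge runs separated by less than min_gap_s
    min_gap = int(round(min_gap_s * fs))
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < min_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    # refine edges on the raw rectified signal
    raw_above = x > threshold
    refined = []
    for s, e in merged:
        lo = s + int(np.argmax(raw_above[s:e])) if raw_above[s:e].any() else s
        while lo > 0 and raw_above[lo - 1]:
            lo -= 1
        hi = e
        while hi > lo and not raw_above[hi - 1]:
            hi -= 1
        while hi < x.size and raw_above[hi]:
            hi += 1
        if hi > lo:
            refined.append((lo, hi))
    return refined
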