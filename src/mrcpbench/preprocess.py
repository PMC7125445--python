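"""Band-pass decomposition, epoching, normalization and stratified splitting.

The analysis decomposes the sub-5 Hz range, where the movement-related
cortical potential lives, into five 1 Hz bands ([0.01-1], [1-2], [2-3],
[3-4], [4-5] Hz), each applied as a *causal* second-order Butterworth
band-pass (forward filtering only — the pipeline targets asynchronous,
i.e. real-time-capable, detection, so zero-phase filtering is off-limits).

Epochs are 2-second windows: an MRCP epoch ends at movement onset, a
non-MRCP epoch starts at movement offset.  Trials whose onset follows the
previous offset by less than 4 s are dropped entirely, mirroring the
labelling rule used for self-paced recordings.  Every epoch is z-normalized
per channel (population standard deviation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .synth import Session

__all__ = [
    "BandSpec",
    "ANALYSIS_BANDS",
    "Epoch",
    "SplitDataset",
    "FilterDesignError",
    "DegenerateEpochError",
    "design_sos",
    "bandpass",
    "apply_notch",
    "segment",
    "znormalize",
    "znormalize_all",
    "decimate_epochs",
    "stratified_split",
]

logger = logging.getLogger(__name__)

MRCP = "MRCP"
NON_MRCP = "NON_MRCP"


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its filter convention (2nd-order causal Butterworth)."""

    lo: float
    hi: float
    order: int = 2
    kind: str = "bandpass"
    causal: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("band must satisfy 0 < lo < hi")
        if self.kind == "bandpass" and self.order != 2:
            raise ValueError("analysis bands use a fixed 2nd-order filter")

    @property
    def name(self) -> str:
        fmt = lambda v: f"{v:g}"
        return f"{fmt(self.lo)}-{fmt(self.hi)}"


#: The five 1 Hz analysis bands covering the MRCP range.
ANALYSIS_BANDS = [
    BandSpec(0.01, 1.0),
    BandSpec(1.0, 2.0),
    BandSpec(2.0, 3.0),
    BandSpec(3.0, 4.0),
    BandSpec(4.0, 5.0),
]


def band_by_name(name: str) -> BandSpec:
    for b in ANALYSIS_BANDS:
        if b.name == name:
            return b
    lo, hi = (float(v) for v in name.split("-"))
    return BandSpec(lo, hi)


@dataclass
class Epoch:
    """A 2-second (z-normalizable) segment with an MRCP / non-MRCP label."""

    data: np.ndarray  # (n_channels, n_samples); single-channel epochs are (1, n)
    label: str
    fs: float
    subject_id: str = "S0"
    band: BandSpec | None = None
    source_event: int = -1
    channel_names: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def series(self) -> np.ndarray:
        """The epoch as a 1-D vector (requires a single channel)."""
        if self.data.shape[0] != 1:
            raise ValueError("series() requires a single-channel epoch")
        return self.data[0]


@dataclass
class SplitDataset:
    train: list[Epoch]
    test: list[Epoch]
    ratio: tuple[float, float] = (2 / 3, 1 / 3)
    seed: int = 0


class FilterDesignError(ValueError):
    """Raised when a requested band yields unstable filter coefficients."""


class DegenerateEpochError(ValueError):
    """Raised when an epoch has a constant channel and cannot be z-normalized."""


def design_sos(band: BandSpec, fs: float, cascade: bool = False) -> np.ndarray:
    """Second-order-section coefficients for ``band`` at sampling rate ``fs``.

    ``cascade=True`` builds the equivalent high-pass-at-lo + low-pass-at-hi
    cascade, which is numerically safer for extreme lo/hi ratios such as
    the [0.01-1] Hz band at high sampling rates.
    """
    if band.hi >= fs / 2:
        raise ValueError(f"band edge {band.hi} Hz must be below Nyquist ({fs / 2} Hz)")
    if cascade:
        sos = np.vstack(
            [
                signal.butter(band.order, band.lo, btype="highpass", fs=fs, output="sos"),
                signal.butter(band.order, band.hi, btype="lowpass", fs=fs, output="sos"),
            ]
        )
    else:
        sos = signal.butter(
            band.order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos"
        )
    for sec in sos:
        poles = np.roots(sec[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise FilterDesignError(
                f"unstable filter for band {band.name} Hz at fs={fs} Hz; "
                "use design_sos(..., cascade=True) (high-pass + low-pass cascade)"
            )
    return sos


def bandpass(session: Session, band: BandSpec, cascade: bool = False) -> Session:
    """Causal band-pass of every EEG channel; EMG is left untouched."""
    sos = design_sos(band, session.fs, cascade=cascade)
    eeg = signal.sosfilt(sos, session.eeg, axis=1)
    return Session(
        eeg=np.asarray(eeg),
        emg=session.emg,
        fs=session.fs,
        channel_names=list(session.channel_names),
        events=list(session.events),
        ground_truth=list(session.ground_truth),
        subject_id=session.subject_id,
    )


def apply_notch(session: Session, lo: float = 49.0, hi: float = 51.0) -> Session:
    """49-51 Hz mains band-stop for raw recordings (not needed for synthetic data)."""
    sos = signal.butter(2, [lo, hi], btype="bandstop", fs=session.fs, output="sos")
    eeg = signal.sosfilt(sos, session.eeg, axis=1)
    return Session(
        eeg=np.asarray(eeg),
        emg=session.emg,
        fs=session.fs,
        channel_names=list(session.channel_names),
        events=list(session.events),
        ground_truth=list(session.ground_truth),
        subject_id=session.subject_id,
    )


def segment(
    session: Session, window_s: float = 2.0, min_sep_s: float = 4.0
) -> list[Epoch]:
    """Extract MRCP / non-MRCP epochs around each retained movement event.

    Per retained trial: one MRCP epoch on the half-open window
    [onset - window_s, onset) and one non-MRCP epoch on [offset,
    offset + window_s).  A trial whose onset is less than ``min_sep_s``
    after the previous trial's offset is dropped entirely; an epoch that
    would extend outside the recording is dropped individually.  All drops
    are logged with their reason.
    """
    n_win = int(round(window_s * session.fs))
    min_sep = int(round(min_sep_s * session.fs))
    epochs: list[Epoch] = []
    prev_offset: int | None = None
    for i, (onset, offset) in enumerate(session.events):
        if prev_offset is not None and onset - prev_offset < min_sep:
            logger.info(
                "drop trial %d (%s): onset %.3fs after previous offset < %.1fs",
                i, session.subject_id, (onset - prev_offset) / session.fs, min_sep_s,
            )
            prev_offset = offset
            continue
        prev_offset = offset
        a = onset - n_win
        if a >= 0:
            epochs.append(
                Epoch(
                    data=session.eeg[:, a:onset].copy(),
                    label=MRCP,
                    fs=session.fs,
                    subject_id=session.subject_id,
                    source_event=i,
                    channel_names=list(session.channel_names),
                )
            )
        else:
            logger.info("drop MRCP epoch of trial %d: window precedes recording", i)
        b = offset + n_win
        if b <= session.n_samples:
            epochs.append(
                Epoch(
                    data=session.eeg[:, offset:b].copy(),
                    label=NON_MRCP,
                    fs=session.fs,
                    subject_id=session.subject_id,
                    source_event=i,
                    channel_names=list(session.channel_names),
                )
            )
        else:
            logger.info("drop non-MRCP epoch of trial %d: window exceeds recording", i)
    return epochs


def znormalize(epoch: Epoch) -> Epoch:
    """Zero-mean, unit-(population)-variance per channel."""
    mean = epoch.data.mean(axis=1, keepdims=True)
    sd = epoch.data.std(axis=1, keepdims=True)  # population (1/N) convention
    if np.any(sd < 1e-12):
        raise DegenerateEpochError(
            f"constant channel in epoch (subject {epoch.subject_id}, "
            f"event {epoch.source_event})"
        )
    out = (epoch.data - mean) / sd
    return Epoch(
        data=out,
        label=epoch.label,
        fs=epoch.fs,
        subject_id=epoch.subject_id,
        band=epoch.band,
        source_event=epoch.source_event,
        channel_names=list(epoch.channel_names),
    )


def znormalize_all(epochs: Sequence[Epoch]) -> list[Epoch]:
    """z-normalize a batch, dropping (and logging) degenerate epochs."""
    out = []
    for ep in epochs:
        try:
            out.append(znormalize(ep))
        except DegenerateEpochError as exc:
            logger.warning("drop epoch: %s", exc)
    return out


def decimate_epochs(epochs: Sequence[Epoch], target_fs: float) -> list[Epoch]:
    """Anti-aliased decimation of every epoch to ``target_fs`` (must divide fs)."""
    out = []
    for ep in epochs:
        if ep.fs == target_fs:
            out.append(ep)
            continue
        q = ep.fs / target_fs
        if abs(q - round(q)) > 1e-9:
            raise ValueError(f"target_fs {target_fs} must divide epoch fs {ep.fs}")
        data = signal.decimate(ep.data, int(round(q)), ftype="fir", axis=1)
        out.append(
            Epoch(
                data=np.asarray(data),
                label=ep.label,
                fs=target_fs,
                subject_id=ep.subject_id,
                band=ep.band,
                source_event=ep.source_event,
                channel_names=list(ep.channel_names),
            )
        )
    return out


def stratified_split(
    epochs: Sequence[Epoch],
    ratio: tuple[float, float] = (2 / 3, 1 / 3),
    seed: int = 0,
) -> SplitDataset:
    """Shuffle and split per class: floor(n_class * ratio[0]) to train, rest to test."""
    if not math.isclose(ratio[0] + ratio[1], 1.0):
        raise ValueError("ratio must sum to 1")
    by_class: dict[str, list[int]] = {}
    for i, ep in enumerate(epochs):
        by_class.setdefault(ep.label, []).append(i)
    if set(by_class) != {MRCP, NON_MRCP}:
        raise ValueError(f"both classes required, got {sorted(by_class)}")
    for lbl, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"need >= 2 epochs of class {lbl}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lbl in (MRCP, NON_MRCP):
        idx = np.array(by_class[lbl])
        rng.shuffle(idx)
        n_train = int(math.floor(len(idx) * ratio[0]))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return SplitDataset(
        train=[epochs[i] for i in sorted(train_idx)],
        test=[epochs[i] for i in sorted(test_idx)],
        ratio=ratio,
        seed=seed,
    )
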