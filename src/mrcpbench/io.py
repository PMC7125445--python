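"""Session serialization: EDF, an NPZ columnar container, and event tables.

Three interchange formats are supported:

* **NPZ** — the native container: a single ``numpy.savez`` archive with
  documented keys (``eeg``, ``emg``, ``fs``, ``channel_names``, ``events``,
  ``ground_truth``, ``subject_id``); lossless round trip.
* **EDF** (European Data Format) — for exchange with standard EEG tooling.
  Reading goes through :func:`mne.io.read_raw_edf`; writing uses a minimal
  EDF writer (16-bit samples, 1-second data records, per-channel physical
  scaling), so round trips are exact only up to the format's quantization.
  Events travel in a sidecar tab-separated file.
* **TSV** event annotations — two integer columns, ``onset_sample`` and
  ``offset_sample``.

A plain delimited reader (:func:`read_delimited_session`) ingests columnar
text exports where each column is one channel.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Session

__all__ = [
    "save_npz",
    "load_npz",
    "save_events_tsv",
    "load_events_tsv",
    "save_edf",
    "load_edf",
    "read_delimited_session",
]


# ---------------------------------------------------------------------------
# NPZ container
# ---------------------------------------------------------------------------

def save_npz(session: Session, path: str | Path) -> None:
    """Write a session to a ``.npz`` archive (lossless)."""
    np.savez(
        path,
        eeg=session.eeg,
        emg=session.emg,
        fs=np.array(session.fs),
        channel_names=np.array(session.channel_names),
        events=np.array(session.events, dtype=np.int64).reshape(-1, 2),
        ground_truth=np.array(session.ground_truth, dtype=np.int64).reshape(-1, 2),
        subject_id=np.array(session.subject_id),
    )


def load_npz(path: str | Path) -> Session:
    with np.load(path, allow_pickle=False) as z:
        return Session(
            eeg=z["eeg"],
            emg=z["emg"],
            fs=float(z["fs"]),
            channel_names=[str(c) for c in z["channel_names"]],
            events=[tuple(int(v) for v in row) for row in z["events"]],
            ground_truth=[tuple(int(v) for v in row) for row in z["ground_truth"]],
            subject_id=str(z["subject_id"]),
        )


# ---------------------------------------------------------------------------
# event annotations
# ---------------------------------------------------------------------------

def save_events_tsv(events: list[tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(events, columns=["onset_sample", "offset_sample"]).to_csv(
        path, sep="\t", index=False
    )


def load_events_tsv(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (int(r.onset_sample), int(r.offset_sample)) for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def save_edf(session: Session, path: str | Path) -> None:
    """Write EEG + EMG to a 16-bit EDF file with 1-second data records.

    The last record is zero-padded when the session length is not a whole
    number of seconds.  Event annotations are not embedded; use
    :func:`save_events_tsv` alongside.
    """
    fs = session.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    signals = np.vstack([session.eeg, session.emg[None, :]]).astype(float)
    labels = [f"EEG {ch}" for ch in session.channel_names] + ["EMG TA"]
    ns = signals.shape[0]
    n_rec = int(np.ceil(signals.shape[1] / spr))
    padded = np.zeros((ns, n_rec * spr))
    padded[:, : signals.shape[1]] = signals

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _edf_field("0", 8)                      # version
    header += _edf_field(f"subject {session.subject_id}", 80)
    header += _edf_field("synthetic self-paced motor session", 80)
    header += _edf_field("01.01.20", 8)               # start date
    header += _edf_field("00.00.00", 8)               # start time
    header += _edf_field(str(256 * (ns + 1)), 8)      # header bytes
    header += _edf_field("", 44)                      # reserved
    header += _edf_field(str(n_rec), 8)
    header += _edf_field("1", 8)                      # record duration (s)
    header += _edf_field(str(ns), 4)
    for lab in labels:
        header += _edf_field(lab, 16)
    header += b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_edf_field("uV", 8) for _ in range(ns))
    header += b"".join(_edf_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(ns))
    header += b"".join(_edf_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(ns))
    header += b"".join(_edf_field(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_edf_field(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))      # prefiltering
    header += b"".join(_edf_field(str(spr), 8) for _ in range(ns))
    header += b"".join(_edf_field("", 32) for _ in range(ns))      # reserved

    # physical -> digital mapping per channel (EDF rounds to int16)
    pmin = padded.min(axis=1)
    pmin[flat] -= 0.0
    gains = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = padded[:, r * spr : (r + 1) * spr]
            for i in range(ns):
                dig = np.round((chunk[i] - phys_min[i]) * gains[i] + dig_min)
                fh.write(struct.pack(f"<{spr}h", *dig.astype(np.int16)))


def load_edf(path: str | Path, events_path: str | Path | None = None) -> Session:
    """Read an EDF recording (via mne); EMG is the channel labelled 'EMG ...'.

    ``events_path`` may point to a TSV annotation sidecar; without it the
    session carries no events.
    """
    import mne  # deferred: heavy import, only needed for EDF reading

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne rescales uV-dimensioned channels to volts
    names = raw.ch_names
    emg_idx = [i for i, n in enumerate(names) if n.upper().startswith("EMG")]
    eeg_idx = [i for i in range(len(names)) if i not in emg_idx]
    emg = data[emg_idx[0]] if emg_idx else np.zeros(data.shape[1])
    clean = [names[i].removeprefix("EEG ").strip() for i in eeg_idx]
    events = load_events_tsv(events_path) if events_path else []
    return Session(
        eeg=data[eeg_idx],
        emg=emg,
        fs=float(raw.info["sfreq"]),
        channel_names=clean,
        events=events,
        ground_truth=list(events),
    )


# ---------------------------------------------------------------------------
# delimited columnar text
# ---------------------------------------------------------------------------

def read_delimited_session(
    path: str | Path,
    fs: float,
    sep: str = "\t",
    emg_column: str | None = "EMG",
    events_path: str | Path | None = None,
) -> Session:
    """Read a delimited text export with one column per channel.

    All columns except ``emg_column`` are taken as EEG channels, in file
    order.  Sampling rate is not stored in such exports and must be given.
    """
    df = pd.read_csv(path, sep=sep)
    emg = np.zeros(len(df))
    if emg_column and emg_column in df.columns:
        emg = df.pop(emg_column).to_numpy(dtype=float)
    events = load_events_tsv(events_path) if events_path else []
    return Session(
        eeg=df.to_numpy(dtype=float).T,
        emg=emg,
        fs=fs,
        channel_names=[str(c) for c in df.columns],
        events=events,
        ground_truth=list(events),
    )
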