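"""Shared fixtures: small deterministic synthetic sessions and toy epochs."""

from __future__ import annotations

import numpy as np
import pytest

import mrcpbench as mb
from mrcpbench.preprocess import MRCP, NON_MRCP, Epoch


@pytest.fixture(scope="session")
def clean_session() -> mb.Session:
    """Noise-free 10-trial session (all idle gaps >= 4.2 s, so nothing is dropped)."""
    cfg = mb.SynthConfig(
        fs=128.0, n_trials=10, idle_range=(4.2, 6.5), noise_sd=0.0, seed=1
    )
    return mb.generate_session(cfg)


@pytest.fixture(scope="session")
def noisy_session() -> mb.Session:
    """Default-noise 24-trial session at desk-scale sampling rate."""
    cfg = mb.SynthConfig(fs=128.0, n_trials=24, idle_range=(4.2, 6.5), seed=7)
    return mb.generate_session(cfg)


def make_single_channel_epochs(
    n_per_class: int = 6,
    n_samples: int = 64,
    sep: float = 3.0,
    noise: float = 0.3,
    seed: int = 0,
    fs: float = 32.0,
) -> list[Epoch]:
    """Toy single-channel epochs: MRCP = noisy negative ramp, non-MRCP = noise."""
    rng = np.random.default_rng(seed)
    ramp = -sep * np.linspace(0, 1, n_samples)
    out = []
    for i in range(n_per_class):
        out.append(Epoch(data=(ramp + noise * rng.standard_normal(n_samples))[None, :],
                         label=MRCP, fs=fs, source_event=i, channel_names=["X"]))
    for i in range(n_per_class):
        out.append(Epoch(data=(noise * rng.standard_normal(n_samples))[None, :],
                         label=NON_MRCP, fs=fs, source_event=i, channel_names=["X"]))
    return out


@pytest.fixture()
def toy_epochs() -> list[Epoch]:
    return make_single_channel_epochs()
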