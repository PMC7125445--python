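"""Electrode montage for the 19-channel 10-20 recording layout.

The montage carries the ordered channel list, a symmetric neighbour graph
used by the surface-Laplacian spatial filter, and the nine interior
"working" electrodes (F3, Fz, F4, C3, Cz, C4, P3, Pz, P4) that have a full
ring of neighbours and therefore admit a Laplacian surrogate channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

#: Ordered 10-20 channel names of the 19-electrode cap.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

#: Interior electrodes with enough neighbours to act as Laplacian centres.
WORKING_SL_CHANNELS = ["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4"]


@dataclass(frozen=True)
class Montage:
    """Channel layout plus adjacency for spatial filtering.

    Parameters
    ----------
    channel_names
        Ordered electrode names; row order of every EEG matrix.
    neighbors
        Symmetric adjacency: electrode name -> set of adjacent electrodes.
    working_sl_channels
        Electrodes usable as surface-Laplacian centres.
    """

    channel_names: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]
    working_sl_channels: tuple[str, ...] = field(
        default_factory=lambda: tuple(WORKING_SL_CHANNELS)
    )

    def __post_init__(self) -> None:
        names = set(self.channel_names)
        for ch, nbrs in self.neighbors.items():
            if ch not in names:
                raise ValueError(f"neighbor table lists unknown channel {ch!r}")
            for nb in nbrs:
                if ch not in self.neighbors.get(nb, frozenset()):
                    raise ValueError(f"neighbor relation not symmetric: {ch}-{nb}")
        for ch in self.working_sl_channels:
            if len(self.neighbors.get(ch, frozenset())) < 3:
                raise ValueError(f"working SL channel {ch} has < 3 neighbors")

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


def default_montage() -> Montage:
    """The 19-channel 10-20 montage with a 4-connected scalp-grid adjacency.

    Midline frontal/parietal electrodes (Fz, Pz) additionally border both
    electrodes of the row in front of / behind them, giving them five
    neighbours; every working electrode has at least four.
    """
    raw = json.loads(
        resources.files("mrcpbench.data").joinpath("neighbors_1020.json").read_text()
    )
    neighbors = {ch: frozenset(nbrs) for ch, nbrs in raw.items()}
    return Montage(channel_names=tuple(CHANNELS_1020), neighbors=neighbors)
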