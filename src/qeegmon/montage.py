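"""Bipolar montage of the monitoring protocol.

Eight anterior-to-posterior bipolar channels are defined per hemisphere,
mirror-symmetric across the midline (left pair / right pair):

====== ============ ============
index  left         right
====== ============ ============
1      Fp1-F3       Fp2-F4
2      F3-C3        F4-C4
3      Fp1-F7       Fp2-F8
4      F7-T3        F8-T4
5      C3-P3        C4-P4
6      P3-O1        P4-O2
7      T3-T5        T4-T6
8      T5-O1        T6-O2
====== ============ ============

Only the channels ipsilateral to the clamped carotid feed the ischemia
analysis. Channel values are simple sample-wise differences (first electrode
minus second).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import ELECTRODES_1020, EEGRecording

__all__ = [
    "BipolarChannel",
    "BIPOLAR_CHANNELS",
    "canonical_label",
    "bipolar_derive",
    "pairs_for_side",
    "channel_table",
]


@dataclass(frozen=True)
class BipolarChannel:
    """One of the eight homologous bipolar channel pairs."""

    index: int
    left_pair: tuple[str, str]
    right_pair: tuple[str, str]

    def pair(self, side: str) -> tuple[str, str]:
        if side == "left":
            return self.left_pair
        if side == "right":
            return self.right_pair
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def reversed(self) -> "BipolarChannel":
        return BipolarChannel(self.index, self.left_pair[::-1], self.right_pair[::-1])

    @property
    def name(self) -> str:
        return (f"{self.left_pair[0]}-{self.left_pair[1]}/"
                f"{self.right_pair[0]}-{self.right_pair[1]}")


BIPOLAR_CHANNELS: tuple[BipolarChannel, ...] = (
    BipolarChannel(1, ("Fp1", "F3"), ("Fp2", "F4")),
    BipolarChannel(2, ("F3", "C3"), ("F4", "C4")),
    BipolarChannel(3, ("Fp1", "F7"), ("Fp2", "F8")),
    BipolarChannel(4, ("F7", "T3"), ("F8", "T4")),
    BipolarChannel(5, ("C3", "P3"), ("C4", "P4")),
    BipolarChannel(6, ("P3", "O1"), ("P4", "O2")),
    BipolarChannel(7, ("T3", "T5"), ("T4", "T6")),
    BipolarChannel(8, ("T5", "O1"), ("T6", "O2")),
)

_CANONICAL = {name.upper(): name for name in ELECTRODES_1020}


def canonical_label(label: str) -> str:
    """Normalize an EDF channel label to its canonical 10-20 form.

    Case-insensitive; strips whitespace, a leading ``"EEG "`` prefix and a
    reference suffix such as ``"-REF"`` (common EDF dialects). Raises
    ``KeyError`` for labels that are not one of the 16 montage electrodes.
    """
    cleaned = label.strip()
    cleaned = re.sub(r"^EEG[\s_]+", "", cleaned, flags=re.IGNORECASE)
    cleaned = re.sub(r"[-_](REF|LE|AVG)$", "", cleaned, flags=re.IGNORECASE)
    cleaned = cleaned.strip()
    try:
        return _CANONICAL[cleaned.upper()]
    except KeyError:
        raise KeyError(f"label {label!r} is not a 10-20 montage electrode") from None


def pairs_for_side(side: str) -> list[tuple[int, tuple[str, str]]]:
    """(index, (electrode, electrode)) for the eight channels of one side."""
    return [(ch.index, ch.pair(side)) for ch in BIPOLAR_CHANNELS]


def bipolar_derive(rec: EEGRecording, channel: BipolarChannel, side: str) -> np.ndarray:
    """Sample-wise difference of the channel's electrode pair on ``side``."""
    first, second = channel.pair(side)
    return rec.channel(first) - rec.channel(second)


def channel_table() -> pd.DataFrame:
    """The bipolar pair scheme as a tidy table (exportable as CSV)."""
    return pd.DataFrame(
        [
            {
                "channel_index": ch.index,
                "left_first": ch.left_pair[0],
                "left_second": ch.left_pair[1],
                "right_first": ch.right_pair[0],
                "right_second": ch.right_pair[1],
            }
            for ch in BIPOLAR_CHANNELS
        ]
    )
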