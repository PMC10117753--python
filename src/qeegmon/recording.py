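"""Core in-memory containers for intraoperative recordings.

An :class:`EEGRecording` holds the multichannel scalp EEG of one patient
together with the clamp/declamp event markers; a :class:`TCDTrace` holds the
middle-cerebral-artery blood-flow velocities (V-MCA) measured by transcranial
Doppler at the protocol time points. Both are plain dataclasses so that the
simulator, the EDF layer and the spectral pipeline can share them without any
file-format dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 16 monopolar data electrodes of the 10-20 cap used for monitoring
#: (ground and reference are not data channels).
ELECTRODES_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "P3", "P4", "T3", "T4", "T5", "T6", "O1", "O2",
)

#: Protocol time-point identifiers: baseline, then 30 s / 1 min / 2 min
#: after carotid clamping.
TIMEPOINT_IDS: tuple[str, ...] = ("TB", "T1", "T2", "T3")


@dataclass
class EEGRecording:
    """Multichannel scalp EEG with event markers.

    Parameters
    ----------
    labels
        Monopolar electrode names, a subset of the standard 10-20 set.
    sampling_rate
        Sampling frequency in Hz.
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    events
        ``(time_seconds, tag)`` pairs; tags are ``"clamp"`` / ``"declamp"``.
    side
        Surgical (clamped) hemisphere, ``"left"`` or ``"right"``.
    patient_id
        Identifier used to join EEG, TCD and ground-truth tables.
    """

    labels: list[str]
    sampling_rate: float
    data: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)
    side: str = "left"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data must be (n_channels={len(self.labels)}, n_samples); "
                f"got shape {self.data.shape}"
            )
        unknown = [lb for lb in self.labels if lb not in ELECTRODES_1020]
        if unknown:
            raise ValueError(f"labels not in the 10-20 montage: {unknown}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector for one monopolar electrode."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not present in recording") from None
        return self.data[idx]

    def event_time(self, tag: str) -> float:
        """Time (s) of the first event with the given tag."""
        for t, name in self.events:
            if name == tag:
                return t
        raise KeyError(f"no {tag!r} event in recording")

    def copy(self) -> "EEGRecording":
        return replace(self, labels=list(self.labels), data=self.data.copy(),
                       events=list(self.events))


@dataclass
class TCDTrace:
    """Per-patient V-MCA values at the protocol time points (cm/s)."""

    patient_id: str
    baseline_vmca: float
    vmca_at: dict[str, float]

    def __post_init__(self) -> None:
        if self.baseline_vmca <= 0:
            raise ValueError("baseline_vmca must be positive")
        if any(v < 0 for v in self.vmca_at.values()):
            raise ValueError("velocities must be non-negative")
        unknown = set(self.vmca_at) - set(TIMEPOINT_IDS)
        if unknown:
            raise ValueError(f"unknown time points: {sorted(unknown)}")
        # baseline entry is implied; insert/validate it
        tb = self.vmca_at.setdefault("TB", self.baseline_vmca)
        if tb != self.baseline_vmca:
            raise ValueError("vmca_at['TB'] must equal baseline_vmca")
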