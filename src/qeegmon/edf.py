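"""EDF+ input/output for monitoring recordings.

Reading goes through MNE's EDF reader and therefore accepts any standard
EDF/EDF+ file; labels are matched case-insensitively against the 16 required
10-20 electrodes and returned in canonical order, and EDF+ annotations named
``clamp`` / ``declamp`` are mapped onto recording events.

Writing is done by a small self-contained EDF+C writer (16-bit samples, one
one-second data record per second, plus an ``EDF Annotations`` signal that
carries the clamp/declamp markers). The writer emits plain continuous EDF+
that MNE and standard EDF viewers read back; round-tripping through it is
exercised in the test suite against the MNE reader.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .montage import canonical_label
from .recording import ELECTRODES_1020, EEGRecording

__all__ = ["read_recording", "write_recording"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_recording(rec: EEGRecording, path) -> None:
    """Write an :class:`EEGRecording` as a 16-bit EDF+C file.

    Samples are scaled per channel into the full digital range, so the
    round-trip error is at most half a quantization step
    (``(pmax - pmin) / 65535 / 2`` microvolts). Recordings whose length is
    not a whole number of seconds are zero-padded to the next second.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = math.ceil(rec.n_samples / fs)
    n_sig = len(rec.labels)

    # per-channel symmetric physical range, integer so it prints exactly
    phys_max = [max(1, math.ceil(float(np.max(np.abs(ch))) + 1e-9))
                for ch in rec.data]

    # annotation byte streams, one per record
    events = sorted(rec.events)
    tals = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for t, tag in events:
            if r <= t < r + 1:
                tal += f"+{t:g}\x14{tag}\x14\x00".encode("ascii")
        tals.append(tal)
    annot_bytes = max(40, max(len(t) for t in tals))
    annot_bytes += annot_bytes % 2  # whole 2-byte samples
    annot_samples = annot_bytes // 2

    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii(f"Startdate 01-JAN-2000 X X {rec.patient_id or 'X'}", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_sig + 2), 8),
        _ascii("EDF+C", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(n_sig + 1, 4),
    ])

    labels = list(rec.labels) + ["EDF Annotations"]
    transducers = ["AgAgCl electrode"] * n_sig + [""]
    dims = ["uV"] * n_sig + [""]
    pmins = [-a for a in phys_max] + [-1]
    pmaxs = list(phys_max) + [1]
    prefilter = ["HP:1.0Hz LP:35Hz"] * n_sig + [""]
    n_samp = [fs] * n_sig + [annot_samples]

    sig_header = b"".join(
        b"".join(_ascii(v, w) for v in vals)
        for vals, w in [
            (labels, 16), (transducers, 80), (dims, 8),
            (pmins, 8), (pmaxs, 8),
            ([_DIG_MIN] * n_sig + [_DIG_MIN], 8),
            ([_DIG_MAX] * n_sig + [_DIG_MAX], 8),
            (prefilter, 80), (n_samp, 8),
            ([""] * (n_sig + 1), 32),
        ]
    )

    # digitize: value -> pmin + (dig - dmin) * (pmax - pmin) / (dmax - dmin)
    padded = np.zeros((n_sig, n_rec * fs))
    padded[:, : rec.n_samples] = rec.data
    digital = np.empty_like(padded, dtype="<i2")
    for i, a in enumerate(phys_max):
        scale = (_DIG_MAX - _DIG_MIN) / (2 * a)
        digital[i] = np.clip(
            np.rint((padded[i] + a) * scale + _DIG_MIN), _DIG_MIN, _DIG_MAX
        ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            for i in range(n_sig):
                fh.write(digital[i, r * fs : (r + 1) * fs].tobytes())
            fh.write(tals[r].ljust(annot_bytes, b"\x00"))


def read_recording(path, side: str = "left", patient_id: str | None = None) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording`.

    The file must contain all 16 monopolar 10-20 electrodes (matched
    case-insensitively, tolerating ``"EEG "`` prefixes and reference
    suffixes); channels are returned in canonical label order and EDF+
    annotations tagged ``clamp``/``declamp`` become recording events.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")

    found: dict[str, str] = {}
    for name in raw.ch_names:
        try:
            found.setdefault(canonical_label(name), name)
        except KeyError:
            continue
    missing = [lb for lb in ELECTRODES_1020 if lb not in found]
    if missing:
        raise ValueError(
            f"EDF file {path.name} lacks required electrodes: {', '.join(missing)}"
        )

    data = np.vstack(
        [raw.get_data(picks=[found[lb]])[0] for lb in ELECTRODES_1020]
    ) * 1e6  # MNE returns volts; recordings are in microvolts

    events = [
        (float(onset), desc)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if desc in ("clamp", "declamp")
    ]
    return EEGRecording(
        labels=list(ELECTRODES_1020),
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
        events=events,
        side=side,
        patient_id=patient_id if patient_id is not None else path.stem,
    )
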