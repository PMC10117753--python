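"""Baseline-relative change records and ischemia labels.

Every measured quantity (RA, ADR, V-MCA) is expressed as its signed percent
change from the pre-clamp baseline. The gold standard follows transcranial
Doppler: a patient is labelled ischemic when V-MCA falls to strictly less
than half of baseline (decline > 50%). A QEEG channel predicts ischemia
when its percent change is at or below a (negative) calibrated cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .recording import TCDTrace
from .spectral import QEEGValues

__all__ = [
    "TimePoint", "TIME_POINTS", "ChangeRecord", "GoldLabel",
    "percent_change", "label_from_tcd", "classify", "qeeg_change_records",
]


@dataclass(frozen=True)
class TimePoint:
    """A protocol time point and its offset from the clamp event."""

    id: str
    offset_from_clamp: float | None  # seconds; None for the baseline


TIME_POINTS: tuple[TimePoint, ...] = (
    TimePoint("TB", None),
    TimePoint("T1", 30.0),
    TimePoint("T2", 60.0),
    TimePoint("T3", 120.0),
)


@dataclass
class ChangeRecord:
    """One (patient, channel, metric, time point) percent-change observation."""

    patient_id: str
    channel_index: int
    metric: str          # "RA" or "ADR"
    time_point: str
    value: float
    baseline_value: float

    @property
    def pct_change(self) -> float:
        return percent_change(self.value, self.baseline_value)


@dataclass
class GoldLabel:
    """TCD gold-standard label for one patient at one time point."""

    patient_id: str
    ischemic: bool
    vmca_decline_pct: float  # positive = decline


def percent_change(value: float, baseline: float) -> float:
    """Signed percent change from baseline; negative means decline."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return 100.0 * (value - baseline) / baseline


def label_from_tcd(trace: TCDTrace, time_point: str) -> GoldLabel:
    """Gold-standard ischemia label at a post-clamp time point.

    Ischemic iff the V-MCA dropped to strictly below 50% of baseline;
    a decline of exactly 50% is non-ischemic.
    """
    if time_point == "TB":
        raise ValueError("gold label requires a post-clamp time point")
    try:
        v = trace.vmca_at[time_point]
    except KeyError:
        raise ValueError(
            f"TCD trace for {trace.patient_id!r} has no value at {time_point}"
        ) from None
    decline = -percent_change(v, trace.baseline_vmca)
    return GoldLabel(trace.patient_id, ischemic=bool(decline > 50.0),
                     vmca_decline_pct=decline)


def classify(pct_change: float, cutoff: float) -> bool:
    """Predict ischemia iff the change is at or below the (negative) cut-off.

    The boundary is inclusive: cut-offs are reported as achieved score
    values from the ROC, so a change exactly equal to the cut-off tests
    positive.
    """
    if cutoff >= 0:
        raise ValueError(f"cutoff must be a negative percent, got {cutoff}")
    return bool(pct_change <= cutoff)


def qeeg_change_records(patient_id: str,
                        baseline: list[QEEGValues],
                        followups: dict[str, list[QEEGValues]]) -> list[ChangeRecord]:
    """Build change records from baseline and follow-up QEEG epochs.

    ``followups`` maps time-point ids (``T1``/``T2``/``T3``) to the
    eight-channel QEEG lists returned by :func:`~qeegmon.spectral.epoch_qeeg`.
    """
    base = {q.channel.index: q for q in baseline}
    records = []
    for tp, values in followups.items():
        for q in values:
            b = base[q.channel.index]
            records.append(ChangeRecord(patient_id, q.channel.index, "RA", tp,
                                        q.ra, b.ra))
            records.append(ChangeRecord(patient_id, q.channel.index, "ADR", tp,
                                        q.adr, b.adr))
    return records


def changes_to_frame(records: list[ChangeRecord]) -> pd.DataFrame:
    """Tidy table of change records (one row per observation)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "channel_index": r.channel_index,
                "metric": r.metric,
                "time_point": r.time_point,
                "value": r.value,
                "baseline_value": r.baseline_value,
                "pct_change": r.pct_change,
            }
            for r in records
        ]
    )
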