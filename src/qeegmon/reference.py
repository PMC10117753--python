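"""Published clinical accuracy values used as verification fixtures.

These are the reported per-channel diagnostic-accuracy figures from the
clinical carotid-endarterectomy study this pipeline models: sensitivity,
specificity, positive/negative predictive value (percent) and Cohen's
kappa of RA and ADR decline against the TCD gold standard, for the eight
bipolar channels at 30 s / 1 min / 2 min after clamping, with 20 ischemic
and 43 non-ischemic patients.

Because the group sizes are known, sensitivity and specificity determine
the underlying 2x2 table exactly (see
:func:`qeegmon.diagnostics.reconstruct_confusion`), so the printed PPV,
NPV and kappa can be recomputed and checked. :func:`verify_printed_metrics`
does that for every cell; a handful of published cells are internally
inconsistent (apparent misprints) and show up as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostics import accuracy_summary, reconstruct_confusion

__all__ = ["PrintedCell", "PRINTED_CELLS", "N_ISCHEMIC", "N_NON_ISCHEMIC",
           "verify_printed_metrics"]

N_ISCHEMIC = 20
N_NON_ISCHEMIC = 43


@dataclass(frozen=True)
class PrintedCell:
    """One published (metric, channel, time point) accuracy row."""

    metric: str        # "RA" | "ADR"
    channel_index: int  # 1..8
    time_point: str    # "T1" | "T2" | "T3"
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float


def _cells(metric, rows):
    out = []
    for ch, per_tp in enumerate(rows, start=1):
        for tp, (se, sp, ppv, npv, k) in zip(("T1", "T2", "T3"), per_tp):
            out.append(PrintedCell(metric, ch, tp, se, sp, ppv, npv, k))
    return out


#: All 48 published accuracy cells: 8 channels x {T1, T2, T3}, for RA then ADR.
PRINTED_CELLS: tuple[PrintedCell, ...] = tuple(
    _cells("RA", [
        [(90.0, 90.7, 81.8, 95.7, 0.786), (80.0, 90.7, 80.0, 90.7, 0.707), (85.0, 90.7, 81.0, 92.9, 0.747)],
        [(80.0, 88.4, 76.2, 90.5, 0.675), (90.0, 76.7, 64.3, 94.3, 0.603), (80.0, 83.7, 69.6, 90.0, 0.613)],
        [(90.0, 90.7, 81.8, 95.1, 0.786), (85.0, 90.7, 81.0, 92.9, 0.747), (85.0, 86.0, 73.9, 92.5, 0.683)],
        [(85.0, 90.7, 81.0, 92.9, 0.747), (80.0, 93.0, 84.2, 90.9, 0.740), (80.0, 81.4, 66.7, 89.7, 0.583)],
        [(90.0, 86.0, 75.0, 94.9, 0.722), (90.0, 90.7, 81.8, 95.1, 0.786), (90.0, 90.7, 81.8, 95.1, 0.786)],
        [(80.0, 81.4, 66.7, 89.7, 0.583), (75.0, 90.7, 78.9, 88.6, 0.747), (80.0, 88.4, 76.2, 90.5, 0.675)],
        [(90.0, 88.4, 78.3, 95.0, 0.753), (90.0, 88.4, 78.3, 95.0, 0.753), (80.0, 88.4, 76.2, 90.5, 0.675)],
        [(80.0, 86.0, 72.7, 90.2, 0.643), (85.0, 90.7, 81.0, 92.9, 0.747), (90.0, 90.7, 81.8, 95.7, 0.786)],
    ])
    + _cells("ADR", [
        [(75.0, 81.4, 65.2, 87.5, 0.542), (75.0, 83.7, 68.2, 87.8, 0.572), (80.0, 86.0, 72.7, 90.2, 0.643)],
        [(75.0, 88.4, 75.0, 88.4, 0.634), (75.0, 86.0, 71.4, 88.1, 0.602), (65.0, 93.0, 81.3, 85.1, 0.613)],
        [(70.0, 95.3, 87.5, 87.2, 0.690), (70.0, 88.4, 73.7, 86.4, 0.592), (75.0, 83.7, 68.2, 87.8, 0.572)],
        [(85.0, 81.4, 68.0, 92.1, 0.622), (80.0, 88.4, 76.2, 90.5, 0.675), (80.0, 81.4, 66.7, 89.7, 0.583)],
        [(80.0, 86.0, 72.7, 90.2, 0.643), (75.0, 86.0, 71.4, 88.1, 0.602), (75.0, 88.4, 75.0, 88.4, 0.634)],
        [(70.0, 93.0, 82.4, 87.0, 0.657), (75.0, 90.7, 78.9, 88.6, 0.666), (70.0, 97.7, 93.3, 87.5, 0.725)],
        [(75.0, 93.0, 83.3, 88.9, 0.699), (80.0, 88.4, 76.2, 90.5, 0.675), (70.0, 93.0, 82.4, 87.0, 0.657)],
        [(75.0, 95.3, 88.2, 89.1, 0.733), (75.0, 93.0, 83.3, 88.9, 0.699), (70.0, 93.0, 82.4, 87.0, 0.657)],
    ])
)


def verify_printed_metrics() -> dict:
    """Recompute PPV/NPV/kappa for every published cell and compare.

    For each cell the 2x2 table is reconstructed from the printed
    sensitivity/specificity and the 20/43 group sizes, the accuracy summary
    is recomputed, and the result is compared to the printed values at
    printed precision (percents to 1 decimal, kappa to 3, half-up).

    Returns a report dict with per-cell results and the list of mismatching
    cells; mismatches indicate internally inconsistent published rows.
    """
    results = []
    mismatches = []
    for cell in PRINTED_CELLS:
        table = reconstruct_confusion(cell.sensitivity, cell.specificity,
                                      N_ISCHEMIC, N_NON_ISCHEMIC)
        computed = accuracy_summary(table).rounded()
        diffs = {
            name: (printed, got)
            for name, printed, got in [
                ("ppv", cell.ppv, computed.ppv),
                ("npv", cell.npv, computed.npv),
                ("kappa", cell.kappa, computed.kappa),
            ]
            if printed != got
        }
        entry = {
            "metric": cell.metric,
            "channel_index": cell.channel_index,
            "time_point": cell.time_point,
            "table": (table.tp, table.fn, table.fp, table.tn),
            "computed": computed,
            "match": not diffs,
            "diffs": diffs,
        }
        results.append(entry)
        if diffs:
            mismatches.append(entry)
    return {
        "n_cells": len(results),
        "n_match": sum(e["match"] for e in results),
        "cells": results,
        "mismatches": mismatches,
    }
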