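"""Result tables: per-animal (one row per cell) and per-cell (one row per
transient), plus distribution summaries for external plotting.

Unit conventions: frame-valued columns are inclusive counts or 0-based
indices; second-valued columns are the frame values divided by the frame
rate.  "Total Rising Frames" counts the closed interval
(rise_stop − rise_start + 1).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .trace_model import CalciumTraceSet, TransientEvent

__all__ = [
    "ANIMAL_COLUMNS",
    "CELL_COLUMNS",
    "animal_table",
    "cell_table",
    "summarize_distribution",
]

ANIMAL_COLUMNS = [
    "Cell ID",
    "Cell Size (pixels)",
    "Footprint X",
    "Footprint Y",
    "Total Transient Count",
    "Frequency (Hz)",
    "Average Amplitude (dFF)",
    "Average Rising (frames)",
    "Average Rising Time (seconds)",
    "Average Interval (seconds)",
    "Std (dFF)",
    "MAD (dFF)",
    "Average Peak Amplitude (dFF)",
    "Category",
]

CELL_COLUMNS = [
    "Rising Start (frames)",
    "Rising Stop (frames)",
    "Total Rising Frames",
    "Rising Start (seconds)",
    "Rising Stop (seconds)",
    "Total Rising Time (seconds)",
    "Interval with Previous Transient (frames)",
    "Peak Amplitude (dFF)",
    "Total Amplitude (dFF)",
]

# A footprint pixel belongs to the cell when it exceeds this fraction of the
# footprint's maximum intensity.
FOOTPRINT_LEVEL = 0.5


def _footprint_stats(fp: Optional[np.ndarray]):
    if fp is None or not np.any(fp > 0):
        return np.nan, np.nan, np.nan
    mask = fp > FOOTPRINT_LEVEL * fp.max()
    ys, xs = np.nonzero(mask)
    w = fp[mask]
    return int(mask.sum()), float(np.average(xs, weights=w)), float(
        np.average(ys, weights=w)
    )


def animal_table(
    ts: CalciumTraceSet,
    events_per_cell: Dict[object, Sequence[TransientEvent]],
    duration_s: Optional[float] = None,
) -> pd.DataFrame:
    """One summary row per cell.

    Frequency = transient count / recording duration (s); cell size is the
    pixel count of the footprint above half its maximum and the location its
    intensity-weighted centroid (blank without footprints); Std and MAD are
    computed over the cell's full ΔF/F trace; "Average Amplitude" averages
    total (area-under-rise) amplitudes while "Average Peak Amplitude"
    averages peak amplitudes.  Cells with no events get count 0 and blank
    kinetic averages.
    """
    if duration_s is None:
        duration_s = ts.n_frames / ts.frame_rate
    rows = []
    for i, cid in enumerate(ts.cell_ids):
        events = list(events_per_cell.get(cid, []))
        fp = None if ts.footprints is None else ts.footprints[i]
        size, x, y = _footprint_stats(fp)
        dff_row = ts.dff[i] if ts.dff is not None else None
        intervals = [
            e.interval_prev for e in events if e.interval_prev is not None
        ]
        rows.append(
            {
                "Cell ID": cid,
                "Cell Size (pixels)": size,
                "Footprint X": x,
                "Footprint Y": y,
                "Total Transient Count": len(events),
                "Frequency (Hz)": len(events) / duration_s,
                "Average Amplitude (dFF)": np.mean(
                    [e.total_amplitude for e in events]
                )
                if events
                else np.nan,
                "Average Rising (frames)": np.mean(
                    [e.n_rise_frames for e in events]
                )
                if events
                else np.nan,
                "Average Rising Time (seconds)": np.mean(
                    [e.n_rise_frames / ts.frame_rate for e in events]
                )
                if events
                else np.nan,
                "Average Interval (seconds)": np.mean(
                    [iv / ts.frame_rate for iv in intervals]
                )
                if intervals
                else np.nan,
                "Std (dFF)": float(np.std(dff_row)) if dff_row is not None else np.nan,
                "MAD (dFF)": float(np.mean(np.abs(dff_row - np.mean(dff_row))))
                if dff_row is not None
                else np.nan,
                "Average Peak Amplitude (dFF)": np.mean(
                    [e.peak_amplitude for e in events]
                )
                if events
                else np.nan,
                "Category": ts.category.get(cid, "unlabeled"),
            }
        )
    return pd.DataFrame(rows, columns=ANIMAL_COLUMNS)


def cell_table(
    events: Sequence[TransientEvent],
    dff_row: Optional[np.ndarray] = None,
    frame_rate: float = 30.0,
) -> pd.DataFrame:
    """One row per transient of a single cell.

    When ``dff_row`` is given, missing amplitudes are filled from it (peak
    minus onset value for the peak; rectified sum above onset for the area).
    The first event's interval column is blank.
    """
    rows = []
    for e in events:
        peak_amp, total_amp = e.peak_amplitude, e.total_amplitude
        if dff_row is not None and (np.isnan(peak_amp) or np.isnan(total_amp)):
            seg = np.asarray(dff_row[e.rise_start : e.rise_stop + 1], float)
            if np.isnan(peak_amp):
                peak_amp = float(dff_row[e.rise_stop])
            if np.isnan(total_amp):
                total_amp = float(np.sum(np.maximum(seg - seg[0], 0.0)))
        rows.append(
            {
                "Rising Start (frames)": e.rise_start,
                "Rising Stop (frames)": e.rise_stop,
                "Total Rising Frames": e.n_rise_frames,
                "Rising Start (seconds)": e.rise_start / frame_rate,
                "Rising Stop (seconds)": e.rise_stop / frame_rate,
                "Total Rising Time (seconds)": e.n_rise_frames / frame_rate,
                "Interval with Previous Transient (frames)": e.interval_prev,
                "Peak Amplitude (dFF)": peak_amp,
                "Total Amplitude (dFF)": total_amp,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def summarize_distribution(
    values: Sequence[float], kind: str = "amplitude", n_bins: int = 20
) -> Dict:
    """Histogram and quartile records for a per-event quantity.

    ``kind`` is a label carried through to the record (amplitude, iti,
    rise_time, ...).  Returns plain lists/floats suitable for JSON export
    and external plotting.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one value")
    counts, edges = np.histogram(vals, bins=n_bins)
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return {
        "kind": kind,
        "n": int(vals.size),
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "quartiles": {"q25": float(q25), "q50": float(q50), "q75": float(q75)},
        "min": float(vals.min()),
        "max": float(vals.max()),
    }
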