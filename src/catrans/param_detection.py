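"""Parameter-based automatic transient identification, plus manual-point snapping.

The detector works on the CNMF temporal pair (C, S).  C reliably tracks
transients but is prone to false-positive bumps; S is positive exactly on
rising frames, so it anchors event boundaries and vetoes spurious C peaks.
The sweep:

1. collect all local maxima of C as candidate peaks;
2. drop peaks with no supporting S>0 run (within a small lookback — C peaks
   can trail the S run by filter lag);
3. sweep left → right, merging a candidate into the previous one while their
   onsets are closer than ``interval_threshold`` frames (the taller C peak
   wins, S allocations are unioned), re-testing the merged event against the
   next candidate;
4. the event's rising segment is ``[run_start − 1, peak]`` — the onset frame
   is the frame *before* the first positive S increment, where fluorescence
   still sits at its pre-rise value;
5. accept iff the in-segment maxima of ΔF/F and SNR clear ``peak_threshold``
   and ``snr_threshold``.

Amplitudes: a peak riding on the decaying tail of the previous transient is
measured from its own onset ΔF/F, an isolated peak from zero.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .signal_processing import compute_snr, ensure_dff
from .trace_model import CalciumTraceSet, DetectionParams, TransientEvent

__all__ = [
    "find_candidate_peaks",
    "allocate_rise_segment",
    "detect_transients",
    "snap_point",
]

# A riding peak is one whose onset ΔF/F exceeds this fraction of the previous
# event's peak amplitude; only then is the amplitude baselined at the onset.
RIDING_ONSET_FRACTION = 0.25


def find_candidate_peaks(C_row: np.ndarray) -> List[int]:
    """Frame indices of local maxima of C (plateaus count once, leftmost frame).

    A run of equal values is a peak when it is higher than the differing
    values on both sides; runs touching the trace ends are not peaks.
    """
    x = np.asarray(C_row, dtype=float)
    n = x.size
    peaks: List[int] = []
    i = 1
    while i < n - 1:
        if x[i] <= x[i - 1]:
            i += 1
            continue
        # rising into x[i]; find end of plateau
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 < n and x[j + 1] < x[i]:
            peaks.append(i)
        i = j + 1
    return peaks


def _runs_positive(S_row: np.ndarray) -> List[Tuple[int, int]]:
    m = (np.asarray(S_row) > 0).astype(np.int8)
    diff = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def allocate_rise_segment(
    S_row: np.ndarray, peak_frame: int, lookback: int = 5
) -> Optional[Tuple[int, int]]:
    """Maximal contiguous S>0 run supporting ``peak_frame``, or ``None``.

    If S is positive at the peak, the containing run is returned.  If the
    peak sits on S == 0 (C maxima can lag the deconvolved rise by filter
    lag), the run whose last frame is the nearest S>0 frame at most
    ``lookback`` frames before the peak is returned.  No such run → the peak
    is erroneous.
    """
    S_row = np.asarray(S_row, dtype=float)
    if S_row[peak_frame] > 0:
        for a, b in _runs_positive(S_row):
            if a <= peak_frame <= b:
                return (a, b)
        raise AssertionError("unreachable: positive frame outside all runs")
    lo = max(0, peak_frame - lookback)
    seg = S_row[lo:peak_frame]
    pos = np.flatnonzero(seg > 0)
    if pos.size == 0:
        return None
    last = lo + int(pos[-1])
    for a, b in _runs_positive(S_row):
        if a <= last <= b:
            return (a, b)
    raise AssertionError("unreachable")


def detect_transients(
    ts: CalciumTraceSet,
    cell_id,
    params: DetectionParams,
    riding_fraction: float = RIDING_ONSET_FRACTION,
) -> List[TransientEvent]:
    """Run the full parameter-based sweep for one cell.

    Returns accepted events sorted by onset, with ``peak_amplitude``,
    ``total_amplitude`` and ``interval_prev`` filled from ΔF/F.
    ``riding_fraction`` sets when an event counts as riding its
    predecessor's decay (onset ΔF/F above that fraction of the previous
    peak amplitude).
    """
    row = ts.cell_index(cell_id)
    C = ts.C[row]
    S = ts.S[row]
    dff = ensure_dff(ts, params)[row]
    snr = compute_snr(dff, params)

    # candidate (onset, peak) pairs, S-erroneous peaks dropped
    cands: List[Tuple[int, int]] = []
    for p in find_candidate_peaks(C):
        seg = allocate_rise_segment(S, p, lookback=params.s_lookback)
        if seg is None:
            continue
        onset = max(seg[0] - 1, 0)
        cands.append((onset, p))

    # left->right merge while onsets are closer than the interval threshold;
    # the merged event keeps the taller C peak and the earliest onset, and is
    # re-tested against the next candidate.
    merged: List[Tuple[int, int]] = []
    for onset, peak in cands:
        while merged and onset - merged[-1][0] < params.interval_threshold:
            prev_onset, prev_peak = merged.pop()
            peak = peak if C[peak] >= C[prev_peak] else prev_peak
            onset = min(onset, prev_onset)
        merged.append((onset, peak))

    events: List[TransientEvent] = []
    prev: Optional[TransientEvent] = None
    for onset, peak in merged:
        a, b = onset, peak
        if np.max(dff[a : b + 1]) < params.peak_threshold:
            continue
        if np.max(snr[a : b + 1]) < params.snr_threshold:
            continue
        onset_val = dff[a]
        riding = (
            prev is not None
            and np.isfinite(prev.peak_amplitude)
            and onset_val > riding_fraction * prev.peak_amplitude
        )
        peak_amp = dff[b] - onset_val if riding else dff[b]
        total_amp = float(np.sum(np.maximum(dff[a : b + 1] - onset_val, 0.0)))
        ev = TransientEvent(
            cell_id=cell_id,
            rise_start=a,
            rise_stop=b,
            peak_amplitude=float(max(peak_amp, 0.0)),
            total_amplitude=total_amp,
            interval_prev=None if prev is None else a - prev.rise_start,
        )
        events.append(ev)
        prev = ev
    return events


def snap_point(
    trace: np.ndarray, frame: int, mode: str = "max", half_window: int = 10
) -> int:
    """Snap a hand-placed frame to the local extremum of ``trace``.

    Searches ``[frame − half_window, frame + half_window]`` clipped to the
    trace; ties go to the candidate nearest the input frame, then leftmost.
    The default 10-frame half window reproduces the 20-frame snapping window
    used during manual annotation.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if not 0 <= frame < n:
        raise ValueError(f"frame {frame} outside trace of {n} frames")
    lo = max(0, frame - half_window)
    hi = min(n, frame + half_window + 1)
    win = trace[lo:hi]
    target = win.max() if mode == "max" else win.min()
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    cand = np.flatnonzero(win == target) + lo
    dist = np.abs(cand - frame)
    best = cand[dist == dist.min()]
    return int(best.min())
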