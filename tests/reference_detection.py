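"""Independent brute-force reference for the parameter-based sweep.

Written as a direct, unoptimized transcription of the detection procedure —
plain Python loops, no shared helpers with the package — so it can serve as
an oracle for equivalence testing.
"""

from typing import List, Optional, Tuple


def ref_local_maxima(x) -> List[int]:
    """Every frame that starts a plateau strictly above both neighbors."""
    x = list(map(float, x))
    n = len(x)
    peaks = []
    for i in range(1, n - 1):
        if x[i] <= x[i - 1]:
            continue
        # walk the plateau to the right
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 < n and x[j + 1] < x[i]:
            peaks.append(i)
    return peaks


def ref_runs(mask) -> List[Tuple[int, int]]:
    """Maximal runs of truthy values, as inclusive (start, stop) pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def ref_allocate(S, peak: int, lookback: int) -> Optional[Tuple[int, int]]:
    runs = ref_runs([s > 0 for s in S])
    for a, b in runs:
        if a <= peak <= b:
            return (a, b)
    # peak sits on zero S: look back a bounded number of frames
    for d in range(1, lookback + 1):
        j = peak - d
        if j < 0:
            break
        if S[j] > 0:
            for a, b in runs:
                if a <= j <= b:
                    return (a, b)
    return None


def ref_detect(
    C,
    S,
    dff,
    snr,
    peak_thr: float,
    interval_thr: int,
    snr_thr: float,
    lookback: int = 5,
    riding_fraction: float = 0.25,
) -> List[dict]:
    """Full sweep: peaks -> S support -> onset -> merge -> thresholds."""
    cands = []
    for p in ref_local_maxima(C):
        seg = ref_allocate(S, p, lookback)
        if seg is None:
            continue
        onset = max(seg[0] - 1, 0)
        cands.append({"onset": onset, "peak": p})

    merged: List[dict] = []
    for cand in cands:
        if not merged:
            merged.append(cand)
            continue
        cur = merged[-1]
        if cand["onset"] - cur["onset"] < interval_thr:
            # merge: taller C peak wins, earliest onset kept; the merged
            # event is re-tested against the following candidate
            if C[cand["peak"]] > C[cur["peak"]]:
                cur["peak"] = cand["peak"]
        else:
            merged.append(cand)

    events = []
    prev = None
    for m in merged:
        a, b = m["onset"], m["peak"]
        seg_dff = [dff[t] for t in range(a, b + 1)]
        seg_snr = [snr[t] for t in range(a, b + 1)]
        if max(seg_dff) < peak_thr or max(seg_snr) < snr_thr:
            continue
        onset_val = dff[a]
        riding = prev is not None and onset_val > riding_fraction * prev["peak_amp"]
        peak_amp = dff[b] - onset_val if riding else dff[b]
        total_amp = sum(max(v - onset_val, 0.0) for v in seg_dff)
        ev = {
            "rise_start": a,
            "rise_stop": b,
            "peak_amp": max(float(peak_amp), 0.0),
            "total_amp": float(total_amp),
            "interval_prev": None if prev is None else a - prev["rise_start"],
        }
        events.append(ev)
        prev = ev
    return events
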