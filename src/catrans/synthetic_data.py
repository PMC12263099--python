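"""CNMF-consistent synthetic calcium traces with ground-truth events.

Emulates the single-photon miniScope regime the detectors are built for:
30 Hz acquisition, 27,000 frames (15 min) per cell, sparse transients whose
rising frames occupy ~2–3% of the recording.  Each transient is a linear
rise to peak (5–15 frames; fast GCaMP kinetics) followed by a
single-exponential decay; amplitudes are log-normal; event onsets form a
censored renewal process honoring a minimum gap.

The generated variables mirror the upstream extraction outputs:

* ``C`` — the noiseless sum of event kernels (denoised dynamics);
* ``S`` — the positive temporal increments of C, so S > 0 exactly on the
  frames where C rises (the deconvolved "rising slope");
* ``raw`` — baseline · (1 + C) plus i.i.d. Gaussian noise, with optional
  slow sinusoidal baseline drift and slowly varying noise sigma (the
  motivation for per-frame rather than global noise estimation);
* ``dff`` — ΔF/F computed from raw with the moving-percentile baseline.

Ground truth is the *realized* rising phase of the noiseless C: for each
planted event, the S > 0 run ending at its peak plus the onset frame just
before it.  An event whose rise is entirely cancelled by a preceding decay
(vanishingly rare at the defaults) is censored from the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .signal_processing import compute_dff
from .trace_model import (
    CalciumTraceSet,
    FrameLabels,
    TransientEvent,
    events_to_labels,
)

__all__ = ["GeneratorConfig", "generate_cell", "generate_traceset"]


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic trace generation.

    Defaults give an expected rising-frame occupancy of
    rate × mean_rise / frames-per-minute ≈ 4.5 × 10.5 / 1800 ≈ 2.6%.
    """

    n_cells: int = 10
    n_frames: int = 27_000
    frame_rate: float = 30.0
    event_rate_per_min: float = 4.5
    min_gap: int = 90  # frames between successive onsets
    rise_range: Tuple[int, int] = (5, 15)  # frames, inclusive
    decay_tau: float = 45.0  # frames (~1.5 s at 30 Hz)
    amp_log_mean: float = 0.4  # log-normal parameters of peak ΔF/F
    amp_log_sigma: float = 0.35
    noise_sigma: float = 0.03  # stdev of raw noise, in baseline units
    noise_sigma_wobble: float = 0.0  # relative slow modulation of sigma
    baseline: float = 1.0
    baseline_drift: float = 0.0  # relative amplitude of slow drift
    baseline_window: int = 600
    baseline_percentile: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_frames, self.min_gap) <= 0:
            raise ValueError("n_cells, n_frames and min_gap must be positive")
        if self.frame_rate <= 0 or self.decay_tau <= 0 or self.baseline <= 0:
            raise ValueError("frame_rate, decay_tau and baseline must be positive")
        if not 1 <= self.rise_range[0] <= self.rise_range[1]:
            raise ValueError("rise_range must satisfy 1 <= min <= max")
        if self.min_gap <= self.rise_range[1]:
            raise ValueError("min_gap must exceed the maximum rise time")
        if self.event_rate_per_min < 0 or self.noise_sigma < 0:
            raise ValueError("event rate and noise sigma must be non-negative")
        # renewal feasibility: the mean inter-onset interval must exceed the
        # hard minimum gap, otherwise onsets cannot honor it in expectation
        if self.event_rate_per_min > 0:
            mean_gap = 60.0 * self.frame_rate / self.event_rate_per_min
            if mean_gap <= self.min_gap:
                raise ValueError(
                    f"event rate {self.event_rate_per_min}/min implies a mean "
                    f"inter-onset gap of {mean_gap:.0f} frames, not above the "
                    f"min_gap of {self.min_gap} frames; lower the rate or gap"
                )


def _draw_onsets(cfg: GeneratorConfig, rng: np.random.Generator) -> List[int]:
    """Censored renewal process: exponential gaps shifted by ``min_gap``."""
    rate = cfg.event_rate_per_min / (60.0 * cfg.frame_rate)  # events per frame
    if rate <= 0:
        return []
    mean_extra = 1.0 / rate - cfg.min_gap
    onsets: List[int] = []
    t = 1  # onset frame 0 would have no pre-rise frame
    while True:
        gap = cfg.min_gap + rng.exponential(mean_extra)
        t += int(round(gap))
        if t + cfg.rise_range[1] >= cfg.n_frames:
            break
        onsets.append(t)
    return onsets


def generate_cell(
    cfg: GeneratorConfig,
    cell_seed: int,
    cell_id=0,
    forced_events: Optional[List[Tuple[int, int]]] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
           List[TransientEvent], np.ndarray]:
    """Simulate one cell.

    Returns ``(C_row, S_row, raw_row, dff_row, events, label_row)``.
    ``forced_events`` — a list of ``(onset, peak)`` frame pairs — overrides
    the renewal draw for constructing exact scenarios in tests.

    Reproducible from ``(cfg.seed-derived) cell_seed`` alone.
    """
    rng = np.random.default_rng(cell_seed)
    n = cfg.n_frames
    if forced_events is not None:
        planted = [(int(a), int(b)) for a, b in forced_events]
        for a, b in planted:
            if not 0 <= a < b < n:
                raise ValueError(f"forced event ({a}, {b}) out of range")
        amps = rng.lognormal(cfg.amp_log_mean, cfg.amp_log_sigma, len(planted))
    else:
        onsets = _draw_onsets(cfg, rng)
        rises = rng.integers(cfg.rise_range[0], cfg.rise_range[1] + 1, len(onsets))
        planted = [(t, t + int(r)) for t, r in zip(onsets, rises)]
        amps = rng.lognormal(cfg.amp_log_mean, cfg.amp_log_sigma, len(planted))

    C = np.zeros(n)
    for (onset, peak), amp in zip(planted, amps):
        r = peak - onset
        C[onset : peak + 1] += amp * np.arange(r + 1) / r
        n_decay = n - peak - 1
        if n_decay > 0:
            C[peak + 1 :] += amp * np.exp(-np.arange(1, n_decay + 1) / cfg.decay_tau)
    S = np.maximum(np.diff(C, prepend=0.0), 0.0)

    # ground truth = realized rising phase: S>0 run ending at each peak,
    # plus the onset frame before the run
    events: List[TransientEvent] = []
    prev_start = None
    for onset, peak in planted:
        if S[peak] <= 0:
            continue  # rise swallowed by a preceding decay: censored
        start = peak
        while start > 0 and S[start - 1] > 0:
            start -= 1
        start = max(start - 1, 0)
        ev = TransientEvent(cell_id, start, peak)
        if prev_start is not None:
            ev.interval_prev = start - prev_start
        prev_start = start
        events.append(ev)

    t = np.arange(n)
    drift = 1.0 + cfg.baseline_drift * np.sin(2 * np.pi * t / max(n, 1) * 3.0)
    sigma = cfg.noise_sigma * (
        1.0 + cfg.noise_sigma_wobble * np.sin(2 * np.pi * t / max(n, 1) * 5.0)
    )
    raw = cfg.baseline * drift * (1.0 + C) + rng.normal(0.0, 1.0, n) * sigma
    dff = compute_dff(raw, cfg.baseline_window, cfg.baseline_percentile)

    labels = (
        events_to_labels(events, 1, n, cell_ids=[cell_id]).mask[0]
        if events
        else np.zeros(n, np.int8)
    )
    return C, S, raw, dff, events, labels


def generate_traceset(
    cfg: GeneratorConfig,
) -> Tuple[CalciumTraceSet, FrameLabels, List[TransientEvent]]:
    """Simulate ``cfg.n_cells`` independent cells.

    Per-cell seeds are spawned from ``cfg.seed``, so the whole set is
    bit-reproducible and individual cells are independent.
    """
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_cells)
    C_rows, S_rows, raw_rows, dff_rows, mask_rows = [], [], [], [], []
    all_events: List[TransientEvent] = []
    for i in range(cfg.n_cells):
        C, S, raw, dff, events, labels = generate_cell(cfg, int(child_seeds[i]), i)
        C_rows.append(C)
        S_rows.append(S)
        raw_rows.append(raw)
        dff_rows.append(dff)
        mask_rows.append(labels)
        all_events.extend(events)
    ts = CalciumTraceSet(
        cell_ids=list(range(cfg.n_cells)),
        C=np.vstack(C_rows),
        S=np.vstack(S_rows),
        YrA=np.vstack(raw_rows) - np.vstack(C_rows),
        dff=np.vstack(dff_rows),
        frame_rate=cfg.frame_rate,
    )
    labels = FrameLabels(np.vstack(mask_rows), cell_ids=ts.cell_ids)
    return ts, labels, all_events
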