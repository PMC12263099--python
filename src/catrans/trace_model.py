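"""Core data types shared by every pipeline stage.

Conventions
-----------
* Frames are 0-based integers; all frame intervals (``rise_start``,
  ``rise_stop``) are inclusive on both ends.
* Seconds = frame / frame_rate.
* Temporal matrices are ``(cells, frames)`` with float dtype; spatial
  footprints are ``(cells, height, width)``.
* A transient is identified by its *rising* segment only: ``rise_start`` is
  the onset frame (fluorescence still at its pre-rise value) and
  ``rise_stop`` is the peak frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "CalciumTraceSet",
    "TransientEvent",
    "FrameLabels",
    "DetectionParams",
    "events_to_labels",
    "labels_to_events",
]

#: Cell quality categories assigned during (out-of-scope, GUI-side) manual
#: review.  Kept as pure metadata — no pipeline stage filters on them.
CATEGORIES = ("verified", "rejected", "missing", "unlabeled")


@dataclass
class CalciumTraceSet:
    """Per-cell temporal outputs of a CNMF-style extraction pipeline.

    Attributes
    ----------
    cell_ids : list
        Ordered unique cell identifiers.
    C : ndarray, (cells, frames)
        Denoised temporal dynamics; non-negative.
    S : ndarray, (cells, frames)
        Deconvolved transient rising slope; non-negative,
        positive exactly where C rises.
    YrA : ndarray or None
        Residual (raw minus model) traces.
    dff : ndarray or None
        Relative fluorescence change ΔF/F.  Optional because upstream
        pipelines do not always produce it; computed lazily by
        :mod:`catrans.signal_processing` when absent.
    footprints : ndarray or None, (cells, height, width)
        Spatial weight maps (matrix A).
    frame_rate : float
        Acquisition rate in frames per second (default 30).
    category : dict
        cell_id -> one of :data:`CATEGORIES`; metadata only.
    """

    cell_ids: List
    C: np.ndarray
    S: np.ndarray
    YrA: Optional[np.ndarray] = None
    dff: Optional[np.ndarray] = None
    footprints: Optional[np.ndarray] = None
    frame_rate: float = 30.0
    category: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.cell_ids = list(self.cell_ids)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids contains duplicates")
        self.C = np.asarray(self.C, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.C.ndim != 2:
            raise ValueError(f"C must be 2-D (cells, frames), got shape {self.C.shape}")
        shapes = {"C": self.C.shape, "S": self.S.shape}
        for name in ("YrA", "dff"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                shapes[name] = arr.shape
        if len(set(shapes.values())) != 1:
            raise ValueError(f"temporal matrices disagree in shape: {shapes}")
        if self.C.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"{len(self.cell_ids)} cell_ids but {self.C.shape[0]} trace rows"
            )
        if self.footprints is not None:
            self.footprints = np.asarray(self.footprints, dtype=float)
            if self.footprints.ndim != 3 or self.footprints.shape[0] != self.n_cells:
                raise ValueError(
                    "footprints must be (cells, height, width) matching cell_ids"
                )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if np.any(self.C < 0):
            raise ValueError("C must be non-negative")
        if np.any(self.S < 0):
            raise ValueError("S must be non-negative")
        bad = {c: v for c, v in self.category.items() if v not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    @property
    def n_cells(self) -> int:
        return self.C.shape[0]

    @property
    def n_frames(self) -> int:
        return self.C.shape[1]

    def cell_index(self, cell_id) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell_id: {cell_id!r}") from None

    def subset(self, cell_ids: Sequence) -> "CalciumTraceSet":
        """Return a new trace set restricted to ``cell_ids`` (order kept)."""
        idx = [self.cell_index(c) for c in cell_ids]
        return replace(
            self,
            cell_ids=list(cell_ids),
            C=self.C[idx],
            S=self.S[idx],
            YrA=None if self.YrA is None else self.YrA[idx],
            dff=None if self.dff is None else self.dff[idx],
            footprints=None if self.footprints is None else self.footprints[idx],
            category={c: self.category[c] for c in cell_ids if c in self.category},
        )


@dataclass
class TransientEvent:
    """One detected or annotated Ca2+ transient (its rising segment).

    ``interval_prev`` is the inter-transient interval (ITI): frame distance
    between the initial frames of two adjacent transients; ``None`` for the
    first event of a cell.
    """

    cell_id: object
    rise_start: int
    rise_stop: int
    peak_amplitude: float = np.nan
    total_amplitude: float = np.nan
    interval_prev: Optional[int] = None

    def __post_init__(self):
        self.rise_start = int(self.rise_start)
        self.rise_stop = int(self.rise_stop)
        if self.rise_start < 0 or self.rise_stop < self.rise_start:
            raise ValueError(
                f"invalid rise interval [{self.rise_start}, {self.rise_stop}] "
                f"for cell {self.cell_id!r}"
            )

    @property
    def n_rise_frames(self) -> int:
        """Inclusive frame count of the rising segment."""
        return self.rise_stop - self.rise_start + 1


@dataclass
class FrameLabels:
    """Per-frame binary rising-phase mask, one row per cell."""

    mask: np.ndarray
    cell_ids: Optional[List] = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (cells, frames)")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.int8)
        if self.cell_ids is not None:
            self.cell_ids = list(self.cell_ids)
            if len(self.cell_ids) != self.mask.shape[0]:
                raise ValueError("cell_ids length must match mask rows")

    @property
    def n_cells(self) -> int:
        return self.mask.shape[0]

    @property
    def n_frames(self) -> int:
        return self.mask.shape[1]


@dataclass
class DetectionParams:
    """Thresholds and signal-conditioning settings for parameter-based detection.

    The three acceptance thresholds:

    peak_threshold : float
        Minimum in-segment peak ΔF/F.
    interval_threshold : int
        Minimum ITI in frames; closer candidate pairs are merged.
    snr_threshold : float
        Minimum in-segment SNR.

    The remaining fields configure ΔF/F baselining and noise/SNR estimation
    (see :mod:`catrans.signal_processing`).
    """

    peak_threshold: float = 0.5
    interval_threshold: int = 10
    snr_threshold: float = 3.0
    savgol_window: int = 31
    savgol_polyorder: int = 3
    noise_window: int = 20
    noise_stat: str = "average"
    noise_floor: float = 0.1
    baseline_window: int = 600
    baseline_percentile: float = 8.0
    s_lookback: int = 5  # frames a C peak may trail the end of its S>0 run

    def __post_init__(self):
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_polyorder:
            raise ValueError("savgol_window must be odd and > savgol_polyorder")
        for name in ("peak_threshold", "interval_threshold", "snr_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be > 0")
        if self.noise_stat not in ("average", "median", "max"):
            raise ValueError("noise_stat must be one of average|median|max")
        if not 0 < self.baseline_percentile < 100:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")


def events_to_labels(
    events: Sequence[TransientEvent], n_cells: int, n_frames: int,
    cell_ids: Optional[Sequence] = None,
) -> FrameLabels:
    """Rasterize events into a binary rising-phase mask.

    The positive class covers the whole closed rising interval
    ``rise_start..rise_stop`` of each event.

    When ``cell_ids`` is given, ``event.cell_id`` is looked up in it;
    otherwise cell ids are taken to be row indices ``0..n_cells-1``.
    """
    mask = np.zeros((n_cells, n_frames), dtype=np.int8)
    if cell_ids is not None:
        cell_ids = list(cell_ids)
        row_of = {c: i for i, c in enumerate(cell_ids)}
    else:
        row_of = None
    for ev in events:
        if row_of is None:
            row = int(ev.cell_id)
            if not 0 <= row < n_cells:
                raise ValueError(f"event cell {ev.cell_id!r} out of range")
        else:
            if ev.cell_id not in row_of:
                raise ValueError(f"event cell {ev.cell_id!r} not in cell_ids")
            row = row_of[ev.cell_id]
        if ev.rise_stop >= n_frames:
            raise ValueError(
                f"event frames [{ev.rise_start}, {ev.rise_stop}] of cell "
                f"{ev.cell_id!r} exceed {n_frames} frames"
            )
        mask[row, ev.rise_start : ev.rise_stop + 1] = 1
    return FrameLabels(mask, cell_ids=cell_ids)


def labels_to_events(
    labels: FrameLabels, min_run: int = 1
) -> List[TransientEvent]:
    """Inverse of :func:`events_to_labels`: one event per maximal run of 1s.

    Runs shorter than ``min_run`` frames are discarded.  Amplitudes are left
    unset (``nan``); fill them from traces downstream.  ``interval_prev`` is
    populated per cell.
    """
    out: List[TransientEvent] = []
    for row in range(labels.n_cells):
        cid = labels.cell_ids[row] if labels.cell_ids is not None else row
        m = labels.mask[row]
        # run boundaries via sign changes of the padded mask
        diff = np.diff(np.concatenate(([0], m, [0])))
        starts = np.flatnonzero(diff == 1)
        stops = np.flatnonzero(diff == -1) - 1
        prev_start = None
        for a, b in zip(starts, stops):
            if b - a + 1 < min_run:
                continue
            ev = TransientEvent(cid, int(a), int(b))
            if prev_start is not None:
                ev.interval_prev = int(a) - prev_start
            prev_start = int(a)
            out.append(ev)
    return out
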