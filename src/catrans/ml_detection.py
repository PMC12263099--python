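"""Sequence-labeling transient detectors: windowing, training, inference.

The task is per-frame binary classification — does this frame lie inside a
transient's rising phase? — from two input channels, the CNMF C signal and
ΔF/F, each normalized to its per-cell maximum.  Four architectures are
supported: bidirectional GRU and LSTM stacks, and standard / local-attention
transformer encoders (see :mod:`catrans.nn`).

Windowing: each training sample is a ``seq_len``-frame core flanked by
``slack`` context frames on both sides (zero-padded at recording edges).
Slack frames inform the prediction but receive no loss.  Because rising
frames are only 2–3% of the data, windows whose core contains neither a
ground-truth positive nor a positive C value are discarded (stratification)
instead of re-weighting the loss, which over-promotes noise.

Inference slides windows with overlap and averages the per-frame sigmoid
probabilities of every window covering a frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .evaluation import macro_f1_from_masks
from .trace_model import CalciumTraceSet, FrameLabels, TransientEvent, labels_to_events

__all__ = [
    "TrainConfig",
    "WindowSample",
    "DetectorModel",
    "normalize_cell",
    "make_windows",
    "build_model",
    "train",
    "predict_frames",
    "classify",
    "save_model",
    "load_model",
]

_DEFAULT_HIDDEN = {"gru": 30, "lstm": 30, "transformer": 42, "local_transformer": 32}
_DEFAULT_HEADS = {"transformer": 2, "local_transformer": 1}


@dataclass
class TrainConfig:
    """Hyperparameters for the sequence-labeling detectors.

    Defaults are the reference configuration: hidden size 30 (recurrent),
    42 (transformer) or 32 (local transformer), 3 layers, Adam at learning
    rate 0.001 with binary cross-entropy on logits, 200-frame cores with
    50-frame slack; 2 attention heads for the standard transformer, 1 for
    the local variant with a 10-frame attention window and a look
    forward/backward of 5 local windows.
    """

    model_kind: str = "gru"
    hidden_size: Optional[int] = None  # resolved per model_kind when None
    n_layers: int = 3
    learning_rate: float = 1e-3
    seq_len: int = 200
    slack: int = 50
    heads: Optional[int] = None  # resolved per model_kind when None
    local_window: int = 10
    look: int = 5  # look forward/backward, in local windows
    epochs: int = 50
    patience: int = 5  # early stopping on validation macro-F1; <=0 disables
    batch_size: int = 8
    step: Optional[int] = None  # window stride; default seq_len // 2
    threshold: float = 0.5
    min_run: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in _DEFAULT_HIDDEN:
            raise ValueError(
                f"unknown model_kind {self.model_kind!r}; "
                f"expected one of {sorted(_DEFAULT_HIDDEN)}"
            )
        if self.hidden_size is None:
            self.hidden_size = _DEFAULT_HIDDEN[self.model_kind]
        if self.heads is None:
            self.heads = _DEFAULT_HEADS.get(self.model_kind, 1)
        if self.step is None:
            self.step = self.seq_len // 2
        if not (self.seq_len > 0 and self.slack >= 0 and self.step > 0):
            raise ValueError("seq_len/step must be positive, slack non-negative")

    @property
    def context_len(self) -> int:
        return self.seq_len + 2 * self.slack


@dataclass
class WindowSample:
    """One training window: 2-channel context input + core-interval targets."""

    cell_id: object
    t0: int  # core start frame
    inputs: np.ndarray  # (context_len, 2): normalized C, normalized dff
    targets: np.ndarray  # (seq_len,) binary labels over the core


def normalize_cell(
    ts: CalciumTraceSet, cell_id
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Scale a cell's C and ΔF/F by their per-cell maxima.

    Returns the two normalized channels and the constants, which are reused
    verbatim at inference so train/test scales match.  An all-zero channel
    normalizes by 1 (with a warning) rather than dividing by zero.
    """
    if ts.dff is None:
        raise ValueError("trace set has no dff; compute it before windowing")
    row = ts.cell_index(cell_id)
    consts = {}
    out = []
    for name, sig in (("C", ts.C[row]), ("dff", ts.dff[row])):
        m = float(np.max(sig))
        if m <= 0:
            warnings.warn(
                f"cell {cell_id!r}: channel {name} has no positive values; "
                "normalizing by 1",
                RuntimeWarning,
                stacklevel=2,
            )
            m = 1.0
        consts[name] = m
        out.append(sig / m)
    return out[0], out[1], consts


def _padded_context(channels: np.ndarray, t0: int, cfg: TrainConfig) -> np.ndarray:
    """Extract (context_len, 2) input around core start ``t0``, zero-padded."""
    n = channels.shape[0]
    lo, hi = t0 - cfg.slack, t0 + cfg.seq_len + cfg.slack
    out = np.zeros((cfg.context_len, channels.shape[1]))
    src_lo, src_hi = max(lo, 0), min(hi, n)
    out[src_lo - lo : src_hi - lo] = channels[src_lo:src_hi]
    return out


def make_windows(
    ts: CalciumTraceSet,
    labels: FrameLabels,
    cfg: TrainConfig,
    step: Optional[int] = None,
    cell_ids: Optional[Sequence] = None,
    stratify: bool = True,
) -> List[WindowSample]:
    """Chunk cells into overlapping training windows.

    Cores start at multiples of ``step`` per cell (windows whose core would
    overrun the recording are dropped).  With ``stratify`` on, a window
    survives only if its core contains a positive label or a positive C
    value — ground-truth positives are therefore never discarded.
    """
    if labels.mask.shape != ts.C.shape:
        raise ValueError("labels are not aligned with the trace set")
    step = cfg.step if step is None else step
    if cfg.seq_len > ts.n_frames:
        raise ValueError(
            f"seq_len {cfg.seq_len} exceeds recording length {ts.n_frames}"
        )
    cids = list(ts.cell_ids) if cell_ids is None else list(cell_ids)
    out: List[WindowSample] = []
    for cid in cids:
        row = ts.cell_index(cid)
        c_norm, d_norm, _ = normalize_cell(ts, cid)
        channels = np.stack([c_norm, d_norm], axis=1)
        raw_c = ts.C[row]
        lab = labels.mask[row]
        for t0 in range(0, ts.n_frames - cfg.seq_len + 1, step):
            core = slice(t0, t0 + cfg.seq_len)
            if stratify and not (lab[core].any() or (raw_c[core] > 0).any()):
                continue
            out.append(
                WindowSample(
                    cell_id=cid,
                    t0=t0,
                    inputs=_padded_context(channels, t0, cfg),
                    targets=lab[core].astype(float),
                )
            )
    return out


@dataclass
class DetectorModel:
    """A trained (or initialized) detector: network + its configuration.

    ``norm_constants`` holds the per-training-cell normalization maxima for
    provenance; inference normalizes each test cell by its own maxima, the
    same per-cell convention used in training.
    """

    cfg: TrainConfig
    net: nn.Module
    norm_constants: Dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def forward_logits(self, inputs: np.ndarray) -> np.ndarray:
        """(batch, context_len, 2) -> core logits (batch, seq_len)."""
        logits = self.net(nn.Tensor(inputs))
        s = self.cfg.slack
        return logits.data[:, s : s + self.cfg.seq_len]


def build_model(cfg: TrainConfig) -> DetectorModel:
    """Instantiate the architecture named by ``cfg.model_kind``."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.model_kind in ("gru", "lstm"):
        net = nn.BiRNN(cfg.model_kind, 2, cfg.hidden_size, cfg.n_layers, rng)
    else:
        net = nn.TransformerEncoder(
            2,
            cfg.hidden_size,
            cfg.n_layers,
            cfg.heads,
            max_len=cfg.context_len,
            rng=rng,
            local=cfg.model_kind == "local_transformer",
            local_window=cfg.local_window,
            look=cfg.look,
        )
    return DetectorModel(cfg=cfg, net=net)


def _core_logits_tensor(model: DetectorModel, inputs: np.ndarray) -> nn.Tensor:
    logits = model.net(nn.Tensor(inputs))
    s = model.cfg.slack
    return logits[:, s : s + model.cfg.seq_len]


def _window_macro_f1(model: DetectorModel, windows: Sequence[WindowSample]) -> float:
    pred_rows, true_rows = [], []
    cfg = model.cfg
    for i in range(0, len(windows), cfg.batch_size):
        chunk = windows[i : i + cfg.batch_size]
        x = np.stack([w.inputs for w in chunk])
        logits = model.forward_logits(x)
        pred_rows.append((1.0 / (1.0 + np.exp(-logits)) >= cfg.threshold))
        true_rows.append(np.stack([w.targets for w in chunk]))
    pred = np.concatenate(pred_rows).astype(np.int8)
    true = np.concatenate(true_rows).astype(np.int8)
    return macro_f1_from_masks(pred, true)


def train(
    model: DetectorModel,
    train_windows: Sequence[WindowSample],
    val_windows: Sequence[WindowSample],
    cfg: Optional[TrainConfig] = None,
) -> Tuple[DetectorModel, List[Dict]]:
    """Fit the detector with Adam on per-frame BCE over core intervals.

    Deterministic given ``cfg.seed``.  Each epoch records train loss, and —
    when a validation set is supplied — validation loss and frame-level
    macro-F1; the parameter snapshot with the best validation macro-F1 is
    restored at the end, with early stopping after ``patience`` epochs
    without improvement.
    """
    cfg = model.cfg if cfg is None else cfg
    if not train_windows:
        raise ValueError("empty training set")
    train_cells = {w.cell_id for w in train_windows}
    val_cells = {w.cell_id for w in val_windows}
    if train_cells & val_cells:
        raise ValueError(
            f"train/val cell sets overlap: {sorted(train_cells & val_cells)}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.net.parameters(), lr=cfg.learning_rate)
    history: List[Dict] = []
    best_f1, best_state, stale = -np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_windows))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            chunk = [train_windows[j] for j in order[i : i + cfg.batch_size]]
            x = np.stack([w.inputs for w in chunk])
            y = np.stack([w.targets for w in chunk])
            logits = _core_logits_tensor(model, x)
            loss = nn.bce_with_logits(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_windows:
            vx = np.stack([w.inputs for w in val_windows])
            vy = np.stack([w.targets for w in val_windows])
            val_losses = []
            for i in range(0, len(val_windows), cfg.batch_size):
                logits = model.forward_logits(vx[i : i + cfg.batch_size])
                z = logits
                yv = vy[i : i + cfg.batch_size]
                val_losses.append(
                    np.mean(
                        np.maximum(z, 0) - z * yv + np.log1p(np.exp(-np.abs(z)))
                    )
                )
            rec["val_loss"] = float(np.mean(val_losses))
            rec["val_macro_f1"] = _window_macro_f1(model, val_windows)
            if rec["val_macro_f1"] > best_f1:
                best_f1 = rec["val_macro_f1"]
                best_state = model.net.state_dict()
                stale = 0
            else:
                stale += 1
        history.append(rec)
        if val_windows and cfg.patience > 0 and stale >= cfg.patience:
            break
    if best_state is not None:
        model.net.load_state_dict(best_state)
    return model, history


def predict_frames(
    model: DetectorModel,
    ts: CalciumTraceSet,
    cell_ids: Optional[Sequence] = None,
    step: Optional[int] = None,
) -> np.ndarray:
    """Per-frame transient probabilities, overlap-averaged.

    Windows slide at ``step`` (default ``cfg.step``); a trailing window
    anchored at the recording end guarantees every frame is covered at least
    once.  Each frame's probability is the mean sigmoid output over all
    windows covering it.
    """
    cfg = model.cfg
    step = cfg.step if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    cids = list(ts.cell_ids) if cell_ids is None else list(cell_ids)
    n = ts.n_frames
    if cfg.seq_len > n:
        raise ValueError(f"seq_len {cfg.seq_len} exceeds recording length {n}")
    starts = list(range(0, n - cfg.seq_len + 1, step))
    if starts[-1] != n - cfg.seq_len:
        starts.append(n - cfg.seq_len)
    probs = np.zeros((len(cids), n))
    for ci, cid in enumerate(cids):
        c_norm, d_norm, _ = normalize_cell(ts, cid)
        channels = np.stack([c_norm, d_norm], axis=1)
        acc = np.zeros(n)
        cov = np.zeros(n)
        for i in range(0, len(starts), cfg.batch_size):
            chunk = starts[i : i + cfg.batch_size]
            x = np.stack([_padded_context(channels, t0, cfg) for t0 in chunk])
            logits = model.forward_logits(x)
            p = 1.0 / (1.0 + np.exp(-logits))
            for t0, prow in zip(chunk, p):
                acc[t0 : t0 + cfg.seq_len] += prow
                cov[t0 : t0 + cfg.seq_len] += 1
        probs[ci] = acc / cov
    return probs


def classify(
    probabilities: np.ndarray,
    threshold: float = 0.5,
    min_run: int = 2,
    cell_ids: Optional[Sequence] = None,
) -> Tuple[FrameLabels, List[TransientEvent]]:
    """Binarize probabilities and extract events from the label runs."""
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    labels = FrameLabels((p >= threshold).astype(np.int8), cell_ids=cell_ids)
    return labels, labels_to_events(labels, min_run=min_run)


def save_model(model: DetectorModel, path) -> None:
    """Checkpoint a detector (architecture config, weights, normalization)."""
    meta = {
        "cfg": asdict(model.cfg),
        "norm_constants": {str(k): v for k, v in model.norm_constants.items()},
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.net.state_dict())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> DetectorModel:
    """Inverse of :func:`save_model`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        n = len([k for k in z.files if k.startswith("param_")])
        state = [z[f"param_{i}"] for i in range(n)]
    model = build_model(TrainConfig(**meta["cfg"]))
    model.net.load_state_dict(state)
    model.norm_constants = meta["norm_constants"]
    return model
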