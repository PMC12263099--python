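"""ΔF/F computation, Savitzky–Golay smoothing, noise and SNR estimation.

The SNR model is local rather than global: a z-score against whole-trace
noise rejects valid transients whenever the noise level drifts, so noise is
estimated per frame from the absolute Savitzky–Golay residual

    noise(t) = rolling_stat(|x(t) - savgol(x)(t)|)

floored at ``noise_floor`` to keep the quotient bounded, and

    SNR(t) = savgol(x)(t) / max(noise(t), noise_floor).

All rolling windows (percentile baseline, noise smoothing) are centered and
truncated at the trace edges — outputs keep full length and no boundary
values are fabricated by padding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .trace_model import CalciumTraceSet, DetectionParams

__all__ = [
    "compute_dff",
    "savgol_smooth",
    "estimate_noise",
    "compute_snr",
    "ensure_dff",
]

# Smallest admissible baseline; F0 below this is clamped before division.
_F0_FLOOR = np.finfo(float).tiny ** 0.5


def compute_dff(
    F: np.ndarray,
    baseline_window: int = 600,
    baseline_percentile: float = 8.0,
    centered: bool = True,
) -> np.ndarray:
    """Relative fluorescence change ΔF/F = (F − F0) / F0.

    F0 is the background fluorescence, estimated per frame as the given
    percentile of F over a moving window (truncated at edges).

    Parameters
    ----------
    F : 1-D array
        Raw fluorescence trace (finite values).
    baseline_window : int
        Moving-percentile window length in frames.
    baseline_percentile : float
        Percentile in (0, 100); low values track the inter-event baseline.
    centered : bool
        Center the window on the current frame (default); ``False`` uses a
        trailing window, matching upstream pipelines that baseline causally.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 1:
        raise ValueError("compute_dff operates on a single 1-D trace")
    if not np.isfinite(F).all():
        raise ValueError("F contains non-finite values")
    if baseline_window < 1:
        raise ValueError("baseline_window must be >= 1")
    f0 = (
        pd.Series(F)
        .rolling(baseline_window, center=centered, min_periods=1)
        .quantile(baseline_percentile / 100.0)
        .to_numpy()
    )
    n_bad = int(np.sum(f0 < _F0_FLOOR))
    if n_bad:
        warnings.warn(
            f"F0 non-positive on {n_bad} frame(s); clamped to machine floor",
            RuntimeWarning,
            stacklevel=2,
        )
    f0 = np.maximum(f0, _F0_FLOOR)
    return (F - f0) / f0


def savgol_smooth(x: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky–Golay least-squares local-polynomial smoothing.

    Reproduces any global polynomial of degree <= ``polyorder`` exactly,
    which is what preserves transient peak shape while removing noise.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if window > x.shape[-1]:
        raise ValueError(
            f"savgol window {window} exceeds trace length {x.shape[-1]}"
        )
    return savgol_filter(x, window, polyorder, axis=-1)


def _rolling_stat(x: np.ndarray, window: int, stat: str) -> np.ndarray:
    r = pd.Series(np.asarray(x, dtype=float)).rolling(
        window, center=True, min_periods=1
    )
    if stat == "average":
        return r.mean().to_numpy()
    if stat == "median":
        return r.median().to_numpy()
    if stat == "max":
        return r.max().to_numpy()
    raise ValueError(f"unknown noise_stat {stat!r}")


def estimate_noise(x: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Per-frame noise: rolling-smoothed |SavGol residual|, floored.

    noise = rolling_stat(|x − savgol(x)|, noise_window, noise_stat),
    then elementwise max with ``noise_floor``.
    """
    x = np.asarray(x, dtype=float)
    resid = np.abs(x - savgol_smooth(x, params.savgol_window, params.savgol_polyorder))
    noise = _rolling_stat(resid, params.noise_window, params.noise_stat)
    return np.maximum(noise, params.noise_floor)


def compute_snr(x: np.ndarray, params: DetectionParams) -> np.ndarray:
    """SNR(t) = smoothed ΔF/F divided by the floored noise estimate.

    The floor applies to the denominator, so on near-noiseless traces the
    SNR degenerates to savgol(x) / noise_floor and mirrors ΔF/F.
    """
    x = np.asarray(x, dtype=float)
    sm = savgol_smooth(x, params.savgol_window, params.savgol_polyorder)
    noise = estimate_noise(x, params)
    return sm / np.maximum(noise, params.noise_floor)


def ensure_dff(ts: CalciumTraceSet, params: DetectionParams) -> np.ndarray:
    """Return the trace set's ΔF/F matrix, computing and caching it if absent.

    When raw traces are unavailable the residual-corrected raw signal
    ``C + YrA`` is used as F; with neither YrA nor dff present, C itself is
    baselined (upstream C is already background-subtracted, so this is a
    degraded fallback and a warning is emitted).
    """
    if ts.dff is not None:
        return ts.dff
    if ts.YrA is not None:
        F = ts.C + ts.YrA
    else:
        warnings.warn(
            "no dff or YrA present; computing ΔF/F from C alone",
            RuntimeWarning,
            stacklevel=2,
        )
        F = ts.C
    dff = np.vstack(
        [
            compute_dff(row, params.baseline_window, params.baseline_percentile)
            for row in F
        ]
    )
    ts.dff = dff
    return dff
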