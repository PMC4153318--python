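"""Firing-onset inference from calcium fluorescence.

Fluorescence is modelled as a first-order autoregressive (AR(1)) process:
each action potential adds a calcium transient that decays exponentially
with time constant ``decay_s``. Inference inverts this forward model with a
non-negative least-squares deconvolution (pool-adjacent-violators, the core
of the standard fast AR(1) spike-inference algorithms), after removing a
slow running-percentile baseline. The continuous activity signal is then
binarized per cell at ``median + k·MAD``, marking one onset per rising
threshold crossing.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .core import ImagingRecording, OnsetRaster

DEFAULT_DECAY_S = 1.0
DEFAULT_K_MAD = 3.0
BASELINE_WINDOW_S = 30.0
BASELINE_PERCENTILE = 20.0


def running_percentile_baseline(
    traces: np.ndarray,
    frame_rate_hz: float,
    window_s: float = BASELINE_WINDOW_S,
    percentile: float = BASELINE_PERCENTILE,
) -> np.ndarray:
    """Centered running-percentile baseline, one row per cell.

    Robust to discharge-dense epochs: a low percentile tracks the resting
    fluorescence even when transients occupy much of the window.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    window = max(int(round(window_s * frame_rate_hz)), 1)
    df = pd.DataFrame(traces.T)
    base = df.rolling(window, center=True, min_periods=1).quantile(
        percentile / 100.0
    )
    return base.to_numpy().T


def _oasis_ar1(y: np.ndarray, gamma: float) -> np.ndarray:
    """Non-negative LS fit of an AR(1) calcium trace (pool adjacent violators).

    Returns the fitted denoised calcium ``c`` with ``c_t >= gamma * c_{t-1}``
    everywhere (all implied spike amplitudes non-negative).
    """
    # pools: [v, w, t, l]; fitted height at pool start is v/w
    pools: list = []
    for i, yt in enumerate(y):
        pools.append([float(yt), 1.0, i, 1])
        while len(pools) > 1:
            v1, w1, t1, l1 = pools[-2]
            v0, w0, t0, l0 = pools[-1]
            if v0 / w0 >= gamma**l1 * (v1 / w1):
                break  # implied spike amplitude non-negative
            g = gamma**l1
            pools.pop()
            pools[-1] = [v1 + g * v0, w1 + g * g * w0, t1, l1 + l0]
    c = np.empty_like(np.asarray(y, dtype=float))
    for v, w, t, l in pools:
        h = max(v / w, 0.0)
        c[t : t + l] = h * gamma ** np.arange(l)
    return c


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust per-cell noise SD from the first difference of the trace."""
    d = np.diff(np.asarray(trace, dtype=float))
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / (0.6745 * np.sqrt(2.0)))


def infer_spike_signal(
    rec: ImagingRecording,
    decay_s: float = DEFAULT_DECAY_S,
    noise_scale: Optional[float] = None,
    baseline_window_s: float = BASELINE_WINDOW_S,
    baseline_percentile: float = BASELINE_PERCENTILE,
) -> np.ndarray:
    """Deconvolved non-negative activity signal, shape (n_cells, n_frames).

    Parameters
    ----------
    rec : ImagingRecording
        Input fluorescence recording.
    decay_s : float
        AR(1) decay time constant of the calcium indicator, seconds.
        Values shorter than one frame are clamped with a warning.
    noise_scale : float, optional
        If given, deconvolved amplitudes below ``noise_scale`` times the
        per-cell robust noise SD are zeroed (sparsification).
    """
    if not decay_s > 0:
        raise ValueError("decay_s must be > 0")
    rate = rec.frame_rate_hz
    frame_dt = 1.0 / rate
    if decay_s < frame_dt:
        warnings.warn(
            f"decay_s={decay_s} shorter than one frame ({frame_dt:.4f} s); clamping"
        )
        decay_s = frame_dt
    gamma = float(np.exp(-frame_dt / decay_s))

    traces = rec.fluorescence - running_percentile_baseline(
        rec.fluorescence, rate, baseline_window_s, baseline_percentile
    )
    signal = np.empty_like(traces)
    for i in range(traces.shape[0]):
        c = _oasis_ar1(traces[i], gamma)
        s = np.empty_like(c)
        s[0] = c[0]
        s[1:] = c[1:] - gamma * c[:-1]
        np.clip(s, 0.0, None, out=s)
        if noise_scale is not None:
            s[s < noise_scale * estimate_noise_sd(traces[i])] = 0.0
        signal[i] = s
    return signal


def reconvolve(signal: np.ndarray, decay_s: float, frame_rate_hz: float) -> np.ndarray:
    """Forward AR(1) model: turn an activity signal back into fluorescence."""
    gamma = float(np.exp(-1.0 / (frame_rate_hz * decay_s)))
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    out = np.empty_like(signal)
    out[:, 0] = signal[:, 0]
    for f in range(1, signal.shape[1]):
        out[:, f] = gamma * out[:, f - 1] + signal[:, f]
    return out


def binarize_onsets(
    signal: np.ndarray,
    k_mad: float = DEFAULT_K_MAD,
    frame_times_s: Optional[np.ndarray] = None,
    source_recording: str = "",
) -> OnsetRaster:
    """Binary onset raster: one onset per rising crossing of median + k·MAD.

    The MAD is the raw median absolute deviation of the cell's signal
    (no normal-consistency scaling), floored at a small fraction of the
    cell's signal maximum so that sparse near-noiseless signals (whose MAD
    is zero) do not yield a degenerate zero threshold. A cell whose signal
    never exceeds its threshold yields an empty row; an all-constant
    signal yields no onsets.
    """
    if not k_mad > 0:
        raise ValueError("k_mad must be > 0")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    med = np.median(signal, axis=1, keepdims=True)
    mad = np.median(np.abs(signal - med), axis=1, keepdims=True)
    mad_floor = 1e-3 * np.abs(signal).max(axis=1, keepdims=True)
    thr = med + k_mad * np.maximum(mad, mad_floor)

    above = signal > thr
    onsets = np.zeros_like(above, dtype=np.uint8)
    onsets[:, 0] = above[:, 0]
    onsets[:, 1:] = above[:, 1:] & ~above[:, :-1]

    if frame_times_s is None:
        frame_times_s = np.arange(signal.shape[1], dtype=float)
    return OnsetRaster(
        onsets=onsets,
        frame_times_s=frame_times_s,
        source_recording=source_recording,
    )


def infer_onsets(
    rec: ImagingRecording,
    decay_s: float = DEFAULT_DECAY_S,
    k_mad: float = DEFAULT_K_MAD,
    noise_scale: Optional[float] = None,
) -> OnsetRaster:
    """Full pipeline: deconvolve a recording and binarize per-cell onsets."""
    signal = infer_spike_signal(rec, decay_s=decay_s, noise_scale=noise_scale)
    return binarize_onsets(
        signal,
        k_mad=k_mad,
        frame_times_s=rec.frame_times_s,
        source_recording=rec.recording_id,
    )
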