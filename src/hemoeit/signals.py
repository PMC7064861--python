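"""Boundary-voltage summary statistics and respiratory/hemorrhage separation.

The total boundary voltage (TBV) per frame is the sum of the valid-channel
voltage magnitudes; TBVV expresses it as a percent change relative to a
reference frame.  Because ventilation is periodic (~0.4 Hz at 25
cycles/min) while a bleed grows monotonically, the hemorrhage component
of each channel is extracted with a zero-phase 4th-order low-pass
Butterworth filter (-3 dB at 0.15 Hz); the respiratory component is the
remainder, so the decomposition is exactly additive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal as sps

from .forward import FrameSeries

__all__ = [
    "TbvSeries",
    "ComponentSplit",
    "compute_tbv",
    "compute_tbvv",
    "tbv_series",
    "power_spectrum",
    "dominant_frequency",
    "separate_components",
]


@dataclass
class TbvSeries:
    times: np.ndarray
    tbv: np.ndarray  # volts, summed channel magnitudes
    tbvv: np.ndarray  # percent, relative to the reference frame
    ref_index: int


def _frame_values(frames) -> np.ndarray:
    if isinstance(frames, FrameSeries):
        return frames.voltages
    return np.asarray(frames, dtype=float)


def compute_tbv(frames) -> np.ndarray:
    """Per-frame total boundary voltage: sum of |v| over valid channels."""
    v = _frame_values(frames)
    if v.size == 0:
        raise ValueError("empty frame series")
    return np.abs(v).sum(axis=1)


def compute_tbvv(tbv: np.ndarray, ref_index: int = 0) -> np.ndarray:
    """Percent variation of TBV relative to the frame at ``ref_index``."""
    tbv = np.asarray(tbv, dtype=float)
    ref = tbv[ref_index]
    if ref == 0:
        raise ZeroDivisionError("reference TBV is zero; TBVV undefined")
    return (tbv - ref) / ref * 100.0


def tbv_series(frames: FrameSeries, ref_index: int = 0) -> TbvSeries:
    tbv = compute_tbv(frames)
    return TbvSeries(
        times=frames.times,
        tbv=tbv,
        tbvv=compute_tbvv(tbv, ref_index),
        ref_index=ref_index,
    )


def power_spectrum(values, fs: float, times=None):
    """One-sided power spectrum of a uniformly sampled series after mean
    removal.  Returns (frequencies Hz, power)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("power_spectrum expects a 1D series")
    if len(values) < 64:
        raise ValueError("need at least 64 samples for a usable spectrum")
    if times is not None:
        dt = np.diff(np.asarray(times, dtype=float))
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time stamps are not uniformly spaced")
    freqs, power = sps.periodogram(values, fs=fs, detrend="constant")
    return freqs, power


def dominant_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    """Argmax frequency of a one-sided spectrum, excluding the DC bin."""
    return float(freqs[1:][np.argmax(power[1:])])


@dataclass
class ComponentSplit:
    """Additive decomposition of a frame series: raw = injection + respiration."""

    injection: FrameSeries  # slow (hemorrhage) component
    respiration: FrameSeries  # periodic remainder
    filter_spec: dict


def separate_components(
    frames: FrameSeries, order: int = 4, cutoff_hz: float = 0.15
) -> ComponentSplit:
    """Split each channel into a slow injection component (zero-phase
    low-pass Butterworth output) and a respiratory remainder.

    The filter is applied forward-backward (no group delay, attenuation
    squared) with reflect padding to suppress startup transients.
    """
    fs = frames.fs
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {fs / 2} Hz")
    padlen = int(3 * fs / cutoff_hz)
    if frames.n_frames <= padlen:
        raise ValueError(
            f"series too short for the filter: need > {padlen} frames, "
            f"got {frames.n_frames}"
        )
    b, a = sps.butter(order, cutoff_hz / (fs / 2))
    low = sps.filtfilt(b, a, frames.voltages, axis=0, padtype="even",
                       padlen=padlen)
    resp = frames.voltages - low
    spec = {"design": "butterworth", "order": order, "cutoff_hz": cutoff_hz,
            "zero_phase": True, "padding": "reflect", "padlen": padlen}
    meta = dict(frames.metadata)
    injection = FrameSeries(frames.times, low, frames.protocol,
                            {**meta, "component": "injection"})
    respiration = FrameSeries(frames.times, resp, frames.protocol,
                              {**meta, "component": "respiration"})
    return ComponentSplit(injection=injection, respiration=respiration,
                          filter_spec=spec)
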