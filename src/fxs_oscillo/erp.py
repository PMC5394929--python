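"""Event-related potentials: sweep averaging and P20/N40 peak picking.

The rodent auditory ERP has a positive component near 20 ms (P20) and
a negative component near 40 ms (N40).  Following the standard
convention, P20 is the largest positive deflection in the closed
15-30 ms window and N40 the largest negative deflection in 30-100 ms;
both are measured relative to the pre-stimulus baseline mean and ties
resolve to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EmptyInputError, EpochSet, ValidationError

P20_WINDOW_MS = (15.0, 30.0)
N40_WINDOW_MS = (30.0, 100.0)


@dataclass(frozen=True)
class ErpFeatures:
    """P20/N40 amplitudes (µV, baseline-referenced) and latencies (ms)."""

    p20_amp: float
    p20_lat_ms: float
    n40_amp: float
    n40_lat_ms: float
    n_sweeps_used: int


def average_erp(ep: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Mean over kept sweeps after per-sweep baseline subtraction.

    The baseline is the mean of each sweep over the pre-stimulus part
    of the epoch (t < 0).  Returns ``(t, avg)`` in seconds / µV.
    """
    if ep.n_kept == 0:
        raise EmptyInputError("no kept sweeps to average")
    data = ep.kept_data()
    pre = ep.t < 0
    if pre.any():
        data = data - data[:, pre].mean(axis=1, keepdims=True)
    return ep.t, data.mean(axis=0)


def _peak(t: np.ndarray, avg: np.ndarray, window_ms: tuple[float, float],
          mode: str) -> tuple[float, float]:
    lo, hi = window_ms[0] / 1e3, window_ms[1] / 1e3
    if t[0] > lo or t[-1] < hi:
        raise ValidationError(
            f"waveform [{t[0] * 1e3:.1f}, {t[-1] * 1e3:.1f}] ms does not cover "
            f"the [{window_ms[0]:.0f}, {window_ms[1]:.0f}] ms search window"
        )
    mask = (t >= lo) & (t <= hi)
    seg, tseg = avg[mask], t[mask]
    idx = int(np.argmax(seg) if mode == "max" else np.argmin(seg))  # first = earliest tie
    return float(seg[idx]), float(tseg[idx] * 1e3)


def detect_p20(t: np.ndarray, avg: np.ndarray,
               window_ms: tuple[float, float] = P20_WINDOW_MS) -> tuple[float, float]:
    """Largest positive deflection in the closed P20 window → (amp µV, lat ms)."""
    return _peak(np.asarray(t, float), np.asarray(avg, float), window_ms, "max")


def detect_n40(t: np.ndarray, avg: np.ndarray,
               window_ms: tuple[float, float] = N40_WINDOW_MS) -> tuple[float, float]:
    """Largest negative deflection (signed minimum) in the N40 window."""
    return _peak(np.asarray(t, float), np.asarray(avg, float), window_ms, "min")


def erp_features(ep: EpochSet) -> ErpFeatures:
    """Average the kept sweeps and extract both components."""
    t, avg = average_erp(ep)
    p20_amp, p20_lat = detect_p20(t, avg)
    n40_amp, n40_lat = detect_n40(t, avg)
    return ErpFeatures(p20_amp, p20_lat, n40_amp, n40_lat, ep.n_kept)
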