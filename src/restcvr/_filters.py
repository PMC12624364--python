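"""Temporal filtering helpers.

Two kinds of band-pass live here:

* :func:`butter_bandpass` — the analysis-side filter: linear detrend followed
  by a zero-phase 4th-order Butterworth (forward-backward), output demeaned.
* :func:`fft_bandlimit` — an ideal (brick-wall) zero-phase band-pass used by
  the synthetic-data generator where exact spectral confinement is wanted.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

BUTTER_ORDER = 4


def _check_band(lo_hz: float, hi_hz: float, tr_s: float) -> None:
    nyq = 0.5 / tr_s
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}] Hz must satisfy 0 < lo < hi < Nyquist ({nyq:.4g} Hz)"
        )


def butter_bandpass(
    ts: np.ndarray,
    lo_hz: float,
    hi_hz: float,
    tr_s: float,
    order: int = BUTTER_ORDER,
    detrend: bool = True,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass after linear detrend; output demeaned.

    Works along the last axis, so a (voxels, frames) array filters every
    voxel at once. Raises if the series is too short for the filter's
    forward-backward padding.
    """
    ts = np.asarray(ts, dtype=np.float64)
    _check_band(lo_hz, hi_hz, tr_s)
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=1.0 / tr_s, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    n = ts.shape[-1]
    if n <= padlen or n < 3 * order:
        raise ValueError(f"series of length {n} too short for order-{order} band-pass")
    x = signal.detrend(ts, axis=-1, type="linear") if detrend else ts
    y = signal.sosfiltfilt(sos, x, axis=-1)
    return y - y.mean(axis=-1, keepdims=True)


def fft_bandlimit(ts: np.ndarray, lo_hz: float, hi_hz: float, tr_s: float) -> np.ndarray:
    """Ideal zero-phase band-pass: zero every DFT bin outside [lo, hi] Hz.

    Band edges are inclusive. Raises if no frequency bin falls in the band.
    """
    ts = np.asarray(ts, dtype=np.float64)
    _check_band(lo_hz, hi_hz, tr_s)
    n = ts.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= lo_hz) & (freqs <= hi_hz)
    if not keep.any():
        raise ValueError(
            f"no DFT bin in [{lo_hz}, {hi_hz}] Hz for n={n}, TR={tr_s}s "
            f"(bin spacing {freqs[1]:.5f} Hz)"
        )
    coef = np.fft.rfft(ts, axis=-1)
    coef[..., ~keep] = 0.0
    return np.fft.irfft(coef, n=n, axis=-1)
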