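"""Small shared signal helpers."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; passthrough if cutoff >= Nyquist."""
    x = np.asarray(x, dtype=float)
    if cutoff >= 0.5 * fs or len(x) < 3 * (order + 1):
        return x.copy()
    sos = sps.butter(order, cutoff, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)
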