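"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np

#: scale factor turning a median absolute deviation into a Gaussian SD
MAD_TO_SD = 1.4826


def robust_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD of a 1-D signal, insensitive to sparse transients.

    The trace is detrended by first differencing (which removes slow
    transients but doubles the noise variance, hence the sqrt(2) factor)
    and the SD is estimated as 1.4826 x the median absolute deviation.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(MAD_TO_SD * mad / np.sqrt(2.0))
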