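"""Guided image filter.

The output q is a local linear transform of the guide I: within each
(2r+1)^2 window w_k,

    a_k = cov_w(I, p) / (var_w(I) + eps),   b_k = mean_w(p) - a_k mean_w(I),

and per pixel the coefficients of all windows containing it are averaged:
q = a_bar * I + b_bar.  Window statistics use truncated (shrinking) windows
at the borders — the mean is over the pixels actually inside the image — so
constants are preserved everywhere, matching the original reference
implementation's normalized box filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GifParams", "box_mean", "guided_filter"]


@dataclass(frozen=True)
class GifParams:
    """Guided-filter tunables: window radius ``r`` and regularizer ``eps``."""

    r: int = 3
    eps: float = 1.0

    def __post_init__(self):
        if not isinstance(self.r, (int, np.integer)) or self.r < 0:
            raise ValueError("r must be a nonnegative integer")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


def box_mean(x: np.ndarray, r: int) -> np.ndarray:
    """Mean over (2r+1)^2 sliding windows, truncated at the borders."""
    if r < 0:
        raise ValueError("r must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("box_mean expects a 2-D array")
    if r == 0:
        return x.copy()
    win = 2 * r + 1
    padded = np.pad(x, r, mode="constant")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (win, win))
    sums = windows.sum(axis=(-2, -1))
    ones = np.pad(np.ones_like(x), r, mode="constant")
    counts = np.lib.stride_tricks.sliding_window_view(ones, (win, win)).sum(axis=(-2, -1))
    return sums / counts


def guided_filter(
    p: np.ndarray, I: np.ndarray, params: GifParams | None = None
) -> np.ndarray:
    """Filter ``p`` guided by ``I`` (notation ``G_{r,eps}(p, I)``)."""
    params = params or GifParams()
    p = np.asarray(p, dtype=np.float64)
    I = np.asarray(I, dtype=np.float64)
    if p.shape != I.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs I {I.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(I))):
        raise ValueError("inputs must be finite")
    r, eps = params.r, params.eps

    mean_I = box_mean(I, r)
    mean_p = box_mean(p, r)
    mean_Ip = box_mean(I * p, r)
    mean_II = box_mean(I * I, r)
    cov_Ip = mean_Ip - mean_I * mean_p
    var_I = np.maximum(mean_II - mean_I * mean_I, 0.0)  # clamp fp negatives

    denom = var_I + eps
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, cov_Ip / np.where(denom > 0, denom, 1.0), 0.0)
    b = mean_p - a * mean_I
    return box_mean(a, r) * I + box_mean(b, r)
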