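"""High-frequency sub-band fusion: WSEML activity + guided-filter refinement.

Each pair of directional sub-bands is fused by

1. measuring per-pixel activity with the weighted sum of the
   eight-neighbourhood modified Laplacian (WSEML);
2. taking the binary argmax decision maps (ties favour source A);
3. smoothing each map with the guided filter, using the corresponding raw
   sub-band as guide, so the weights follow coefficient edges;
4. normalizing the two refined maps to per-pixel weights summing to 1 and
   blending the sub-bands.

Sub-bands are signed band-pass coefficients; activities are computed on the
raw signed values (absolute values appear only inside the modified-Laplacian
terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .guided import GifParams, guided_filter

__all__ = [
    "WsemlParams",
    "WeightMaps",
    "eml",
    "wseml",
    "initial_decision_maps",
    "fuse_high_frequency",
]

_DEFAULT_WEIGHTS = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0

#: weight on the two diagonal second-difference terms of the modified
#: Laplacian (1/sqrt(2): inverse Euclidean distance of the diagonal
#: neighbours)
DEFAULT_DIAG_WEIGHT = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class WsemlParams:
    """WSEML window: radius ``r`` and (2r+1)^2 weighting matrix summing to 1."""

    r: int = 1
    weights: np.ndarray = field(default_factory=lambda: _DEFAULT_WEIGHTS.copy())
    diag_weight: float = DEFAULT_DIAG_WEIGHT

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        size = 2 * self.r + 1
        if w.shape != (size, size):
            raise ValueError(f"weights must be {size}x{size} for r={self.r}")
        if not np.isclose(w.sum(), 1.0, atol=1e-12):
            raise ValueError("weighting matrix must sum to 1")
        object.__setattr__(self, "weights", w)


@dataclass
class WeightMaps:
    """Per-pixel convex fusion weights for a sub-band pair (wa + wb = 1)."""

    wa: np.ndarray
    wb: np.ndarray


def eml(S: np.ndarray, diag_weight: float = DEFAULT_DIAG_WEIGHT) -> np.ndarray:
    """Eight-neighbourhood modified Laplacian.

    |2S - left - right| + |2S - up - down| plus ``diag_weight`` times each of
    the two diagonal second differences; mirror borders.
    """
    S = np.asarray(S, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise ValueError("input contains non-finite values")
    p = np.pad(S, 1, mode="reflect")
    c = p[1:-1, 1:-1]
    up, down = p[:-2, 1:-1], p[2:, 1:-1]
    left, right = p[1:-1, :-2], p[1:-1, 2:]
    ul, dr = p[:-2, :-2], p[2:, 2:]
    ur, dl = p[:-2, 2:], p[2:, :-2]
    out = np.abs(2 * c - up - down) + np.abs(2 * c - left - right)
    out += diag_weight * np.abs(2 * c - ul - dr)
    out += diag_weight * np.abs(2 * c - ur - dl)
    return out


def wseml(S: np.ndarray, params: WsemlParams | None = None) -> np.ndarray:
    """Windowed (weighted) sum of :func:`eml` over the (2r+1)^2 window."""
    params = params or WsemlParams()
    e = eml(S, params.diag_weight)
    return ndimage.correlate(e, params.weights, mode="mirror")


def initial_decision_maps(
    ha: np.ndarray, hb: np.ndarray, params: WsemlParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary activity-argmax maps: mapA = 1 where WSEML(A) >= WSEML(B)."""
    ha = np.asarray(ha, dtype=np.float64)
    hb = np.asarray(hb, dtype=np.float64)
    if ha.shape != hb.shape:
        raise ValueError(f"shape mismatch: {ha.shape} vs {hb.shape}")
    map_a = (wseml(ha, params) >= wseml(hb, params)).astype(np.float64)
    return map_a, 1.0 - map_a


def fuse_high_frequency(
    ha: np.ndarray,
    hb: np.ndarray,
    wseml_params: WsemlParams | None = None,
    gif_params: GifParams | None = None,
) -> tuple[np.ndarray, WeightMaps]:
    """Fuse a directional sub-band pair; returns ``(fused, WeightMaps)``.

    The guided-filter outputs are clipped to [0, 1] before per-pixel
    normalization (the filter can overshoot the binary range); where both
    refined maps vanish (< 1e-12 total) the weights fall back to 1/2 each.
    """
    gif_params = gif_params or GifParams()
    map_a, map_b = initial_decision_maps(ha, hb, wseml_params)
    ref_a = np.clip(guided_filter(map_a, ha, gif_params), 0.0, 1.0)
    ref_b = np.clip(guided_filter(map_b, hb, gif_params), 0.0, 1.0)
    total = ref_a + ref_b
    degenerate = total < 1e-12
    wa = np.where(degenerate, 0.5, ref_a / np.where(degenerate, 1.0, total))
    wb = 1.0 - wa
    fused = wa * ha + wb * hb
    return fused, WeightMaps(wa=wa, wb=wb)
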