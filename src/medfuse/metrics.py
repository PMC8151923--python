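"""Objective fusion-quality metrics.

Five indices commonly used to judge a fused image F against its sources
A, B:

* ``api`` — average pixel intensity (mean, 0-255 scale): overall brightness.
* ``sd``  — population standard deviation (0-255 scale): global contrast.
* ``en``  — Shannon entropy (bits) of the 256-bin histogram of the
  8-bit-quantized image: information content; bounded by 8.
* ``q_w`` — Piella's weighted fusion quality index: the universal image
  quality index Q0 between each source and F over sliding windows, combined
  with local-saliency weights and window importances.
* ``viff`` — visual information fidelity for fusion: a multi-scale
  Gaussian-scale-mixture information ratio between each source and F.

All functions accept images in [0, 1] (or any common linear scale for the
reference-based metrics); ``api``/``sd``/``en`` report on the conventional
0-255 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = ["MetricsReport", "api", "sd", "en", "q_w", "viff", "evaluate"]

_EPS = 1e-12


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3 and img.shape[-1] == 3:
        from .pipeline import rgb_to_yuv

        img = rgb_to_yuv(img)[0]
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def _to_255(img: np.ndarray) -> np.ndarray:
    return _as_gray(img) * 255.0


def api(img: np.ndarray) -> float:
    """Average pixel intensity on the 0-255 scale."""
    return float(_to_255(img).mean())


def sd(img: np.ndarray) -> float:
    """Population standard deviation on the 0-255 scale."""
    return float(_to_255(img).std())


def en(img: np.ndarray) -> float:
    """Shannon entropy (base 2) of the 8-bit histogram; 0*log0 = 0."""
    q = np.clip(np.floor(_to_255(img) + 0.5), 0, 255).astype(np.int64)
    counts = np.bincount(q.ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------------
# Piella's weighted fusion quality index
# ---------------------------------------------------------------------------

def _window_moments(x: np.ndarray, win: int):
    w = np.lib.stride_tricks.sliding_window_view(x, (win, win))
    mean = w.mean(axis=(-2, -1))
    var = (w * w).mean(axis=(-2, -1)) - mean * mean
    return mean, np.maximum(var, 0.0)


def _window_cov(x: np.ndarray, y: np.ndarray, win: int, mx, my):
    wxy = np.lib.stride_tricks.sliding_window_view(x * y, (win, win))
    return wxy.mean(axis=(-2, -1)) - mx * my


def q_w(a: np.ndarray, b: np.ndarray, f: np.ndarray, win: int = 8) -> float:
    """Piella's weighted fusion quality index Q_W.

    Per sliding ``win``x``win`` window w: the universal image quality index
    Q0(x, F | w) = 4 cov mx mf / ((vx + vf)(mx^2 + mf^2)) is computed for
    both sources; they are mixed with the saliency weight
    lam = var(A|w) / (var(A|w) + var(B|w)) and aggregated over windows with
    importance c(w) = max(var(A|w), var(B|w)).
    """
    a, b, f = _as_gray(a), _as_gray(b), _as_gray(f)
    if not (a.shape == b.shape == f.shape):
        raise ValueError("A, B, F must share a shape")
    if min(a.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} window")

    ma, va = _window_moments(a, win)
    mb, vb = _window_moments(b, win)
    mf, vf = _window_moments(f, win)

    def q0(mx, vx, cxf):
        # degenerate windows (both signals constant / zero-mean) score 0;
        # they carry zero importance weight anyway
        num = 4.0 * cxf * mx * mf
        den = (vx + vf) * (mx * mx + mf * mf)
        return np.where(den > _EPS, num / np.where(den > _EPS, den, 1.0), 0.0)

    qa = q0(ma, va, _window_cov(a, f, win, ma, mf))
    qb = q0(mb, vb, _window_cov(b, f, win, mb, mf))

    s = va + vb
    lam = np.where(s > _EPS, va / np.where(s > _EPS, s, 1.0), 0.5)
    local = lam * qa + (1.0 - lam) * qb
    c = np.maximum(va, vb)
    ctot = c.sum()
    if ctot <= _EPS:  # both sources globally constant
        return float(local.mean())
    return float((c * local).sum() / ctot)


# ---------------------------------------------------------------------------
# Visual information fidelity for fusion
# ---------------------------------------------------------------------------

_VIFF_SCALE_WEIGHTS = np.array([8.0, 4.0, 2.0, 1.0]) / 15.0
_VIFF_SIGMA_N2 = 2.0  # visual-noise variance on the 0-255 scale


def _gauss_window(n: int) -> np.ndarray:
    sigma = n / 5.0
    ax = np.arange(n) - (n - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _local_stats(x: np.ndarray, y: np.ndarray, k: np.ndarray):
    conv = lambda z: ndimage.convolve(z, k, mode="mirror")
    mx, my = conv(x), conv(y)
    vx = np.maximum(conv(x * x) - mx * mx, 0.0)
    vy = np.maximum(conv(y * y) - my * my, 0.0)
    cxy = conv(x * y) - mx * my
    return vx, vy, cxy


def _vif_terms(src: np.ndarray, fused: np.ndarray, k: np.ndarray):
    """Per-pixel VID / VIND maps for one source-fused pair at one scale."""
    vs, vf, c = _local_stats(src, fused, k)
    g = c / (vs + _EPS)
    sv2 = vf - g * c
    g = np.where(vs > _EPS, g, 0.0)
    sv2 = np.where(vs > _EPS, sv2, vf)
    g = np.maximum(g, 0.0)
    sv2 = np.maximum(sv2, 0.0)
    vid = np.log2(1.0 + g * g * vs / (sv2 + _VIFF_SIGMA_N2))
    vind = np.log2(1.0 + vs / _VIFF_SIGMA_N2)
    return vid, vind


def viff(a: np.ndarray, b: np.ndarray, f: np.ndarray, n_scales: int = 4) -> float:
    """Visual information fidelity of the fused image.

    At each of ``n_scales`` dyadic scales, local Gaussian-window moments
    drive a Gaussian-scale-mixture signal model; per pixel the source with
    the larger information content (VIND) is selected and the scale score is
    the ratio of the summed distorted to distortion-free information.
    Scales are combined with geometric weights (finest scale heaviest).
    Identical inputs score 1; blurring F strictly lowers the score.
    """
    a, b, f = _to_255(a), _to_255(b), _to_255(f)
    if not (a.shape == b.shape == f.shape):
        raise ValueError("A, B, F must share a shape")
    weights = _VIFF_SCALE_WEIGHTS[:n_scales]
    weights = weights / weights.sum()
    score = 0.0
    for scale in range(1, n_scales + 1):
        n = 2 ** (n_scales - scale + 1) + 1
        k = _gauss_window(n)
        if scale > 1:
            a = ndimage.convolve(a, k, mode="mirror")[::2, ::2]
            b = ndimage.convolve(b, k, mode="mirror")[::2, ::2]
            f = ndimage.convolve(f, k, mode="mirror")[::2, ::2]
        vid_a, vind_a = _vif_terms(a, f, k)
        vid_b, vind_b = _vif_terms(b, f, k)
        use_a = vind_a >= vind_b
        vid = np.where(use_a, vid_a, vid_b)
        vind = np.where(use_a, vind_a, vind_b)
        denom = vind.sum()
        ratio = vid.sum() / denom if denom > _EPS else 1.0
        score += weights[scale - 1] * ratio
    return float(score)


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All five quality indices plus the parameters they were computed with."""

    viff: float
    q_w: float
    api: float
    sd: float
    en: float
    q_w_window: int = 8
    en_bins: int = 256
    viff_scales: int = 4

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> MetricsReport:
    """Compute all five metrics with default parameters.

    RGB inputs are reduced to their BT.601 luminance first, so color fusions
    are scored on the fused luminance.
    """
    a, b, f = _as_gray(a), _as_gray(b), _as_gray(f)
    return MetricsReport(
        viff=viff(a, b, f),
        q_w=q_w(a, b, f),
        api=api(f),
        sd=sd(f),
        en=en(f),
    )
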