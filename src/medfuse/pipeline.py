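"""End-to-end fusion pipelines.

Gray-gray fusion (e.g. CT + MRI): NSCT analysis of both inputs, PCNN rule on
the low-frequency pair, WSEML + guided-filter rule on every directional
high-frequency pair, NSCT synthesis of the merged pyramid.

Gray-color fusion (e.g. MRI + PET/SPECT): the functional RGB image is taken
to YUV (BT.601); its luminance is fused against the anatomical image with
the gray pipeline and recombined with the untouched chroma planes.  The
method is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .guided import GifParams
from .highfreq import WsemlParams, fuse_high_frequency
from .nsct import NsctPyramid, build_pyramid_filters, nsct_forward, nsct_inverse
from .pcnn import PcnnParams, fuse_low_frequency

__all__ = [
    "FusionConfig",
    "fuse_gray",
    "fuse_color",
    "rgb_to_yuv",
    "yuv_to_rgb",
]

# BT.601 analog YUV: Y = 0.299 R + 0.587 G + 0.114 B, with zero-centred
# chroma U = 0.492 (B - Y), V = 0.877 (R - Y).  Writing chroma as scaled
# differences keeps achromatic inputs at exactly U = V = 0 and makes the
# round trip exact to machine precision.
_KR, _KG, _KB = 0.299, 0.587, 0.114
_KU, _KV = 0.492, 0.877


@dataclass
class FusionConfig:
    """All tunables of the fusion method; defaults are the proposed settings.

    ``dirs_per_level`` is ordered coarse -> fine (4 directional sub-bands at
    each of 4 pyramid levels by default).
    """

    levels: int = 4
    dirs_per_level: tuple = (4, 4, 4, 4)
    filter_name: str = "9-7"
    boundary: str = "mirror"
    pcnn: PcnnParams = field(default_factory=PcnnParams)
    wseml: WsemlParams = field(default_factory=WsemlParams)
    gif: GifParams = field(default_factory=GifParams)
    pcnn_normalize: str = "joint"
    color_space: str = "yuv601"

    def __post_init__(self):
        self.dirs_per_level = tuple(int(d) for d in self.dirs_per_level)
        if len(self.dirs_per_level) != self.levels:
            raise ValueError("len(dirs_per_level) must equal levels")

    # -- flat key=value serialization ------------------------------------
    def to_text(self) -> str:
        lines = [
            f"levels = {self.levels}",
            f"dirs_per_level = {','.join(str(d) for d in self.dirs_per_level)}",
            f"filter_name = {self.filter_name}",
            f"boundary = {self.boundary}",
            f"pcnn_normalize = {self.pcnn_normalize}",
            f"color_space = {self.color_space}",
            f"pcnn.alpha_l = {float(self.pcnn.alpha_l)!r}",
            f"pcnn.alpha_theta = {float(self.pcnn.alpha_theta)!r}",
            f"pcnn.beta = {float(self.pcnn.beta)!r}",
            f"pcnn.v_l = {float(self.pcnn.v_l)!r}",
            f"pcnn.v_theta = {float(self.pcnn.v_theta)!r}",
            f"pcnn.n_iter = {self.pcnn.n_iter}",
            f"wseml.r = {self.wseml.r}",
            f"wseml.diag_weight = {float(self.wseml.diag_weight)!r}",
            f"gif.r = {self.gif.r}",
            f"gif.eps = {float(self.gif.eps)!r}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FusionConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        cfg = cls(
            levels=int(kv.get("levels", 4)),
            dirs_per_level=tuple(
                int(x) for x in kv.get("dirs_per_level", "4,4,4,4").split(",")
            ),
            filter_name=kv.get("filter_name", "9-7"),
            boundary=kv.get("boundary", "mirror"),
            pcnn=PcnnParams(
                alpha_l=float(kv.get("pcnn.alpha_l", 0.06931)),
                alpha_theta=float(kv.get("pcnn.alpha_theta", 0.2)),
                beta=float(kv.get("pcnn.beta", 3.0)),
                v_l=float(kv.get("pcnn.v_l", 1.0)),
                v_theta=float(kv.get("pcnn.v_theta", 20.0)),
                n_iter=int(kv.get("pcnn.n_iter", 200)),
            ),
            wseml=WsemlParams(
                r=int(kv.get("wseml.r", 1)),
                diag_weight=float(kv.get("wseml.diag_weight", 1 / np.sqrt(2))),
            ),
            gif=GifParams(
                r=int(kv.get("gif.r", 3)), eps=float(kv.get("gif.eps", 1.0))
            ),
            pcnn_normalize=kv.get("pcnn_normalize", "joint"),
            color_space=kv.get("color_space", "yuv601"),
        )
        return cfg


def _check_gray(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"{name} must be a 2-D grayscale image, got {x.shape}")
    if min(x.shape) < 16:
        raise ValueError(f"{name} must be at least 16x16, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def fuse_gray(
    a: np.ndarray, b: np.ndarray, cfg: FusionConfig | None = None
) -> np.ndarray:
    """Fuse two co-registered grayscale images (values in [0, 1])."""
    cfg = cfg or FusionConfig()
    a = _check_gray(a, "A")
    b = _check_gray(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    fb = build_pyramid_filters(cfg.filter_name)
    pa = nsct_forward(a, cfg.dirs_per_level, fb, cfg.boundary)
    pb = nsct_forward(b, cfg.dirs_per_level, fb, cfg.boundary)

    low_f, _ = fuse_low_frequency(pa.low, pb.low, cfg.pcnn, cfg.pcnn_normalize)
    highs_f = []
    for lvl_a, lvl_b in zip(pa.highs, pb.highs):
        highs_f.append(
            [
                fuse_high_frequency(ha, hb, cfg.wseml, cfg.gif)[0]
                for ha, hb in zip(lvl_a, lvl_b)
            ]
        )
    merged = NsctPyramid(
        low=low_f,
        highs=highs_f,
        dirs_per_level=list(cfg.dirs_per_level),
        boundary=cfg.boundary,
        filter_name=cfg.filter_name,
    )
    return np.clip(nsct_inverse(merged, fb), 0.0, 1.0)


def rgb_to_yuv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BT.601 RGB -> (Y, U, V); chroma zero-centred."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {rgb.shape}")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = _KR * r + _KG * g + _KB * b
    return y, _KU * (b - y), _KV * (r - y)


def yuv_to_rgb(y: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_yuv` (no gamut clipping applied)."""
    y = np.asarray(y, dtype=np.float64)
    r = y + v / _KV
    b = y + u / _KU
    g = (y - _KR * r - _KB * b) / _KG
    return np.stack([r, g, b], axis=-1)


def fuse_color(
    anatomical: np.ndarray,
    functional_rgb: np.ndarray,
    cfg: FusionConfig | None = None,
    output: str = "rgb",
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fuse a gray anatomical image with an RGB functional image.

    The functional image's luminance is fused against the anatomical image;
    its chroma planes pass through untouched.  ``output="rgb"`` (default)
    returns the recombined RGB image clipped to [0, 1]; ``output="yuv"``
    returns the ``(Y_fused, U, V)`` planes before any gamut clipping.
    """
    anatomical = _check_gray(anatomical, "anatomical")
    y, u, v = rgb_to_yuv(functional_rgb)
    if y.shape != anatomical.shape:
        raise ValueError(
            f"shape mismatch: anatomical {anatomical.shape} vs functional {y.shape}"
        )
    y_fused = fuse_gray(anatomical, y, cfg)
    if output == "yuv":
        return y_fused, u, v
    if output == "rgb":
        return np.clip(yuv_to_rgb(y_fused, u, v), 0.0, 1.0)
    raise ValueError(f"unknown output mode {output!r}")
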