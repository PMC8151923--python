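"""Non-subsampled contourlet transform (NSCT).

The NSCT is a shift-invariant, multiscale and multidirectional image
decomposition: a non-subsampled pyramid (NSP) separates scales, and a
non-subsampled directional filter bank (NSDFB) splits each band-pass level
into directional wedges.  No stage subsamples, so every sub-band keeps the
input resolution and the transform is fully shift-invariant (exactly so
under periodic boundary handling).

Filter construction
-------------------
* Pyramid ("9-7"): the CDF 9/7 biorthogonal low-pass pair (analysis ``h0``,
  9 taps; synthesis ``g0``, 7 taps), normalized to DC gain 1.  The high-pass
  analysis filter is ``h1 = delta - h0*g0`` with synthesis ``g1 = delta``,
  which makes perfect reconstruction structural::

      H0(w) G0(w) + H1(w) G1(w) = H0 G0 + (1 - H0 G0) = 1

  Level ``l`` uses the filters upsampled a trous by ``2**(l-1)``; the
  identity is preserved under upsampling.
* Directional ("pkva"): a zero-phase fan filter built by the McClellan
  transform of a 7-tap maxflat halfband prototype, with complementary
  channel ``delta - fan0`` (again structural PR).  The second tree stage
  uses the fan upsampled on the quincunx lattice, yielding the standard
  four-direction wedge split; deeper stages dilate the quincunx fan a trous.

Sub-band ordering: :class:`NsctPyramid` stores levels coarse -> fine;
within a level, directional channels follow filter-tree order (channel 0 is
the all-low path of the fan tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "FilterBank",
    "NsctPyramid",
    "build_pyramid_filters",
    "nsp_decompose",
    "nsp_reconstruct",
    "nsdfb_decompose",
    "nsdfb_reconstruct",
    "nsct_forward",
    "nsct_inverse",
]

_BOUNDARY_MODES = {"mirror": "mirror", "periodic": "wrap"}


def _check_image(x: np.ndarray, name: str = "image") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _ndimage_mode(boundary: str) -> str:
    try:
        return _BOUNDARY_MODES[boundary]
    except KeyError:
        raise ValueError(
            f"unknown boundary {boundary!r}; expected one of {sorted(_BOUNDARY_MODES)}"
        ) from None


def _atrous_1d(h: np.ndarray, step: int) -> np.ndarray:
    """Insert ``step - 1`` zeros between taps (a trous upsampling)."""
    if step == 1:
        return h
    out = np.zeros((len(h) - 1) * step + 1, dtype=np.float64)
    out[::step] = h
    return out


def _sep_filter(x: np.ndarray, h: np.ndarray, step: int, mode: str) -> np.ndarray:
    """Separable 2-D filtering with the a-trous-upsampled 1-D kernel ``h``."""
    k = _atrous_1d(h, step)
    y = ndimage.convolve1d(x, k, axis=0, mode=mode)
    return ndimage.convolve1d(y, k, axis=1, mode=mode)


def _upsample_kernel(k: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Upsample a zero-phase 2-D kernel on the lattice of integer matrix ``mat``.

    The tap at offset ``n`` (relative to the centre) moves to ``mat @ n``.
    """
    ci, cj = np.asarray(k.shape) // 2
    ii, jj = np.nonzero(k)
    oi, oj = ii - ci, jj - cj
    ni = mat[0, 0] * oi + mat[0, 1] * oj
    nj = mat[1, 0] * oi + mat[1, 1] * oj
    ri, rj = np.abs(ni).max(), np.abs(nj).max()
    out = np.zeros((2 * ri + 1, 2 * rj + 1), dtype=np.float64)
    out[ni + ri, nj + rj] = k[ii, jj]
    return out


def _fan_kernel() -> np.ndarray:
    """Zero-phase fan filter via McClellan transform.

    Prototype: the 7-tap maxflat halfband [-1, 0, 9, 16, 9, 0, -1]/32 whose
    amplitude response is P(x) = (2 + 3x - x^3)/4 in x = cos(w).  The fan
    substitution x -> (cos w_col - cos w_row)/2 maps P's passband (x near 1)
    to frequencies varying mostly along rows, i.e. horizontal stripe
    patterns; the complement ``delta - fan`` passes the other wedge.
    """
    t = np.zeros((3, 3))
    t[1, 0] = t[1, 2] = 0.25   # +cos(w_col)/2
    t[0, 1] = t[2, 1] = -0.25  # -cos(w_row)/2
    delta = np.zeros((7, 7))
    delta[3, 3] = 1.0
    t1 = np.zeros((7, 7))
    t1[2:5, 2:5] = t
    t3 = ndimage.convolve(ndimage.convolve(t1, t1, mode="constant"), t1, mode="constant")
    return 0.5 * delta + 0.75 * t1 - 0.25 * t3


@dataclass(frozen=True)
class FilterBank:
    """Analysis/synthesis kernels for the NSP and NSDFB stages.

    ``h0``/``h1`` and ``g0``/``g1`` are the 2-D pyramid analysis/synthesis
    kernels; ``fan0``/``fan1`` (with synthesis ``fan0_syn``/``fan1_syn``)
    drive the directional stage.  1-D separable factors are kept privately
    for fast pyramid filtering.
    """

    name: str
    h0: np.ndarray
    h1: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    fan0: np.ndarray
    fan1: np.ndarray
    fan0_syn: np.ndarray
    fan1_syn: np.ndarray
    # separable 1-D factors of h0, g0 and of the composed low branch h0*g0
    h0_1d: np.ndarray = field(repr=False, default=None)
    g0_1d: np.ndarray = field(repr=False, default=None)
    h0g0_1d: np.ndarray = field(repr=False, default=None)


def build_pyramid_filters(name: str = "9-7") -> FilterBank:
    """Build the pyramid + directional filter bank for a named family.

    Supported tags: ``"9-7"`` (CDF 9/7 pyramid with the McClellan fan
    directional pair; ``"pkva"`` is accepted as an alias naming the
    directional stage).
    """
    if name not in ("9-7", "pkva"):
        raise ValueError(f"unsupported filter family {name!r}; supported: '9-7', 'pkva'")
    w = pywt.Wavelet("bior4.4")
    h0 = np.trim_zeros(np.asarray(w.dec_lo, dtype=np.float64))
    g0 = np.trim_zeros(np.asarray(w.rec_lo, dtype=np.float64))
    h0 = h0 / h0.sum()  # DC gain 1
    g0 = g0 / g0.sum()
    h0g0 = np.convolve(h0, g0)

    h0_2d = np.outer(h0, h0)
    g0_2d = np.outer(g0, g0)
    hg_2d = np.outer(h0g0, h0g0)
    h1_2d = -hg_2d.copy()
    c = hg_2d.shape[0] // 2
    h1_2d[c, c] += 1.0  # delta - h0*g0
    g1_2d = np.zeros((1, 1))
    g1_2d[0, 0] = 1.0

    fan0 = _fan_kernel()
    fan1 = -fan0.copy()
    fan1[3, 3] += 1.0  # delta - fan0
    fdelta = np.zeros((1, 1))
    fdelta[0, 0] = 1.0
    return FilterBank(
        name=name,
        h0=h0_2d,
        h1=h1_2d,
        g0=g0_2d,
        g1=g1_2d.copy(),
        fan0=fan0,
        fan1=fan1,
        fan0_syn=fdelta.copy(),
        fan1_syn=fdelta.copy(),
        h0_1d=h0,
        g0_1d=g0,
        h0g0_1d=h0g0,
    )


# ---------------------------------------------------------------------------
# Non-subsampled pyramid
# ---------------------------------------------------------------------------

def nsp_decompose(
    image: np.ndarray,
    levels: int,
    fb: FilterBank | None = None,
    boundary: str = "mirror",
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Non-subsampled pyramid analysis.

    Returns ``(low, highs)`` where ``highs`` is ordered coarse -> fine and
    every band has the input's shape.  Level ``l`` (1-based, fine first
    internally) filters with kernels a-trous-upsampled by ``2**(l-1)``.
    """
    image = _check_image(image)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    fb = fb or build_pyramid_filters()
    mode = _ndimage_mode(boundary)
    low = image
    highs_fine_first = []
    for l in range(levels):
        step = 2 ** l
        new_low = _sep_filter(low, fb.h0_1d, step, mode)
        high = low - _sep_filter(low, fb.h0g0_1d, step, mode)
        highs_fine_first.append(high)
        low = new_low
    return low, highs_fine_first[::-1]


def nsp_reconstruct(
    low: np.ndarray,
    highs: list[np.ndarray],
    fb: FilterBank | None = None,
    boundary: str = "mirror",
) -> np.ndarray:
    """Inverse of :func:`nsp_decompose` (``highs`` coarse -> fine)."""
    fb = fb or build_pyramid_filters()
    mode = _ndimage_mode(boundary)
    rec = np.asarray(low, dtype=np.float64)
    levels = len(highs)
    for idx, high in enumerate(highs):  # coarse -> fine
        step = 2 ** (levels - 1 - idx)
        rec = _sep_filter(rec, fb.g0_1d, step, mode) + high
    return rec


# ---------------------------------------------------------------------------
# Non-subsampled directional filter bank
# ---------------------------------------------------------------------------

_QUINCUNX = np.array([[1, -1], [1, 1]])


def _stage_fan(fb: FilterBank, stage: int) -> np.ndarray:
    """Fan kernel for tree stage ``stage`` (1-based)."""
    if stage == 1:
        return fb.fan0
    mat = _QUINCUNX * (2 ** (stage - 2))
    return _upsample_kernel(fb.fan0, mat)


def nsdfb_decompose(
    band: np.ndarray,
    n_dirs: int,
    fb: FilterBank | None = None,
    boundary: str = "mirror",
) -> list[np.ndarray]:
    """Split a band into ``n_dirs`` directional sub-bands (power of two).

    ``n_dirs = 1`` is a pass-through.  Each tree node applies the stage fan
    filter and its structural complement (``band - fan*band``), so the
    synthesis sum of the channels reconstructs the band exactly.
    """
    band = _check_image(band, "band")
    if n_dirs == 1:
        return [band]
    if n_dirs < 1 or (n_dirs & (n_dirs - 1)) != 0:
        raise ValueError(f"n_dirs must be a power of two, got {n_dirs}")
    fb = fb or build_pyramid_filters()
    mode = _ndimage_mode(boundary)
    depth = int(np.log2(n_dirs))
    channels = [band]
    for stage in range(1, depth + 1):
        k = _stage_fan(fb, stage)
        nxt = []
        for c in channels:
            low = ndimage.convolve(c, k, mode=mode)
            nxt.append(low)
            nxt.append(c - low)
        channels = nxt
    return channels


def nsdfb_reconstruct(
    channels: list[np.ndarray],
    fb: FilterBank | None = None,
    boundary: str = "mirror",
) -> np.ndarray:
    """Inverse of :func:`nsdfb_decompose`: synthesis is the channel sum."""
    if not channels:
        raise ValueError("no channels to reconstruct")
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"channel shape mismatch: {shapes}")
    out = np.zeros_like(np.asarray(channels[0], dtype=np.float64))
    for c in channels:
        out += c
    return out


# ---------------------------------------------------------------------------
# Full transform
# ---------------------------------------------------------------------------

@dataclass
class NsctPyramid:
    """NSCT coefficients: one low band + per-level directional sub-bands.

    ``highs[0]`` is the coarsest level; ``highs[-1]`` the finest.  Every
    sub-band has the input image's shape.
    """

    low: np.ndarray
    highs: list[list[np.ndarray]]
    dirs_per_level: list[int]
    boundary: str = "mirror"
    filter_name: str = "9-7"

    @property
    def levels(self) -> int:
        return len(self.highs)

    def validate_shapes(self) -> tuple[int, int]:
        shape = self.low.shape
        for level in self.highs:
            for band in level:
                if band.shape != shape:
                    raise ValueError(
                        f"sub-band shape {band.shape} != low band shape {shape}"
                    )
        return shape

    def __mul__(self, scalar: float) -> "NsctPyramid":
        return NsctPyramid(
            low=self.low * scalar,
            highs=[[b * scalar for b in lvl] for lvl in self.highs],
            dirs_per_level=list(self.dirs_per_level),
            boundary=self.boundary,
            filter_name=self.filter_name,
        )

    __rmul__ = __mul__

    def __add__(self, other: "NsctPyramid") -> "NsctPyramid":
        return NsctPyramid(
            low=self.low + other.low,
            highs=[
                [a + b for a, b in zip(la, lb)]
                for la, lb in zip(self.highs, other.highs)
            ],
            dirs_per_level=list(self.dirs_per_level),
            boundary=self.boundary,
            filter_name=self.filter_name,
        )


def nsct_forward(
    image: np.ndarray,
    dirs_per_level: list[int],
    fb: FilterBank | None = None,
    boundary: str = "mirror",
) -> NsctPyramid:
    """Forward NSCT: NSP scale split, then NSDFB per band-pass level.

    ``dirs_per_level`` is ordered coarse -> fine, matching ``highs``.
    """
    if len(dirs_per_level) < 1:
        raise ValueError("dirs_per_level must have at least one entry")
    fb = fb or build_pyramid_filters()
    low, bands = nsp_decompose(image, len(dirs_per_level), fb, boundary)
    highs = [
        nsdfb_decompose(band, nd, fb, boundary)
        for band, nd in zip(bands, dirs_per_level)
    ]
    return NsctPyramid(
        low=low,
        highs=highs,
        dirs_per_level=list(dirs_per_level),
        boundary=boundary,
        filter_name=fb.name,
    )


def nsct_inverse(pyr: NsctPyramid, fb: FilterBank | None = None) -> np.ndarray:
    """Inverse NSCT; exact synthesis inverse of :func:`nsct_forward`."""
    pyr.validate_shapes()
    fb = fb or build_pyramid_filters(pyr.filter_name)
    bands = [nsdfb_reconstruct(lvl, fb, pyr.boundary) for lvl in pyr.highs]
    return nsp_reconstruct(pyr.low, bands, fb, pyr.boundary)
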