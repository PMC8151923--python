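"""Synthetic co-registered phantom pairs for exercising the fusion pipeline.

The generators emulate the *statistical contrast* between modalities rather
than their physics:

* CT-like: a bright elliptical rim (skull/bone analogue) with sharp edges
  around a near-uniform dark soft-tissue interior.
* MRI-like: the same geometry with a dark rim and a textured interior
  (smooth blobs plus band-limited noise), so fine detail lives in the MRI
  while the strong edge lives in the CT — each source dominates somewhere.
* Functional RGB (PET/SPECT-like): a few smooth colored activity blobs with
  low-spatial-frequency chroma and moderate luminance.

All randomness flows through one seeded ``numpy.random.default_rng``; equal
seed and parameters give bit-identical output.  Values are in [0, 1] and
ground-truth masks for the generated structures are returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomPair", "make_ct_mri_pair", "make_mri_pet_pair",
           "CHROMA_SMOOTHNESS_BOUND"]

#: generator-set upper bound on the mean chroma gradient magnitude of the
#: functional phantom (its blobs are Gaussian with sigma >= shape/10)
CHROMA_SMOOTHNESS_BOUND = 0.02

# intensity levels of the CT phantom (rim vs interior separation >= 0.4 is a
# construction guarantee)
_CT_RING, _CT_INTERIOR, _CT_BG = 0.92, 0.18, 0.05
_MRI_RING, _MRI_BG = 0.08, 0.03


@dataclass
class PhantomPair:
    """A co-registered synthetic image pair plus ground-truth masks."""

    imgA: np.ndarray
    imgB: np.ndarray | None = None
    imgRGB: np.ndarray | None = None
    masks: dict = field(default_factory=dict)
    seed: int = 0
    kind: str = "ct-mri"


def _check_shape(shape) -> tuple[int, int]:
    h, w = int(shape[0]), int(shape[1])
    if h < 16 or w < 16:
        raise ValueError(f"phantom shape must be at least 16x16, got {(h, w)}")
    return h, w


def _ellipse_coords(shape, rng):
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    ci, cj = (h - 1) / 2.0, (w - 1) / 2.0
    # mild random anisotropy and rotation keep pairs from being degenerate
    ra = 0.40 * h * rng.uniform(0.92, 1.0)
    rb = 0.40 * w * rng.uniform(0.85, 0.98)
    ang = rng.uniform(0, np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    x = (ii - ci) * ca + (jj - cj) * sa
    y = -(ii - ci) * sa + (jj - cj) * ca
    return np.sqrt((x / ra) ** 2 + (y / rb) ** 2)


def _smooth_noise(shape, rng, sigma):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")


def _blobs(shape, rng, n, sigma_frac):
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    out = np.zeros(shape)
    for _ in range(n):
        ci = rng.uniform(0.3 * h, 0.7 * h)
        cj = rng.uniform(0.3 * w, 0.7 * w)
        s = rng.uniform(0.7, 1.3) * sigma_frac * min(h, w)
        amp = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        out += amp * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * s * s))
    return out


def make_ct_mri_pair(shape=(256, 256), seed: int = 0) -> PhantomPair:
    """CT-like + MRI-like co-registered gray pair with structure masks."""
    shape = _check_shape(shape)
    rng = np.random.default_rng(seed)
    r = _ellipse_coords(shape, rng)
    thick = 0.16
    ring = (r >= 1.0 - thick) & (r <= 1.0 + thick / 2)
    interior = r < 1.0 - thick
    background = ~(ring | interior)

    ct = np.full(shape, _CT_BG)
    ct[interior] = _CT_INTERIOR
    ct[ring] = _CT_RING
    # faint smooth interior variation; amplitude small so the interior stays
    # near-uniform and the rim/interior contrast guarantee holds
    ct += 0.02 * _smooth_noise(shape, rng, sigma=min(shape) / 8) * interior
    ct = np.clip(ct, 0.0, 1.0)

    mri = np.full(shape, _MRI_BG)
    mri[ring] = _MRI_RING
    texture = 0.12 * _smooth_noise(shape, rng, sigma=1.2)
    blobs = 0.30 * _blobs(shape, rng, n=4, sigma_frac=0.08)
    mri_interior = 0.45 + blobs + texture
    mri = np.where(interior, np.clip(mri_interior, 0.1, 0.95), mri)

    # interior minus the WSEML support near the rim: activity measured here
    # reflects interior texture, not rim-edge bleed
    core = ndimage.binary_erosion(interior, iterations=4)
    return PhantomPair(
        imgA=ct,
        imgB=mri,
        masks={
            "ring": ring,
            "interior": interior,
            "interior_core": core,
            "background": background,
        },
        seed=seed,
        kind="ct-mri",
    )


def make_mri_pet_pair(shape=(256, 256), seed: int = 0) -> PhantomPair:
    """MRI-like gray anatomical + RGB functional phantom pair."""
    shape = _check_shape(shape)
    rng = np.random.default_rng(seed)
    anat_pair = make_ct_mri_pair(shape, seed=int(rng.integers(0, 2 ** 31 - 1)))
    anat = anat_pair.imgB  # the textured MRI-like image
    interior = anat_pair.masks["interior"]

    h, w = shape
    sigma = min(h, w) / 10.0
    # luminance: moderate activity blobs confined to the head interior
    lum = 0.15 + 0.45 * np.abs(_blobs(shape, rng, n=3, sigma_frac=0.12))
    lum = np.clip(lum, 0.0, 0.75) * interior
    # chroma: independent very smooth fields, scaled well inside the gamut
    u = 0.10 * ndimage.gaussian_filter(_blobs(shape, rng, n=3, sigma_frac=0.15),
                                       sigma / 3, mode="reflect")
    v = 0.12 * ndimage.gaussian_filter(_blobs(shape, rng, n=3, sigma_frac=0.15),
                                       sigma / 3, mode="reflect")
    u *= interior
    v *= interior

    from .pipeline import yuv_to_rgb

    rgb = np.clip(yuv_to_rgb(lum, u, v), 0.0, 1.0)
    return PhantomPair(
        imgA=anat,
        imgRGB=rgb,
        masks=dict(anat_pair.masks),
        seed=seed,
        kind="mri-pet",
    )
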