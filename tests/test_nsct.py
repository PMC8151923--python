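"""Transform-domain contracts: perfect reconstruction, shape preservation,
shift invariance, DC separation and directional selectivity."""

import numpy as np
import pytest
from scipy import ndimage

from medfuse import (
    build_pyramid_filters,
    nsct_forward,
    nsct_inverse,
    nsdfb_decompose,
    nsdfb_reconstruct,
    nsp_decompose,
    nsp_reconstruct,
)
from medfuse.nsct import NsctPyramid, _atrous_1d


def test_unknown_filter_family_rejected():
    with pytest.raises(ValueError, match="unsupported"):
        build_pyramid_filters("haar")


def test_pyramid_kernel_dc_gains(fb):
    assert abs(fb.h0.sum() - 1.0) < 1e-10
    assert abs(fb.g0.sum() - 1.0) < 1e-10
    assert abs(fb.h1.sum()) < 1e-10


def test_filterbank_single_stage_perfect_reconstruction(fb, rng):
    """Analysis then synthesis through the 2-D kernel pair sums to identity."""
    x = rng.random((32, 32))
    low = ndimage.convolve(x, fb.h0, mode="mirror")
    high = ndimage.convolve(x, fb.h1, mode="mirror")
    rec = ndimage.convolve(low, fb.g0, mode="mirror") + high  # g1 = delta
    assert np.abs(rec - x).max() < 1e-6


def test_constant_image_splits_to_constant_low(fb):
    c = np.full((32, 32), 0.5)
    low, highs = nsp_decompose(c, 3, fb)
    assert np.abs(low - 0.5).max() < 1e-10
    for h in highs:
        assert np.abs(h).max() < 1e-8


@pytest.mark.parametrize("levels", [1, 2, 4])
def test_nsp_round_trip(fb, rng, levels):
    x = rng.random((64, 64))
    low, highs = nsp_decompose(x, levels, fb)
    assert low.shape == x.shape and all(h.shape == x.shape for h in highs)
    rec = nsp_reconstruct(low, highs, fb)
    assert np.abs(rec - x).max() < 1e-6


def test_nsp_impulse_bands_match_composed_atrous_kernels(fb):
    """Each band of a centred impulse equals the composed band-pass kernel."""
    n = 65
    x = np.zeros((n, n))
    x[n // 2, n // 2] = 1.0
    low, highs = nsp_decompose(x, 2, fb, boundary="periodic")

    def sep(img, k1d, step):
        k = _atrous_1d(k1d, step)
        img = ndimage.convolve1d(img, k, axis=0, mode="wrap")
        return ndimage.convolve1d(img, k, axis=1, mode="wrap")

    # fine level (highs[-1]): h1 = delta - h0*g0 at step 1
    expect_fine = x - sep(x, fb.h0g0_1d, 1)
    # coarse level: h0 at step 1 then (delta - h0*g0) at step 2
    l1 = sep(x, fb.h0_1d, 1)
    expect_coarse = l1 - sep(l1, fb.h0g0_1d, 2)
    expect_low = sep(l1, fb.h0_1d, 2)
    assert np.abs(highs[-1] - expect_fine).max() < 1e-12
    assert np.abs(highs[0] - expect_coarse).max() < 1e-12
    assert np.abs(low - expect_low).max() < 1e-12
    rec = nsp_reconstruct(low, highs, fb, boundary="periodic")
    assert np.abs(rec - x).max() < 1e-6


def test_nsdfb_pass_through(fb, rng):
    x = rng.random((16, 16))
    out = nsdfb_decompose(x, 1, fb)
    assert len(out) == 1 and np.array_equal(out[0], x)


def test_nsdfb_rejects_non_power_of_two(fb, rng):
    with pytest.raises(ValueError, match="power of two"):
        nsdfb_decompose(rng.random((16, 16)), 3, fb)


@pytest.mark.parametrize("n_dirs", [2, 4, 8])
def test_nsdfb_round_trip(fb, rng, n_dirs):
    x = rng.random((32, 32))
    chans = nsdfb_decompose(x, n_dirs, fb)
    assert len(chans) == n_dirs and all(c.shape == x.shape for c in chans)
    assert np.abs(nsdfb_reconstruct(chans, fb) - x).max() < 1e-6


def test_fan_channels_separate_orientations(fb):
    """A pure grating lands in the channel whose fan passband contains it.

    The fan substitution maps x = 1 (P(x) = 1) to frequencies varying along
    rows, so a row-alternating grating is kept by channel 0 and rejected by
    its complement; a column grating does the opposite.
    """
    n = 32
    row_grating = np.cos(np.pi * np.arange(n))[:, None] * np.ones((1, n))
    col_grating = row_grating.T
    c0, c1 = nsdfb_decompose(row_grating, 2, fb, boundary="periodic")
    assert (c0 ** 2).sum() > 10 * max((c1 ** 2).sum(), 1e-30)
    d0, d1 = nsdfb_decompose(col_grating, 2, fb, boundary="periodic")
    assert (d1 ** 2).sum() > 10 * max((d0 ** 2).sum(), 1e-30)


@pytest.mark.parametrize("dirs", [[4], [4, 4], [2, 4, 8], [4, 4, 4, 4]])
def test_nsct_round_trip_configurations(fb, rng, dirs):
    x = rng.random((64, 64))
    pyr = nsct_forward(x, dirs, fb)
    assert pyr.levels == len(dirs)
    assert [len(lvl) for lvl in pyr.highs] == dirs
    for lvl in pyr.highs:
        for band in lvl:
            assert band.shape == x.shape
    assert np.abs(nsct_inverse(pyr, fb) - x).max() < 1e-6


def test_nsct_constant_image(fb):
    pyr = nsct_forward(np.full((32, 32), 0.7), [4, 4, 4, 4], fb)
    assert np.abs(pyr.low - 0.7).max() < 1e-8
    for lvl in pyr.highs:
        for band in lvl:
            assert np.abs(band).max() < 1e-8


def test_nsct_shift_invariance_periodic(fb, rng):
    x = rng.random((64, 64))
    xs = np.roll(x, (5, 3), axis=(0, 1))
    pa = nsct_forward(x, [4], fb, boundary="periodic")
    pb = nsct_forward(xs, [4], fb, boundary="periodic")
    assert np.abs(np.roll(pa.low, (5, 3), axis=(0, 1)) - pb.low).max() < 1e-8
    for a, b in zip(pa.highs[0], pb.highs[0]):
        assert np.abs(np.roll(a, (5, 3), axis=(0, 1)) - b).max() < 1e-8


def test_nsct_inverse_linearity(fb, rng):
    x, y = rng.random((32, 32)), rng.random((32, 32))
    p1 = nsct_forward(x, [2, 4], fb)
    p2 = nsct_forward(y, [2, 4], fb)
    combo = nsct_inverse(2.0 * p1 + (-0.5) * p2, fb)
    expect = 2.0 * nsct_inverse(p1, fb) - 0.5 * nsct_inverse(p2, fb)
    assert np.abs(combo - expect).max() < 1e-8
    zero = NsctPyramid(
        low=np.zeros((32, 32)),
        highs=[[np.zeros((32, 32)) for _ in range(2)]],
        dirs_per_level=[2],
    )
    assert np.abs(nsct_inverse(zero, fb)).max() == 0.0


def test_nsct_inverse_rejects_shape_mismatch(fb, rng):
    pyr = nsct_forward(rng.random((32, 32)), [2], fb)
    pyr.highs[0][0] = np.zeros((16, 16))
    with pytest.raises(ValueError, match="shape"):
        nsct_inverse(pyr, fb)


def test_non_finite_input_rejected(fb):
    bad = np.full((32, 32), np.nan)
    with pytest.raises(ValueError, match="finite"):
        nsp_decompose(bad, 2, fb)
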