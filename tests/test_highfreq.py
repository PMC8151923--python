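"""WSEML activity measure and the guided-filter-refined high-frequency rule."""

import numpy as np
import pytest

from medfuse import (
    GifParams,
    WsemlParams,
    eml,
    fuse_high_frequency,
    initial_decision_maps,
    wseml,
)
from medfuse.highfreq import DEFAULT_DIAG_WEIGHT

from oracles import fuse_high_frequency_loop, wseml_loop


def test_weight_matrix_sums_to_one():
    w = WsemlParams().weights
    assert w.sum() == 1.0
    assert np.array_equal(w * 16, [[1, 2, 1], [2, 4, 2], [1, 2, 1]])


def test_weight_matrix_validation():
    with pytest.raises(ValueError):
        WsemlParams(weights=np.ones((3, 3)))  # sums to 9
    with pytest.raises(ValueError):
        WsemlParams(r=2)  # default 3x3 weights do not fit r=2


def test_eml_of_constant_is_zero():
    assert np.abs(eml(np.full((10, 10), 0.6))).max() == 0.0


def test_eml_annihilates_linear_ramps():
    i = np.arange(12, dtype=float)[:, None] * np.ones((1, 10))
    # mirror borders break the ramp at the edges; the interior is exact
    assert np.abs(eml(i)[1:-1, 1:-1]).max() < 1e-12


def test_eml_impulse_centre_value():
    """Hand evaluation at an isolated impulse: 2 + 2 + 2 dw + 2 dw."""
    x = np.zeros((9, 9))
    x[4, 4] = 1.0
    dw = DEFAULT_DIAG_WEIGHT
    assert abs(eml(x)[4, 4] - (4.0 + 4.0 * dw)) < 1e-12


def test_wseml_constant_zero_and_preserves_constant_activity(rng):
    assert np.abs(wseml(np.full((8, 8), 0.3))).max() == 0.0
    # W sums to 1, so a constant EML field passes through unchanged
    from scipy import ndimage

    e = np.full((8, 8), 0.7)
    out = ndimage.correlate(e, WsemlParams().weights, mode="mirror")
    assert np.abs(out - 0.7).max() < 1e-12


@pytest.mark.parametrize("seed", range(5))
def test_wseml_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    S = rng.standard_normal((10, 10))
    params = WsemlParams()
    expect = wseml_loop(S, params.weights, params.r, params.diag_weight)
    assert np.abs(wseml(S, params) - expect).max() < 1e-12


def test_decision_maps_complementary_and_tie_rule(rng):
    ha = rng.standard_normal((12, 12))
    map_a, map_b = initial_decision_maps(ha, ha.copy())
    assert np.all(map_a == 1.0) and np.all(map_b == 0.0)
    hb = rng.standard_normal((12, 12))
    map_a, map_b = initial_decision_maps(ha, hb)
    assert np.array_equal(map_a + map_b, np.ones_like(map_a))
    # dominant activity wins everywhere
    big = 10.0 * rng.standard_normal((12, 12))
    map_a, map_b = initial_decision_maps(big, 0.01 * hb)
    assert np.all(map_a == 1.0)


def test_decision_maps_match_loop_oracle(rng):
    ha, hb = rng.standard_normal((10, 10)), rng.standard_normal((10, 10))
    params = WsemlParams()
    wa = wseml_loop(ha, params.weights, params.r, params.diag_weight)
    wb = wseml_loop(hb, params.weights, params.r, params.diag_weight)
    map_a, _ = initial_decision_maps(ha, hb, params)
    assert np.array_equal(map_a, (wa >= wb).astype(float))


def test_identical_subbands_fuse_to_themselves(rng):
    ha = rng.standard_normal((16, 16))
    fused, weights = fuse_high_frequency(ha, ha.copy())
    assert np.array_equal(fused, ha)
    assert np.all(weights.wa == 1.0) and np.all(weights.wb == 0.0)


def test_r0_guided_filter_reduces_to_hard_selection(rng):
    ha, hb = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
    fused, weights = fuse_high_frequency(ha, hb, gif_params=GifParams(r=0, eps=1.0))
    map_a, _ = initial_decision_maps(ha, hb)
    assert np.array_equal(fused, np.where(map_a == 1.0, ha, hb))
    assert np.array_equal(weights.wa, map_a)


def test_weights_are_convex(rng):
    ha, hb = rng.standard_normal((20, 20)), rng.standard_normal((20, 20))
    _, weights = fuse_high_frequency(ha, hb)
    assert np.abs(weights.wa + weights.wb - 1.0).max() < 1e-10
    assert weights.wa.min() >= 0.0 and weights.wa.max() <= 1.0


def test_convex_combination_bound_where_signs_agree(rng):
    ha, hb = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
    fused, _ = fuse_high_frequency(ha, hb)
    same_sign = (ha * hb) >= 0
    bound = np.maximum(np.abs(ha), np.abs(hb))
    assert np.all(np.abs(fused)[same_sign] <= bound[same_sign] + 1e-12)


def test_swap_symmetry_without_ties(rng):
    ha, hb = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
    # ties are measure-zero for continuous random inputs
    f1, w1 = fuse_high_frequency(ha, hb)
    f2, w2 = fuse_high_frequency(hb, ha)
    assert np.abs(w1.wa - w2.wb).max() < 1e-12
    assert np.abs(f1 - f2).max() < 1e-12


@pytest.mark.parametrize("seed", range(3))
def test_full_rule_matches_end_to_end_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    ha, hb = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
    wp, gp = WsemlParams(), GifParams(r=3, eps=1.0)
    expect = fuse_high_frequency_loop(
        ha, hb, wp.weights, wp.r, wp.diag_weight, gp.r, gp.eps
    )
    fused, _ = fuse_high_frequency(ha, hb, wp, gp)
    assert np.abs(fused - expect).max() < 1e-10


def test_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError, match="shape"):
        fuse_high_frequency(rng.random((8, 8)), rng.random((9, 8)))
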