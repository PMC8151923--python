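"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit Python loops and the defining
formulas, deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# PCNN
# ---------------------------------------------------------------------------

def pcnn_loop(S, w, alpha_l, alpha_theta, beta, v_l, v_theta, n_iter):
    """Naive per-pixel, per-iteration PCNN simulation (mirror borders)."""
    S = np.asarray(S, dtype=float)
    h, wd = S.shape
    L = np.zeros((h, wd))
    theta = np.zeros((h, wd))
    Y = np.zeros((h, wd))
    T = np.zeros((h, wd), dtype=np.int64)
    dec_l = np.exp(-alpha_l)
    dec_t = np.exp(-alpha_theta)

    def mirror(i, n):
        # whole-sample symmetric index (scipy 'mirror')
        if n == 1:
            return 0
        period = 2 * n - 2
        i = i % period
        return i if i < n else period - i

    # neighbour index tables (precomputed; the update itself stays a loop)
    nbr = [
        [
            [
                (mirror(i + di, h), mirror(j + dj, wd))
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
            ]
            for j in range(wd)
        ]
        for i in range(h)
    ]
    wflat = [w[di + 1][dj + 1] for di in (-1, 0, 1) for dj in (-1, 0, 1)]

    for _ in range(n_iter):
        L_new = np.zeros((h, wd))
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for wk, (a, b) in zip(wflat, nbr[i][j]):
                    acc += wk * Y[a, b]
                L_new[i, j] = dec_l * L[i, j] + v_l * acc
        L = L_new
        U = S * (1.0 + beta * L)
        theta = dec_t * theta + v_theta * Y
        Y = (U > theta).astype(float)
        T += Y.astype(np.int64)
    return T


def pcnn_isolated_schedule(s, alpha_theta, v_theta, n_iter):
    """Firing count of one uncoupled neuron (beta = 0) with stimulus s.

    Scalar recurrence of the threshold/pulse pair only: theta decays by
    exp(-alpha_theta) each step and jumps by v_theta after a pulse; the
    neuron pulses whenever s > theta.
    """
    theta = 0.0
    y = 0.0
    count = 0
    for _ in range(n_iter):
        theta = math.exp(-alpha_theta) * theta + v_theta * y
        y = 1.0 if s > theta else 0.0
        count += int(y)
    return count


# ---------------------------------------------------------------------------
# Guided filter
# ---------------------------------------------------------------------------

def box_mean_loop(x, r):
    x = np.asarray(x, dtype=float)
    h, w = x.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - r), min(h, i + r + 1)
            j0, j1 = max(0, j - r), min(w, j + r + 1)
            acc = 0.0
            cnt = 0
            for a in range(i0, i1):
                for b in range(j0, j1):
                    acc += x[a, b]
                    cnt += 1
            out[i, j] = acc / cnt
    return out


def guided_filter_loop(p, I, r, eps):
    """Literal per-window evaluation of the local linear model."""
    p = np.asarray(p, dtype=float)
    I = np.asarray(I, dtype=float)
    mean_I = box_mean_loop(I, r)
    mean_p = box_mean_loop(p, r)
    mean_Ip = box_mean_loop(I * p, r)
    mean_II = box_mean_loop(I * I, r)
    cov = mean_Ip - mean_I * mean_p
    var = np.maximum(mean_II - mean_I * mean_I, 0.0)
    denom = var + eps
    a = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    b = mean_p - a * mean_I
    return box_mean_loop(a, r) * I + box_mean_loop(b, r)


# ---------------------------------------------------------------------------
# WSEML
# ---------------------------------------------------------------------------

def _mirror_idx(i, n):
    if n == 1:
        return 0
    period = 2 * n - 2
    i = i % period
    return i if i < n else period - i


def eml_loop(S, diag_weight):
    S = np.asarray(S, dtype=float)
    h, w = S.shape

    def at(i, j):
        return S[_mirror_idx(i, h), _mirror_idx(j, w)]

    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            c = 2 * at(i, j)
            out[i, j] = (
                abs(c - at(i - 1, j) - at(i + 1, j))
                + abs(c - at(i, j - 1) - at(i, j + 1))
                + diag_weight * abs(c - at(i - 1, j - 1) - at(i + 1, j + 1))
                + diag_weight * abs(c - at(i - 1, j + 1) - at(i + 1, j - 1))
            )
    return out


def wseml_loop(S, weights, r, diag_weight):
    e = eml_loop(S, diag_weight)
    h, w = e.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for m in range(-r, r + 1):
                for n in range(-r, r + 1):
                    acc += weights[m + r][n + r] * e[_mirror_idx(i + m, h),
                                                     _mirror_idx(j + n, w)]
            out[i, j] = acc
    return out


def fuse_high_frequency_loop(ha, hb, weights, wr, diag_weight, gr, geps):
    """End-to-end loop oracle for the high-frequency rule chain."""
    wa_act = wseml_loop(ha, weights, wr, diag_weight)
    wb_act = wseml_loop(hb, weights, wr, diag_weight)
    h, w = wa_act.shape
    map_a = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            map_a[i, j] = 1.0 if wa_act[i, j] >= wb_act[i, j] else 0.0
    map_b = 1.0 - map_a
    ref_a = np.clip(guided_filter_loop(map_a, ha, gr, geps), 0.0, 1.0)
    ref_b = np.clip(guided_filter_loop(map_b, hb, gr, geps), 0.0, 1.0)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            tot = ref_a[i, j] + ref_b[i, j]
            wa = 0.5 if tot < 1e-12 else ref_a[i, j] / tot
            out[i, j] = wa * ha[i, j] + (1.0 - wa) * hb[i, j]
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def q0_window(x, y):
    """Universal image quality index of two equally-sized blocks."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    cxy = ((x - mx) * (y - my)).mean()
    den = (vx + vy) * (mx * mx + my * my)
    return 4 * cxy * mx * my / den if den > 0 else 0.0
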