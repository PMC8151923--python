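"""Pulse coupled neural network (PCNN) and the low-frequency fusion rule.

One spiking neuron per pixel.  Each iteration ``n``:

    F(n)     = S                                   (feeding = stimulus)
    L(n)     = exp(-alpha_l) L(n-1) + v_l * (W ** Y(n-1))   (linking)
    U(n)     = F(n) * (1 + beta L(n))              (internal activity)
    theta(n) = exp(-alpha_theta) theta(n-1) + v_theta * Y(n-1)
    Y(n)     = 1 if U(n) > theta(n) else 0         (pulse)
    T(n)     = T(n-1) + Y(n)                       (firing-time total)

``**`` is 2-D correlation over the 3x3 linking window (mirror borders, so a
border neuron is coupled exactly like an interior one and a spatially
constant stimulus stays perfectly symmetric).  All state starts at zero, so
every neuron
with positive stimulus fires at n = 1.  A larger accumulated firing count T
marks a locally stronger / more salient stimulus, which is how two
low-frequency sub-bands are compared pixel-by-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PcnnParams", "PcnnState", "pcnn_firing_times", "fuse_low_frequency"]

_DEFAULT_W = np.array(
    [
        [0.7071, 1.0, 0.7071],
        [1.0, 0.0, 1.0],
        [0.7071, 1.0, 0.7071],
    ]
)


@dataclass(frozen=True)
class PcnnParams:
    """PCNN constants; defaults are the proposed-method settings."""

    alpha_l: float = 0.06931
    alpha_theta: float = 0.2
    beta: float = 3.0
    v_l: float = 1.0
    v_theta: float = 20.0
    n_iter: int = 200
    w: np.ndarray = field(default_factory=lambda: _DEFAULT_W.copy())

    def __post_init__(self):
        if self.alpha_l <= 0 or self.alpha_theta <= 0:
            raise ValueError("decay constants alpha_l, alpha_theta must be > 0")
        if self.v_l <= 0 or self.v_theta <= 0:
            raise ValueError("amplitude gains v_l, v_theta must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        w = np.asarray(self.w, dtype=np.float64)
        if w.shape != (3, 3):
            raise ValueError("linking kernel W must be 3x3")
        if w[1, 1] != 0:
            raise ValueError("linking kernel W must have zero centre")
        object.__setattr__(self, "w", w)


@dataclass
class PcnnState:
    """Neuron fields after simulation (all stimulus-shaped)."""

    F: np.ndarray
    L: np.ndarray
    U: np.ndarray
    theta: np.ndarray
    Y: np.ndarray
    T: np.ndarray


def _simulate(S: np.ndarray, params: PcnnParams) -> PcnnState:
    S = np.asarray(S, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise ValueError("stimulus contains non-finite values")
    if np.any(S < 0):
        raise ValueError("stimulus must be nonnegative")
    dec_l = np.exp(-params.alpha_l)
    dec_t = np.exp(-params.alpha_theta)
    L = np.zeros_like(S)
    theta = np.zeros_like(S)
    Y = np.zeros_like(S)
    T = np.zeros(S.shape, dtype=np.int64)
    F = S
    U = np.zeros_like(S)
    for _ in range(params.n_iter):
        link = ndimage.correlate(Y, params.w, mode="mirror")
        L = dec_l * L + params.v_l * link
        U = F * (1.0 + params.beta * L)
        theta = dec_t * theta + params.v_theta * Y
        Y = (U > theta).astype(np.float64)
        T += Y.astype(np.int64)
    return PcnnState(F=F, L=L, U=U, theta=theta, Y=Y, T=T)


def pcnn_firing_times(S: np.ndarray, params: PcnnParams | None = None) -> np.ndarray:
    """Accumulated firing counts T after ``params.n_iter`` iterations."""
    return _simulate(S, params or PcnnParams()).T


def _joint_rescale(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi > lo:
        return (a - lo) / (hi - lo), (b - lo) / (hi - lo)
    return np.zeros_like(a), np.zeros_like(b)


def fuse_low_frequency(
    la: np.ndarray,
    lb: np.ndarray,
    params: PcnnParams | None = None,
    normalize: str = "joint",
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse two low-frequency sub-bands by comparing PCNN firing totals.

    The decision map is ``D = 1`` where ``T_A >= T_B`` (ties go to A) and the
    fused band takes A there, B elsewhere.  With ``normalize="joint"``
    (default) both bands are rescaled to [0, 1] by their joint min/max before
    driving the network, so firing dynamics are intensity-comparable across
    modalities; ``normalize="none"`` feeds the raw bands (which must be
    nonnegative).

    Returns ``(fused, decision_map)``.
    """
    la = np.asarray(la, dtype=np.float64)
    lb = np.asarray(lb, dtype=np.float64)
    if la.shape != lb.shape:
        raise ValueError(f"shape mismatch: {la.shape} vs {lb.shape}")
    params = params or PcnnParams()
    if normalize == "joint":
        sa, sb = _joint_rescale(la, lb)
    elif normalize == "none":
        sa, sb = la, lb
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    ta = pcnn_firing_times(sa, params)
    tb = pcnn_firing_times(sb, params)
    d = (ta >= tb).astype(np.float64)
    fused = np.where(d == 1.0, la, lb)
    return fused, d
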