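"""Convolutional form of the DIM processing stage.

Functionally interchangeable with the matrix form, but prediction neurons
with identical receptive fields are replicated at every pixel: each
prediction "class" j is a 2-D response map, and weights are small 2-D
kernels per (class, input channel) pair.  Cross-correlation with zero
padding keeps every map at the input's spatial size, so there is one
prediction response per pixel.

Kernel conventions (fixed, documented choices):

* feedforward kernels of one class are normalised jointly over all input
  channels and positions to sum to one (the spatial analogue of a weight
  row summing to one);
* feedback kernels are the 180-degree rotation of the feedforward ones,
  rescaled per class so the maximum weight across all channels is one;
* odd-sized kernels anchor at their centre; even-sized kernels anchor at
  ``floor(size/2)`` (the centred crop used by :func:`scipy.signal.fftconvolve`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import fftconvolve

from pcbc.core import DEFAULT_EPSILON2, DEFAULT_N_ITER, DEFAULT_RESPONSE_FLOOR

__all__ = [
    "ConvNetwork", "ConvState", "build_conv_network", "conv_step",
    "conv_solve_steady_state",
]


@dataclasses.dataclass
class ConvNetwork:
    """One explaining-away stage with spatially replicated neurons.

    ``kernels_w`` and ``kernels_v`` have shape ``(p, k, kh, kw)`` for
    ``p`` prediction classes and ``k`` input channels.
    """

    kernels_w: np.ndarray
    kernels_v: np.ndarray
    epsilon1: float
    epsilon2: float
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.kernels_w.shape[0]

    @property
    def n_channels(self) -> int:
        return self.kernels_w.shape[1]


@dataclasses.dataclass
class ConvState:
    """Channel maps for input, predictions, reconstruction and error."""

    X: np.ndarray  # (k, H, W)
    Y: np.ndarray  # (p, H, W)
    R: np.ndarray  # (k, H, W)
    E: np.ndarray  # (k, H, W)
    iteration: int = 0


def build_conv_network(raw_kernels, epsilon2: float = DEFAULT_EPSILON2,
                       meta: dict | None = None) -> ConvNetwork:
    """Normalise raw ``(p, k, kh, kw)`` kernels into a :class:`ConvNetwork`."""
    K0 = np.asarray(raw_kernels, dtype=np.float64)
    if K0.ndim != 4:
        raise ValueError(
            f"raw_kernels must have shape (p, k, kh, kw), got {K0.shape}")
    if not np.all(np.isfinite(K0)):
        raise ValueError("raw_kernels contains non-finite values")
    if np.any(K0 < 0):
        raise ValueError("raw_kernels must be non-negative")
    totals = K0.sum(axis=(1, 2, 3))
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"cannot normalise all-zero kernel class(es) {bad.tolist()}")
    w = K0 / totals[:, None, None, None]
    maxes = w.max(axis=(1, 2, 3))
    v = w[:, :, ::-1, ::-1] / maxes[:, None, None, None]
    # Total feedback weight received by an interior reconstruction neuron
    # of each channel; sets epsilon1 as in the matrix form.
    channel_mass = v.sum(axis=(0, 2, 3))
    epsilon1 = float(epsilon2) / float(channel_mass.max())
    return ConvNetwork(kernels_w=w, kernels_v=v, epsilon1=epsilon1,
                       epsilon2=float(epsilon2), meta=dict(meta or {}))


def _corr_sum(maps: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """``out[b] = sum_a maps[a] (cross-correlate) kernels[a, b]``.

    ``maps`` has shape (A, H, W) and ``kernels`` (A, B, kh, kw); output is
    (B, H, W), zero-padded to keep the spatial size.  FFT round-off can
    produce tiny negatives, which are clipped so non-negativity is exact.
    """
    kh, kw = kernels.shape[-2:]
    H, W = maps.shape[-2:]
    full = fftconvolve(maps[:, None], kernels[:, :, ::-1, ::-1],
                       mode="full", axes=(2, 3))
    r0, c0 = (kh - 1) // 2, (kw - 1) // 2
    out = full[:, :, r0:r0 + H, c0:c0 + W].sum(axis=0)
    return np.maximum(out, 0.0)


def conv_step(net: ConvNetwork, state: ConvState) -> ConvState:
    """One synchronous update of the convolutional populations."""
    w, v = net.kernels_w, net.kernels_v
    X, Y = state.X, state.Y
    if X.ndim != 3 or X.shape[0] != net.n_channels:
        raise ValueError(
            f"X must have {net.n_channels} channels, got shape {X.shape}")
    if Y.ndim != 3 or Y.shape[0] != net.n_classes or Y.shape[1:] != X.shape[1:]:
        raise ValueError(
            f"Y must have shape ({net.n_classes},)+{X.shape[1:]}, got {Y.shape}")
    R = _corr_sum(Y, v)                                    # (k, H, W)
    E = X / np.maximum(net.epsilon2, R)
    Y_new = np.maximum(net.epsilon1, Y) * _corr_sum(E, np.swapaxes(w, 0, 1))
    return ConvState(X=X, Y=Y_new, R=R, E=E, iteration=state.iteration + 1)


def conv_solve_steady_state(net: ConvNetwork, X,
                            n_iter: int = DEFAULT_N_ITER,
                            response_floor: float = DEFAULT_RESPONSE_FLOOR,
                            ) -> ConvState:
    """Iterate from ``Y = 0``, floor small responses, return a consistent state."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3 or X.shape[0] != net.n_channels:
        raise ValueError(
            f"X must have {net.n_channels} channels, got shape {X.shape}")
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("X must be non-negative and finite")
    shape = (net.n_classes,) + X.shape[1:]
    state = ConvState(X=X, Y=np.zeros(shape), R=np.zeros_like(X),
                      E=np.zeros_like(X))
    for _ in range(n_iter):
        state = conv_step(net, state)
    Y = state.Y.copy()
    Y[Y < response_floor] = 0.0
    R = _corr_sum(Y, net.kernels_v)
    E = X / np.maximum(net.epsilon2, R)
    return ConvState(X=X, Y=Y, R=R, E=E, iteration=state.iteration)
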