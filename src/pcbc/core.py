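"""Matrix form of the divisive-input-modulation (DIM) processing stage.

One stage holds a non-negative dictionary in its feedforward weights ``W``
(one row per prediction neuron) and a rescaled transpose in its feedback
weights ``V``.  Inference iterates three populations: reconstruction
neurons ``r = V y``, error neurons ``e = x / max(eps2, r)`` and prediction
neurons ``y <- max(eps1, y) * (W e)``.  At the fixed point the prediction
responses minimise the generalized Kullback-Leibler divergence between the
input and its reconstruction, which implements explaining away: dictionary
elements compete for the evidence and the best-supported ones suppress
the rest.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "DEFAULT_EPSILON2", "DEFAULT_N_ITER", "DEFAULT_RESPONSE_FLOOR",
    "DIMNetwork", "DIMState", "build_network", "dim_step",
    "solve_steady_state", "kl_divergence",
]

#: Division floor preventing divide-by-zero in the error neurons.
DEFAULT_EPSILON2 = 1e-2
#: Number of update iterations used to reach the steady state.
DEFAULT_N_ITER = 50
#: Prediction responses below this value are zeroed after inference.
DEFAULT_RESPONSE_FLOOR = 1e-3


@dataclasses.dataclass
class DIMNetwork:
    """One explaining-away processing stage (matrix form).

    Attributes
    ----------
    W : ndarray, shape (n, m)
        Feedforward weights; every row sums to one.
    V : ndarray, shape (m, n)
        Feedback weights; transpose of ``W`` with each column rescaled to a
        maximum of one.
    epsilon1, epsilon2 : float
        Small positive floors applied to ``y`` and ``r`` respectively.
    v_row_sums : ndarray, shape (m,)
        Total feedback weight targeting each reconstruction neuron.
    meta : dict
        Free-form metadata (dictionary element labels etc.), carried along
        so that downstream stages can group prediction neurons.
    """

    W: np.ndarray
    V: np.ndarray
    epsilon1: float
    epsilon2: float
    v_row_sums: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_prediction(self) -> int:
        return self.W.shape[0]

    @property
    def n_input(self) -> int:
        return self.W.shape[1]


@dataclasses.dataclass
class DIMState:
    """Activations of one stage: input, predictions, reconstruction, error."""

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    e: np.ndarray
    iteration: int = 0


def build_network(raw_weights, epsilon2: float = DEFAULT_EPSILON2,
                  meta: dict | None = None) -> DIMNetwork:
    """Normalise raw dictionary weights into a :class:`DIMNetwork`.

    Rows of ``W`` are rescaled to sum to one; ``V`` is the transpose of
    ``W`` with each column rescaled to a maximum of one; ``epsilon1`` is
    ``epsilon2 / max(v_row_sums)``.

    Raises
    ------
    ValueError
        If any weight is negative or non-finite, or a row sums to zero
        (a zero row cannot be normalised).
    """
    W0 = np.asarray(raw_weights, dtype=np.float64)
    if W0.ndim != 2:
        raise ValueError(f"raw_weights must be 2-D, got shape {W0.shape}")
    if not np.all(np.isfinite(W0)):
        raise ValueError("raw_weights contains non-finite values")
    if np.any(W0 < 0):
        raise ValueError("raw_weights must be non-negative")
    if epsilon2 <= 0:
        raise ValueError("epsilon2 must be positive")
    row_sums = W0.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = np.flatnonzero(row_sums <= 0)
        raise ValueError(
            f"cannot normalise all-zero weight row(s) {bad.tolist()}")
    W = W0 / row_sums[:, None]
    # Each column of V corresponds to one prediction neuron's row of W.
    col_max = W.max(axis=1)
    V = W.T / col_max[None, :]
    v_row_sums = V.sum(axis=1)
    epsilon1 = float(epsilon2) / float(v_row_sums.max())
    return DIMNetwork(W=W, V=V, epsilon1=epsilon1, epsilon2=float(epsilon2),
                      v_row_sums=v_row_sums, meta=dict(meta or {}))


def dim_step(net: DIMNetwork, state: DIMState) -> DIMState:
    """Apply one synchronous update of the three neural populations.

    The returned state carries the reconstruction and error computed from
    the *incoming* prediction responses, plus the updated predictions.
    """
    x, y = state.x, state.y
    if x.shape != (net.n_input,):
        raise ValueError(
            f"input length {x.shape} does not match network m={net.n_input}")
    if y.shape != (net.n_prediction,):
        raise ValueError(
            f"y length {y.shape} does not match network n={net.n_prediction}")
    r = net.V @ y
    e = x / np.maximum(net.epsilon2, r)
    y_new = np.maximum(net.epsilon1, y) * (net.W @ e)
    return DIMState(x=x, y=y_new, r=r, e=e, iteration=state.iteration + 1)


def solve_steady_state(net: DIMNetwork, x, n_iter: int = DEFAULT_N_ITER,
                       response_floor: float = DEFAULT_RESPONSE_FLOOR,
                       ) -> DIMState:
    """Run the dynamics from ``y = 0`` and return a consistent final state.

    After ``n_iter`` iterations, prediction responses below
    ``response_floor`` are set to zero and the reconstruction and error
    are recomputed from the floored responses so that downstream stages
    see a self-consistent state.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (net.n_input,):
        raise ValueError(
            f"input length {x.shape} does not match network m={net.n_input}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("input must be non-negative and finite")
    state = DIMState(x=x, y=np.zeros(net.n_prediction),
                     r=np.zeros(net.n_input), e=np.zeros(net.n_input))
    for _ in range(n_iter):
        state = dim_step(net, state)
    y = state.y.copy()
    y[y < response_floor] = 0.0
    r = net.V @ y
    e = x / np.maximum(net.epsilon2, r)
    return DIMState(x=x, y=y, r=r, e=e, iteration=state.iteration)


def kl_divergence(x, r, floor: float = DEFAULT_EPSILON2) -> float:
    """Generalized KL divergence ``sum(x log(x/r) - x + r)``.

    Uses the ``0 log 0 = 0`` convention and floors ``r`` at ``floor``
    inside the logarithm for numerical stability.  Non-negative, and zero
    iff ``x == r`` (up to the flooring).
    """
    x = np.asarray(x, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {r.shape}")
    r_safe = np.maximum(r, floor)
    log_term = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / r_safe), 0.0)
    return float(np.sum(log_term - x + r))
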