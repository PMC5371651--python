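"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: the KL minimiser
uses a generic constrained optimiser, and the matrix equivalent of a
convolutional network is assembled by explicit kernel placement loops.
"""

import numpy as np
from scipy.optimize import minimize

from pcbc.core import DIMNetwork


def kl_minimizer(V: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Non-negative minimiser of KL(x || V y) via L-BFGS-B."""
    V = np.asarray(V, dtype=float)
    x = np.asarray(x, dtype=float)
    n = V.shape[1]

    def f(y):
        r = V @ y + 1e-300
        return float(np.sum(np.where(x > 0, x * np.log(
            np.where(x > 0, x, 1.0) / r), 0.0) - x + r))

    def g(y):
        r = V @ y + 1e-300
        return V.T @ (1.0 - x / r)

    res = minimize(f, np.full(n, max(x.mean(), 1e-3)), jac=g,
                   bounds=[(0.0, None)] * n, method="L-BFGS-B",
                   options=dict(ftol=1e-16, gtol=1e-14, maxiter=10000))
    return res.x


def conv_as_matrix(net, height: int, width: int) -> DIMNetwork:
    """Matrix-form network equivalent to a ConvNetwork on an HxW image.

    Every (class, row, col) prediction neuron gets a weight row built by
    placing its kernel at that offset (truncated at the borders, matching
    zero padding); feedback weights place the feedback kernels the same
    way.  Built with plain loops as an independent oracle.
    """
    w, v = net.kernels_w, net.kernels_v
    p, k, kh, kw = w.shape
    ar, ac = (kh - 1) // 2, (kw - 1) // 2
    n = p * height * width
    m = k * height * width
    W = np.zeros((n, m))
    V = np.zeros((m, n))
    for j in range(p):
        for r in range(height):
            for c in range(width):
                ni = (j * height + r) * width + c
                for i in range(k):
                    for u in range(kh):
                        for t in range(kw):
                            # feedforward: neuron (j, r, c) reads input at
                            # (r + u - ar, c + t - ac)
                            rr = r + u - ar
                            cc = c + t - ac
                            if 0 <= rr < height and 0 <= cc < width:
                                mi = (i * height + rr) * width + cc
                                W[ni, mi] += w[j, i, u, t]
                            # feedback: reconstruction pixel at position x
                            # receives v[u, t] from the neuron at
                            # (x + u - ar, c + t - ac), i.e. neuron (r, c)
                            # feeds pixel (r - (u - ar), c - (t - ac))
                            rv = r - (u - ar)
                            cv = c - (t - ac)
                            if 0 <= rv < height and 0 <= cv < width:
                                mi = (i * height + rv) * width + cv
                                V[mi, ni] += v[j, i, u, t]
    return DIMNetwork(W=W, V=V, epsilon1=net.epsilon1, epsilon2=net.epsilon2,
                      v_row_sums=V.sum(axis=1))


def enumerate_merge_orders(sims: np.ndarray, kappa: float) -> set:
    """All terminal partitions reachable by any order of valid merges.

    A merge of two clusters is valid when their complete-linkage
    similarity (minimum pairwise similarity between members) is at least
    ``kappa``; a partition is terminal when no valid merge remains.
    """
    n = sims.shape[0]
    start = frozenset(frozenset([i]) for i in range(n))
    seen = set()
    terminals = set()

    def linkage(a, b):
        return min(sims[i, j] for i in a for j in b)

    stack = [start]
    while stack:
        part = stack.pop()
        if part in seen:
            continue
        seen.add(part)
        clusters = list(part)
        merges = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if linkage(clusters[i], clusters[j]) >= kappa:
                    merges.append((clusters[i], clusters[j]))
        if not merges:
            terminals.add(part)
            continue
        for a, b in merges:
            nxt = (part - {a, b}) | {a | b}
            stack.append(nxt)
    return terminals
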