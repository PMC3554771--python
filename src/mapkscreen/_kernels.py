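"""Compiled mass-action kernels.

The right-hand side and Jacobian are evaluated thousands of times per
steady-state solve during ensemble screening, so the inner loops are
JIT-compiled with numba.  The pure-numpy fallbacks in :mod:`.network` give
identical results (same arithmetic, same order within each reaction).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def rhs_kernel(x, keff, idx_a, idx_b, stoich):
    n_s = stoich.shape[0]
    n_r = stoich.shape[1]
    dx = np.zeros(n_s)
    for j in range(n_r):
        v = keff[j] * x[idx_a[j]]
        if idx_b[j] >= 0:
            v *= x[idx_b[j]]
        if v != 0.0:
            for i in range(n_s):
                c = stoich[i, j]
                if c != 0.0:
                    dx[i] += c * v
    return dx


@njit(cache=True)
def jac_kernel(x, keff, idx_a, idx_b, stoich):
    n_s = stoich.shape[0]
    n_r = stoich.shape[1]
    J = np.zeros((n_s, n_s))
    for j in range(n_r):
        a = idx_a[j]
        b = idx_b[j]
        if b < 0:
            da = keff[j]
            for i in range(n_s):
                c = stoich[i, j]
                if c != 0.0:
                    J[i, a] += c * da
        else:
            da = keff[j] * x[b]
            db = keff[j] * x[a]
            for i in range(n_s):
                c = stoich[i, j]
                if c != 0.0:
                    J[i, a] += c * da
                    J[i, b] += c * db
    return J
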