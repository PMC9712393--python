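"""Hot loops of the propagation machinery.

The forward/backward scans over the timestep axis are inherently sequential,
so the vectorized numpy formulation is dominated by per-step call overhead at
realistic step counts (~700).  When numba is importable the scans are JIT
compiled; otherwise a pure-numpy fallback with identical semantics is used.
All products are Hamilton products in the (A, B, C, D) component layout.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every propagation call
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _scan_forward_jit(q, out):  # q: (N, E, 4); out: (N+1, E, 4) with out[0] preset
    n, e, _ = q.shape
    for k in range(n):
        for i in range(e):
            a2, b2, c2, d2 = q[k, i, 0], q[k, i, 1], q[k, i, 2], q[k, i, 3]
            a1, b1, c1, d1 = out[k, i, 0], out[k, i, 1], out[k, i, 2], out[k, i, 3]
            out[k + 1, i, 0] = d2 * a1 - c2 * b1 + b2 * c1 + a2 * d1
            out[k + 1, i, 1] = c2 * a1 + d2 * b1 - a2 * c1 + b2 * d1
            out[k + 1, i, 2] = -b2 * a1 + a2 * b1 + d2 * c1 + c2 * d1
            out[k + 1, i, 3] = -a2 * a1 - b2 * b1 - c2 * c1 + d2 * d1


@njit(cache=True)
def _scan_backward_jit(q, out):  # out: (N, E, 4) with out[N-1] preset to P_N
    n, e, _ = q.shape
    for k in range(n - 2, -1, -1):
        for i in range(e):
            # conj(q[k+1]) * out[k+1]
            a2, b2, c2, d2 = -q[k + 1, i, 0], -q[k + 1, i, 1], -q[k + 1, i, 2], q[k + 1, i, 3]
            a1, b1, c1, d1 = out[k + 1, i, 0], out[k + 1, i, 1], out[k + 1, i, 2], out[k + 1, i, 3]
            out[k, i, 0] = d2 * a1 - c2 * b1 + b2 * c1 + a2 * d1
            out[k, i, 1] = c2 * a1 + d2 * b1 - a2 * c1 + b2 * d1
            out[k, i, 2] = -b2 * a1 + a2 * b1 + d2 * c1 + c2 * d1
            out[k, i, 3] = -a2 * a1 - b2 * b1 - c2 * c1 + d2 * d1


def _mul_np(q2, q1, out):
    a2, b2, c2, d2 = q2[:, 0], q2[:, 1], q2[:, 2], q2[:, 3]
    a1, b1, c1, d1 = q1[:, 0], q1[:, 1], q1[:, 2], q1[:, 3]
    out[:, 0] = d2 * a1 - c2 * b1 + b2 * c1 + a2 * d1
    out[:, 1] = c2 * a1 + d2 * b1 - a2 * c1 + b2 * d1
    out[:, 2] = -b2 * a1 + a2 * b1 + d2 * c1 + c2 * d1
    out[:, 3] = -a2 * a1 - b2 * b1 - c2 * c1 + d2 * d1


def scan_forward(q):
    """Cumulative propagators: returns X of shape (N+1, E, 4), X[0] = identity."""
    q = np.ascontiguousarray(q, dtype=np.float64)
    out = np.empty((q.shape[0] + 1,) + q.shape[1:], dtype=np.float64)
    out[0, :, :3] = 0.0
    out[0, :, 3] = 1.0
    if _HAVE_NUMBA:
        _scan_forward_jit(q, out)
    else:
        for k in range(q.shape[0]):
            _mul_np(q[k], out[k], out[k + 1])
    return out


def scan_backward(q, p_n):
    """Costate transport: returns P of shape (N, E, 4) with P[N-1] = p_n."""
    q = np.ascontiguousarray(q, dtype=np.float64)
    out = np.empty_like(q)
    out[-1] = p_n
    if q.shape[0] == 1:
        return out
    if _HAVE_NUMBA:
        _scan_backward_jit(q, out)
    else:
        conj = -q
        conj[..., 3] = q[..., 3]
        for k in range(q.shape[0] - 2, -1, -1):
            _mul_np(conj[k + 1], out[k + 1], out[k])
    return out


def scan_final(q):
    """Net propagator only: returns X_N of shape (E, 4)."""
    return scan_forward(q)[-1]
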