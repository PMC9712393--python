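"""Independent oracles used across the test suite.

These deliberately avoid the package's quaternion path: the SU(2) oracle
multiplies 2x2 complex matrices, and the Bloch oracle integrates the
magnetization ODE dM/dt = 2*pi*(u_x, u_y, nu_off) x M with an adaptive
solver over each piecewise-constant step.
"""

import numpy as np
from scipy.integrate import solve_ivp

_SX = np.array([[0, 1], [1, 0]], dtype=complex)
_SY = np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = np.array([[1, 0], [0, -1]], dtype=complex)


def su2_step(u_x, u_y, nu_off, dt):
    """SU(2) propagator of one piecewise-constant step."""
    omega = np.sqrt(u_x**2 + u_y**2 + nu_off**2)
    if omega == 0:
        return np.eye(2, dtype=complex)
    theta = 2 * np.pi * dt * omega
    n = np.array([u_x, u_y, nu_off]) / omega
    h = n[0] * _SX + n[1] * _SY + n[2] * _SZ
    return np.cos(theta / 2) * np.eye(2) - 1j * np.sin(theta / 2) * h


def su2_final(pulse, nu_off, b1_scale=1.0):
    """SU(2) matrix product over the whole pulse (applied left to right)."""
    u = np.eye(2, dtype=complex)
    for k in range(pulse.n_steps):
        u = su2_step(b1_scale * pulse.u_x[k], b1_scale * pulse.u_y[k], nu_off, pulse.dt) @ u
    return u


def quat_to_su2(q):
    """Map (A, B, C, D) to D*I - i*(A*sx + B*sy + C*sz)."""
    a, b, c, d = q
    return d * np.eye(2) - 1j * (a * _SX + b * _SY + c * _SZ)


def bloch_final(pulse, nu_off, m0, b1_scale=1.0, rtol=1e-11, atol=1e-12):
    """Integrate dM/dt = 2*pi*(u_x, u_y, nu_off) x M step by step."""
    m = np.asarray(m0, dtype=float)
    for k in range(pulse.n_steps):
        w = 2 * np.pi * np.array(
            [b1_scale * pulse.u_x[k], b1_scale * pulse.u_y[k], nu_off]
        )
        sol = solve_ivp(
            lambda t, y: np.cross(w, y),
            (0.0, pulse.dt),
            m,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        m = sol.y[:, -1]
    return m
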