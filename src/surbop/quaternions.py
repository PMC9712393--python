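"""Quaternion propagation of a spin-1/2 isochromat under piecewise-constant controls.

A rotation is stored as a 4-vector ``(A, B, C, D)`` where ``(A, B, C)`` is the
rotation axis scaled by ``sin(theta/2)`` and ``D = cos(theta/2)`` (the
Cayley--Klein parametrization of SU(2)).  The identity rotation is
``(0, 0, 0, 1)``.  ``q`` and ``-q`` encode the same physical SO(3) rotation
(double cover).

Rotation convention
-------------------
Rotations are right-handed and active: a 90 degree rotation about +x maps
``+z`` to ``-y``, and free evolution at a positive offset rotates ``+x``
towards ``+y``.  Mirrored conventions produce equally valid (phase-reflected)
pulse shapes; all modules in this package use this one convention.

Controls ``u_x``, ``u_y`` and offsets are nutation frequencies in Hz; the
rotation angle of one step of length ``dt`` seconds is
``theta = 2*pi*dt*sqrt(u_x**2 + u_y**2 + nu_off**2)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "step_quaternion",
    "step_quaternion_derivatives",
    "quat_mul",
    "quat_conj",
    "composition_matrix",
    "from_axis_angle",
    "target_rotation",
    "propagate",
    "final_propagator",
    "apply_to_magnetization",
]

IDENTITY = np.array([0.0, 0.0, 0.0, 1.0])

#: below this rotation angle (rad) the sin(x)/x forms switch to their series limits
_SMALL_ANGLE = 1e-9


def _as_float(x, name):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def step_quaternion(u_x, u_y, nu_off, dt):
    """Rotation quaternion of one piecewise-constant step.

    Parameters are broadcast; amplitudes in Hz, ``dt`` in seconds.  Returns an
    array with shape ``broadcast(...) + (4,)`` holding ``(A, B, C, D)``.  A
    zero-angle step returns the identity ``(0, 0, 0, 1)``.
    """
    u_x = _as_float(u_x, "u_x")
    u_y = _as_float(u_y, "u_y")
    nu_off = _as_float(nu_off, "nu_off")
    if not np.isscalar(dt) and np.ndim(dt) != 0:
        raise ValueError("dt must be a scalar")
    dt = float(dt)
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError("dt must be a positive finite number")

    u_x, u_y, nu_off = np.broadcast_arrays(u_x, u_y, nu_off)
    omega = np.sqrt(u_x**2 + u_y**2 + nu_off**2)  # effective nutation rate, Hz
    half = np.pi * dt * omega                      # theta/2
    # sin(half)/omega with its limit pi*dt at omega -> 0
    safe = np.where(omega > 0, omega, 1.0)
    s = np.where(half > _SMALL_ANGLE, np.sin(half) / safe, np.pi * dt)
    q = np.empty(np.shape(omega) + (4,))
    q[..., 0] = s * u_x
    q[..., 1] = s * u_y
    q[..., 2] = s * nu_off
    q[..., 3] = np.cos(half)
    return q


def step_quaternion_derivatives(u_x, u_y, nu_off, dt):
    """Exact derivatives of the step quaternion w.r.t. ``u_x`` and ``u_y``.

    Returns ``(dq_dux, dq_duy)`` with the same leading shape as the broadcast
    inputs plus a trailing axis of 4.  Used to assemble analytic control
    gradients; validated against central finite differences.
    """
    u_x = _as_float(u_x, "u_x")
    u_y = _as_float(u_y, "u_y")
    nu_off = _as_float(nu_off, "nu_off")
    dt = float(dt)
    if dt <= 0:
        raise ValueError("dt must be positive")

    u_x, u_y, nu_off = np.broadcast_arrays(u_x, u_y, nu_off)
    h = np.pi * dt
    omega = np.sqrt(u_x**2 + u_y**2 + nu_off**2)
    half = h * omega
    small = half <= _SMALL_ANGLE
    safe = np.where(omega > 0, omega, 1.0)

    f = np.where(small, h, np.sin(half) / safe)                     # sin(h w)/w
    # f'(w) = (h w cos(h w) - sin(h w)) / w**2 ;  series: -h**3 w / 3
    fp = np.where(
        small,
        -(h**3) * omega / 3.0,
        (h * safe * np.cos(half) - np.sin(half)) / safe**2,
    )
    dw = np.where(small, 0.0, 1.0 / safe)  # d(omega)/d(u) = u/omega

    shape = np.shape(omega) + (4,)
    dqx = np.zeros(shape)
    dqy = np.zeros(shape)

    cx = fp * u_x * dw  # d f / d u_x
    dqx[..., 0] = cx * u_x + f
    dqx[..., 1] = cx * u_y
    dqx[..., 2] = cx * nu_off
    dqx[..., 3] = -h * np.sin(half) * u_x * dw

    cy = fp * u_y * dw
    dqy[..., 0] = cy * u_x
    dqy[..., 1] = cy * u_y + f
    dqy[..., 2] = cy * nu_off
    dqy[..., 3] = -h * np.sin(half) * u_y * dw
    return dqx, dqy


def quat_mul(q2, q1):
    """Hamilton product ``q2 * q1`` in ``(A, B, C, D)`` layout (broadcasting).

    Composition of rotations: applying ``q1`` first and then ``q2`` gives the
    net rotation ``quat_mul(q2, q1)``.  Equivalent to
    ``composition_matrix(q2) @ q1`` but vectorized.
    """
    q2 = np.asarray(q2, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    a2, b2, c2, d2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    a1, b1, c1, d1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    out = np.empty(np.broadcast_shapes(q2.shape, q1.shape))
    out[..., 0] = d2 * a1 - c2 * b1 + b2 * c1 + a2 * d1
    out[..., 1] = c2 * a1 + d2 * b1 - a2 * c1 + b2 * d1
    out[..., 2] = -b2 * a1 + a2 * b1 + d2 * c1 + c2 * d1
    out[..., 3] = -a2 * a1 - b2 * b1 - c2 * c1 + d2 * d1
    return out


def quat_conj(q):
    """Conjugate (inverse rotation for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    out = -q.copy()
    out[..., 3] = q[..., 3]
    return out


def composition_matrix(q2):
    """4x4 matrix ``R2`` such that ``X2 = R2 @ U1`` composes two rotations.

    ``R2`` is the left-multiplication matrix of ``q2`` in the quaternion
    algebra.  ``q2`` must be unit-norm (checked to 1e-9).
    """
    q2 = np.asarray(q2, dtype=float)
    if q2.shape[-1] != 4:
        raise ValueError("quaternion must have 4 components")
    norm = np.sqrt(np.sum(q2**2, axis=-1))
    if not np.allclose(norm, 1.0, atol=1e-9):
        raise ValueError("composition_matrix requires a unit quaternion")
    a, b, c, d = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    rows = [
        [d, -c, b, a],
        [c, d, -a, b],
        [-b, a, d, c],
        [-a, -b, -c, d],
    ]
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def from_axis_angle(axis, angle_rad):
    """Unit quaternion for a rotation of ``angle_rad`` about the 3-vector ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    s = np.sin(angle_rad / 2.0)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s, np.cos(angle_rad / 2.0)])


def target_rotation(angle_deg, phase_deg=0.0):
    """Target propagator for a hard rotation in the transverse plane.

    ``angle_deg`` is the flip angle; ``phase_deg`` the rf phase (0 = x axis,
    90 = y axis).  ``target_rotation(180)`` is ``(1, 0, 0, 0)`` and
    ``target_rotation(90)`` is ``(1/sqrt(2), 0, 0, 1/sqrt(2))``.
    """
    phi = np.deg2rad(phase_deg)
    return from_axis_angle([np.cos(phi), np.sin(phi), 0.0], np.deg2rad(angle_deg))


def propagate(pulse, nu_off, b1_scale=1.0):
    """Cumulative propagators ``X_1 .. X_N`` of a shaped pulse at one offset.

    ``b1_scale`` multiplies the control amplitudes (rf-field inhomogeneity);
    the offset is never scaled.  Returns an ``(N, 4)`` array; ``X_k`` is the
    net rotation of the first ``k`` steps applied to the identity.
    """
    if pulse.n_steps == 0:
        raise ValueError("cannot propagate an empty pulse")
    if b1_scale <= 0:
        raise ValueError("b1_scale must be positive")
    q = step_quaternion(b1_scale * pulse.u_x, b1_scale * pulse.u_y, nu_off, pulse.dt)
    out = np.empty((pulse.n_steps, 4))
    x = IDENTITY
    for k in range(pulse.n_steps):
        x = quat_mul(q[k], x)
        out[k] = x
    return out


def final_propagator(pulse, nu_off, b1_scale=1.0):
    """Net rotation quaternion ``X_N`` of the whole pulse (one offset)."""
    return propagate(pulse, nu_off, b1_scale)[-1]


def apply_to_magnetization(q, M):
    """Rotate magnetization 3-vector(s) ``M`` by the rotation encoded in ``q``.

    Euler--Rodrigues form, quadratic in ``q``, so ``q`` and ``-q`` give the
    same output.  Broadcasts over leading axes; preserves ``|M|``.
    """
    q = np.asarray(q, dtype=float)
    M = np.asarray(M, dtype=float)
    v = q[..., :3]
    w = q[..., 3:4]
    cross1 = np.cross(v, M)
    return M + 2.0 * w * cross1 + 2.0 * np.cross(v, cross1)
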