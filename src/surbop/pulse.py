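"""Shaped-pulse data model: Cartesian controls, amplitude limits, random starts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ShapedPulse",
    "ControlLimits",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "clip_to_limit",
    "random_start",
]


@dataclass(frozen=True)
class ControlLimits:
    """Hardware constraint on the rf field: peak nutation frequency in Hz."""

    u_max: float

    def __post_init__(self):
        if not np.isfinite(self.u_max) or self.u_max <= 0:
            raise ValueError("u_max must be a positive finite frequency in Hz")


@dataclass(frozen=True)
class ShapedPulse:
    """Piecewise-constant control sequence.

    ``u_x[k]`` and ``u_y[k]`` are the Cartesian control amplitudes in Hz of
    the k-th step, ``dt`` the step duration in seconds.
    """

    u_x: np.ndarray
    u_y: np.ndarray
    dt: float
    label: str = field(default="")

    def __post_init__(self):
        ux = np.atleast_1d(np.asarray(self.u_x, dtype=float))
        uy = np.atleast_1d(np.asarray(self.u_y, dtype=float))
        if ux.ndim != 1 or uy.ndim != 1 or ux.size != uy.size or ux.size == 0:
            raise ValueError("u_x and u_y must be 1-D arrays of equal, non-zero length")
        if not (np.all(np.isfinite(ux)) and np.all(np.isfinite(uy))):
            raise ValueError("control amplitudes must be finite")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError("dt must be a positive step duration in seconds")
        ux.setflags(write=False)
        uy.setflags(write=False)
        object.__setattr__(self, "u_x", ux)
        object.__setattr__(self, "u_y", uy)

    @property
    def n_steps(self) -> int:
        return self.u_x.size

    @property
    def duration(self) -> float:
        """Total pulse length in seconds."""
        return self.n_steps * self.dt

    def amplitude(self) -> np.ndarray:
        """Per-step rf amplitude sqrt(u_x**2 + u_y**2) in Hz."""
        return np.hypot(self.u_x, self.u_y)

    def phase_deg(self) -> np.ndarray:
        """Per-step rf phase in degrees on [0, 360); zero-amplitude steps get 0."""
        _, phase = cartesian_to_polar(self.u_x, self.u_y)
        return phase

    def with_controls(self, u_x, u_y) -> "ShapedPulse":
        return replace(self, u_x=np.asarray(u_x, float), u_y=np.asarray(u_y, float))


def polar_to_cartesian(amplitude, phase_deg):
    """Convert rf amplitude (Hz) and phase (degrees) to Cartesian controls."""
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    phi = np.deg2rad(np.asarray(phase_deg, dtype=float))
    return amplitude * np.cos(phi), amplitude * np.sin(phi)


def cartesian_to_polar(u_x, u_y):
    """Inverse of :func:`polar_to_cartesian`; zero-amplitude phase is 0 by convention."""
    u_x = np.asarray(u_x, dtype=float)
    u_y = np.asarray(u_y, dtype=float)
    amp = np.hypot(u_x, u_y)
    phase = np.where(amp > 0, np.rad2deg(np.arctan2(u_y, u_x)), 0.0) % 360.0
    return amp, phase


def clip_to_limit(pulse: ShapedPulse, limits: ControlLimits) -> ShapedPulse:
    """Radially rescale over-limit steps to ``u_max``, preserving the phase.

    Steps within the limit are returned bit-identically; a 1e-12 relative
    dead-band absorbs the rounding of the rescale itself, which makes the
    operation exactly idempotent.
    """
    amp = pulse.amplitude()
    over = amp > limits.u_max * (1.0 + 1e-12)
    if not np.any(over):
        return pulse
    scale = np.where(over, limits.u_max / np.where(amp > 0, amp, 1.0), 1.0)
    return pulse.with_controls(pulse.u_x * scale, pulse.u_y * scale)


def random_start(
    n_steps: int,
    dt: float,
    limits: ControlLimits,
    seed: int,
    label: str = "",
) -> ShapedPulse:
    """Random starting shape: per-step amplitude uniform on [0, u_max],
    phase uniform on [0, 360) degrees; reproducible under a fixed seed."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.0, limits.u_max, n_steps)
    phase = rng.uniform(0.0, 360.0, n_steps)
    u_x, u_y = polar_to_cartesian(amp, phase)
    return ShapedPulse(u_x, u_y, dt, label=label or f"random-start seed={seed}")
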