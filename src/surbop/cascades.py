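"""Gaussian pulse cascades (Q5, Q3, G4) for qualitative comparison.

These literature band-selective shapes are sums of Gaussian envelopes; the
coefficient tables below (relative amplitude, centre as a fraction of the
pulse length, FWHM as a fraction of the pulse length) are the published
cascade constants.  Negative lobes are rendered as a 180-degree phase jump,
so the phase of any cascade takes exactly two values.

They serve only as comparison baselines for the optimized universal-rotation
shapes; their correctness here is asserted through qualitative envelope
properties (number of near-peak maxima, two-valued phase).
"""

from __future__ import annotations

import numpy as np

from .pulse import ShapedPulse, polar_to_cartesian

__all__ = [
    "GAUSSIAN_CASCADES",
    "gaussian_cascade",
    "Q_CASCADE_PEAK_RF_HZ",
    "G4_PEAK_RF_HZ",
]

#: peak rf amplitude (Hz) needed by Q5/Q3 cascades to cover the flagship
#: aliphatic band at 1.2 GHz -- sqrt(3) times the 15 kHz optimized-pulse cap
Q_CASCADE_PEAK_RF_HZ = 26_000.0
#: peak rf amplitude (Hz) of the G4 excitation cascade for the same band
G4_PEAK_RF_HZ = 22_700.0

# (relative amplitude, centre/T, FWHM/T) per Gaussian component
GAUSSIAN_CASCADES = {
    # universal 90-degree rotation, five Gaussians
    "Q5": (
        (-1.48, 0.162, 0.186),
        (-4.34, 0.307, 0.139),
        (7.33, 0.497, 0.143),
        (-2.30, 0.525, 0.290),
        (5.66, 0.803, 0.137),
    ),
    # universal 180-degree rotation (refocusing), three Gaussians
    "Q3": (
        (-4.39, 0.306, 0.180),
        (4.57, 0.545, 0.183),
        (2.60, 0.804, 0.245),
    ),
    # point-to-point excitation, four Gaussians
    "G4": (
        (0.62, 0.177, 0.172),
        (0.72, 0.492, 0.129),
        (-0.91, 0.653, 0.119),
        (-0.33, 0.892, 0.139),
    ),
}


def gaussian_cascade(
    name: str,
    duration: float,
    n_steps: int,
    peak_amplitude_hz: float = 1.0,
) -> ShapedPulse:
    """Sample the named cascade to ``n_steps`` piecewise-constant steps.

    The envelope is rescaled so its largest absolute value equals
    ``peak_amplitude_hz``; phase is 0 where the envelope is positive and 180
    degrees where it is negative.
    """
    key = str(name).upper()
    if key not in GAUSSIAN_CASCADES:
        raise ValueError(
            f"unknown cascade {name!r}; available: {sorted(GAUSSIAN_CASCADES)}"
        )
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if duration <= 0 or peak_amplitude_hz <= 0:
        raise ValueError("duration and peak_amplitude_hz must be positive")

    # midpoints of the steps as fractions of the pulse length
    tau = (np.arange(n_steps) + 0.5) / n_steps
    env = np.zeros(n_steps)
    for a, centre, fwhm in GAUSSIAN_CASCADES[key]:
        env += a * np.exp(-4.0 * np.log(2.0) * ((tau - centre) / fwhm) ** 2)
    env *= peak_amplitude_hz / np.max(np.abs(env))
    amplitude = np.abs(env)
    phase = np.where(env >= 0, 0.0, 180.0)
    u_x, u_y = polar_to_cartesian(amplitude, phase)
    return ShapedPulse(u_x, u_y, duration / n_steps, label=key)
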