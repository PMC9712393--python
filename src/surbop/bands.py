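"""Band definitions: passband/stopband offset grids and the B1 ensemble.

The flagship design problem is the aliphatic carbon band on a 1.2 GHz
spectrometer (300 MHz carbon Larmor frequency): an 80 ppm selective band
(nu_p = 12 kHz half-width), a 20 ppm transition (nu_s = 18 kHz) and two
symmetric 140 ppm (42 kHz) stopbands in which only z-rotations are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandSpec",
    "ppm_to_hz",
    "MAX_RF_AMPLITUDE_HZ",
    "DEFAULT_TIMESTEP_S",
    "DEFAULT_N_STEPS",
    "DEFAULT_B1_SCALES",
]

#: peak rf amplitude of the flagship design (Hz)
MAX_RF_AMPLITUDE_HZ = 15_000.0
#: control timestep of the flagship design (s)
DEFAULT_TIMESTEP_S = 0.5e-6
#: number of steps of the flagship design (duration 333.5 us)
DEFAULT_N_STEPS = 667
#: rf-inhomogeneity ensemble used during optimization: 0, +-2.5 %, +-5 %
DEFAULT_B1_SCALES = (0.95, 0.975, 1.0, 1.025, 1.05)


def ppm_to_hz(ppm: float, larmor_mhz: float) -> float:
    """Bandwidth in Hz of a chemical-shift range in ppm at the given Larmor
    frequency in MHz (1 ppm at 300 MHz = 300 Hz)."""
    return float(ppm) * float(larmor_mhz)


@dataclass(frozen=True)
class BandSpec:
    """Offset grids and B1 ensemble defining the optimization landscape.

    ``passband_offsets`` lie inside ``[-nu_p, nu_p]``; ``stopband_offsets``
    inside the two symmetric bands ``nu_s <= |w| <= outer``; ``b1_scales``
    multiply the control amplitudes.
    """

    nu_p: float
    nu_s: float
    passband_offsets: np.ndarray
    stopband_offsets: np.ndarray
    b1_scales: tuple = DEFAULT_B1_SCALES

    def __post_init__(self):
        if not (0 < self.nu_p < self.nu_s):
            raise ValueError("need 0 < nu_p < nu_s")
        po = np.sort(np.asarray(self.passband_offsets, dtype=float))
        so = np.sort(np.asarray(self.stopband_offsets, dtype=float))
        if po.size == 0 or so.size == 0:
            raise ValueError("offset grids must be non-empty")
        if np.any(np.abs(po) > self.nu_p + 1e-9):
            raise ValueError("passband offsets must lie within [-nu_p, nu_p]")
        if np.any(np.abs(so) < self.nu_s - 1e-9):
            raise ValueError("stopband offsets must satisfy |w| >= nu_s")
        b1 = tuple(float(b) for b in self.b1_scales)
        if len(b1) == 0 or any(b <= 0 for b in b1):
            raise ValueError("b1_scales must be positive and non-empty")
        po.setflags(write=False)
        so.setflags(write=False)
        object.__setattr__(self, "passband_offsets", po)
        object.__setattr__(self, "stopband_offsets", so)
        object.__setattr__(self, "b1_scales", b1)

    @property
    def outer_edge(self) -> float:
        """Outer edge of the stopbands (Hz)."""
        return float(np.max(np.abs(self.stopband_offsets)))

    @classmethod
    def from_edges(
        cls,
        nu_p: float,
        nu_s: float,
        outer: float,
        n_passband: int = 31,
        n_per_stopband: int = 31,
        b1_scales=DEFAULT_B1_SCALES,
    ) -> "BandSpec":
        """Equally spaced grids with endpoints included: ``n_passband`` points
        on ``[-nu_p, nu_p]`` and ``n_per_stopband`` points in each stopband."""
        if not (0 < nu_p < nu_s < outer):
            raise ValueError("need 0 < nu_p < nu_s < outer")
        passband = np.linspace(-nu_p, nu_p, n_passband)
        upper = np.linspace(nu_s, outer, n_per_stopband)
        stopband = np.concatenate([-upper[::-1], upper])
        return cls(nu_p, nu_s, passband, stopband, tuple(b1_scales))

    @classmethod
    def from_ppm(
        cls,
        band_ppm: float,
        transition_ppm: float,
        stopband_ppm: float,
        larmor_mhz: float,
        **kwargs,
    ) -> "BandSpec":
        """Band construction in chemical-shift units.

        ``band_ppm`` is the full selective bandwidth (so nu_p is half of it),
        ``transition_ppm`` the width of each transition region
        (nu_s = nu_p + transition) and ``stopband_ppm`` the width of each
        stopband (outer = nu_s + stopband).
        """
        nu_p = ppm_to_hz(band_ppm, larmor_mhz) / 2.0
        nu_s = nu_p + ppm_to_hz(transition_ppm, larmor_mhz)
        outer = nu_s + ppm_to_hz(stopband_ppm, larmor_mhz)
        return cls.from_edges(nu_p, nu_s, outer, **kwargs)

    @classmethod
    def default_aliphatic(cls) -> "BandSpec":
        """The flagship aliphatic-carbon design bands: 31 passband points on
        [-12, 12] kHz (800 Hz spacing) and 31 points per stopband on
        +-[18, 60] kHz (1.4 kHz spacing)."""
        return cls.from_edges(12_000.0, 18_000.0, 60_000.0)
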