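"""Response maps, offset profiles, and scalar quality metrics."""

import numpy as np
import pytest

import surbop as sb
from surbop.profiler import ProfileGrid, ResponseMap

from helpers import bloch_final

DT = 0.5e-6


def small_grid(initial=(0.0, 0.0, 1.0)):
    return ProfileGrid(np.linspace(-65e3, 65e3, 27), np.linspace(0.8, 1.2, 5), initial)


class TestResponseMap:
    def test_zero_pulse_leaves_z_everywhere(self):
        p = sb.ShapedPulse(np.zeros(10), np.zeros(10), DT)
        m = sb.response_map(p, small_grid())
        np.testing.assert_allclose(m.Mz, 1.0, atol=1e-14)
        np.testing.assert_allclose(m.Mx, 0.0, atol=1e-14)

    def test_hard_half_turn_inverts_on_resonance(self):
        # single-step hard 180x: at offset 0 and nominal B1 the spin inverts
        p = sb.ShapedPulse(np.array([1 / (2 * DT)]), np.array([0.0]), DT)
        grid = ProfileGrid(np.linspace(-65e3, 65e3, 27), np.array([0.9, 1.0, 1.1]))
        m = sb.response_map(p, grid)
        i0 = 13  # offset 0
        assert m.Mz[i0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_norm_conserved_at_every_grid_point(self, limits):
        p = sb.random_start(30, DT, limits, seed=6)
        m = sb.response_map(p, small_grid((1.0, 0.0, 0.0)))
        norm = m.Mx**2 + m.My**2 + m.Mz**2
        np.testing.assert_allclose(norm, 1.0, atol=1e-9)

    def test_matches_bloch_ode_on_subsample(self, limits):
        p = sb.random_start(12, DT, limits, seed=7)
        grid = ProfileGrid(np.array([-40e3, 0.0, 25e3]), np.array([0.85, 1.1]))
        m = sb.response_map(p, grid)
        for i, off in enumerate(grid.offsets):
            for j, b1 in enumerate(grid.b1_scales):
                want = bloch_final(p, off, [0, 0, 1], b1_scale=b1)
                got = np.array([m.Mx[i, j], m.My[i, j], m.Mz[i, j]])
                np.testing.assert_allclose(got, want, atol=1e-6)

    def test_x_only_pulse_has_offset_symmetric_mz(self, limits):
        p = sb.random_start(20, DT, limits, seed=2)
        p = p.with_controls(p.amplitude(), np.zeros(20))
        m = sb.response_map(p, small_grid())
        np.testing.assert_allclose(m.Mz, m.Mz[::-1], atol=1e-12)

    def test_default_grid_shape(self):
        g = ProfileGrid.default()
        assert g.offsets.size == 141 and g.b1_scales.size == 51
        assert g.offsets[0] == -65e3 and g.offsets[-1] == 65e3
        assert g.b1_scales[0] == 0.8 and g.b1_scales[-1] == 1.2


class TestOffsetProfile:
    def test_ideal_hard_quarter_turn_is_fully_absorptive(self):
        p = sb.ShapedPulse(np.array([1 / (4 * DT)]), np.array([0.0]), DT)
        prof = sb.offset_profile(p, np.linspace(-5e3, 5e3, 11))
        centre = 5
        assert prof.Mx[centre] == pytest.approx(1.0, abs=1e-10)
        assert prof.My[centre] == pytest.approx(0.0, abs=1e-10)

    def test_zero_pulse_has_no_transverse_signal(self):
        p = sb.ShapedPulse(np.zeros(6), np.zeros(6), DT)
        prof = sb.offset_profile(p, np.linspace(-5e3, 5e3, 11))
        np.testing.assert_allclose(np.hypot(prof.Mx, prof.My), 0.0, atol=1e-12)

    def test_phasing_rotates_transverse_plane_only(self, limits):
        p = sb.random_start(15, DT, limits, seed=1)
        offs = np.linspace(-10e3, 10e3, 21)
        prof = sb.offset_profile(p, offs)
        raw = sb.response_map(p, ProfileGrid(offs, np.array([1.0])))
        np.testing.assert_allclose(
            np.hypot(prof.Mx, prof.My), np.hypot(raw.Mx[:, 0], raw.My[:, 0]), atol=1e-12
        )
        np.testing.assert_allclose(prof.Mz, raw.Mz[:, 0], atol=1e-15)


class TestMetrics:
    def _synthetic_map(self, band, intensity_passband):
        """Map with prescribed -Mz passband intensity, identity stopbands."""
        grid = ProfileGrid(np.linspace(-65e3, 65e3, 131), np.linspace(0.9, 1.1, 11))
        n_off, n_b1 = grid.offsets.size, grid.b1_scales.size
        mz = -np.ones((n_off, n_b1))
        sel = np.abs(grid.offsets) <= band.nu_p
        mz[sel, :] = -np.asarray(intensity_passband)[:, None]
        props = np.zeros((n_off, n_b1, 4))
        props[..., 3] = 1.0
        props[sel, :, 0] = 1.0  # passband: 180x rotation, axis phase 0
        props[sel, :, 3] = 0.0
        return ResponseMap(grid, np.zeros_like(mz), np.zeros_like(mz), mz, props)

    def test_uniform_map_has_zero_ripple(self, band):
        sel = np.abs(np.linspace(-65e3, 65e3, 131)) <= band.nu_p
        m = self._synthetic_map(band, np.ones(sel.sum()))
        metrics = sb.compute_metrics(m, band, 180)
        assert metrics.passband_ripple == 0.0
        assert metrics.stopband_leakage == 0.0
        assert metrics.max_phase_deviation == 0.0

    def test_five_percent_span_gives_five_percent_ripple(self, band):
        sel = np.abs(np.linspace(-65e3, 65e3, 131)) <= band.nu_p
        inten = np.linspace(0.95, 1.0, sel.sum())
        m = self._synthetic_map(band, inten)
        metrics = sb.compute_metrics(m, band, 180)
        assert metrics.passband_ripple == pytest.approx(5.0, abs=1e-9)

    def test_band_outside_grid_rejected(self, band, limits):
        p = sb.random_start(10, DT, limits, seed=0)
        m = sb.response_map(p, ProfileGrid(np.linspace(-5e3, 5e3, 11), np.array([1.0])))
        with pytest.raises(ValueError):
            sb.compute_metrics(m, band, 90)

    def test_invalid_target_rejected(self, band, limits):
        p = sb.random_start(10, DT, limits, seed=0)
        m = sb.response_map(p, small_grid())
        with pytest.raises(ValueError):
            sb.compute_metrics(m, band, 45)


def test_rotation_consistency_small_for_any_pulse(limits):
    """Maps from x, y, z starts assemble into one orthogonal rotation per
    grid point (the universal-rotation consistency check)."""
    p = sb.random_start(25, DT, limits, seed=10)
    grid = ProfileGrid(np.linspace(-30e3, 30e3, 9), np.array([0.9, 1.05]))
    assert sb.rotation_consistency(p, grid) < 1e-9
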