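"""Glutamate field: kernel physics, uptake, and superposition."""

import numpy as np
import pytest

from spinesim.cleft import (DiffusionParams, GlutamateField, ReleaseEvent,
                            TransporterParams, field_mass,
                            glutamate_timecourse, summation_profile,
                            uptake_flux)
from spinesim.core import AVOGADRO


@pytest.fixture(scope="module")
def diffusion():
    return DiffusionParams()


@pytest.fixture(scope="module")
def single_field(diffusion):
    return GlutamateField([ReleaseEvent(0.0)], diffusion, None)


@pytest.fixture(scope="module")
def single_field_uptake(diffusion):
    return GlutamateField([ReleaseEvent(0.0)], diffusion, TransporterParams())


t_grid = np.arange(0.0, 3.0, 1e-3)


class TestKernel:
    def test_causality_before_first_event(self, diffusion):
        f = GlutamateField([ReleaseEvent(1.0)], diffusion, None)
        assert np.all(f.concentration(500.0, np.linspace(0, 0.99, 10))
                      == diffusion.ambient)

    def test_zero_radius_rejected(self, single_field):
        with pytest.raises(ValueError, match="radius"):
            single_field.concentration(0.0, 0.01)

    def test_mass_conserved_without_uptake(self, single_field):
        """Spatial integral of the above-ambient field equals the released
        amount within 1% at all probed times (quadrature oracle)."""
        expected = 3000.0 / AVOGADRO
        for t in (1e-3, 0.05, 0.5, 2.0):
            assert field_mass(single_field, t) == pytest.approx(expected, rel=0.01)

    def test_linearity_in_simultaneous_events(self, diffusion):
        f1 = GlutamateField([ReleaseEvent(0.0)], diffusion, None)
        f3 = GlutamateField([ReleaseEvent(0.0)] * 3, diffusion, None)
        t = np.linspace(0.0, 1.0, 50)
        np.testing.assert_allclose(f3.concentration(700.0, t),
                                   3 * f1.concentration(700.0, t), rtol=1e-12)

    def test_ambient_added_and_approached(self):
        p = DiffusionParams(ambient=1.5)
        f = GlutamateField([ReleaseEvent(0.0)], p, None)
        assert float(f.concentration(2500.0, 1e-6)[0]) == pytest.approx(1.5, rel=1e-3)
        assert np.all(f.concentration(900.0, t_grid) >= 1.5)


class TestTransporters:
    def test_zero_density_identical_to_off(self, diffusion, single_field):
        f0 = GlutamateField([ReleaseEvent(0.0)], diffusion,
                            TransporterParams(density=0.0))
        t = np.linspace(0, 2, 40)
        np.testing.assert_array_equal(f0.concentration(1000.0, t),
                                      single_field.concentration(1000.0, t))

    def test_pde_with_zero_binding_matches_closed_form(self, diffusion,
                                                       single_field):
        """The finite-volume kernel reduces to the analytic solution when the
        uptake rate is zero (discretization check)."""
        f0 = GlutamateField([ReleaseEvent(0.0)], diffusion,
                            TransporterParams(k_bind=0.0))
        t = np.linspace(5e-3, 2, 30)
        a = f0.concentration(1000.0, t)
        b = single_field.concentration(1000.0, t)
        assert np.max(np.abs(a - b)) / b.max() < 0.02

    def test_uptake_never_increases_glutamate(self, diffusion, single_field,
                                              single_field_uptake):
        # exact comparison against the zero-binding solution of the same
        # discretization; the analytic comparison carries the ~0.2%
        # finite-volume projection error
        f_free = GlutamateField([ReleaseEvent(0.0)], diffusion,
                                TransporterParams(k_bind=0.0))
        for r in (20.0, 100.0, 400.0, 1000.0, 2000.0):
            on = single_field_uptake.concentration(r, t_grid)
            free = f_free.concentration(r, t_grid)
            off = single_field.concentration(r, t_grid)
            assert np.all(on <= free * (1 + 1e-9) + 1e-12)
            # vs analytic: relative plus small absolute slack for the
            # leading-edge projection error
            assert np.all(on <= off * 1.005 + 5e-2)

    def test_flux_zero_inside_exclusion_zone(self):
        tp = TransporterParams()
        assert uptake_flux(100.0, 150.0, tp) == 0.0
        assert uptake_flux(100.0, 250.0, tp) > 0.0

    def test_flux_zero_at_zero_glutamate(self):
        assert uptake_flux(0.0, 500.0, TransporterParams()) == 0.0

    def test_flux_monotone_and_at_most_linear_in_density(self, diffusion):
        """Peak suppression at 1000 nm grows monotonically with transporter
        density (scan oracle), and the binding flux doubles exactly when
        density doubles."""
        tp = TransporterParams()
        assert uptake_flux(10.0, 500.0,
                           TransporterParams(density=1000.0)) == pytest.approx(
            2 * uptake_flux(10.0, 500.0, tp))
        peaks = []
        for dens in (0.0, 250.0, 500.0, 1000.0):
            f = GlutamateField([ReleaseEvent(0.0)], diffusion,
                               TransporterParams(density=dens))
            peaks.append(f.concentration(1000.0, t_grid).max())
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))


class TestSummation:
    def test_single_pulse_consistency(self, diffusion):
        t1, y1 = summation_profile(100.0, 1, 1000.0, diffusion, None,
                                   t_end=1.0, dt=1e-3)
        t2, y2 = glutamate_timecourse([ReleaseEvent(0.0)], 1000.0, diffusion,
                                      None, t_end=1.0, dt=1e-3)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)

    def test_transporters_limit_summation_at_1000nm(self, diffusion):
        _, on = summation_profile(100.0, 4, 1000.0, diffusion,
                                  TransporterParams())
        _, off = summation_profile(100.0, 4, 1000.0, diffusion, None)
        assert on.max() < off.max()

    def test_cleft_trace_insensitive_far_trace_sensitive(self, single_field,
                                                         single_field_uptake):
        """Uptake barely touches the synaptic cleft (100 nm) but strongly
        shapes the extrasynaptic profile (1000 nm): the relative peak
        discrepancy must be at least 5x larger at 1000 nm."""
        def rel_peak_gap(r):
            on = single_field_uptake.concentration(r, t_grid).max()
            off = single_field.concentration(r, t_grid).max()
            return (off - on) / off
        assert rel_peak_gap(1000.0) > 5 * rel_peak_gap(100.0)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            summation_profile(0.0, 4, 1000.0)


def test_release_event_validation():
    with pytest.raises(ValueError, match="molecule"):
        ReleaseEvent(0.0, molecules=0.0)
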