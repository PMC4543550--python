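"""Reaction-diffusion Wnt field: 1D calibration oracle, deposition, sampling,
explicit stepping and the quasi-steady solver."""

import numpy as np
import pytest

import cryptsim as cs
from cryptsim.chemfield import (Calibration1D, ChemicalGrid, steady_state_1d,
                                calibrate_base_production, solve_steady_1d,
                                march_explicit_1d, threshold_crossing,
                                deposit_sources, element_density,
                                effective_diffusivity, step_field,
                                sample_field)

D, DELTA, TH, XSTAR = 10.0, 1.0e-3, 0.85, 12.5


class TestClosedForm1D:
    def test_boundary_value(self):
        cal = Calibration1D(D=D, delta=DELTA, P=0.2)
        assert steady_state_1d(0.0, cal) == pytest.approx(
            0.2 / np.sqrt(DELTA * D))

    def test_decay_length(self):
        cal = Calibration1D(D=D, delta=DELTA, P=0.2)
        lam = np.sqrt(D / DELTA)
        assert lam == pytest.approx(100.0)
        assert steady_state_1d(lam, cal) == pytest.approx(
            steady_state_1d(0.0, cal) / np.e)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            steady_state_1d(1.0, Calibration1D(D=-1.0))


class TestCalibration:
    def test_calibrated_rate_hits_threshold_at_target_distance(self):
        P = calibrate_base_production(D, DELTA, TH, XSTAR)
        cal = Calibration1D(D=D, delta=DELTA, P=P)
        assert steady_state_1d(XSTAR, cal) == pytest.approx(TH, rel=1e-12)
        # closed-form value: th*sqrt(delta*D)*exp(x*sqrt(delta/D))
        assert P == pytest.approx(0.0963, abs=2e-4)

    def test_linear_in_threshold(self):
        P1 = calibrate_base_production(D, DELTA, TH, XSTAR)
        P2 = calibrate_base_production(D, DELTA, 2 * TH, XSTAR)
        assert P2 == pytest.approx(2 * P1)

    def test_numeric_steady_state_confirms_calibration(self):
        P = calibrate_base_production(D, DELTA, TH, XSTAR)
        x, W = solve_steady_1d(P, D, DELTA, L=300.0, h=0.5)
        at_xstar = np.interp(XSTAR, x, W)
        assert at_xstar == pytest.approx(TH, rel=5e-3)
        assert threshold_crossing(x, W, TH) == pytest.approx(XSTAR, abs=0.1)

    def test_monotone_in_diffusivity_and_decay(self):
        """Faster diffusion or decay lowers the concentration near the source."""
        P = calibrate_base_production(D, DELTA, TH, XSTAR)
        base = steady_state_1d(XSTAR, Calibration1D(D=D, delta=DELTA, P=P))
        up_D = steady_state_1d(XSTAR, Calibration1D(D=2 * D, delta=DELTA, P=P))
        up_d = steady_state_1d(XSTAR, Calibration1D(D=D, delta=2 * DELTA, P=P))
        assert up_D < base and up_d < base
        # and reducing either raises it (the expansion-promoting direction)
        dn_D = steady_state_1d(XSTAR, Calibration1D(D=0.3 * D, delta=DELTA, P=P))
        dn_d = steady_state_1d(XSTAR, Calibration1D(D=D, delta=0.3 * DELTA, P=P))
        assert dn_D > base and dn_d > base


class TestExplicit1DOracle:
    def test_explicit_marching_matches_closed_form_within_2pct(self):
        P = calibrate_base_production(D, DELTA, TH, XSTAR)
        x, W = march_explicit_1d(P, D, DELTA, L=300.0, h=1.0, t_end=10000.0)
        exact = steady_state_1d(x, Calibration1D(D=D, delta=DELTA, P=P))
        rel = np.abs(W - exact) / exact
        assert np.max(rel) < 0.02


def toy_grid(n=11, spacing=1.0, D_val=1.0):
    g = ChemicalGrid(origin=(0.0, 0.0, 0.0), spacing=spacing, shape=(n, n, n))
    g.mask[:] = True
    g.D_node[:] = D_val
    return g


class TestDeposition:
    def test_element_on_node_gets_full_weight(self):
        g = toy_grid()
        f = deposit_sources(np.array([[3.0, 4.0, 5.0]]), 0.7, g)
        assert f[3, 4, 5] == pytest.approx(0.7)
        assert f.sum() == pytest.approx(0.7)

    def test_voxel_centre_spreads_eighth_weight(self):
        g = toy_grid()
        f = deposit_sources(np.array([[3.5, 4.5, 5.5]]), 0.8, g)
        block = f[3:5, 4:6, 5:7]
        assert np.allclose(block, 0.1)
        assert f.sum() == pytest.approx(0.8)

    def test_total_deposit_conserved(self):
        rng = np.random.default_rng(0)
        g = toy_grid()
        pts = rng.uniform(1, 9, (3, 3))
        f = deposit_sources(pts, 0.01, g)
        assert f.sum() == pytest.approx(0.03, rel=1e-12)

    def test_outside_box_rejected(self):
        g = toy_grid()
        with pytest.raises(ValueError):
            deposit_sources(np.array([[20.0, 0, 0]]), 1.0, g)


class TestEffectiveDiffusivity:
    def test_free_medium_keeps_full_diffusivity(self):
        assert effective_diffusivity(np.array(0.0), 10.0, 1.0) == 10.0

    def test_saturated_and_halfway(self):
        assert effective_diffusivity(np.array(2.0), 10.0, 1.0) == 0.0
        assert effective_diffusivity(np.array(0.5), 10.0, 1.0) == 5.0

    def test_floor_and_mask(self):
        D = effective_diffusivity(np.full((2, 2, 2), 5.0), 10.0, 1.0,
                                  floor_frac=0.05,
                                  mask=np.ones((2, 2, 2), bool))
        assert np.allclose(D, 0.5)


class TestExplicitStep:
    def test_uniform_field_decays(self):
        g = toy_grid()
        g.c[:] = 2.0
        step_field(g, np.zeros(g.shape), dt=0.05, substeps=1, d_c=0.01)
        assert np.allclose(g.c, 2.0 * (1 - 0.01 * 0.05))

    def test_single_source_node_first_step(self):
        g = toy_grid()
        src = np.zeros(g.shape)
        src[5, 5, 5] = 3.0
        step_field(g, src, dt=0.05, substeps=1, d_c=0.0)
        assert g.c[5, 5, 5] == pytest.approx(3.0 * 0.05)

    def test_exterior_stays_zero(self):
        g = toy_grid()
        g.mask[0, :, :] = False
        g.D_node[0, :, :] = 0.0
        g.c[:] = 1.0
        g.c[0, :, :] = 0.0
        step_field(g, np.zeros(g.shape), dt=0.05, substeps=3, d_c=0.0)
        assert np.all(g.c[0] == 0.0)

    def test_mass_conserved_without_decay(self):
        rng = np.random.default_rng(1)
        g = toy_grid()
        g.c[:] = rng.uniform(0, 1, g.shape)
        m0 = g.c.sum()
        for _ in range(50):
            step_field(g, np.zeros(g.shape), dt=0.1, substeps=1, d_c=0.0)
            assert g.c.sum() == pytest.approx(m0, abs=1e-10 * m0)

    def test_stability_guard(self):
        g = toy_grid(D_val=10.0)
        with pytest.raises(ValueError, match="unstable"):
            step_field(g, np.zeros(g.shape), dt=0.1, substeps=1, d_c=0.0)


class TestSampling:
    def test_node_value_recovered(self):
        g = toy_grid()
        g.c[2, 3, 4] = 7.0
        assert sample_field(g, np.array([2.0, 3.0, 4.0])) == pytest.approx(7.0)

    def test_affine_fields_sampled_exactly(self):
        g = toy_grid()
        ii, jj, kk = np.meshgrid(*[np.arange(11)] * 3, indexing="ij")
        g.c = 0.3 + 1.2 * ii - 0.7 * jj + 0.25 * kk
        rng = np.random.default_rng(2)
        pts = rng.uniform(0.5, 9.5, (50, 3))
        got = sample_field(g, pts)
        want = 0.3 + 1.2 * pts[:, 0] - 0.7 * pts[:, 1] + 0.25 * pts[:, 2]
        assert np.allclose(got, want, atol=1e-12)

    def test_uniform_voxel_centre(self):
        g = toy_grid()
        g.c[:] = 4.2
        assert sample_field(g, np.array([5.5, 5.5, 5.5])) == pytest.approx(4.2)

    def test_outside_box_rejected(self):
        g = toy_grid()
        with pytest.raises(ValueError):
            sample_field(g, np.array([-1.0, 0, 0]))


class TestQuasiSteady:
    def test_agrees_with_explicit_long_time_on_toy_crypt(self):
        """Quasi-steady solve matches the explicit solver's long-time field.

        One Paneth-like source mid-crypt in a reduced test tube; the two
        discretisations agree within 3% where the field is appreciable.
        """
        cfg = cs.load_config({"crypt_height": 50.0, "crypt_diameter": 30.0,
                              "grid_spacing": 2.5, "dt_mech": 3.6,
                              "dt_chem": 0.0036})
        surf = cs.CryptSurface(15.0, 50.0)
        rng = np.random.default_rng(3)
        els = np.array([12.0, 0.0, 15.0]) + rng.normal(0, 1.5, (20, 3))
        g1 = ChemicalGrid.from_crypt(surf, cfg)
        g2 = ChemicalGrid.from_crypt(surf, cfg)
        src = deposit_sources(els, 0.01, g1)
        # explicit marching to steady state (several decay times)
        dt = 0.8 * g1.spacing**2 / (6 * 10.0)
        steps = int(6000.0 / dt)
        step_field(g1, src, dt=dt, substeps=steps, d_c=1e-3)
        g2.solve_quasi_steady(deposit_sources(els, 0.01, g2), 1e-3)
        big = g1.c > 0.05 * g1.c.max()
        rel = np.abs(g1.c[big] - g2.c[big]) / g1.c[big]
        assert np.max(rel) < 0.03
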