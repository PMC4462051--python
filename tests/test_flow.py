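"""Flow solver: closed-form oracles, conservation, moving boundaries."""

import numpy as np
import pytest

from capsim.flow import (FluidProperties, calibrated_pressure_drop,
                         effective_viscosity, interpolate_velocity,
                         poiseuille_profile, rbc_force_free_velocity,
                         reynolds_number, solve_flow)
from capsim.geometry import RBCAgent, VesselGeometry, place_rbcs
from capsim.mesh import build_mesh


class TestEffectiveViscosity:
    def test_acellular_limit_is_plasma(self):
        assert effective_viscosity(0.0, 1.2e-3) == 1.2e-3

    def test_default_polynomial_at_whole_blood(self):
        # 1.2e-3 * (1 + 2.5*0.45 + 7.35*0.45^2) = 4.336e-3
        assert effective_viscosity(0.45, 1.2e-3) == pytest.approx(
            1.2e-3 * (1.0 + 1.125 + 7.35 * 0.2025), rel=1e-12)

    @pytest.mark.parametrize("model", ["polynomial", "exponential"])
    def test_strictly_increasing_and_superlinear(self, model):
        hs = np.linspace(0.0, 0.45, 10)
        mus = [effective_viscosity(h, 1e-3, model) for h in hs]
        assert np.all(np.diff(mus) > 0)
        # superlinear: secant slope grows
        slopes = np.diff(mus) / np.diff(hs)
        assert np.all(np.diff(slopes) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            effective_viscosity(1.2, 1e-3)


class TestReynolds:
    def test_formula(self):
        assert reynolds_number(1000.0, 1e-3, 8e-6, 1e-3) == pytest.approx(8e-3)

    def test_zero_velocity(self):
        assert reynolds_number(1000.0, 0.0, 8e-6, 1e-3) == 0.0

    def test_zero_viscosity_rejected(self):
        with pytest.raises(ValueError):
            reynolds_number(1000.0, 1e-3, 8e-6, 0.0)

    def test_capillary_regime_is_laminar(self, geom, fluid):
        """Default conditions sit far below the ~2400 transition."""
        dp = fluid.resolve_pressure_drop(geom)
        vmax = poiseuille_profile(geom, dp, fluid.plasma_viscosity, 0.0)
        re = reynolds_number(fluid.density, 0.5 * vmax * 1e-6,
                             2 * geom.radius * 1e-9, fluid.plasma_viscosity)
        assert re < 0.1 < 2400


class TestPoiseuille:
    def test_no_slip_at_wall(self, geom):
        assert poiseuille_profile(geom, 82.5, 1.2e-3, geom.radius) == 0.0

    def test_centreline_twice_mean(self, geom):
        r = np.linspace(0.0, geom.radius, 2000)
        v = poiseuille_profile(geom, 82.5, 1.2e-3, r)
        vmean = np.trapezoid(v * 2 * np.pi * r, r) / (np.pi * geom.radius**2)
        assert v[0] == pytest.approx(2.0 * vmean, rel=1e-3)

    def test_calibrated_pressure_drop(self, geom):
        # dp = 4 mu L vmax / R^2 = 82.5 Pa for 5500 um/s in a 4 um vessel
        dp = calibrated_pressure_drop(geom, 1.2e-3, 5500.0)
        assert dp == pytest.approx(82.5, rel=1e-9)
        assert poiseuille_profile(geom, dp, 1.2e-3, 0.0) == pytest.approx(5500.0)

    def test_outside_radius_rejected(self, geom):
        with pytest.raises(ValueError):
            poiseuille_profile(geom, 82.5, 1.2e-3, geom.radius + 1.0)


class TestSolveFlowAcellular:
    def test_matches_poiseuille_within_one_percent(self, geom, fluid,
                                                   acellular_field):
        dp = fluid.resolve_pressure_drop(geom)
        exact = poiseuille_profile(geom, dp, fluid.plasma_viscosity,
                                   acellular_field.mesh.nodes[:, 0])
        err = np.max(np.abs(acellular_field.v_z - exact)) / np.max(exact)
        assert err < 0.01
        assert np.max(np.abs(acellular_field.v_r)) < 1e-3 * np.max(exact)

    def test_refinement_halves_error(self, geom, fluid):
        dp = fluid.resolve_pressure_drop(geom)
        errs = []
        for n_r, n_z in [(8, 40), (16, 80)]:
            mesh = build_mesh(geom, [], n_r=n_r, n_z=n_z)
            field = solve_flow(mesh, fluid)
            exact = poiseuille_profile(geom, dp, fluid.plasma_viscosity,
                                       mesh.nodes[:, 0])
            errs.append(np.max(np.abs(field.v_z - exact)) / np.max(exact))
        assert errs[0] / errs[1] >= 2.0

    def test_velocity_decreases_towards_wall(self, acellular_field):
        mesh = self_mesh = acellular_field.mesh
        col = np.argsort(mesh.nodes[: mesh.n_r + 1, 0])
        v = acellular_field.v_z[col]
        assert np.all(np.diff(v) < 0)  # monotone decay axis -> wall

    def test_mass_conservation_between_sections(self, acellular_field):
        fluxes = [acellular_field.axial_flux(z)
                  for z in (5000.0, 25000.0, 45000.0)]
        assert np.ptp(fluxes) / np.mean(fluxes) < 0.01


@pytest.fixture(scope="module")
def cell_field(geom, fluid):
    """Force-free solve at capillary haematocrit (3 cells)."""
    rbcs = place_rbcs(3, geom)
    mesh = build_mesh(geom, rbcs, n_r=16, n_z=120)
    speed, field = rbc_force_free_velocity(
        mesh, fluid,
        viscosity=effective_viscosity(0.107, fluid.plasma_viscosity))
    return speed, field


class TestSolveFlowWithCells:
    def test_force_free_speed_below_centreline(self, geom, fluid, cell_field):
        speed, field = cell_field
        vmax = poiseuille_profile(geom, fluid.resolve_pressure_drop(geom),
                                  field.viscosity, 0.0)
        assert 0.0 < speed < vmax

    def test_rbc_boundary_carries_cell_velocity(self, cell_field):
        speed, field = cell_field
        nodes = field.mesh.rbc_nodes
        assert np.allclose(field.v_z[nodes], speed, rtol=1e-9)
        assert np.allclose(field.v_r[nodes], 0.0, atol=1e-9)

    def test_mass_conservation_with_cells(self, geom, fluid):
        """Total axial flux (fluid + moving cells) equal across sections."""
        rbcs = place_rbcs(3, geom)
        mesh = build_mesh(geom, rbcs, n_r=24, n_z=250)  # default resolution
        _, field = rbc_force_free_velocity(
            mesh, fluid,
            viscosity=effective_viscosity(0.107, fluid.plasma_viscosity))
        zs = np.linspace(1000.0, 49000.0, 7)
        fluxes = [field.axial_flux(z, n_samples=1000) for z in zs]
        assert np.ptp(fluxes) / np.mean(fluxes) < 0.03

    def test_small_obstacle_limit_reaches_centreline(self, geom, fluid):
        """A vanishing cell rides the flow at the centreline speed."""
        tiny = RBCAgent(z_center=geom.length / 2.0, effective_radius=320.0,
                        cell_volume=0.12, cap_depth=150.0)
        mesh = build_mesh(geom, [tiny], n_r=20, n_z=160)
        speed, _ = rbc_force_free_velocity(mesh, fluid)
        vmax = poiseuille_profile(geom, fluid.resolve_pressure_drop(geom),
                                  fluid.plasma_viscosity, 0.0)
        assert speed == pytest.approx(vmax, rel=0.05)
        assert speed < vmax

    def test_annular_drag_flow_matches_couette(self, fluid):
        """A lumen-spanning plug driven with no pressure drop produces the
        annular drag (log-profile) flow in the gap."""
        geom = VesselGeometry(radius=4000.0, length=50000.0)
        plug = RBCAgent(z_center=25000.0, effective_radius=3400.0,
                        cell_volume=1000.0, cap_depth=100.0,
                        axial_semi_axis=500000.0)  # spans the periodic length
        mesh = build_mesh(geom, [plug], n_r=24, n_z=100)
        v_cell = 1000.0
        field = solve_flow(mesh, fluid, rbc_velocity=v_cell, pressure_drop=0.0)
        b, R = plug.effective_radius, geom.radius
        r = np.linspace(b + 20.0, R - 20.0, 30)
        _, vz = field.velocity_rz(r, np.full_like(r, 25000.0))
        exact = v_cell * np.log(R / r) / np.log(R / b)
        assert np.max(np.abs(vz - exact)) / v_cell < 0.05

    def test_cellular_phase_moves_with_cells(self, geom, fluid):
        """Galilean consistency: with no pressure drop, fluid between
        closely spaced driven cells moves at the cell speed."""
        from capsim.mesh import combined_silhouette
        rbcs = place_rbcs(12, geom)  # whole-blood packing
        mesh = build_mesh(geom, rbcs, n_r=16, n_z=160)
        v_cell = 1000.0
        field = solve_flow(mesh, fluid, rbc_velocity=v_cell,
                           pressure_drop=0.0)
        z_mid = (rbcs[0].z_center + rbcs[1].z_center) / 2.0
        s_mid = float(combined_silhouette(rbcs, np.array([z_mid]),
                                          geom.length)[0])
        # just above the merged cellular core the fluid co-moves ...
        _, vz = field.velocity_rz(np.array([s_mid + 20.0]),
                                  np.array([z_mid]))
        assert vz[0] == pytest.approx(v_cell, rel=0.05)
        # ... and decays monotonically through the cell-free layer
        r = np.linspace(s_mid + 20.0, geom.radius, 20)
        _, prof = field.velocity_rz(r, np.full_like(r, z_mid))
        assert np.all(np.diff(prof) < 1e-9)


class TestInterpolation:
    def test_wall_point_is_no_slip(self, acellular_field, geom):
        v = interpolate_velocity(acellular_field,
                                 [geom.radius, 0.0, 10000.0])
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_axis_point_has_no_transverse_velocity(self, acellular_field):
        v = interpolate_velocity(acellular_field, [0.0, 0.0, 12345.0])
        assert v[0] == 0.0 and v[1] == 0.0
        assert v[2] > 0

    def test_half_radius_three_quarters_of_max(self, acellular_field, geom):
        v = interpolate_velocity(acellular_field,
                                 [geom.radius / 2.0, 0.0, 30000.0])
        vmax = float(acellular_field.v_z.max())
        assert v[2] == pytest.approx(0.75 * vmax, rel=0.01)

    def test_azimuthal_mapping(self, acellular_field, geom):
        """v_x, v_y follow cos/sin of the azimuth of the query point."""
        r = 2000.0
        for theta in (0.3, 2.0, 4.5):
            p = [r * np.cos(theta), r * np.sin(theta), 20000.0]
            v = interpolate_velocity(acellular_field, p)
            vr = np.hypot(v[0], v[1])
            if vr > 1e-12:
                assert np.arctan2(v[1], v[0]) == pytest.approx(
                    np.arctan2(p[1], p[0]), abs=1e-6)

    def test_outside_wall_rejected(self, acellular_field, geom):
        with pytest.raises(ValueError, match="wall"):
            interpolate_velocity(acellular_field,
                                 [geom.radius + 10.0, 0.0, 10000.0])
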