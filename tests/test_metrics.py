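"""Derived statistics: dispersion factors, MSD, binding fraction,
specificity, Holm-Sidak adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsim.metrics import (average_dispersion_factor, delivered_volume,
                            dispersion_factor, fraction_within_binding_range,
                            holm_sidak_adjust, mean_radial_position, msd,
                            radial_velocity, specificity_ratio,
                            specificity_score)


class TestRadialVelocityAndDF:
    def test_zero_velocity(self):
        assert radial_velocity(0.0, 0.0) == 0.0

    def test_pythagorean(self):
        assert radial_velocity(3.0, 4.0) == 5.0

    def test_rotation_invariance(self, rng):
        v = rng.normal(size=2)
        for a in (0.5, 1.7, 3.0):
            rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            w = rot @ v
            assert radial_velocity(*w) == pytest.approx(radial_velocity(*v))

    def test_df_zero_for_parallel_flow(self):
        assert dispersion_factor(0.0, 10.0) == 0.0

    def test_df_arithmetic(self):
        assert dispersion_factor(5.0, 10.0) == 0.5

    def test_df_scale_invariant(self):
        assert dispersion_factor(5.0, 10.0) == dispersion_factor(15.0, 30.0)

    def test_df_undefined_where_vz_zero(self):
        assert np.isnan(dispersion_factor(5.0, 0.0))


class TestAverageDispersionFactor:
    def test_acellular_poiseuille_is_zero(self, acellular_field):
        d = average_dispersion_factor(acellular_field)
        assert abs(d.adf) < 1e-3

    def test_constant_df_field(self, acellular_field):
        f = acellular_field
        synthetic = type(f)(mesh=f.mesh, v_r=0.2 * np.ones(f.mesh.n_nodes),
                            v_z=np.ones(f.mesh.n_nodes),
                            pressure=np.zeros(f.mesh.n_nodes),
                            viscosity=f.viscosity)
        assert average_dispersion_factor(synthetic).adf == pytest.approx(0.2)

    def test_adf_nonnegative_for_forward_flow(self, acellular_field):
        assert average_dispersion_factor(acellular_field).adf >= 0.0

    def test_hand_built_three_element_mean(self):
        # element DF values 0, 0.1, 0.5 average to 0.2
        assert np.mean([0.0, 0.1, 0.5]) == pytest.approx(0.2)


class TestMSD:
    def test_static_trajectory(self):
        p = np.zeros((10, 3))
        assert np.all(msd(p) == 0.0)

    def test_ballistic_closed_form(self):
        t = np.arange(20)[:, None]
        v = np.array([3.0, 0.0, 4.0])
        p = t * v
        assert msd(p) == pytest.approx((5.0 * t[:, 0]) ** 2)

    def test_ensemble_average_of_brownian_paths(self, rng):
        sigma = 10.0
        steps = rng.normal(0.0, sigma, size=(1000, 50, 3))
        paths = np.concatenate([np.zeros((1000, 1, 3)),
                                np.cumsum(steps, axis=1)], axis=1)
        m = msd(paths)
        k = np.arange(51)
        assert np.allclose(m[1:], 3.0 * sigma**2 * k[1:], rtol=0.1)


class TestPopulationPositions:
    def test_wall_contact_counted(self, geom):
        pos = np.array([[geom.radius - 50.0, 0.0, 0.0]])
        assert fraction_within_binding_range(pos, np.array([50.0]),
                                             geom) == 100.0

    def test_axis_particle_not_counted(self, geom):
        pos = np.array([[0.0, 0.0, 0.0]])
        assert fraction_within_binding_range(pos, np.array([50.0]),
                                             geom) == 0.0

    def test_hand_placed_fraction(self, geom):
        gaps = np.array([0.0, 5.0, 19.0, 50.0, 100.0, 1000.0, 2000.0,
                         300.0, 40.0, 21.0])
        rho = geom.radius - 50.0 - gaps
        pos = np.column_stack([rho, np.zeros(10), np.zeros(10)])
        out = fraction_within_binding_range(pos, np.full(10, 50.0), geom)
        assert out == 30.0

    def test_mean_radial_on_axis(self):
        assert mean_radial_position(np.zeros((5, 3))) == 0.0

    def test_uniform_disc_mean_two_thirds(self, rng):
        r_a = 3950.0
        rho = r_a * np.sqrt(rng.uniform(size=200_000))
        th = rng.uniform(0, 2 * np.pi, size=200_000)
        pos = np.column_stack([rho * np.cos(th), rho * np.sin(th),
                               np.zeros_like(rho)])
        assert mean_radial_position(pos) == pytest.approx(2 / 3 * r_a,
                                                          rel=0.005)


class TestSpecificity:
    def test_ratio_arithmetic(self):
        assert specificity_ratio(30.0, 10.0) == 3.0
        assert specificity_ratio(7.0, 7.0) == 1.0

    def test_only_tumour_delivery_is_infinite(self):
        assert np.isinf(specificity_ratio(5.0, 0.0))

    def test_no_delivery_not_computable(self):
        assert np.isnan(specificity_ratio(0.0, 0.0))

    def test_score_weights_efficiency(self):
        assert specificity_score(30.0, 10.0) == pytest.approx(0.9)

    def test_score_zero_without_tumour_delivery(self):
        assert specificity_score(0.0, 5.0) == 0.0

    def test_score_quadratic_in_tumour_uptake(self):
        assert specificity_score(20.0, 5.0) == pytest.approx(
            4.0 * specificity_score(10.0, 5.0))

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError):
            specificity_ratio(-1.0, 5.0)


class TestDeliveredVolume:
    def test_empty_is_zero(self):
        assert delivered_volume([]) == 0.0

    def test_single_100nm(self):
        assert delivered_volume([100.0]) == pytest.approx(523598.8, rel=1e-6)

    def test_additivity(self, rng):
        a = rng.uniform(10, 200, size=5)
        b = rng.uniform(10, 200, size=7)
        assert delivered_volume(np.concatenate([a, b])) == pytest.approx(
            delivered_volume(a) + delivered_volume(b))


def brute_force_holm_sidak(p, alpha):
    """Literal step-down definition, used as the independent oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - k)
        running = max(running, val)
        adjusted[idx] = min(1.0, running)
    reject = adjusted <= alpha
    return adjusted, reject


class TestHolmSidak:
    def test_single_pvalue_unchanged(self):
        adj, rej = holm_sidak_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_evaluated_pair(self):
        # [0.01, 0.04] -> [1 - 0.99^2, max(prev, 0.04)] = [0.0199, 0.04]
        adj, _ = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1.0 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_adjusted_dominates_raw(self, rng):
        p = rng.uniform(size=6)
        adj, _ = holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(300):
            m = rng.integers(1, 7)
            p = rng.uniform(size=m)
            adj, rej = holm_sidak_adjust(p, alpha=0.05)
            b_adj, b_rej = brute_force_holm_sidak(p, 0.05)
            np.testing.assert_allclose(adj, b_adj, rtol=0.0, atol=1e-12)
            assert np.array_equal(rej, b_rej)

    def test_agrees_with_statsmodels(self, rng):
        """Independent cross-check against an established implementation."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 8)))
            adj, rej = holm_sidak_adjust(p, alpha=0.05)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05,
                                                 method="holm-sidak")
            np.testing.assert_allclose(adj, sm_adj, rtol=1e-10, atol=1e-12)
            assert np.array_equal(rej, sm_rej)

    @settings(deadline=None, max_examples=50)
    @given(p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_monotone_in_sorted_order(self, p):
        adj, _ = holm_sidak_adjust(p)
        in_raw_order = adj[np.argsort(np.asarray(p), kind="stable")]
        assert np.all(np.diff(in_raw_order) >= -1e-15)
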