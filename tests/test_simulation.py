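"""Main loop, configuration, reproducibility, experiment drivers, IO."""

import json

import numpy as np
import pytest

from capsim.experiments import (msd_decomposition,
                                run_experiment_force_balance,
                                run_experiment_haematocrit_sweep)
from capsim.io import (dump_config_toml, load_config, metrics_json,
                       save_config, write_run_outputs, write_vtk)
from capsim.simulation import Simulation, SimulationConfig


def small_config(**overrides) -> SimulationConfig:
    base = {
        "haematocrit": 0.0,
        "particles": {"count": 20,
                      "population": {"kind": "mono", "diameter_nm": 100.0}},
        "time": {"dt_s": 1e-4, "total_s": 1e-3},
        "mesh": {"n_r": 8, "n_z": 24},
        "seed": 42,
    }
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception, match="extra"):
            SimulationConfig(haematocrit=0.1, no_such_key=1)

    def test_nested_unknown_keys_rejected(self):
        with pytest.raises(Exception):
            SimulationConfig(time={"dt_s": 1e-4, "bogus": 3})

    def test_pore_substep_must_not_exceed_step(self):
        with pytest.raises(Exception, match="sub-step"):
            SimulationConfig(time={"dt_s": 1e-5, "dt_pore_s": 1e-4})

    def test_total_time_at_least_one_step(self):
        with pytest.raises(Exception, match="one step"):
            SimulationConfig(time={"dt_s": 1e-3, "total_s": 1e-4})

    def test_haematocrit_range_enforced(self):
        with pytest.raises(Exception):
            SimulationConfig(haematocrit=0.6)

    def test_toml_round_trip(self, tmp_path):
        cfg = small_config(haematocrit=0.107)
        path = tmp_path / "run.toml"
        save_config(cfg, path)
        assert load_config(path) == cfg

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        path = tmp_path / "run.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg


class TestMainLoop:
    def test_time_bookkeeping(self):
        sim = Simulation(small_config())
        sim.run()
        assert sim.state.step_index == 10
        assert sim.state.time == pytest.approx(1e-3)

    def test_toggles_off_freeze_particles(self):
        cfg = small_config(toggles={"brownian_on": False, "laminar_on": False})
        sim = Simulation(cfg)
        start = sim.state.positions.copy()
        sim.run()
        assert np.array_equal(sim.state.positions, start)

    def test_uniform_advection_step(self, geom):
        """Laminar-only step advances particles by u(x) dt along z."""
        cfg = small_config(toggles={"brownian_on": False, "laminar_on": True},
                           time={"dt_s": 1e-4, "total_s": 1e-4})
        starts = np.array([[0.0, 0.0, 25000.0], [1000.0, 0.0, 25000.0]])
        sim = Simulation(cfg, initial_positions=starts,
                         diameters=np.array([100.0, 100.0]))
        u = sim._fluid_velocity_3d(starts)
        sim.run()
        expect = starts + u * 1e-4 * 1e3
        assert np.allclose(sim.state.positions, expect)

    def test_particle_count_conserved_with_pores(self):
        cfg = small_config(
            haematocrit=0.107,
            fenestrations={"density_per_um2": 1.0, "diameter_nm": 240.0},
            particles={"count": 50,
                       "population": {"kind": "mono", "diameter_nm": 100.0}},
            time={"dt_s": 1e-4, "total_s": 5e-3},
            mesh={"n_r": 10, "n_z": 60},
        )
        sim = Simulation(cfg)
        sim.run()
        c = sim.state.ledger.counts(sim.state.particle_list())
        assert c["translocated"] + c["in_pore"] + c["free"] == 50

    def test_empty_population_and_no_rbcs_advances_time(self):
        cfg = small_config(particles={"count": 0,
                                      "population": {"kind": "mono",
                                                     "diameter_nm": 100.0}})
        sim = Simulation(cfg)
        sim.run()
        assert sim.state.time == pytest.approx(1e-3)

    def test_free_particles_stay_inside_lumen(self):
        cfg = small_config(haematocrit=0.107, time={"dt_s": 1e-4,
                                                    "total_s": 5e-3},
                           mesh={"n_r": 10, "n_z": 60})
        sim = Simulation(cfg)
        sim.run()
        st = sim.state
        rho = np.hypot(st.positions[:, 0], st.positions[:, 1])
        assert np.all(rho + st.radii <= sim.geom.radius + 1e-6)
        for k in range(len(st.radii)):
            assert sim.obstacles.signed_clearance(
                st.positions[k], st.radii[k], st.z_shift) > -0.1


class TestDeterminism:
    def test_identical_seeds_identical_positions(self):
        cfg = small_config(haematocrit=0.107, mesh={"n_r": 10, "n_z": 60})
        a = Simulation(cfg).run()
        b = Simulation(cfg).run()
        assert np.array_equal(a.state.positions, b.state.positions)

    def test_different_seeds_differ(self):
        a = Simulation(small_config(seed=1)).run()
        b = Simulation(small_config(seed=2)).run()
        assert not np.array_equal(a.state.positions, b.state.positions)

    def test_particle_streams_independent_of_population_size(self):
        """Adding particles never changes existing trajectories."""
        cfg_small = small_config(particles={
            "count": 5, "population": {"kind": "mono", "diameter_nm": 100.0}},
            toggles={"brownian_on": True, "laminar_on": False})
        cfg_big = small_config(particles={
            "count": 9, "population": {"kind": "mono", "diameter_nm": 100.0}},
            toggles={"brownian_on": True, "laminar_on": False})
        starts5 = np.tile([0.0, 0.0, 25000.0], (5, 1))
        starts9 = np.tile([0.0, 0.0, 25000.0], (9, 1))
        a = Simulation(cfg_small, initial_positions=starts5,
                       diameters=np.full(5, 100.0)).run()
        b = Simulation(cfg_big, initial_positions=starts9,
                       diameters=np.full(9, 100.0)).run()
        assert np.array_equal(a.state.positions[:5], b.state.positions[:5])


class TestExperiments:
    def test_sweep_row_count_and_acellular_adf(self):
        cfg = small_config(mesh={"n_r": 10, "n_z": 60})
        table = run_experiment_haematocrit_sweep(
            cfg, [0.0, 0.107], replicates=2, particle_metrics=False)
        assert len(table) == 4
        acell = table[table.haematocrit == 0.0]
        assert np.all(np.abs(acell.adf) < 1e-3)

    def test_force_balance_shares(self):
        cfg = small_config(mesh={"n_r": 12, "n_z": 40},
                           time={"dt_s": 1e-4, "total_s": 0.003})
        out = run_experiment_force_balance(cfg, n_replicates=20)
        # laminar-only from the wall is slower than from the centre
        centre = out["centre"]["decomposition"]["laminar_only"].msd[-1]
        wall = out["wall"]["decomposition"]["laminar_only"].msd[-1]
        assert wall < centre
        assert out["centre"]["brownian_share"] < 0.01

    def test_msd_decomposition_laminar_only_without_noise(self):
        cfg = small_config(mesh={"n_r": 10, "n_z": 40},
                           time={"dt_s": 1e-4, "total_s": 5e-4})
        dec = msd_decomposition(cfg, [0.0, 0.0, 25000.0], n_replicates=3)
        assert dec["laminar_only"].msd[0] == 0.0
        # a centre start moves ballistically: MSD = (v t)^2
        v = dec["laminar_only"].msd[-1] ** 0.5 / dec["laminar_only"].times[-1]
        assert v == pytest.approx(5500.0 * 1e3, rel=0.02)  # nm/s


class TestOutputs:
    def test_metrics_json_byte_stable(self):
        cfg = small_config(haematocrit=0.107,
                           fenestrations={"density_per_um2": 0.5,
                                          "diameter_nm": 240.0},
                           mesh={"n_r": 10, "n_z": 60})
        a = metrics_json(Simulation(cfg).run().metrics_summary())
        b = metrics_json(Simulation(cfg).run().metrics_summary())
        assert a.encode() == b.encode()

    def test_run_directory_contents(self, tmp_path):
        res = Simulation(small_config(), record_trajectories=True).run()
        write_run_outputs(res, tmp_path)
        for name in ("config.toml", "run.log", "metrics.json", "events.csv",
                     "flow_field.vtk", "trajectories.csv"):
            assert (tmp_path / name).exists()
        json.loads((tmp_path / "metrics.json").read_text())

    def test_vtk_header_and_sizes(self, tmp_path, acellular_field):
        path = tmp_path / "field.vtk"
        write_vtk(acellular_field, path)
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        n = acellular_field.mesh.n_nodes
        assert f"POINTS {n} float" in text

    def test_dump_config_is_parseable_toml(self):
        import tomllib
        cfg = small_config()
        data = tomllib.loads(dump_config_toml(cfg))
        assert data["haematocrit"] == cfg.haematocrit
        assert data["time"]["dt_s"] == cfg.time.dt_s


class TestCli:
    def test_run_and_validate_verbs(self, tmp_path):
        from click.testing import CliRunner
        from capsim.cli import main

        cfg_path = tmp_path / "c.toml"
        save_config(small_config(), cfg_path)
        runner = CliRunner()
        out_dir = tmp_path / "out"
        res = runner.invoke(main, ["run", str(cfg_path), "--out",
                                   str(out_dir)])
        assert res.exit_code == 0, res.output
        assert (out_dir / "metrics.json").exists()
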