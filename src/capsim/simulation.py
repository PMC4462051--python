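"""Simulation configuration, state and the synchronous main loop.

Each step applies the same deterministic update order to every agent:

1. advance RBC positions (the cell train translates rigidly at its
   force-free speed, wrapping periodically);
2. refresh the flow field (the Stokes field is steady in the co-moving
   frame, so the refresh is a rigid axial translation of the solved field);
3. move every free nanoparticle: advection + Brownian displacement, wall
   reflection, RBC push-out;
4. test pore entry for wall-adjacent particles;
5. advance pore sub-walks for particles inside fenestrations;
6. accumulate metrics; advance time by dt.

Randomness is organised as one stream per particle id derived from the
master seed (plus a separate stream per particle for pore transits and one
for initial placement), so trajectories are reproducible and independent
of population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import metrics as _metrics
from .brownian import (brownian_sigma, diffusion_coefficient,
                       particle_stream_seed, polar_gaussian)
from .fenestration import (Fenestration, PoreIndex, PoreOutcome, PoreWalkState,
                           UptakeLedger, place_fenestrations, pore_walk,
                           uptake_summary)
from .flow import (FluidProperties, FlowField, effective_viscosity,
                   rbc_force_free_velocity, solve_flow)
from .geometry import (Haematocrit, RBCAgent, VesselGeometry,
                       haematocrit_to_rbc_count, place_rbcs)
from .mesh import build_mesh
from .particles import (Nanoparticle, ParticleStatus, RBCObstacleSet,
                        reflect_at_wall_many)
from .sizes import (SizeDistribution, monodisperse, parse_dls_table,
                    sample_sizes, synthetic_dls)


# ----------------------------------------------------------------------
# configuration schema (fail-fast: unknown keys rejected)
# ----------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Section):
    radius_nm: float = 4000.0
    length_nm: float = 50000.0
    periodic_axial: bool = True
    wall_thickness_nm: float = 400.0


class FluidConfig(_Section):
    density_kg_m3: float = 1025.0
    plasma_viscosity_pa_s: float = 1.2e-3
    temperature_k: float = 310.0
    #: None -> calibrated so the acellular centreline speed is 5500 um/s
    pressure_drop_pa: Optional[float] = None


class RBCConfig(_Section):
    effective_radius_nm: float = 2900.0
    cell_volume_um3: float = 94.0
    cap_depth_nm: float = 1200.0
    placement: Literal["uniform"] = "uniform"
    jitter_frac: float = 0.0


class PopulationConfig(_Section):
    kind: Literal["mono", "dls_csv", "synthetic_dls"] = "mono"
    diameter_nm: float = 100.0
    csv_path: Optional[str] = None
    mean_diameter_nm: Optional[float] = None
    pdi: Optional[float] = None
    n_classes: int = 26


class ParticlesConfig(_Section):
    count: int = 200
    population: PopulationConfig = Field(default_factory=PopulationConfig)


class FenestrationConfig(_Section):
    density_per_um2: float = 0.0
    diameter_nm: float = 60.0
    channel_length_nm: Optional[float] = None   # None -> wall thickness
    capture_distance_nm: float = 20.0


class TimeConfig(_Section):
    dt_s: float = 1e-4
    dt_pore_s: float = 1e-7
    total_s: float = 0.003
    flow_update_every: int = 10


class MeshConfig(_Section):
    n_r: int = 24
    n_z: int = 250


class TogglesConfig(_Section):
    brownian_on: bool = True
    laminar_on: bool = True


class SimulationConfig(_Section):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    haematocrit: float = 0.107
    rbc: RBCConfig = Field(default_factory=RBCConfig)
    particles: ParticlesConfig = Field(default_factory=ParticlesConfig)
    fenestrations: FenestrationConfig = Field(default_factory=FenestrationConfig)
    time: TimeConfig = Field(default_factory=TimeConfig)
    mesh: MeshConfig = Field(default_factory=MeshConfig)
    toggles: TogglesConfig = Field(default_factory=TogglesConfig)
    viscosity_model: Literal["polynomial", "exponential"] = "polynomial"
    seed: int = 0
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not 0.0 <= self.haematocrit <= 0.45:
            raise ValueError("haematocrit must lie in [0, 0.45]")
        if self.time.total_s < self.time.dt_s:
            raise ValueError("total time must be at least one step")
        if self.time.dt_pore_s > self.time.dt_s:
            raise ValueError("pore sub-step must not exceed the main step")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        return self

    def build_geometry(self) -> VesselGeometry:
        g = self.geometry
        return VesselGeometry(g.radius_nm, g.length_nm, g.periodic_axial,
                              g.wall_thickness_nm)

    def build_fluid(self) -> FluidProperties:
        f = self.fluid
        return FluidProperties(f.density_kg_m3, f.plasma_viscosity_pa_s,
                               f.temperature_k, f.pressure_drop_pa)

    def build_population(self) -> SizeDistribution:
        p = self.particles.population
        if p.kind == "mono":
            return monodisperse(p.diameter_nm)
        if p.kind == "dls_csv":
            if not p.csv_path:
                raise ValueError("dls_csv population needs csv_path")
            return parse_dls_table(p.csv_path)
        if p.mean_diameter_nm is None or p.pdi is None:
            raise ValueError("synthetic_dls population needs mean_diameter_nm and pdi")
        return synthetic_dls(p.mean_diameter_nm, p.pdi, p.n_classes)


# ----------------------------------------------------------------------
# state
# ----------------------------------------------------------------------

@dataclass
class SimulationState:
    """Mutable state of one run (arrays indexed by particle id)."""

    time: float
    step_index: int
    z_shift: float                    # RBC train displacement, nm
    positions: np.ndarray             # (n, 3) nm (z wrapped into [0, L))
    z_unwrapped: np.ndarray           # (n,) axial coordinate without wrapping
    radii: np.ndarray                 # (n,) nm
    status: np.ndarray                # (n,) int codes
    pore_of: np.ndarray               # (n,) pore id or -1
    rbcs: list[RBCAgent]
    fenestrations: list[Fenestration]
    flow: FlowField | None
    ledger: UptakeLedger
    pore_states: dict[int, PoreWalkState] = field(default_factory=dict)

    STATUS_FREE = 0
    STATUS_IN_PORE = 1
    STATUS_TRANSLOCATED = 2

    def particle_list(self) -> list[Nanoparticle]:
        codes = {0: ParticleStatus.FREE, 1: ParticleStatus.IN_PORE,
                 2: ParticleStatus.TRANSLOCATED}
        out = []
        for i in range(len(self.radii)):
            out.append(Nanoparticle(
                id=i, position=self.positions[i].copy(),
                radius=float(self.radii[i]), status=codes[int(self.status[i])],
                pore_id=int(self.pore_of[i]) if self.pore_of[i] >= 0 else None,
            ))
        return out


class Simulation:
    """One configured run of the capillary model."""

    def __init__(
        self,
        config: SimulationConfig,
        initial_positions: np.ndarray | None = None,
        diameters: np.ndarray | None = None,
        record_trajectories: bool = False,
    ) -> None:
        self.config = config
        self.geom = config.build_geometry()
        self.fluid = config.build_fluid()
        self.record_trajectories = record_trajectories

        rng_init = np.random.default_rng(
            np.random.SeedSequence((config.seed, 0xA11CE))
        )

        # --- RBCs and flow -------------------------------------------
        self.viscosity = effective_viscosity(
            config.haematocrit, self.fluid.plasma_viscosity,
            config.viscosity_model,
        )
        n_cells = haematocrit_to_rbc_count(
            Haematocrit(config.haematocrit), self.geom,
            config.rbc.cell_volume_um3,
        )
        self.rbcs = place_rbcs(
            n_cells, self.geom,
            effective_radius=config.rbc.effective_radius_nm,
            cell_volume=config.rbc.cell_volume_um3,
            cap_depth=config.rbc.cap_depth_nm,
            jitter_frac=config.rbc.jitter_frac,
            rng=rng_init if config.rbc.jitter_frac > 0 else None,
        )
        self.mesh = build_mesh(self.geom, self.rbcs,
                               config.mesh.n_r, config.mesh.n_z)
        if self.rbcs:
            self.rbc_speed, self.flow = rbc_force_free_velocity(
                self.mesh, self.fluid, viscosity=self.viscosity)
        else:
            self.rbc_speed = 0.0
            self.flow = solve_flow(self.mesh, self.fluid,
                                   viscosity=self.viscosity)
        self.obstacles = RBCObstacleSet(self.rbcs, self.geom)

        # --- fenestrations -------------------------------------------
        fc = config.fenestrations
        self.fenestrations = place_fenestrations(
            self.geom, fc.density_per_um2, fc.diameter_nm, rng_init,
            channel_length=fc.channel_length_nm,
        )
        self.pore_index = PoreIndex(self.fenestrations, self.geom)
        self.capture_distance = fc.capture_distance_nm

        # --- particles -----------------------------------------------
        n = config.particles.count
        if diameters is None:
            if n == 0:
                diameters = np.empty(0)
            else:
                dist = config.build_population()
                diameters = sample_sizes(dist, n, rng_init)
        else:
            diameters = np.asarray(diameters, dtype=float)
            n = len(diameters)
        radii = diameters / 2.0
        if initial_positions is None:
            positions = self._uniform_positions(radii, rng_init)
        else:
            positions = np.array(initial_positions, dtype=float)
        # per-particle diffusion: nanoparticles diffuse through plasma, so
        # the Stokes-Einstein drag uses the plasma viscosity
        self.d_c = np.array([
            diffusion_coefficient(self.fluid.temperature,
                                  self.fluid.plasma_viscosity, r)
            for r in radii
        ])
        self.sigma = np.array([
            brownian_sigma(d, config.time.dt_s) for d in self.d_c
        ])
        self.sigma_pore = np.array([
            brownian_sigma(d, config.time.dt_pore_s) for d in self.d_c
        ])

        self.n_steps = int(round(config.time.total_s / config.time.dt_s))
        self.state = SimulationState(
            time=0.0, step_index=0, z_shift=0.0,
            positions=positions, z_unwrapped=positions[:, 2].copy(),
            radii=radii,
            status=np.zeros(n, dtype=int),
            pore_of=np.full(n, -1, dtype=int),
            rbcs=self.rbcs, fenestrations=self.fenestrations,
            flow=self.flow, ledger=UptakeLedger(population_size=n),
        )

        # Brownian displacement blocks, one stream per particle id
        if config.toggles.brownian_on:
            self._noise = np.empty((n, self.n_steps, 3))
            for i in range(n):
                rng = np.random.default_rng(np.random.SeedSequence(
                    particle_stream_seed(config.seed, i, 0)))
                self._noise[i] = self.sigma[i] * polar_gaussian(
                    rng, 3 * self.n_steps).reshape(self.n_steps, 3)
        else:
            self._noise = None
        self._pore_rngs: dict[int, np.random.Generator] = {}

        # metric accumulators
        self.binding_fraction_series: list[float] = []
        self.mean_radial_series: list[float] = []
        self.mean_speed_series: list[float] = []
        self.wall_speed_series: list[float] = []
        self.trajectory: list[np.ndarray] = (
            [positions.copy()] if record_trajectories else []
        )

    # -- helpers -------------------------------------------------------
    def _uniform_positions(self, radii: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
        """Uniform positions in the accessible lumen, outside RBC envelopes."""
        n = len(radii)
        pos = np.empty((n, 3))
        for i in range(n):
            for _ in range(10000):
                rho_max = self.geom.radius - radii[i]
                rho = rho_max * np.sqrt(rng.uniform())
                th = rng.uniform(0.0, 2.0 * np.pi)
                z = rng.uniform(0.0, self.geom.length)
                cand = np.array([rho * np.cos(th), rho * np.sin(th), z])
                if not self.rbcs or self.obstacles.signed_clearance(
                        cand, radii[i]) > 0.0:
                    pos[i] = cand
                    break
            else:
                raise ValueError("could not place particle outside RBCs")
        return pos

    def _pore_rng(self, pid: int) -> np.random.Generator:
        if pid not in self._pore_rngs:
            self._pore_rngs[pid] = np.random.default_rng(np.random.SeedSequence(
                particle_stream_seed(self.config.seed, pid, 1)))
        return self._pore_rngs[pid]

    def _fluid_velocity_3d(self, pos: np.ndarray) -> np.ndarray:
        """(n, 3) fluid velocity in um/s at particle positions."""
        rho = np.hypot(pos[:, 0], pos[:, 1])
        vr, vz = self.flow.velocity_rz(rho, pos[:, 2], self.state.z_shift)
        out = np.empty_like(pos)
        with np.errstate(invalid="ignore", divide="ignore"):
            ct = np.where(rho > 0, pos[:, 0] / rho, 0.0)
            st = np.where(rho > 0, pos[:, 1] / rho, 0.0)
        out[:, 0] = vr * ct
        out[:, 1] = vr * st
        out[:, 2] = vz
        return out

    # -- the synchronous update ---------------------------------------
    def step(self) -> None:
        if self.state.step_index >= self.n_steps:
            raise ValueError("simulation already ran to completion")
        try:
            self._step_inner()
        except Exception as exc:
            raise RuntimeError(
                f"step {self.state.step_index} "
                f"(t = {self.state.time:.6g} s) aborted: {exc}"
            ) from exc

    def _step_inner(self) -> None:
        st = self.state
        cfg = self.config
        dt = cfg.time.dt_s

        # (1) advance RBCs; (2) flow refresh = rigid translation of the
        # co-moving steady field, applied at the configured cadence
        if self.rbcs and st.step_index % cfg.time.flow_update_every == 0:
            st.z_shift = (self.rbc_speed * 1e3 * dt * st.step_index) \
                % self.geom.length

        free = np.where(st.status == SimulationState.STATUS_FREE)[0]
        speeds = None

        # (3) advect + Brownian + wall reflection + RBC push-out
        if free.size:
            pos = st.positions[free]
            z_old = pos[:, 2].copy()
            disp = np.zeros_like(pos)
            if cfg.toggles.laminar_on:
                u = self._fluid_velocity_3d(pos)       # um/s
                disp += u * (dt * 1e3)                 # -> nm
                speeds = np.linalg.norm(u, axis=1)
            if self._noise is not None:
                disp += self._noise[free, st.step_index]
            pos = pos + disp
            pos[:, :2] = reflect_at_wall_many(pos[:, :2], st.radii[free],
                                              self.geom)
            if self.rbcs:
                pos = self.obstacles.resolve_overlaps(pos, st.radii[free],
                                                      st.z_shift)
            if self.geom.periodic_axial:
                pos[:, 2] %= self.geom.length
            st.positions[free] = pos
            # accumulate the physical (unwrapped) axial displacement; per-step
            # motion is far below L/2, so the minimum-image difference is exact
            L = self.geom.length
            dz = np.mod(pos[:, 2] - z_old + 0.5 * L, L) - 0.5 * L
            st.z_unwrapped[free] += dz

            # (4) pore entry tests for wall-adjacent particles
            if self.fenestrations:
                self._pore_entries(free)

        # (5) pore sub-walks
        if self.fenestrations:
            self._pore_transits()

        # (6) metrics
        st.step_index += 1
        st.time = st.step_index * dt
        self._accumulate(free, speeds)
        if self.record_trajectories:
            rec = st.positions.copy()
            rec[:, 2] = st.z_unwrapped
            self.trajectory.append(rec)

    def _pore_entries(self, free: np.ndarray) -> None:
        st = self.state
        pores = self.fenestrations
        max_pore_r = max(p.radius for p in pores)
        pos = st.positions[free]
        rho = np.hypot(pos[:, 0], pos[:, 1])
        gap = self.geom.radius - rho - st.radii[free]
        near = gap <= self.capture_distance
        if not np.any(near):
            return
        cand = free[near]
        theta = np.mod(np.arctan2(st.positions[cand, 1],
                                  st.positions[cand, 0]), 2.0 * np.pi)
        pid, dist = self.pore_index.nearest(theta, st.positions[cand, 2],
                                            r_query=max_pore_r)
        for k, i in enumerate(cand):
            if pid[k] < 0:
                continue
            pore = pores[int(pid[k])]
            clearance = pore.radius - st.radii[i]
            if clearance <= 0.0 or dist[k] >= clearance:
                continue
            st.status[i] = SimulationState.STATUS_IN_PORE
            st.pore_of[i] = pore.id
            st.pore_states[int(i)] = PoreWalkState(
                xi=float(st.radii[i]), lateral=np.zeros(2))
            st.ledger.record(st.time, int(i), pore.id, "entered")

    def _pore_transits(self) -> None:
        st = self.state
        cfg = self.config
        n_sub = max(1, int(round(cfg.time.dt_s / cfg.time.dt_pore_s)))
        in_pore = np.where(st.status == SimulationState.STATUS_IN_PORE)[0]
        for i in in_pore:
            pore = self.fenestrations[st.pore_of[i]]
            outcome = pore_walk(
                st.pore_states[int(i)], pore, float(st.radii[i]),
                float(self.sigma_pore[i]) if cfg.toggles.brownian_on else 0.0,
                n_sub, self._pore_rng(int(i)),
            )
            if outcome == PoreOutcome.TRANSLOCATED:
                st.status[i] = SimulationState.STATUS_TRANSLOCATED
                st.ledger.record(st.time, int(i), pore.id, "translocated",
                                 diameter=2.0 * float(st.radii[i]))
                del st.pore_states[int(i)]
            elif outcome == PoreOutcome.RETURNED:
                st.status[i] = SimulationState.STATUS_FREE
                st.pore_of[i] = -1
                # re-emerge at the inner mouth, just inside the lumen
                rho = self.geom.radius - st.radii[i] - 1.0
                L = self.geom.length
                dz = np.mod(pore.z - st.positions[i, 2] + 0.5 * L, L) - 0.5 * L
                st.z_unwrapped[i] += dz
                st.positions[i] = [rho * np.cos(pore.theta),
                                   rho * np.sin(pore.theta), pore.z]
                st.ledger.record(st.time, int(i), pore.id, "returned")
                del st.pore_states[int(i)]

    def _accumulate(self, free: np.ndarray, speeds: np.ndarray | None) -> None:
        st = self.state
        lum = st.status != SimulationState.STATUS_TRANSLOCATED
        if np.any(lum):
            self.binding_fraction_series.append(
                _metrics.fraction_within_binding_range(
                    st.positions[lum], st.radii[lum], self.geom))
            self.mean_radial_series.append(
                _metrics.mean_radial_position(st.positions[lum]))
        if speeds is not None and speeds.size:
            self.mean_speed_series.append(float(np.mean(speeds)))
            pos = st.positions[free]
            gap = self.geom.radius - np.hypot(pos[:, 0], pos[:, 1]) \
                - st.radii[free]
            wall = gap <= _metrics.BINDING_RANGE_NM
            if np.any(wall):
                self.wall_speed_series.append(float(np.mean(speeds[wall])))

    def run(self) -> "SimulationResult":
        while self.state.step_index < self.n_steps:
            self.step()
        return SimulationResult(self)


class SimulationResult:
    """Read-only view over a finished run."""

    def __init__(self, sim: Simulation) -> None:
        self.sim = sim
        self.config = sim.config
        self.state = sim.state
        self.geom = sim.geom

    @property
    def particles(self) -> list[Nanoparticle]:
        return self.state.particle_list()

    def uptake(self) -> dict:
        return uptake_summary(self.state.ledger, self.particles,
                              self.state.time)

    def dispersion(self) -> _metrics.DispersionField:
        return _metrics.average_dispersion_factor(self.sim.flow)

    def trajectory_array(self) -> np.ndarray:
        """(n_steps + 1, n_particles, 3) recorded positions, nm."""
        if not self.sim.trajectory:
            raise ValueError("run was not recorded (record_trajectories=False)")
        return np.stack(self.sim.trajectory)

    def metrics_summary(self) -> dict:
        st = self.state
        out = {
            "seed": self.config.seed,
            "haematocrit": self.config.haematocrit,
            "n_rbcs": len(self.sim.rbcs),
            "rbc_speed_um_s": self.sim.rbc_speed,
            "viscosity_pa_s": self.sim.viscosity,
            "time_s": st.time,
            "n_particles": int(len(st.radii)),
            "adf": self.dispersion().adf,
            "mean_binding_fraction_pct": (
                float(np.mean(self.sim.binding_fraction_series))
                if self.sim.binding_fraction_series else float("nan")),
            "final_binding_fraction_pct": (
                self.sim.binding_fraction_series[-1]
                if self.sim.binding_fraction_series else float("nan")),
            "mean_radial_position_nm": (
                float(np.mean(self.sim.mean_radial_series))
                if self.sim.mean_radial_series else float("nan")),
            "mean_particle_speed_um_s": (
                float(np.mean(self.sim.mean_speed_series))
                if self.sim.mean_speed_series else float("nan")),
            "mean_wall_particle_speed_um_s": (
                float(np.mean(self.sim.wall_speed_series))
                if self.sim.wall_speed_series else float("nan")),
        }
        if self.sim.fenestrations:
            out.update(self.uptake())
        return out
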