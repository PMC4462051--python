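"""Vessel-wall fenestrations: pore placement, entry, transit, accounting.

Fenestrations are narrow cylindrical pores running radially through the
endothelium (channel length = wall thickness), 60 nm in diameter for a
normal capillary and 240 nm for the leaky vasculature supplying tumours.
A free nanoparticle can enter a pore only if it fits (hard-sphere: particle
radius strictly below pore radius), its surface is within the capture
distance of the wall, and its wall projection lies within the clearance of
the pore centre.  Inside the pore the particle performs a Brownian walk at
a much shorter sub-step (the channel is only a few hundred nm long);
crossing the outer end is absorbing (translocated to tissue), re-crossing
the inner mouth returns the particle to the lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VesselGeometry
from .particles import Nanoparticle, ParticleStatus


@dataclass(frozen=True)
class Fenestration:
    """A radial pore through the vessel wall."""

    id: int
    theta: float          # azimuthal position, rad
    z: float              # axial position, nm
    diameter: float       # nm
    channel_length: float  # nm (endothelium depth)

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.channel_length <= 0:
            raise ValueError("pore diameter and channel length must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def place_fenestrations(
    geom: VesselGeometry,
    density_per_um2: float,
    diameter: float,
    rng: np.random.Generator,
    channel_length: float | None = None,
    max_attempts_factor: int = 200,
) -> list[Fenestration]:
    """Scatter non-overlapping pores uniformly over the cylindrical wall.

    The pore count is Poisson with mean density x wall area; placement is
    by dart throwing with the non-overlap rule that centre-to-centre
    surface distance exceeds the pore diameter.
    """
    if density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    if density_per_um2 == 0:
        return []
    channel_length = geom.wall_thickness if channel_length is None else channel_length
    target = rng.poisson(density_per_um2 * geom.wall_area_um2)
    if target == 0:
        return []

    R, L = geom.radius, geom.length
    placed_xy: list[tuple[float, float]] = []  # (R*theta unrolled, z)
    pores: list[Fenestration] = []
    attempts = 0
    max_attempts = max_attempts_factor * target
    min_d = diameter
    while len(pores) < target:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {target} pores without overlap after "
                f"{max_attempts} attempts (placed {len(pores)}); density too high"
            )
        theta = rng.uniform(0.0, 2.0 * np.pi)
        z = rng.uniform(0.0, L)
        x = R * theta
        ok = True
        for (px, pz) in placed_xy:
            dx = abs(x - px)
            dx = min(dx, 2.0 * np.pi * R - dx)
            dz = abs(z - pz)
            if geom.periodic_axial:
                dz = min(dz, L - dz)
            if dx * dx + dz * dz <= min_d * min_d:
                ok = False
                break
        if not ok:
            continue
        placed_xy.append((x, z))
        pores.append(
            Fenestration(
                id=len(pores), theta=theta, z=z,
                diameter=diameter, channel_length=channel_length,
            )
        )
    return pores


class PoreIndex:
    """Fast nearest-pore lookup on the unrolled cylinder surface.

    The wall is unrolled to (R*theta, z); pores near the azimuthal seam and
    the periodic axial seam are duplicated so a single KD-tree query covers
    the wrap-around.
    """

    def __init__(self, pores: list[Fenestration], geom: VesselGeometry) -> None:
        self.pores = pores
        self.geom = geom
        if not pores:
            self._tree = None
            return
        R, L = geom.radius, geom.length
        pts = []
        ids = []
        margin = max(p.radius for p in pores) + 100.0
        for p in pores:
            x = R * p.theta
            base = [(x, p.z)]
            if x < margin:
                base.append((x + 2 * np.pi * R, p.z))
            if 2 * np.pi * R - x < margin:
                base.append((x - 2 * np.pi * R, p.z))
            if geom.periodic_axial:
                base += [(bx, bz + L) for bx, bz in base if bz < margin]
                base += [(bx, bz - L) for bx, bz in base if L - bz < margin]
            for b in base:
                pts.append(b)
                ids.append(p.id)
        self._tree = cKDTree(np.array(pts))
        self._ids = np.array(ids)

    def nearest(self, theta: np.ndarray, z: np.ndarray,
                r_query: float) -> tuple[np.ndarray, np.ndarray]:
        """Nearest pore id and surface distance for each (theta, z)."""
        if self._tree is None:
            n = len(np.atleast_1d(theta))
            return np.full(n, -1), np.full(n, np.inf)
        q = np.column_stack([self.geom.radius * np.asarray(theta),
                             np.asarray(z)])
        dist, idx = self._tree.query(q, distance_upper_bound=r_query)
        found = np.isfinite(dist)
        pid = np.where(found, self._ids[np.clip(idx, 0, len(self._ids) - 1)], -1)
        return pid, dist


def try_enter_pore(p: Nanoparticle, f: Fenestration, geom: VesselGeometry,
                   capture_distance: float = 20.0) -> bool:
    """Hard-sphere pore-entry test for a free particle.

    True iff the particle fits (r < pore radius, strict clearance), its
    surface is within ``capture_distance`` of the wall, and its wall
    projection lies within (pore radius - particle radius) of the pore
    centre.
    """
    if p.status != ParticleStatus.FREE:
        raise ValueError("only free particles can enter pores")
    if p.radius >= f.radius:
        return False
    rho = float(np.hypot(p.position[0], p.position[1]))
    gap = geom.radius - rho - p.radius
    if gap > capture_distance:
        return False
    theta = float(np.arctan2(p.position[1], p.position[0])) % (2.0 * np.pi)
    dx = geom.radius * ((theta - f.theta + np.pi) % (2.0 * np.pi) - np.pi)
    dz = p.position[2] - f.z
    if geom.periodic_axial:
        dz = (dz + geom.length / 2.0) % geom.length - geom.length / 2.0
    clearance = f.radius - p.radius
    return bool(dx * dx + dz * dz < clearance * clearance)


@dataclass
class PoreWalkState:
    """Progress of one particle through one pore channel."""

    xi: float                    # axial penetration along the channel, nm
    lateral: np.ndarray          # 2D offset from the channel axis, nm


class PoreOutcome(str, Enum):
    TRANSLOCATED = "translocated"
    RETURNED = "returned"
    IN_TRANSIT = "in_transit"


def pore_walk(
    state: PoreWalkState,
    f: Fenestration,
    particle_radius: float,
    sigma_pore: float,
    n_substeps: int,
    rng: np.random.Generator,
) -> PoreOutcome:
    """Advance a pore transit by up to ``n_substeps`` Brownian sub-steps.

    The axial coordinate xi runs from 0 (inner mouth) to the channel length
    (outer end, absorbing).  The transit outcome is decided by the axial
    walk; lateral excursions are confined to the accessible channel radius
    by radial folding (they carry no observable, the channel wall is
    neither absorbing nor sticky).  Updates ``state`` in place.
    """
    if particle_radius >= f.radius:
        raise ValueError(
            "particle does not fit the pore (should have been blocked at entry)"
        )
    if sigma_pore == 0.0:
        return PoreOutcome.IN_TRANSIT
    from .brownian import polar_gaussian

    steps = sigma_pore * polar_gaussian(rng, 3 * n_substeps).reshape(n_substeps, 3)
    path = state.xi + np.cumsum(steps[:, 0])
    out_idx = np.argmax(path >= f.channel_length) if np.any(
        path >= f.channel_length) else -1
    ret_idx = np.argmax(path <= 0.0) if np.any(path <= 0.0) else -1

    if out_idx >= 0 and (ret_idx < 0 or out_idx < ret_idx):
        state.xi = f.channel_length
        return PoreOutcome.TRANSLOCATED
    if ret_idx >= 0:
        state.xi = 0.0
        return PoreOutcome.RETURNED
    state.xi = float(path[-1])
    lat = state.lateral + np.sum(steps[:, 1:], axis=0)
    rho_max = f.radius - particle_radius
    rho = float(np.hypot(lat[0], lat[1]))
    if rho > rho_max and rho > 0:
        # radial fold: triangle-wave map of the radius into [0, rho_max]
        period = 2.0 * rho_max
        folded = rho_max - abs((rho % period) - rho_max)
        lat = lat * (folded / rho)
    state.lateral = lat
    return PoreOutcome.IN_TRANSIT


# ----------------------------------------------------------------------
# accounting
# ----------------------------------------------------------------------

@dataclass
class UptakeLedger:
    """Time-ordered entry/return/translocation events plus status counts."""

    population_size: int
    events: list[tuple[float, int, int, str]] = field(default_factory=list)
    translocated: dict[int, float] = field(default_factory=dict)  # id -> diameter

    def record(self, time: float, particle_id: int, pore_id: int,
               event: str, diameter: float | None = None) -> None:
        if self.events and time < self.events[-1][0]:
            raise ValueError("ledger events must be time-ordered")
        self.events.append((time, particle_id, pore_id, event))
        if event == "translocated":
            if diameter is None:
                raise ValueError("translocation events must carry the diameter")
            self.translocated[particle_id] = diameter

    def counts(self, particles: list[Nanoparticle]) -> dict[str, int]:
        c = {"translocated": 0, "in_pore": 0, "free": 0}
        for p in particles:
            c[p.status.value] += 1
        entered = {e[1] for e in self.events if e[3] == "entered"}
        c["never_entered"] = sum(
            1 for p in particles
            if p.status == ParticleStatus.FREE and p.id not in entered
        )
        return c


def uptake_summary(ledger: UptakeLedger, particles: list[Nanoparticle],
                   time: float,
                   size_class_edges: np.ndarray | None = None) -> dict:
    """Population uptake statistics at readout time ``time``.

    Percent translocated / in pore, mean diameter of translocated vs
    luminal particles, and the delivered volume live here; only fully
    translocated particles count as delivered.  With ``size_class_edges``
    the translocated particles are additionally binned into per-class
    uptake counts.
    """
    if not particles:
        raise ValueError("empty particle population")
    n = len(particles)
    counts = ledger.counts(particles)
    trans_d = np.array(sorted(ledger.translocated.values()), dtype=float)
    lum_d = np.array(
        [2.0 * p.radius for p in particles if p.status != ParticleStatus.TRANSLOCATED]
    )
    from .sizes import particle_volume

    extra = {}
    if size_class_edges is not None:
        edges = np.asarray(size_class_edges, dtype=float)
        extra["size_class_uptake_counts"] = np.histogram(
            trans_d, bins=edges)[0].tolist()
    return {
        **extra,
        "time_s": time,
        "population": n,
        "percent_translocated": 100.0 * counts["translocated"] / n,
        "percent_in_pore": 100.0 * counts["in_pore"] / n,
        "n_translocated": counts["translocated"],
        "mean_diameter_translocated_nm": float(trans_d.mean()) if trans_d.size else float("nan"),
        "mean_diameter_luminal_nm": float(lum_d.mean()) if lum_d.size else float("nan"),
        "delivered_volume_nm3": float(np.sum(particle_volume(trans_d))) if trans_d.size else 0.0,
        "translocated_diameters_nm": trans_d.tolist(),
    }
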