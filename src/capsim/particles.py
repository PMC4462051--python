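"""Nanoparticle agents: advection + Brownian displacement, wall reflection
and RBC excluded volume.

Particles are rigid spheres carried by the local fluid velocity and kicked
by Gaussian Brownian steps (overdamped composition F_total = F_L + F_B as
displacement vectors).  The vessel wall is specularly reflective for the
particle centre about the accessible cylinder rho = R - r; RBC overlap is
resolved geometrically by pushing the particle back along the local
outward normal of the cell envelope to tangential contact (no momentum
exchange).  Particle-particle interactions are neglected: the populations
simulated are dilute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import shapely

from .brownian import BrownianStepper
from .flow import FlowField
from .geometry import RBCAgent, VesselGeometry


class ParticleStatus(str, Enum):
    FREE = "free"
    IN_PORE = "in_pore"
    TRANSLOCATED = "translocated"


_ALLOWED_TRANSITIONS = {
    (ParticleStatus.FREE, ParticleStatus.IN_PORE),
    (ParticleStatus.IN_PORE, ParticleStatus.FREE),
    (ParticleStatus.IN_PORE, ParticleStatus.TRANSLOCATED),
}


@dataclass
class Nanoparticle:
    """A spherical nanoparticle agent (position in nm)."""

    id: int
    position: np.ndarray
    radius: float
    status: ParticleStatus = ParticleStatus.FREE
    pore_id: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        self.position = np.asarray(self.position, dtype=float)

    def set_status(self, new: ParticleStatus) -> None:
        if new != self.status and (self.status, new) not in _ALLOWED_TRANSITIONS:
            raise ValueError(f"illegal status transition {self.status} -> {new}")
        self.status = new


# ----------------------------------------------------------------------
# wall reflection
# ----------------------------------------------------------------------

def reflect_at_wall(position, radius: float, geom: VesselGeometry,
                    max_iter: int = 16) -> np.ndarray:
    """Specularly reflect an overshooting centre about rho = R - r.

    Mirror reflection preserves the axial coordinate and, unlike re-drawing
    the step, preserves the uniform equilibrium distribution of a purely
    diffusing population.  Idempotent for interior points.
    """
    p = np.array(position, dtype=float)
    rho_max = geom.radius - radius
    if rho_max <= 0:
        raise ValueError("particle larger than the vessel")
    rho = float(np.hypot(p[0], p[1]))
    for _ in range(max_iter):
        if rho <= rho_max:
            return p
        rho_new = 2.0 * rho_max - rho
        if rho_new < 0.0:
            rho_new = -rho_new  # passed through the axis: reflect again
        scale = rho_new / rho if rho > 0 else 0.0
        p[0] *= scale
        p[1] *= scale
        rho = abs(rho_new)
    raise ValueError(
        f"wall reflection did not terminate after {max_iter} mirrors "
        f"(overshoot rho = {float(np.hypot(*position[:2])):.1f} nm)"
    )


def reflect_at_wall_many(xy: np.ndarray, radii: np.ndarray,
                         geom: VesselGeometry) -> np.ndarray:
    """Vectorised wall reflection of the (x, y) columns for many particles."""
    rho_max = geom.radius - radii
    rho = np.hypot(xy[:, 0], xy[:, 1])
    out = xy.copy()
    bad = rho > rho_max
    for _ in range(16):
        if not np.any(bad):
            return out
        rho_new = np.abs(2.0 * rho_max[bad] - rho[bad])
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho[bad] > 0, rho_new / rho[bad], 0.0)
        out[bad] *= scale[:, None]
        rho[bad] = rho_new
        bad = rho > rho_max
    raise ValueError("wall reflection did not terminate")


# ----------------------------------------------------------------------
# RBC excluded volume
# ----------------------------------------------------------------------

class RBCObstacleSet:
    """Excluded-volume resolver for a train of identically shaped RBCs.

    The obstacle is the filled spheroidal envelope of the parachute
    (trapped plasma in the dent travels with the cell).  Overlap tests and
    push-out use the Minkowski dilation of the envelope profile by the
    particle radius in the (rho, z) half-plane, computed with shapely; the
    azimuthal angle is preserved (the obstacle is axisymmetric).

    Cell positions at time t are the initial centres advanced by the common
    rigid-train speed, wrapped periodically.
    """

    def __init__(self, rbcs: list[RBCAgent], geom: VesselGeometry,
                 quad_segs: int = 32) -> None:
        self.geom = geom
        self.rbcs = rbcs
        self._dilated: dict[float, shapely.Geometry] = {}
        self._quad_segs = quad_segs
        if rbcs:
            cell = rbcs[0]
            a, c = cell.effective_radius, cell.axial_semi_axis
            z_up = cell.z_upstream - cell.z_center
            # full meridian cross-section (mirrored about the axis) so that
            # Minkowski dilation never creates a boundary on the axis itself
            t_rim = np.arccos(np.clip(z_up / c, -1.0, 1.0))
            t = np.linspace(t_rim, 0.0, 120)
            r = a * np.sin(t)
            z = c * np.cos(t)
            pts = np.concatenate([
                np.column_stack([r, z]),            # rim -> pole (right)
                np.column_stack([-r[::-1], z[::-1]])[1:],  # pole -> rim (left)
            ])
            self._profile = shapely.Polygon(pts)
            self.half_extent = max(abs(z_up), c)
        else:
            self._profile = None
            self.half_extent = 0.0
        self._z0 = np.array([c.z_center for c in rbcs], dtype=float)

    def _dilated_profile(self, radius: float) -> shapely.Geometry:
        key = round(float(radius), 6)
        if key not in self._dilated:
            self._dilated[key] = self._profile.buffer(
                key, quad_segs=self._quad_segs
            )
        return self._dilated[key]

    def centers_at(self, z_shift: float) -> np.ndarray:
        return np.mod(self._z0 + z_shift, self.geom.length)

    def signed_clearance(self, position, radius: float,
                         z_shift: float = 0.0) -> float:
        """Distance from the particle surface to the nearest envelope.

        Positive outside (clearance), negative when overlapping.
        """
        if not self.rbcs:
            return np.inf
        p = np.asarray(position, dtype=float)
        rho = float(np.hypot(p[0], p[1]))
        best = np.inf
        L = self.geom.length
        for zc in self.centers_at(z_shift):
            dz = (p[2] - zc + 0.5 * L) % L - 0.5 * L
            pt = shapely.Point(rho, dz)
            d = pt.distance(self._profile)
            if d == 0.0:
                d = -pt.distance(self._profile.exterior)
            best = min(best, d - radius)
        return best

    def resolve_overlaps(self, pos: np.ndarray, radii: np.ndarray,
                         z_shift: float = 0.0) -> np.ndarray:
        """Push overlapping particles out to tangential contact.

        ``pos`` is (n, 3) in nm; returns a corrected copy.
        """
        if not self.rbcs or pos.shape[0] == 0:
            return pos
        out = pos.copy()
        rho = np.hypot(out[:, 0], out[:, 1])
        L = self.geom.length
        centers = self.centers_at(z_shift)
        for zc in centers:
            dz = (out[:, 2] - zc + 0.5 * L) % L - 0.5 * L
            near = (np.abs(dz) <= self.half_extent + radii) & (
                rho <= self.rbcs[0].effective_radius + radii
            )
            if not np.any(near):
                continue
            idx = np.where(near)[0]
            for k in idx:
                dil = self._dilated_profile(float(radii[k]))
                pt = shapely.Point(rho[k], dz[k])
                if not dil.contains(pt):
                    continue
                # nearest boundary point of the dilated envelope
                ring = dil.exterior
                q = ring.interpolate(ring.project(pt))
                rho_new, dz_new = float(q.x), float(q.y)
                # nudge outward so the contact is not re-detected
                nrm = np.array([rho_new - pt.x, dz_new - pt.y])
                nn = np.linalg.norm(nrm)
                if nn > 0:
                    rho_new += 1e-6 * nrm[0] / nn
                    dz_new += 1e-6 * nrm[1] / nn
                rho_new = abs(rho_new)
                theta = np.arctan2(out[k, 1], out[k, 0])
                out[k, 0] = rho_new * np.cos(theta)
                out[k, 1] = rho_new * np.sin(theta)
                out[k, 2] = (zc + dz_new) % L
                rho[k] = rho_new
        return out


def resolve_rbc_overlap(p: Nanoparticle, rbcs: list[RBCAgent],
                        geom: VesselGeometry,
                        z_shift: float = 0.0) -> Nanoparticle:
    """Push a single particle out of any RBC envelope it intersects."""
    obst = RBCObstacleSet(rbcs, geom)
    pos = obst.resolve_overlaps(
        p.position[None, :], np.array([p.radius]), z_shift
    )[0]
    rho = np.hypot(pos[0], pos[1])
    if rho + p.radius > geom.radius + 1e-6:
        raise ValueError(
            f"particle {p.id} cannot satisfy both the wall and RBC constraints"
        )
    p.position = pos
    return p


# ----------------------------------------------------------------------
# single-particle update (module surface; the simulator uses the
# vectorised ensemble path in simulation.py)
# ----------------------------------------------------------------------

def advance_particle(
    p: Nanoparticle,
    field: FlowField | None,
    stepper: BrownianStepper,
    geom: VesselGeometry,
    rbcs: list[RBCAgent] | None = None,
    dt: float | None = None,
    laminar_on: bool = True,
    brownian_on: bool = True,
    z_shift: float = 0.0,
) -> Nanoparticle:
    """One combined advection + Brownian step for a free particle.

    new position = old + u(position) dt + sigma * N(0,1)^3, followed by
    wall reflection and RBC push-out.  The laminar/Brownian toggles expose
    the force-decomposition runs.
    """
    if p.status != ParticleStatus.FREE:
        raise ValueError("only free particles advance in the lumen")
    dt = stepper.dt if dt is None else dt
    rho = float(np.hypot(p.position[0], p.position[1]))
    if rho + p.radius > geom.radius * (1.0 + 1e-9):
        raise ValueError(f"particle {p.id} starts outside the accessible lumen")
    disp = np.zeros(3)
    if laminar_on and field is not None:
        from .flow import interpolate_velocity
        u = interpolate_velocity(field, p.position)  # um/s
        disp += u * dt * 1e3                         # um/s * s -> nm
    if brownian_on:
        disp += stepper.step()
    newp = p.position + disp
    newp = reflect_at_wall(newp, p.radius, geom)
    p.position = newp
    if rbcs:
        resolve_rbc_overlap(p, rbcs, geom, z_shift)
    if geom.periodic_axial:
        p.position[2] %= geom.length
    return p
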