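"""Quasi-static incompressible flow in the RBC-laden capillary.

At capillary scale the Reynolds number is ~1e-3, so inertia is negligible
and each flow update solves the axisymmetric Stokes problem

    -mu lap(u) + grad p = f,      div u = 0,

with no-slip walls, symmetry on the axis, rigid-body velocity on every RBC
envelope, and a uniform axial body force f_z = dp/L standing in for the
arteriole-venule pressure drop (the domain is axially periodic).

Discretisation: linear (P1/P1) triangles with Galerkin/least-squares
pressure stabilisation (the PSPG term tau * (grad p - f, grad q) per
element), assembled in cylindrical coordinates and solved with a direct
sparse factorisation.  Equal-order interpolation is inf-sup unstable
without the stabilisation term; with it, the pressure checkerboard mode is
suppressed at O(h^2) consistency cost.

The RBC translation speed is not prescribed: cells "move at a rate set by
the pressure and viscosity", i.e. the speed at which the net axial
hydrodynamic traction on the cell train vanishes.  Because Stokes flow is
linear in the boundary data, that force-free speed is found exactly from
two solves.

Units: mesh lengths in nm (converted to metres internally), velocities
exposed in um/s, pressure in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .constants import M_PER_NM, UM_S_PER_M_S
from .geometry import Haematocrit, VesselGeometry
from .mesh import Mesh

#: PSPG stabilisation coefficient tau = ALPHA_PSPG * h_e^2 / mu.
ALPHA_PSPG = 0.1

#: Centreline speed the default pressure drop is calibrated to, um/s.
DEFAULT_CENTERLINE_SPEED_UM_S = 5500.0


# ----------------------------------------------------------------------
# fluid properties and closed forms
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Plasma properties and the driving pressure drop.

    ``pressure_drop`` is the pressure difference over the vessel segment
    length; if None it is calibrated so the acellular centreline speed is
    5500 um/s at plasma viscosity (use :func:`calibrated_pressure_drop`).
    """

    density: float = 1025.0            # kg/m^3
    plasma_viscosity: float = 1.2e-3   # Pa s
    temperature: float = 310.0         # K
    pressure_drop: float | None = None  # Pa over the segment

    def __post_init__(self) -> None:
        for name in ("density", "plasma_viscosity", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resolve_pressure_drop(self, geom: VesselGeometry) -> float:
        if self.pressure_drop is not None:
            return self.pressure_drop
        return calibrated_pressure_drop(
            geom, self.plasma_viscosity, DEFAULT_CENTERLINE_SPEED_UM_S
        )


def effective_viscosity(
    h: Haematocrit | float, plasma_viscosity: float, model: str = "polynomial"
) -> float:
    """Suspension viscosity as a function of haematocrit, Pa s.

    The polynomial relation mu_rel = 1 + 2.5 H + 7.35 H^2 (Einstein's dilute
    coefficient plus a quadratic crowding term) is the default; an
    exponential relation mu_rel = exp(3 H) is selectable.  Both reduce to
    the plasma viscosity at H = 0 and increase superlinearly, capturing the
    non-linear viscosity rise of concentrated RBC suspensions.
    """
    frac = h.fraction if isinstance(h, Haematocrit) else float(h)
    if not 0.0 <= frac < 1.0:
        raise ValueError(f"haematocrit must lie in [0, 1), got {frac}")
    if plasma_viscosity <= 0:
        raise ValueError("plasma viscosity must be positive")
    if model == "polynomial":
        rel = 1.0 + 2.5 * frac + 7.35 * frac * frac
    elif model == "exponential":
        rel = float(np.exp(3.0 * frac))
    else:
        raise ValueError(f"unknown viscosity model {model!r}")
    return plasma_viscosity * rel


def reynolds_number(density: float, mean_velocity: float,
                    hydraulic_diameter: float, viscosity: float) -> float:
    """Re = rho v D_H / mu (all SI). Laminar below ~2400."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if density <= 0 or hydraulic_diameter <= 0 or mean_velocity < 0:
        raise ValueError("density, diameter must be positive; velocity >= 0")
    return density * mean_velocity * hydraulic_diameter / viscosity


def poiseuille_profile(geom: VesselGeometry, pressure_drop: float,
                       viscosity: float, r_nm) -> np.ndarray:
    """Analytic parabolic profile v_z(r) = dp (R^2 - r^2) / (4 mu L), um/s."""
    r = np.asarray(r_nm, dtype=float)
    if np.any(r < 0) or np.any(r > geom.radius):
        raise ValueError("radial position outside the vessel")
    R = geom.radius * M_PER_NM
    L = geom.length * M_PER_NM
    v = pressure_drop * (R**2 - (r * M_PER_NM) ** 2) / (4.0 * viscosity * L)
    return v * UM_S_PER_M_S


def calibrated_pressure_drop(geom: VesselGeometry, viscosity: float,
                             centerline_um_s: float) -> float:
    """Pressure drop giving the requested acellular centreline speed, Pa."""
    R = geom.radius * M_PER_NM
    L = geom.length * M_PER_NM
    return 4.0 * viscosity * L * centerline_um_s / UM_S_PER_M_S / R**2


# ----------------------------------------------------------------------
# the discrete field
# ----------------------------------------------------------------------

@dataclass
class FlowField:
    """Nodal axisymmetric velocity/pressure field on a :class:`Mesh`.

    ``v_r``/``v_z`` in um/s, ``pressure`` in Pa.  ``rbc_velocity`` is the
    rigid-body speed imposed on the cell envelopes (um/s).  The field is
    steady in the frame co-moving with the RBC train; :meth:`velocity_at`
    accepts an axial shift so a later snapshot is a rigid translation.
    """

    mesh: Mesh
    v_r: np.ndarray
    v_z: np.ndarray
    pressure: np.ndarray
    viscosity: float
    rbc_velocity: float = 0.0

    @cached_property
    def _interp(self):
        from matplotlib.tri import LinearTriInterpolator, Triangulation

        m = self.mesh
        triang = Triangulation(m.nodes[:, 0], m.nodes[:, 1], m.elements)
        return (
            LinearTriInterpolator(triang, self.v_r),
            LinearTriInterpolator(triang, self.v_z),
            LinearTriInterpolator(triang, self.pressure),
        )

    def velocity_rz(self, r_nm: np.ndarray, z_nm: np.ndarray,
                    z_shift: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(v_r, v_z) in um/s at (r, z) points; z wrapped periodically.

        Points falling inside an RBC envelope (masked by the triangulation)
        are assigned the trapped-plasma velocity (0, rbc_velocity).
        """
        L = self.mesh.geom.length
        zq = np.mod(np.asarray(z_nm, dtype=float) - z_shift, L)
        rq = np.asarray(r_nm, dtype=float)
        f_r, f_z, _ = self._interp
        vr = f_r(rq, zq)
        vz = f_z(rq, zq)
        bad = np.ma.getmaskarray(vr) | np.ma.getmaskarray(vz)
        vr = np.ma.filled(vr, 0.0)
        vz = np.ma.filled(vz, self.rbc_velocity)
        if np.any(bad):
            outside = rq > self.mesh.geom.radius * (1.0 + 1e-12)
            if np.any(bad & outside):
                raise ValueError(
                    "velocity query outside the vessel wall "
                    f"(max r = {float(np.max(rq[bad & outside])):.1f} nm)"
                )
        return vr, vz

    def element_centroid_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-element (v_r, v_z) at centroids, um/s."""
        e = self.mesh.elements
        vr = self.v_r[e].mean(axis=1)
        vz = self.v_z[e].mean(axis=1)
        return vr, vz

    def axial_flux(self, z_nm: float, n_samples: int = 400) -> float:
        """Volumetric flux through the cross-section at z, um^3/s * 1e-9...

        Returned in units of nm^2 * um/s integrated with the 2 pi r measure
        (consistent across sections; used for mass-conservation checks).
        """
        r = np.linspace(0.0, self.mesh.geom.radius, n_samples)
        _, vz = self.velocity_rz(r, np.full_like(r, z_nm % self.mesh.geom.length))
        return float(np.trapezoid(vz * 2.0 * np.pi * r, r))


def interpolate_velocity(field: FlowField, point_nm) -> np.ndarray:
    """3D velocity (um/s) at a 3D position (nm).

    Maps the axisymmetric field to Cartesian components:
    v_x = v_r cos(theta), v_y = v_r sin(theta).
    """
    p = np.asarray(point_nm, dtype=float)
    rho = float(np.hypot(p[0], p[1]))
    if rho > field.mesh.geom.radius * (1.0 + 1e-12):
        raise ValueError(
            f"point at rho = {rho:.1f} nm lies outside the vessel wall "
            f"(R = {field.mesh.geom.radius:.1f} nm)"
        )
    vr, vz = field.velocity_rz(np.array([rho]), np.array([p[2]]))
    if rho > 0.0:
        ct, st = p[0] / rho, p[1] / rho
    else:
        ct = st = 0.0
    return np.array([vr[0] * ct, vr[0] * st, vz[0]])


# ----------------------------------------------------------------------
# assembly and solve
# ----------------------------------------------------------------------

def _assemble(mesh: Mesh, viscosity: float, f_z: float):
    """Assemble the stabilised axisymmetric Stokes system (SI units).

    Returns (K, rhs) for the symmetric saddle system with dof ordering
    [u_r (n), u_z (n), p (n)].
    """
    nodes = mesh.nodes * M_PER_NM
    elems = mesh.elements
    em = mesh.owner[elems]          # periodic dof folding at the seam
    n = mesh.n_nodes
    mu = viscosity

    x = nodes[elems, 0]  # (ne, 3) r-coords
    y = nodes[elems, 1]  # (ne, 3) z-coords
    # P1 gradient coefficients: grad phi_i = (b_i, c_i) / (2A)
    b = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    )
    c = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    )
    area = 0.5 * (
        (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
        - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    )
    if np.any(area <= 0):
        raise ValueError("inverted element during assembly")
    rbar = x.mean(axis=1)
    # edge midpoint radii rm_k (midpoint opposite vertex k)
    rm = 0.5 * (x[:, [1, 2, 0]] + x[:, [2, 0, 1]])
    rm_sum = rm.sum(axis=1)
    # S_j = int psi_j r dA  (exact, degree-2 midpoint rule)
    S = (area[:, None] / 6.0) * (rm_sum[:, None] - rm)

    ii = np.repeat(np.arange(3), 3)
    jj = np.tile(np.arange(3), 3)
    rows_local = em[:, ii]  # (ne, 9)
    cols_local = em[:, jj]

    inv4A = 1.0 / (4.0 * area)
    gg = (b[:, ii] * b[:, jj] + c[:, ii] * c[:, jj]) * inv4A[:, None]
    kvisc = mu * gg * rbar[:, None]                      # grad-grad, both components
    delta = (np.arange(3)[:, None] == np.arange(3)[None, :]).astype(float)
    mass = area[:, None] * (1.0 + delta.ravel()[None, :]) / 12.0
    hoop = mu * mass                                     # u_r v_r / r term

    # pressure coupling (test index i, pressure basis j)
    Br = -(b[:, ii] / (2.0 * area[:, None]) * S[:, jj] + mass)
    Bz = -(c[:, ii] / (2.0 * area[:, None]) * S[:, jj])

    h2 = 2.0 * area                                      # element size^2 proxy
    tau = ALPHA_PSPG * h2 / mu
    Cstab = tau[:, None] * gg * rbar[:, None]

    def coo(vals, roff, coff):
        return (
            (rows_local + roff).ravel(),
            (cols_local + coff).ravel(),
            vals.ravel(),
        )

    blocks = [
        coo(kvisc + hoop, 0, 0),        # A_rr
        coo(kvisc, n, n),               # A_zz
        coo(Br, 0, 2 * n),              # u_r test, p trial
        coo(Bz, n, 2 * n),              # u_z test, p trial
        coo(np.transpose(Br.reshape(-1, 3, 3), (0, 2, 1)).reshape(-1, 9), 2 * n, 0),
        coo(np.transpose(Bz.reshape(-1, 3, 3), (0, 2, 1)).reshape(-1, 9), 2 * n, n),
        coo(-Cstab, 2 * n, 2 * n),
    ]
    # identity rows for the folded seam-slave dofs (solved trivially to 0,
    # overwritten with their master's value after the solve)
    slaves = np.where(mesh.owner != np.arange(n))[0]
    sl = np.concatenate([slaves, n + slaves, 2 * n + slaves])

    rows = np.concatenate([blk[0] for blk in blocks] + [sl])
    cols = np.concatenate([blk[1] for blk in blocks] + [sl])
    vals = np.concatenate([blk[2] for blk in blocks] + [np.ones(sl.size)])
    K = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()

    rhs = np.zeros(3 * n)
    # body force on u_z rows: int f_z phi_i r dA = f_z S_i
    np.add.at(rhs, n + em.ravel(), (f_z * S).ravel())
    # PSPG consistency: -h_i = -tau int f . grad psi_i r dA on pressure rows
    np.add.at(
        rhs,
        2 * n + em.ravel(),
        (-(tau * f_z * rbar)[:, None] * c / 2.0).ravel(),
    )
    return K, rhs


def solve_flow(
    mesh: Mesh,
    fluid: FluidProperties,
    rbc_velocity: float = 0.0,
    viscosity: float | None = None,
    pressure_drop: float | None = None,
    return_reaction: bool = False,
):
    """Solve the stabilised Stokes problem on ``mesh``.

    Parameters
    ----------
    rbc_velocity : float
        Rigid-body axial speed imposed on every RBC envelope, um/s.
    viscosity : float, optional
        Effective suspension viscosity (Pa s); defaults to plasma viscosity.
    pressure_drop : float, optional
        Pa over the segment; defaults to the fluid's calibrated value.

    Returns
    -------
    FlowField, or (FlowField, reaction) with ``return_reaction``; the
    reaction is the net axial force on the RBC envelopes in Newtons.
    """
    mu = fluid.plasma_viscosity if viscosity is None else viscosity
    dp = fluid.resolve_pressure_drop(mesh.geom) if pressure_drop is None \
        else pressure_drop
    L = mesh.geom.length * M_PER_NM
    K, rhs = _assemble(mesh, mu, dp / L)
    n = mesh.n_nodes

    v_rbc_si = rbc_velocity / UM_S_PER_M_S
    own = mesh.owner
    fixed: dict[int, float] = {}
    for nd in own[mesh.wall_nodes]:
        fixed[nd] = 0.0          # u_r
        fixed[n + nd] = 0.0      # u_z
    for nd in own[mesh.axis_nodes]:
        fixed[nd] = 0.0
    for nd in own[mesh.rbc_nodes]:
        fixed[nd] = 0.0
        fixed[n + nd] = v_rbc_si
    fixed[2 * n + own[0]] = 0.0  # pin one pressure dof

    idx = np.fromiter(fixed.keys(), dtype=int)
    vals = np.fromiter(fixed.values(), dtype=float)

    K0, rhs0 = K, rhs.copy()
    keep = np.ones(3 * n)
    keep[idx] = 0.0
    rhs = keep * (rhs - K[:, idx] @ vals)
    rhs[idx] = vals
    D = sp.diags(keep)
    K_bc = D @ K @ D + sp.diags(1.0 - keep)
    sol = spsolve(K_bc.tocsc(), rhs)

    resid_fixed = K0 @ sol - rhs0
    # expand seam slaves with their master's values
    field = FlowField(
        mesh=mesh,
        v_r=(sol[:n])[own] * UM_S_PER_M_S,
        v_z=(sol[n: 2 * n])[own] * UM_S_PER_M_S,
        pressure=(sol[2 * n:])[own],
        viscosity=mu,
        rbc_velocity=rbc_velocity,
    )
    if not return_reaction:
        return field
    # reaction = residual of unconstrained momentum rows at constrained dofs;
    # net axial force on the cells is its sum over RBC u_z rows (x 2 pi for
    # the azimuthal measure).
    rbc_owned = np.unique(own[mesh.rbc_nodes])
    f_axial = 2.0 * np.pi * float(np.sum(resid_fixed[n + rbc_owned]))
    return field, f_axial


def rbc_force_free_velocity(
    mesh: Mesh,
    fluid: FluidProperties,
    viscosity: float | None = None,
    pressure_drop: float | None = None,
    tol_rel: float = 1e-8,
) -> tuple[float, FlowField]:
    """Speed at which the net axial traction on the RBC train vanishes.

    Stokes flow is linear, so F(V) = F0 + k V and a secant step from two
    trial solves lands on the root exactly; a final solve verifies the
    residual force.

    Returns (speed um/s, FlowField at that speed).
    """
    if len(mesh.rbc_nodes) == 0:
        raise ValueError("mesh has no RBC boundaries")
    mu = fluid.plasma_viscosity if viscosity is None else viscosity
    dp = fluid.resolve_pressure_drop(mesh.geom) if pressure_drop is None \
        else pressure_drop
    v1 = poiseuille_profile(mesh.geom, dp, mu, 0.0)  # centreline speed guess
    _, f0 = solve_flow(mesh, fluid, 0.0, mu, dp, return_reaction=True)
    _, f1 = solve_flow(mesh, fluid, float(v1), mu, dp, return_reaction=True)
    if f1 == f0:
        raise ValueError("cannot bracket the force-free RBC speed")
    v_star = -f0 * float(v1) / (f1 - f0)
    field, f_star = solve_flow(mesh, fluid, v_star, mu, dp, return_reaction=True)
    if abs(f_star) > tol_rel * max(abs(f0), abs(f1)):
        raise ValueError(
            f"force-free solve did not converge (residual force {f_star:.3e} N)"
        )
    field.rbc_velocity = v_star
    return v_star, field
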