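"""Vessel geometry, red-blood-cell agents and haematocrit bookkeeping.

The capillary is a hollow cylinder with no-slip walls, radius ~4000 nm
(8-12 um diameter vessels).  Red blood cells travelling through such a
confined vessel adopt the axisymmetric "parachute" conformation: a shell
with a convex downstream cap and a concave (dented) upstream face, centred
on the vessel axis and oriented perpendicular to the flow.

The parachute is modelled as a spheroidal-cap shell: take the spheroid with
radial semi-axis ``a`` (the post-deformation effective radius) and axial
semi-axis ``c``, cut it with a plane at distance ``c - h`` upstream of the
centre (``h`` is the cap depth) and mirror the cut cap inward, producing the
dent.  The shell volume is then

    V(a, c, h) = 4/3 pi a^2 c  -  2 pi (a/c)^2 h^2 (c - h/3)

and ``c`` is solved from the prescribed cell volume.  Identically shaped
cells nest (the downstream cap of one cell fits the dent of the next), which
is what lets a train of parachutes reach whole-blood haematocrit in a
capillary.

Lengths in nm, volumes in um^3 where stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

NM3_PER_UM3 = 1e9

#: Post-deformation effective radius, nm (literature stand-in, configurable).
DEFAULT_RBC_RADIUS_NM = 2900.0
#: Mean corpuscular volume, um^3 (literature stand-in, configurable).
DEFAULT_RBC_VOLUME_UM3 = 94.0
#: Depth of the upstream dent, nm.
DEFAULT_CAP_DEPTH_NM = 1200.0


@dataclass(frozen=True)
class VesselGeometry:
    """Cylindrical capillary segment.

    Parameters
    ----------
    radius : float
        Lumen radius in nm (default 4000, an 8 um diameter vessel).
    length : float
        Axial length of the simulated segment in nm.
    periodic_axial : bool
        Whether the axial direction wraps around (a repeating segment of an
        effectively infinite capillary).
    wall_thickness : float
        Endothelium depth in nm; the channel length of wall fenestrations.
    """

    radius: float = 4000.0
    length: float = 50000.0
    periodic_axial: bool = True
    wall_thickness: float = 400.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"vessel radius must be positive, got {self.radius}")
        if self.length <= 0:
            raise ValueError(f"vessel length must be positive, got {self.length}")
        if self.wall_thickness <= 0:
            raise ValueError(
                f"wall thickness must be positive, got {self.wall_thickness}"
            )

    @property
    def volume_um3(self) -> float:
        """Lumen volume in um^3."""
        return float(np.pi * self.radius**2 * self.length / NM3_PER_UM3)

    @property
    def wall_area_um2(self) -> float:
        """Lumen wall (inner cylinder) area in um^2."""
        return float(2.0 * np.pi * self.radius * self.length / 1e6)


@dataclass(frozen=True)
class Haematocrit:
    """Red-blood-cell volume fraction.

    Whole blood sits at 38-46%; capillary haematocrit drops to 10-12%.
    The model covers the acellular (0%) to whole-blood (45%) range.
    """

    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 0.45:
            raise ValueError(
                f"haematocrit must lie in [0, 0.45], got {self.fraction}"
            )


def _shell_volume_nm3(a: float, c: float, h: float) -> float:
    """Volume of the dented spheroid (parachute shell), nm^3."""
    if not 0.0 < h < c:
        raise ValueError(f"cap depth must lie in (0, c); h={h}, c={c}")
    full = 4.0 / 3.0 * np.pi * a * a * c
    dent = 2.0 * np.pi * (a / c) ** 2 * h * h * (c - h / 3.0)
    return full - dent


def _solve_axial_semi_axis(a: float, volume_nm3: float, h: float) -> float:
    """Solve c so the dented spheroid matches the prescribed cell volume."""

    def f(c: float) -> float:
        return _shell_volume_nm3(a, c, h) - volume_nm3

    lo = h * 1.0001
    hi = max(10.0 * a, 10.0 * h)
    if f(lo) > 0:
        raise ValueError(
            "cell volume too small for this effective radius and cap depth"
        )
    if f(hi) < 0:
        raise ValueError(
            "cell volume too large for this effective radius (no axial "
            "semi-axis below 10x the radius fits it)"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


@dataclass
class RBCAgent:
    """A parachute-conformation red blood cell, radially centred in the vessel.

    Attributes
    ----------
    z_center : float
        Axial position of the spheroid centre, nm.
    velocity_z : float
        Axial speed, um/s (>= 0; set by the force-free flow condition).
    effective_radius : float
        Maximum radial extent after deformation, nm.
    cell_volume : float
        Volume of the shell, um^3.
    cap_depth : float
        Depth of the upstream dent, nm.
    axial_semi_axis : float
        Axial semi-axis ``c`` of the generating spheroid, nm (solved from the
        cell volume unless given).
    """

    z_center: float
    velocity_z: float = 0.0
    effective_radius: float = DEFAULT_RBC_RADIUS_NM
    cell_volume: float = DEFAULT_RBC_VOLUME_UM3
    cap_depth: float = DEFAULT_CAP_DEPTH_NM
    axial_semi_axis: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.effective_radius <= 0:
            raise ValueError("effective radius must be positive")
        if self.velocity_z < 0:
            raise ValueError("RBC axial velocity must be non-negative")
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if self.axial_semi_axis <= 0.0:
            self.axial_semi_axis = _solve_axial_semi_axis(
                self.effective_radius,
                self.cell_volume * NM3_PER_UM3,
                self.cap_depth,
            )
        if self.cap_depth >= 2.0 * self.axial_semi_axis:
            raise ValueError("cap depth would self-intersect the shell")

    # -- axial extents -------------------------------------------------
    @property
    def z_upstream(self) -> float:
        """Upstream truncation plane (start of the solid), nm."""
        return self.z_center - (self.axial_semi_axis - self.cap_depth)

    @property
    def z_downstream(self) -> float:
        """Downstream pole of the cap, nm."""
        return self.z_center + self.axial_semi_axis

    @property
    def axial_extent(self) -> float:
        """Axial length of the solid shell, nm."""
        return self.z_downstream - self.z_upstream

    @property
    def nesting_extent(self) -> float:
        """Minimum centre spacing at which identical cells still nest, nm."""
        return 2.0 * (self.axial_semi_axis - self.cap_depth)

    # -- silhouette (filled envelope used as the flow obstacle) --------
    def silhouette_radius(self, z: np.ndarray | float) -> np.ndarray:
        """Radius of the filled spheroidal envelope at axial position z (nm).

        Zero outside the cell.  The envelope fills the upstream concavity:
        plasma trapped in the dent moves with the cell at capillary Reynolds
        numbers, so the envelope is the effective flow obstacle.
        """
        z = np.asarray(z, dtype=float)
        a, c = self.effective_radius, self.axial_semi_axis
        xi = (z - self.z_center) / c
        inside = np.abs(xi) < 1.0
        s = np.where(inside, a * np.sqrt(np.clip(1.0 - xi * xi, 0.0, None)), 0.0)
        # truncate upstream of the dent plane
        s = np.where(z < self.z_upstream, 0.0, s)
        return s

    def boundary_profile(self, n_points: int = 64) -> np.ndarray:
        """Closed (r, z) polyline of the dented shell, axis included.

        The profile runs: axis point on the dent -> dent face (concave,
        upstream) -> rim -> spheroid surface over the equator to the
        downstream pole (convex) -> back to the start.  Revolving it about
        the axis recovers the cell volume.
        """
        if n_points < 8:
            raise ValueError("need at least 8 points for a closed profile")
        a, c, h = self.effective_radius, self.axial_semi_axis, self.cap_depth
        zc = self.z_center
        z_plane = zc - (c - h)
        # radius of the cut circle (rim of the dent)
        r_cap = a * np.sqrt(max(0.0, 1.0 - ((c - h) / c) ** 2))

        n_half = max(4, n_points // 2)
        # dent face: mirror of the spheroid cap about the cut plane,
        # z = 2*z_plane - (zc - c*sqrt(1-(r/a)^2)) for r in [0, r_cap]
        r_dent = np.linspace(0.0, r_cap, n_half)
        z_dent = 2.0 * z_plane - (zc - c * np.sqrt(1.0 - (r_dent / a) ** 2))
        # outer spheroid surface from the rim over the equator to the
        # downstream pole, parametrised by angle
        t0 = np.arccos(-(c - h) / c)  # polar angle of the rim
        t = np.linspace(t0, 0.0, 2 * n_half)
        # include the equator exactly so max(r) == effective_radius
        t = np.sort(np.append(t, np.pi / 2.0))[::-1]
        r_out = a * np.sin(t)
        z_out = zc + c * np.cos(t)
        r = np.concatenate([r_dent, r_out[1:], [0.0]])
        z = np.concatenate([z_dent, z_out[1:], [z_dent[0]]])
        return np.column_stack([r, z])


def revolved_volume_nm3(profile: np.ndarray) -> float:
    """Volume of the solid of revolution of a closed (r, z) profile.

    Uses the divergence theorem: V = -pi * closed-integral of r^2 dz taken
    counter-clockwise in the (r, z) half-plane.
    """
    r, z = profile[:, 0], profile[:, 1]
    v = -np.pi * np.sum(0.5 * (r[:-1] ** 2 + r[1:] ** 2) * np.diff(z))
    return float(abs(v))


def haematocrit_to_rbc_count(
    h: Haematocrit | float,
    geom: VesselGeometry,
    cell_volume: float = DEFAULT_RBC_VOLUME_UM3,
) -> int:
    """Number of RBCs producing haematocrit ``h`` in the vessel segment.

    count = round(H * pi R^2 L / V_cell).
    """
    frac = h.fraction if isinstance(h, Haematocrit) else Haematocrit(h).fraction
    if cell_volume <= 0:
        raise ValueError("cell volume must be positive")
    return int(round(frac * geom.volume_um3 / cell_volume))


def achieved_haematocrit(count: int, geom: VesselGeometry,
                         cell_volume: float = DEFAULT_RBC_VOLUME_UM3) -> float:
    """Volume fraction actually realised by ``count`` cells (quantised)."""
    return count * cell_volume / geom.volume_um3


def place_rbcs(
    count: int,
    geom: VesselGeometry,
    *,
    effective_radius: float = DEFAULT_RBC_RADIUS_NM,
    cell_volume: float = DEFAULT_RBC_VOLUME_UM3,
    cap_depth: float = DEFAULT_CAP_DEPTH_NM,
    spacing_rule: str = "uniform",
    jitter_frac: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[RBCAgent]:
    """Place ``count`` identical RBCs along the vessel axis.

    The uniform rule puts cell k at (2k+1)/(2*count) of the vessel length.
    With ``jitter_frac`` > 0 each centre is perturbed by a uniform jitter of
    up to ``jitter_frac`` of the free slack per cell (never enough to break
    nesting), which is how replicate initial conditions are generated.

    Raises
    ------
    ValueError
        If the cells cannot fit without shell overlap; the message names the
        maximum feasible count.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return []
    if spacing_rule != "uniform":
        raise ValueError(f"unknown spacing rule {spacing_rule!r}")
    if effective_radius >= geom.radius:
        raise ValueError("RBC effective radius must be smaller than the vessel radius")

    template = RBCAgent(
        z_center=0.0,
        effective_radius=effective_radius,
        cell_volume=cell_volume,
        cap_depth=cap_depth,
    )
    spacing = geom.length / count
    min_spacing = template.nesting_extent if geom.periodic_axial or count > 1 \
        else template.axial_extent
    if spacing < min_spacing:
        max_feasible = int(geom.length // min_spacing)
        raise ValueError(
            f"{count} cells cannot fit in a {geom.length:.0f} nm vessel "
            f"without overlap (centre spacing {spacing:.0f} nm < minimum "
            f"{min_spacing:.0f} nm); maximum feasible count is {max_feasible}"
        )

    centers = (np.arange(count) + 0.5) * spacing
    if jitter_frac > 0.0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        slack = 0.5 * (spacing - min_spacing)
        centers = centers + rng.uniform(-1.0, 1.0, size=count) * jitter_frac * slack

    return [
        RBCAgent(
            z_center=float(zc),
            effective_radius=effective_radius,
            cell_volume=cell_volume,
            cap_depth=cap_depth,
        )
        for zc in centers
    ]
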