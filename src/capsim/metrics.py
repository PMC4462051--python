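"""Derived statistics: dispersion factor, MSD, binding-range fraction,
specificity ratio/score, delivered volume, multiple-testing adjustment.

The dispersion factor DF = V_R / v_z (radial over longitudinal speed) is 0
where flow runs parallel to the wall; its unweighted mean over the fluid
elements (the average dispersion factor, ADF) summarises how strongly the
flow mixes material between the core and the wall.  Elements where v_z
vanishes have no defined DF; they are excluded and counted rather than
zero-filled (zero-filling would silently bias the ADF downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .flow import FlowField
from .geometry import VesselGeometry
from .sizes import particle_volume

#: Wall binding range: gap between particle surface and wall, nm.
BINDING_RANGE_NM = 20.0


def radial_velocity(v_x, v_y) -> np.ndarray | float:
    """V_R = sqrt(v_x^2 + v_y^2), um/s."""
    return np.hypot(v_x, v_y)


def dispersion_factor(v_r, v_z):
    """DF = V_R / v_z; NaN where v_z = 0 (undefined, excluded upstream)."""
    v_r = np.abs(np.asarray(v_r, dtype=float))
    v_z = np.asarray(v_z, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = np.where(v_z != 0.0, v_r / v_z, np.nan)
    return df


@dataclass
class DispersionField:
    """Element-level dispersion statistics of a flow field."""

    v_radial: np.ndarray     # per-element V_R, um/s
    df: np.ndarray           # per-element DF (NaN where undefined)
    n_elements: int          # fluid elements entering the average
    n_undefined: int         # excluded v_z = 0 elements
    adf: float               # average dispersion factor


def average_dispersion_factor(
    field: FlowField,
    rbc_mask: np.ndarray | None = None,
    vz_floor_rel: float = 1e-9,
) -> DispersionField:
    """Unweighted element-centroid mean of DF over the fluid elements.

    ``rbc_mask`` flags elements to exclude (the mesh is boundary-fitted so
    none exist by default; the hook mirrors the definition's sum over flow
    elements).  Elements whose |v_z| is below ``vz_floor_rel`` times the
    field maximum are treated as undefined and excluded with a counter.
    """
    vr, vz = field.element_centroid_velocity()
    if rbc_mask is not None:
        keep = ~np.asarray(rbc_mask, dtype=bool)
        vr, vz = vr[keep], vz[keep]
    if vr.size == 0:
        raise ValueError("no fluid elements to average over")
    floor = vz_floor_rel * float(np.max(np.abs(vz))) if np.any(vz != 0) else 0.0
    defined = np.abs(vz) > floor
    df = np.abs(vr[defined]) / vz[defined]
    if df.size == 0:
        raise ValueError("dispersion factor undefined on every element")
    return DispersionField(
        v_radial=np.abs(vr),
        df=dispersion_factor(vr, np.where(np.abs(vz) > floor, vz, np.nan)),
        n_elements=int(df.size),
        n_undefined=int(np.sum(~defined)),
        adf=float(np.mean(df)),
    )


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

@dataclass
class MSDSeries:
    """Mean squared displacement against lag time, nm^2."""

    times: np.ndarray
    msd: np.ndarray
    component: str = "total"   # total | laminar_only | brownian_only

    def __post_init__(self) -> None:
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")


def msd(positions: np.ndarray, times: np.ndarray | None = None) -> np.ndarray:
    """|x(t) - x(0)|^2 along a trajectory, or ensemble mean.

    ``positions`` is (n_times, 3) for one particle or
    (n_particles, n_times, 3) for an ensemble (averaged over particles).
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim == 2:
        d = p - p[0]
        return np.einsum("ij,ij->i", d, d)
    if p.ndim == 3:
        d = p - p[:, :1, :]
        return np.einsum("kij,kij->ki", d, d).mean(axis=0)
    raise ValueError("positions must be (n_t, 3) or (n_particles, n_t, 3)")


def fraction_within_binding_range(
    positions: np.ndarray,
    radii: np.ndarray,
    geom: VesselGeometry,
    binding_range: float = BINDING_RANGE_NM,
) -> float:
    """Percent of particles whose surface is within the binding range.

    A particle counts when R - rho_centre - r_particle <= binding range.
    """
    p = np.asarray(positions, dtype=float)
    if p.size == 0:
        raise ValueError("empty particle population")
    rho = np.hypot(p[:, 0], p[:, 1])
    gap = geom.radius - rho - np.asarray(radii, dtype=float)
    return float(100.0 * np.mean(gap <= binding_range))


def mean_radial_position(positions: np.ndarray) -> float:
    """Mean distance of particle centres from the vessel axis, nm.

    For a population uniform over an accessible cross-section of radius
    R_a this tends to (2/3) R_a.
    """
    p = np.asarray(positions, dtype=float)
    if p.size == 0:
        raise ValueError("empty particle population")
    return float(np.mean(np.hypot(p[:, 0], p[:, 1])))


# ----------------------------------------------------------------------
# delivery specificity
# ----------------------------------------------------------------------

def specificity_ratio(uptake_tumour: float, uptake_normal: float) -> float:
    """Tumour-to-normal delivery ratio; inf when only tumours receive.

    0/0 is not computable and returns NaN.
    """
    if uptake_tumour < 0 or uptake_normal < 0:
        raise ValueError("uptake percentages must be non-negative")
    if uptake_normal == 0.0:
        return float("inf") if uptake_tumour > 0 else float("nan")
    return uptake_tumour / uptake_normal


def specificity_score(uptake_tumour: float, uptake_normal: float) -> float:
    """Specificity weighted by delivery efficiency.

    score = specificity ratio x tumour uptake fraction — the minimal form
    that rewards both selectivity and the absolute amount delivered
    (quadratic in tumour uptake at fixed normal uptake).
    """
    ratio = specificity_ratio(uptake_tumour, uptake_normal)
    if np.isnan(ratio):
        return float("nan")
    if np.isinf(ratio):
        return float("inf") if uptake_tumour > 0 else float("nan")
    return ratio * (uptake_tumour / 100.0)


def delivered_volume(translocated_diameters) -> float:
    """Total delivered nanoparticle volume, nm^3 (the cargo proxy)."""
    d = np.asarray(translocated_diameters, dtype=float)
    if d.size == 0:
        return 0.0
    return float(np.sum(particle_volume(d)))


# ----------------------------------------------------------------------
# statistics utilities
# ----------------------------------------------------------------------

def holm_sidak_adjust(p_values, alpha: float = 0.05):
    """Step-down Holm-Sidak adjustment.

    Sorted ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1), enforced
    monotone non-decreasing, mapped back to input order.  Returns
    (adjusted p-values, reject flags at ``alpha``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - k)
        running = max(running, val)          # enforce monotonicity
        adjusted[idx] = min(1.0, running)
    return adjusted, adjusted <= alpha


def replicate_ttest(a, b) -> tuple[float, float]:
    """Two-sample t-test on run replicates (thin utility)."""
    t, p = _scipy_stats.ttest_ind(np.asarray(a), np.asarray(b))
    return float(t), float(p)
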