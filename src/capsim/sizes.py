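"""Nanoparticle size populations.

DLS instruments (Zetasizer convention) report particle diameters binned
into logarithmically spaced size classes with a percent frequency per
class.  Populations are sampled in two stages: the class is chosen by
inverse CDF on the class weights, then the diameter within the class is
drawn from a piecewise-linear density whose endpoint values interpolate
the neighbouring classes' weights — a smooth reading of "weighting the
probability of sizes within the class by the neighbouring classes".

A synthetic generator stands in for measured DLS curves: a lognormal
number-weighted density with prescribed mean diameter and polydispersity
index (variance = pdi * mean^2), binned into Zetasizer-style classes.
Diameters (not radii) are the working quantity throughout; conversion to
radii happens at the Nanoparticle boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SizeDistribution:
    """Binned diameter distribution (nm classes, percent weights)."""

    class_edges: np.ndarray    # (n_classes + 1,) strictly increasing, nm
    class_weights: np.ndarray  # (n_classes,) percent, sums to 100
    label: str = ""

    def __post_init__(self) -> None:
        self.class_edges = np.asarray(self.class_edges, dtype=float)
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if self.class_edges.ndim != 1 or self.class_edges.size < 2:
            raise ValueError("need at least one size class")
        if np.any(np.diff(self.class_edges) <= 0):
            raise ValueError("class edges must be strictly increasing")
        if self.class_weights.size != self.class_edges.size - 1:
            raise ValueError("one weight per class required")
        if np.any(self.class_weights < 0):
            raise ValueError("class weights must be non-negative")
        total = self.class_weights.sum()
        if abs(total - 100.0) > 0.1:
            raise ValueError(
                f"class weights must sum to 100% (within 0.1%), got {total:.3f}"
            )
        if total != 100.0:
            self.class_weights = self.class_weights * (100.0 / total)

    @property
    def n_classes(self) -> int:
        return self.class_weights.size

    def mean_diameter(self) -> float:
        """Mean diameter of the piecewise-linear continuous density, nm."""
        dens = _class_densities(self)
        lo, hi = self.class_edges[:-1], self.class_edges[1:]
        vl, vr = dens
        w = 0.5 * (vl + vr) * (hi - lo)
        # centroid of a trapezoid on [lo, hi] with heights (vl, vr)
        with np.errstate(invalid="ignore", divide="ignore"):
            cent = np.where(
                vl + vr > 0,
                lo + (hi - lo) * (vl + 2.0 * vr) / (3.0 * (vl + vr)),
                0.5 * (lo + hi),
            )
        return float(np.sum(w * cent) / np.sum(w))


def monodisperse(diameter_nm: float, width_nm: float = 0.0) -> SizeDistribution:
    """Degenerate one-class distribution; sampling returns the diameter."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    half = max(width_nm, 0.0) / 2.0
    if half > 0:
        return SizeDistribution(
            class_edges=np.array([diameter_nm - half, diameter_nm + half]),
            class_weights=np.array([100.0]),
            label=f"monodisperse {diameter_nm:g} nm",
        )
    return _DegenerateDistribution(diameter_nm)


class _DegenerateDistribution(SizeDistribution):
    """Single exact diameter (zero-width class)."""

    def __init__(self, diameter_nm: float) -> None:
        self.diameter = float(diameter_nm)
        # represent as a vanishingly narrow class for the common machinery
        eps = max(1e-9, 1e-9 * diameter_nm)
        super().__init__(
            class_edges=np.array([diameter_nm - eps, diameter_nm + eps]),
            class_weights=np.array([100.0]),
            label=f"monodisperse {diameter_nm:g} nm",
        )

    def mean_diameter(self) -> float:
        return self.diameter


def parse_dls_table(path_or_buffer) -> SizeDistribution:
    """Read a DLS size-class CSV with columns lower_nm, upper_nm, percent.

    Rows may arrive in any order (sorted by lower edge); weights off 100%
    by less than 1% are renormalised with a warning, larger discrepancies
    are an error.
    """
    df = pd.read_csv(path_or_buffer)
    required = {"lower_nm", "upper_nm", "percent"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"DLS table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.sort_values("lower_nm").reset_index(drop=True)
    for i in range(len(df)):
        lo, hi = df.loc[i, "lower_nm"], df.loc[i, "upper_nm"]
        if hi <= lo:
            raise ValueError(f"row {i}: upper edge {hi} not above lower edge {lo}")
        if df.loc[i, "percent"] < 0:
            raise ValueError(f"row {i}: negative percent weight")
        if i > 0 and not np.isclose(lo, df.loc[i - 1, "upper_nm"]):
            raise ValueError(
                f"row {i}: classes not contiguous "
                f"(lower {lo} != previous upper {df.loc[i - 1, 'upper_nm']})"
            )
    total = df["percent"].sum()
    if abs(total - 100.0) >= 1.0:
        raise ValueError(
            f"class weights sum to {total:.2f}%, more than 1% from 100%"
        )
    if abs(total - 100.0) > 1e-9:
        warnings.warn(
            f"class weights sum to {total:.3f}%; renormalising to 100%",
            stacklevel=2,
        )
        df["percent"] *= 100.0 / total
    edges = np.concatenate([df["lower_nm"].to_numpy(),
                            [df["upper_nm"].iloc[-1]]])
    return SizeDistribution(edges, df["percent"].to_numpy(), label="DLS table")


def _class_densities(dist: SizeDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Left/right endpoint density values for each class.

    The density height of class k is w_k / width_k; endpoint values at the
    interior edges are the mean of the two adjacent heights, clipped to be
    non-negative, then each class is rescaled so its trapezoid still
    integrates to its own weight.
    """
    lo, hi = dist.class_edges[:-1], dist.class_edges[1:]
    width = hi - lo
    height = dist.class_weights / width
    edge_vals = np.empty(dist.n_classes + 1)
    edge_vals[1:-1] = 0.5 * (height[:-1] + height[1:])
    edge_vals[0] = height[0]
    edge_vals[-1] = height[-1]
    vl = edge_vals[:-1].copy()
    vr = edge_vals[1:].copy()
    # rescale each class so the trapezoid area equals the class weight
    area = 0.5 * (vl + vr) * width
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(area > 0, dist.class_weights / area, 0.0)
    return vl * scale, vr * scale


def sample_sizes(dist: SizeDistribution, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw n diameters (nm) from the binned distribution.

    Class by inverse CDF on the class weights; diameter within the class by
    inverse CDF of the neighbour-interpolated linear density.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if isinstance(dist, _DegenerateDistribution):
        return np.full(n, dist.diameter)
    probs = dist.class_weights / 100.0
    cls = rng.choice(dist.n_classes, size=n, p=probs)
    u = rng.uniform(0.0, 1.0, size=n)
    lo = dist.class_edges[cls]
    hi = dist.class_edges[cls + 1]
    vl, vr = _class_densities(dist)
    a, b = vl[cls], vr[cls]
    width = hi - lo
    # inverse CDF of the linear density f(t) = a + (b-a) t on t in [0,1]
    # (normalised): solve (a t + (b-a) t^2 / 2) / ((a+b)/2) = u
    t = np.empty(n)
    flat = np.isclose(a, b)
    t[flat] = u[flat]
    k = ~flat
    disc = a[k] ** 2 + (b[k] ** 2 - a[k] ** 2) * u[k]
    t[k] = (np.sqrt(disc) - a[k]) / (b[k] - a[k])
    return lo + np.clip(t, 0.0, 1.0) * width


def synthetic_dls(mean_diameter: float, pdi: float,
                  n_classes: int = 26,
                  span: tuple[float, float] = (1.0, 1000.0),
                  label: str | None = None) -> SizeDistribution:
    """Synthetic DLS-like distribution: binned lognormal.

    The underlying number-weighted density is lognormal with the stated
    mean and variance pdi * mean^2, binned into ``n_classes`` log-spaced
    classes over ``span`` (Zetasizer export convention).  pdi -> 0
    degenerates to the class containing the mean.
    """
    if mean_diameter <= 0:
        raise ValueError("mean diameter must be positive")
    if not 0.0 <= pdi < 0.5:
        raise ValueError(f"polydispersity index must lie in [0, 0.5), got {pdi}")
    if n_classes < 5:
        raise ValueError("need at least 5 size classes")
    if pdi == 0.0:
        return monodisperse(mean_diameter)
    edges = np.geomspace(span[0], span[1], n_classes + 1)
    sigma2 = np.log1p(pdi)
    sigma = np.sqrt(sigma2)
    mu = np.log(mean_diameter) - sigma2 / 2.0
    cdf = stats.lognorm.cdf(edges, s=sigma, scale=np.exp(mu))
    w = np.diff(cdf)
    if w.sum() <= 0:
        raise ValueError("distribution mass falls outside the class span")
    w = 100.0 * w / w.sum()
    return SizeDistribution(
        edges, w, label=label or f"synthetic DLS {mean_diameter:g} nm pdi {pdi:g}"
    )


def rebin(diameters: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Percent weight of samples per class (round-trip checks)."""
    counts, _ = np.histogram(diameters, bins=edges)
    return 100.0 * counts / max(len(diameters), 1)


def particle_volume(diameter_nm: float | np.ndarray) -> np.ndarray | float:
    """Sphere volume (pi/6) d^3 in nm^3 — the cargo-capacity proxy."""
    d = np.asarray(diameter_nm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    v = np.pi / 6.0 * d**3
    return float(v) if np.isscalar(diameter_nm) else v
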