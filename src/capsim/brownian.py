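"""Brownian displacement machinery.

A nanoparticle's random walk is built from the Stokes-Einstein diffusion
coefficient D_c = k_B T / (6 pi mu r), the per-axis Gaussian step standard
deviation sigma = sqrt(2 D_c dt), and zero-mean Gaussian draws generated by
the modified (polar) Box-Muller transformation.  Advective and Brownian
contributions are composed additively as displacement vectors: the particle
momentum relaxation time (~ns) is far below the 1e-4 s step, so the
overdamped update replaces the inertial equation of motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOLTZMANN_J_PER_K, M_PER_NM, NM_PER_M


def diffusion_coefficient(temperature: float, viscosity: float,
                          radius_nm: float) -> float:
    """Stokes-Einstein diffusion coefficient, m^2/s.

    D_c = k_B T / (6 pi mu r) for a sphere of radius r in a fluid of
    dynamic viscosity mu at absolute temperature T.
    """
    if radius_nm <= 0:
        raise ValueError("particle radius must be positive")
    if temperature <= 0 or viscosity <= 0:
        raise ValueError("temperature and viscosity must be positive")
    r_m = radius_nm * M_PER_NM
    return BOLTZMANN_J_PER_K * temperature / (6.0 * np.pi * viscosity * r_m)


def brownian_sigma(d_c: float, dt: float) -> float:
    """Per-axis Gaussian step standard deviation sqrt(2 D_c dt), in nm."""
    if d_c < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("time step must be positive")
    return float(np.sqrt(2.0 * d_c * dt) * NM_PER_M)


def polar_gaussian(rng: np.random.Generator, n: int) -> np.ndarray:
    """n standard-normal draws via the polar (modified) Box-Muller method.

    Pairs of uniforms on the unit disc are transformed without trig calls:
    accept (u, v) with s = u^2 + v^2 in (0, 1), then
    u * sqrt(-2 ln s / s) and v * sqrt(-2 ln s / s) are independent N(0,1).
    Rejection is vectorised; the acceptance rate is pi/4.
    """
    out = np.empty(n)
    have = 0
    while have < n:
        need = n - have
        m = max(8, int(need / 1.5) + 8)  # pairs to draw this round
        u = rng.uniform(-1.0, 1.0, size=m)
        v = rng.uniform(-1.0, 1.0, size=m)
        s = u * u + v * v
        ok = (s > 0.0) & (s < 1.0)
        f = np.sqrt(-2.0 * np.log(s[ok]) / s[ok])
        draws = np.concatenate([u[ok] * f, v[ok] * f])
        take = min(need, draws.size)
        out[have: have + take] = draws[:take]
        have += take
    return out


@dataclass
class BrownianStepper:
    """Seedable per-axis Gaussian step generator for one particle.

    sigma is derived from (D_c, dt) as sqrt(2 D_c dt); the same seed always
    reproduces the same trajectory.
    """

    d_c: float                    # m^2/s
    dt: float                     # s
    seed: int | tuple = 0
    sigma: float = field(init=False)
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sigma = brownian_sigma(self.d_c, self.dt)
        self.rng = np.random.default_rng(np.random.SeedSequence(self.seed))

    def step(self) -> np.ndarray:
        """One 3-vector Brownian displacement, nm."""
        if self.sigma == 0.0:
            return np.zeros(3)
        return self.sigma * polar_gaussian(self.rng, 3)

    def steps(self, n: int) -> np.ndarray:
        """(n, 3) block of Brownian displacements, nm."""
        if self.sigma == 0.0:
            return np.zeros((n, 3))
        return self.sigma * polar_gaussian(self.rng, 3 * n).reshape(n, 3)


def particle_stream_seed(master_seed: int, particle_id: int,
                         purpose: int = 0) -> tuple:
    """Derived seed tuple for one particle's random stream.

    Each particle id owns its own stream, so trajectories do not depend on
    how many particles share the simulation.  ``purpose`` separates the
    lumen walk (0) from pore sub-walks (1).
    """
    return (int(master_seed) & 0x7FFFFFFF, int(particle_id), int(purpose))
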