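"""Synthetic fixtures with known ground truth.

Every estimator in this package can be exercised against data whose true
transport coefficient, correlation time or change point is known by
construction:

* Brownian trajectories with a chosen diffusion constant D — per-frame
  displacements are i.i.d. normal with variance 2 D dt per Cartesian
  component, so MSD(t) = 6 D t exactly in expectation.
* Ornstein-Uhlenbeck series with ACF exp(-t/tau) via the exact discrete
  update x' = phi x + sqrt(1-phi^2) sigma xi, phi = exp(-dt/tau).
* Heat-flux series: three independent OU components with covariance
  C(t) = C0 exp(-t/tau), giving the closed-form Green-Kubo conductivity
  kappa_true = C0 tau / (k_B T^2 V).
* Step series with a known change point for equilibration detection.
* A velocity-Verlet Lennard-Jones integrator (NVE or Langevin) producing
  physically coherent frames for RDF and end-to-end workflow tests.

All generators are deterministic from (parameters, seed); one seed per
generator call, streams never shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import Trajectory
from .datamodel import Configuration
from .errors import ValidationError
from .thermal import HeatFluxSeries


def brownian_trajectory(
    n_particles: int,
    D: float,
    dt: float,
    n_frames: int,
    box: float | np.ndarray | None,
    seed: int,
    D_unit: str = "m2/s",
) -> Trajectory:
    """Random walkers with diffusion constant D.

    D in m^2/s (converted to A^2/fs internally) or "reduced" for A^2/fs
    directly; dt in fs.  Coordinates are wrapped into the box when one is
    given, with the trajectory marked wrapped so MSD unwraps them.
    """
    if D < 0:
        raise ValidationError("D must be non-negative")
    rng = np.random.default_rng(seed)
    d_red = D / 1e-5 if D_unit == "m2/s" else D  # A^2/fs
    sigma = math.sqrt(2.0 * d_red * dt)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_particles, 3))
    coords = np.empty((n_frames, n_particles, 3))
    if box is not None:
        box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
        coords[0] = rng.uniform(0.0, box, size=(n_particles, 3))
    else:
        coords[0] = 0.0
    np.cumsum(steps, axis=0, out=coords[1:])
    coords[1:] += coords[0]
    wrapped = box is not None
    if wrapped:
        coords %= box
    return Trajectory(coords, dt=dt, box=box, wrapped=wrapped)


def ou_series(
    mean: float, variance: float, tau: float, dt: float, n: int, seed: int
) -> np.ndarray:
    """Stationary Gauss-Markov series with ACF variance * exp(-t/tau)."""
    if tau <= 0:
        raise ValidationError("tau must be positive")
    rng = np.random.default_rng(seed)
    phi = math.exp(-dt / tau)
    sigma = math.sqrt(variance)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * math.sqrt(1.0 - phi * phi), size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i - 1]
    return x + mean


def heat_flux(
    C0: float,
    tau: float,
    T: float,
    V: float,
    dt: float,
    n: int,
    n_runs: int = 1,
    seed: int = 0,
    k_B: float = 1.0,
) -> tuple[list[HeatFluxSeries], float]:
    """Synthetic heat-current runs with closed-form conductivity.

    Each run holds three independent OU components with autocovariance
    C0 exp(-t/tau); the Green-Kubo integral of that ACF is C0 tau, so
    kappa_true = C0 tau / (k_B T^2 V) is returned alongside the runs.
    """
    runs = []
    for r in range(n_runs):
        J = np.stack([
            ou_series(0.0, C0, tau, dt, n, seed=seed * 1_000 + r * 10 + a)
            for a in range(3)
        ])
        runs.append(HeatFluxSeries(J=J, dt=dt, T=T, V=V, k_B=k_B))
    kappa_true = C0 * tau / (k_B * T**2 * V)
    return runs, kappa_true


def step_series(
    level1: float, level2: float, n1: int, n2: int, noise: float, seed: int
) -> np.ndarray:
    """Two noisy plateaus with a change point at index n1."""
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("both segment lengths must be positive")
    rng = np.random.default_rng(seed)
    x = np.concatenate([np.full(n1, level1), np.full(n2, level2)])
    if noise > 0:
        x = x + rng.normal(0.0, noise, size=n1 + n2)
    return x


# ---------------------------------------------------------------------------
# Lennard-Jones molecular dynamics (velocity Verlet)
# ---------------------------------------------------------------------------

def _lj_forces(x: np.ndarray, box: np.ndarray | None, eps: float, sig: float,
               cutoff: float) -> tuple[float, np.ndarray]:
    n = len(x)
    ii, jj = np.triu_indices(n, k=1)
    d = x[ii] - x[jj]
    if box is not None:
        d -= box * np.round(d / box)
    r2 = (d * d).sum(1)
    mask = r2 < cutoff**2
    ii, jj, d, r2 = ii[mask], jj[mask], d[mask], r2[mask]
    sr6 = (sig**2 / r2) ** 3
    src6 = (sig / cutoff) ** 6
    # truncated-and-shifted potential: continuous energy at the cutoff
    e = float((4.0 * eps * (sr6**2 - sr6 - (src6**2 - src6))).sum())
    fmag = 4.0 * eps * (12.0 * sr6**2 - 6.0 * sr6) / r2  # -dU/dr / r
    forces = np.zeros_like(x)
    fv = fmag[:, None] * d
    np.add.at(forces, ii, fv)
    np.add.at(forces, jj, -fv)
    return e, forces


def lj_md(
    config: Configuration,
    dt: float,
    n_steps: int,
    seed: int,
    thermostat: str = "none",
    T: float = 1.0,
    epsilon: float = 1.0,
    sigma: float = 1.0,
    mass: float = 1.0,
    cutoff: float = 2.5,
    friction: float = 0.1,
    sample_every: int = 1,
    force_limit: float = 1e6,
) -> tuple[Trajectory, np.ndarray]:
    """Velocity-Verlet Lennard-Jones dynamics in reduced units.

    NVE (``thermostat='none'``) conserves total energy to integrator
    tolerance at small dt; the Langevin thermostat (BAOAB splitting) keeps
    the kinetic temperature near T.  Returns (trajectory, total-energy
    series).  Aborts with the frame index if forces blow up (overlap).
    """
    if thermostat not in ("none", "langevin"):
        raise ValidationError(f"unknown thermostat {thermostat!r}")
    rng = np.random.default_rng(seed)
    x = config.coordinates.copy()
    box = config.cell.lengths if config.cell.periodic else None
    n = len(x)
    if thermostat == "langevin" or T > 0:
        v = rng.normal(0.0, math.sqrt(T / mass), size=(n, 3))
        v -= v.mean(axis=0)
    else:
        v = np.zeros((n, 3))
    e_pot, f = _lj_forces(x, box, epsilon, sigma, cutoff)
    if np.abs(f).max() > force_limit:
        raise ValidationError("force blow-up (overlap) at step 0")
    frames, energies, velocities = [], [], []
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * T / mass)
    for step in range(n_steps):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        if thermostat == "langevin":
            v = c1 * v + c2 * rng.normal(size=(n, 3))
        x += 0.5 * dt * v
        if box is not None:
            x %= box
        e_pot, f = _lj_forces(x, box, epsilon, sigma, cutoff)
        if np.abs(f).max() > force_limit:
            raise ValidationError(f"force blow-up (overlap) at step {step}")
        v += 0.5 * dt * f / mass
        if step % sample_every == 0:
            frames.append(x.copy())
            velocities.append(v.copy())
            e_kin = 0.5 * mass * float((v * v).sum())
            energies.append(e_pot + e_kin)
    traj = Trajectory(
        np.array(frames), dt=dt * sample_every, box=box,
        species=[a.element for a in config.atom_set], wrapped=box is not None,
        velocities=np.array(velocities),
    )
    return traj, np.array(energies)
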