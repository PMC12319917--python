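"""Potential-energy-surface toolkit over pluggable energy/gradient engines.

An *engine* is any object exposing ``energy(x)`` and ``gradient(x)`` on a
flat coordinate vector (3N Cartesian for molecules; 2-D for model
surfaces).  Everything here needs only energies and gradients:

* finite-difference Hessians (central differences of gradients),
* mass-weighted harmonic frequencies with Eckart projection of
  translations/rotations,
* rigid-rotor harmonic-oscillator (RRHO) ideal-gas thermochemistry,
* nudged elastic band (improved tangent, optional climbing image),
* transition-state refinement by Newton/eigenvector-following with
  verification that exactly one imaginary mode remains.

Bundled analytic engines (harmonic, Morse, Lennard-Jones cluster,
Mueller-Brown) provide closed-form oracles for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import constants
from .errors import ValidationError


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

class HarmonicEngine:
    """V = 1/2 (x-x0)^T K (x-x0) with an exact analytic Hessian."""

    def __init__(self, K: np.ndarray, x0: np.ndarray | None = None):
        self.K = np.atleast_2d(np.asarray(K, dtype=float))
        self.x0 = (np.zeros(len(self.K)) if x0 is None
                   else np.asarray(x0, dtype=float))

    def energy(self, x):
        d = np.asarray(x, dtype=float) - self.x0
        return 0.5 * float(d @ self.K @ d)

    def gradient(self, x):
        return self.K @ (np.asarray(x, dtype=float) - self.x0)

    def hessian(self, x):
        return self.K.copy()


class MorseDimerEngine:
    """Two atoms on a Morse curve V = De (1 - exp(-a (r - r0)))^2.

    Coordinates are the 6 Cartesian components of the two atoms.  The
    analytic Hessian follows from d2V/dr2 and the chain rule.
    """

    def __init__(self, De: float = 100.0, a: float = 1.5, r0: float = 1.2):
        self.De, self.a, self.r0 = De, a, r0

    def _split(self, x):
        x = np.asarray(x, dtype=float).reshape(2, 3)
        d = x[0] - x[1]
        return x, d, float(np.linalg.norm(d))

    def energy(self, x):
        _, _, r = self._split(x)
        return self.De * (1.0 - math.exp(-self.a * (r - self.r0))) ** 2

    def _dV_dr(self, r):
        e = math.exp(-self.a * (r - self.r0))
        return 2.0 * self.De * self.a * e * (1.0 - e)

    def d2V_dr2(self, r):
        e = math.exp(-self.a * (r - self.r0))
        return 2.0 * self.De * self.a**2 * e * (2.0 * e - 1.0)

    def gradient(self, x):
        _, d, r = self._split(x)
        g = self._dV_dr(r) * d / r
        return np.concatenate([g, -g])

    def hessian(self, x):
        _, d, r = self._split(x)
        u = d / r
        P = np.outer(u, u)
        block = self.d2V_dr2(r) * P + self._dV_dr(r) / r * (np.eye(3) - P)
        H = np.zeros((6, 6))
        H[:3, :3] = H[3:, 3:] = block
        H[:3, 3:] = H[3:, :3] = -block
        return H


class LJClusterEngine:
    """Lennard-Jones cluster in reduced units (3N Cartesian coordinates)."""

    def __init__(self, n_atoms: int, epsilon: float = 1.0, sigma: float = 1.0):
        self.n, self.eps, self.sig = n_atoms, epsilon, sigma

    def energy(self, x):
        x = np.asarray(x, dtype=float).reshape(self.n, 3)
        ii, jj = np.triu_indices(self.n, k=1)
        r2 = ((x[ii] - x[jj]) ** 2).sum(1)
        sr6 = (self.sig**2 / r2) ** 3
        return float((4.0 * self.eps * (sr6**2 - sr6)).sum())

    def gradient(self, x):
        xr = np.asarray(x, dtype=float).reshape(self.n, 3)
        ii, jj = np.triu_indices(self.n, k=1)
        d = xr[ii] - xr[jj]
        r2 = (d * d).sum(1)
        sr6 = (self.sig**2 / r2) ** 3
        dudr_r = 4.0 * self.eps * (-12.0 * sr6**2 + 6.0 * sr6) / r2
        g = np.zeros_like(xr)
        gv = dudr_r[:, None] * d
        np.add.at(g, ii, gv)
        np.add.at(g, jj, -gv)
        return g.ravel()


class MuellerBrownEngine:
    """The Mueller-Brown two-dimensional model surface.

    A standard benchmark with three minima and two saddle points; the
    global minimum is near (-0.558, 1.442) and the saddle between the two
    lowest minima near (-0.822, 0.624).
    """

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, x):
        xx, yy = x
        dx = xx - self.x0
        dy = yy - self.y0
        return self.A * np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2), dx, dy

    def energy(self, x):
        t, _, _ = self._terms(np.asarray(x, dtype=float))
        return float(t.sum())

    def gradient(self, x):
        t, dx, dy = self._terms(np.asarray(x, dtype=float))
        gx = float((t * (2.0 * self.a * dx + self.b * dy)).sum())
        gy = float((t * (self.b * dx + 2.0 * self.c * dy)).sum())
        return np.array([gx, gy])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class VibrationalResult:
    """Frequencies in cm^-1, ascending; imaginary modes are negative and
    render with an "i" suffix (e.g. "458.0i")."""

    frequencies: np.ndarray
    modes: np.ndarray  # mass-weighted normal modes, columns
    n_imaginary: int

    def labels(self) -> list[str]:
        return [f"{abs(f):.1f}i" if f < 0 else f"{f:.1f}" for f in self.frequencies]

    def table(self) -> str:
        return "Frequencies (cm^-1)\n" + "  ".join(self.labels())


@dataclass
class PathResult:
    images: np.ndarray  # (n_images, dof)
    energies: np.ndarray
    highest: int
    converged: bool
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# hessians & frequencies
# ---------------------------------------------------------------------------

def numerical_hessian(engine, x: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Central-difference Hessian from gradients, symmetrized (H+H^T)/2.

    Costs 2 * dof gradient calls (6N for a molecule).
    """
    x = np.asarray(x, dtype=float).ravel()
    dof = len(x)
    H = np.empty((dof, dof))
    for i in range(dof):
        xp = x.copy()
        xp[i] += step
        gp = np.asarray(engine.gradient(xp), dtype=float).ravel()
        xm = x.copy()
        xm[i] -= step
        gm = np.asarray(engine.gradient(xm), dtype=float).ravel()
        if not (np.isfinite(gp).all() and np.isfinite(gm).all()):
            raise ValidationError(
                f"engine failed at displacement of coordinate {i} (step {step})"
            )
        H[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def _eckart_projector(masses: np.ndarray, geometry: np.ndarray) -> np.ndarray:
    """Projector removing mass-weighted translations and rotations."""
    n = len(masses)
    sqm = np.sqrt(np.repeat(masses, 3))
    vecs = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        vecs.append((t.ravel() * sqm))
    com = (geometry * masses[:, None]).sum(0) / masses.sum()
    rel = geometry - com
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        r = np.cross(rel, axis)
        vecs.append(r.ravel() * sqm)
    basis = []
    for v in vecs:
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    P = np.eye(3 * n)
    for b in basis:
        P -= np.outer(b, b)
    return P


def harmonic_frequencies(
    hessian: np.ndarray,
    masses: Sequence[float],
    geometry: np.ndarray | None = None,
    project: bool = True,
) -> VibrationalResult:
    """Mass-weighted eigenproblem -> wavenumbers.

    Hessian in kcal/mol/A^2, masses in amu, geometry (N, 3) in Angstrom.
    Translations (and rotations, when a geometry is supplied) are projected
    out with an Eckart-frame projector; eigenvalues convert via
    nu_tilde = sqrt(lambda)/(2 pi c), negative eigenvalues mapping to
    imaginary (negative) frequencies.
    """
    H = np.asarray(hessian, dtype=float)
    if not np.allclose(H, H.T, atol=1e-8 * max(1.0, np.abs(H).max())):
        raise ValidationError("Hessian must be symmetric")
    masses = np.asarray(masses, dtype=float)
    if (masses <= 0).any():
        raise ValidationError("masses must be positive")
    sqm = np.sqrt(np.repeat(masses, H.shape[0] // len(masses)))
    Hmw = H / np.outer(sqm, sqm)
    n_projected = 0
    if project and geometry is not None and H.shape[0] == 3 * len(masses):
        P = _eckart_projector(masses, np.asarray(geometry, dtype=float))
        Hmw = P @ Hmw @ P
        n_projected = 3 * len(masses) - int(round(np.trace(P)))
    evals, evecs = np.linalg.eigh(Hmw)
    if n_projected:
        # drop the |smallest| eigenvalues belonging to the projected modes
        order = np.argsort(np.abs(evals))
        keep = np.sort(order[n_projected:])
        evals, evecs = evals[keep], evecs[:, keep]
    omega2 = evals * constants.HESSIAN_EIG_TO_S2  # s^-2
    wavenumbers = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (
        2.0 * math.pi * constants.C_LIGHT * 100.0
    )
    order = np.argsort(wavenumbers)
    wavenumbers = wavenumbers[order]
    evecs = evecs[:, order]
    return VibrationalResult(
        frequencies=wavenumbers, modes=evecs,
        n_imaginary=int((wavenumbers < 0).sum()),
    )


def finite_difference_vs_analytic(
    engine, x: np.ndarray, masses: Sequence[float],
    geometry: np.ndarray | None = None, step: float = 0.01,
) -> float:
    """Max |nu_FD - nu_analytic| (cm^-1) between Hessian routes."""
    if not hasattr(engine, "hessian"):
        raise ValidationError("engine has no analytic hessian")
    vib_fd = harmonic_frequencies(numerical_hessian(engine, x, step), masses, geometry)
    vib_an = harmonic_frequencies(np.asarray(engine.hessian(x), dtype=float),
                                  masses, geometry)
    return float(np.abs(vib_fd.frequencies - vib_an.frequencies).max())


# ---------------------------------------------------------------------------
# RRHO thermochemistry
# ---------------------------------------------------------------------------

@dataclass
class ThermoResult:
    """Ideal-gas RRHO thermochemistry, kcal/mol and cal/(mol K)."""

    zpe: float  # kcal/mol
    H: float    # kcal/mol, thermal enthalpy incl. ZPE (relative scale)
    S: float    # cal/(mol K)
    G: float    # kcal/mol
    T: float
    P: float
    n_excluded: int = 0


def rrho_thermo(
    vib: VibrationalResult,
    masses: Sequence[float],
    T: float = 298.15,
    P_atm: float = 1.0,
    linear: bool = False,
    sigma_rot: int = 1,
    inertia_amu_A2: Sequence[float] | None = None,
) -> ThermoResult:
    """Rigid-rotor harmonic-oscillator thermochemistry from frequencies.

    Imaginary and near-zero modes are excluded from the partition functions
    (counted in ``n_excluded``).  Rotational terms use the classical
    rigid-rotor expressions when principal moments of inertia are given;
    otherwise only translational + vibrational contributions are summed,
    which cancels in differences between configurations of equal mass and
    similar rotor.
    """
    R = constants.R_KCAL  # kcal/(mol K)
    freqs = np.asarray(vib.frequencies, dtype=float)
    real = freqs[freqs > 1e-3]
    n_excluded = len(freqs) - len(real)
    zpe = float(0.5 * constants.CM1_TO_KCAL_MOL * real.sum())
    # vibrational thermal energy & entropy
    theta = constants.CM1_TO_KCAL_MOL * real / R  # K
    xs = theta / T
    ex = np.exp(-xs)
    E_vib = float(R * (theta * ex / (1.0 - ex)).sum())
    S_vib = float(R * (xs * ex / (1.0 - ex) - np.log(1.0 - ex)).sum())
    # translation (ideal gas, Sackur-Tetrode)
    M_kg = float(np.sum(masses)) * constants.AMU
    P = P_atm * constants.ATM
    q_trans = ((2.0 * math.pi * M_kg * constants.K_B * T / constants.H_PLANCK**2)
               ** 1.5) * constants.K_B * T / P
    E_trans = 1.5 * R * T
    S_trans = R * (math.log(q_trans) + 2.5)
    # rotation
    E_rot = S_rot = 0.0
    if inertia_amu_A2 is not None:
        I = np.asarray(inertia_amu_A2, dtype=float) * constants.AMU * 1e-20
        I = I[I > 1e-60]
        if linear:
            B = constants.H_PLANCK**2 / (8.0 * math.pi**2 * I[0])
            q_rot = constants.K_B * T / (sigma_rot * B)
            E_rot = R * T
            S_rot = R * (math.log(q_rot) + 1.0)
        else:
            q_rot = (math.sqrt(math.pi) / sigma_rot
                     * (8.0 * math.pi**2 * constants.K_B * T
                        / constants.H_PLANCK**2) ** 1.5 * math.sqrt(np.prod(I)))
            E_rot = 1.5 * R * T
            S_rot = R * (math.log(q_rot) + 1.5)
    H = zpe + E_vib + E_trans + E_rot + R * T  # +RT: H = E + PV
    S = S_vib + S_trans + S_rot
    G = H - T * S
    return ThermoResult(zpe=zpe, H=H, S=S * 1000.0 / 1.0, G=G, T=T, P=P_atm,
                        n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# nudged elastic band
# ---------------------------------------------------------------------------

def _neb_tangent(images: np.ndarray, energies: np.ndarray, i: int) -> np.ndarray:
    """Improved tangent estimate (upwind scheme)."""
    tp = images[i + 1] - images[i]
    tm = images[i] - images[i - 1]
    ep, e0, em = energies[i + 1], energies[i], energies[i - 1]
    if ep > e0 > em:
        tau = tp
    elif ep < e0 < em:
        tau = tm
    else:
        dmax = max(abs(ep - e0), abs(em - e0))
        dmin = min(abs(ep - e0), abs(em - e0))
        tau = tp * dmax + tm * dmin if ep > em else tp * dmin + tm * dmax
    norm = np.linalg.norm(tau)
    return tau / norm if norm > 0 else tau


def neb(
    engine,
    reactant: np.ndarray,
    product: np.ndarray,
    n_images: int = 11,
    k_spring: float = 5.0,
    climbing: bool = True,
    tol: float = 1e-3,
    max_iterations: int = 2000,
    step_size: float = 0.01,
) -> PathResult:
    """Nudged elastic band with improved tangent and optional climbing image.

    Endpoints stay fixed; interior images feel the true force perpendicular
    to the tangent plus a spring force along it.  The climbing image (the
    current highest, once the path is roughly converged) inverts the
    parallel component of the true force and carries no spring force.
    Converged when the maximum projected-force component drops below
    ``tol``; on non-convergence the best path found is returned with
    ``converged=False``.
    """
    if n_images < 3:
        raise ValidationError("need at least 3 images")
    a = np.asarray(reactant, dtype=float).ravel()
    b = np.asarray(product, dtype=float).ravel()
    images = np.array([a + (b - a) * t for t in np.linspace(0.0, 1.0, n_images)])
    velocity = np.zeros_like(images)
    fmax_hist = np.inf
    for it in range(max_iterations):
        energies = np.array([engine.energy(im) for im in images])
        climb_idx = int(np.argmax(energies)) if climbing else -1
        if climb_idx in (0, n_images - 1):
            climb_idx = -1
        forces = np.zeros_like(images)
        fmax = 0.0
        for i in range(1, n_images - 1):
            g = np.asarray(engine.gradient(images[i]), dtype=float).ravel()
            tau = _neb_tangent(images, energies, i)
            f_true = -g
            f_par = (f_true @ tau) * tau
            f_perp = f_true - f_par
            if i == climb_idx and it > 20:
                forces[i] = f_true - 2.0 * f_par
            else:
                spring = k_spring * (
                    np.linalg.norm(images[i + 1] - images[i])
                    - np.linalg.norm(images[i] - images[i - 1])
                ) * tau
                forces[i] = f_perp + spring
            fmax = max(fmax, float(np.abs(f_perp).max()))
        if fmax < tol:
            energies = np.array([engine.energy(im) for im in images])
            return PathResult(images=images, energies=energies,
                              highest=int(np.argmax(energies)), converged=True,
                              n_iterations=it)
        # quick-min: velocity projected on force, zeroed when antiparallel
        for i in range(1, n_images - 1):
            f = forces[i]
            vdotf = velocity[i] @ f
            ff = f @ f
            velocity[i] = (vdotf / ff) * f if (vdotf > 0 and ff > 0) else 0.0
            velocity[i] += step_size * f
            images[i] = images[i] + step_size * velocity[i]
        fmax_hist = fmax
    energies = np.array([engine.energy(im) for im in images])
    return PathResult(images=images, energies=energies,
                      highest=int(np.argmax(energies)), converged=False,
                      n_iterations=max_iterations)


# ---------------------------------------------------------------------------
# transition-state refinement
# ---------------------------------------------------------------------------

@dataclass
class TSResult:
    x: np.ndarray
    gradient_norm: float
    vib: VibrationalResult
    valid: bool
    message: str


def ts_refine(
    engine,
    guess: np.ndarray,
    masses: Sequence[float] | None = None,
    tol: float = 1e-8,
    max_iterations: int = 100,
    hessian_step: float = 0.01,
    max_step: float = 0.2,
) -> TSResult:
    """Newton/eigenvector-following refinement of a first-order saddle.

    Steps along the Newton direction from the numerical Hessian (with the
    lowest mode followed uphill) until the gradient norm drops below
    ``tol``, then verifies that exactly one Hessian eigenvalue is negative.
    Convergence to a minimum or a higher-order saddle is reported as a
    verification failure naming n_imaginary.
    """
    x = np.asarray(guess, dtype=float).ravel().copy()
    dof = len(x)
    if masses is None:
        masses = np.ones(dof)  # unit masses: mode count still meaningful
    for it in range(max_iterations):
        g = np.asarray(engine.gradient(x), dtype=float).ravel()
        if np.abs(g).max() < tol:
            break
        H = numerical_hessian(engine, x, hessian_step)
        evals, evecs = np.linalg.eigh(H)
        # eigenvector following: invert the sign of the lowest-mode
        # curvature so the step maximizes along it, minimizes elsewhere
        coeffs = evecs.T @ g
        step = np.zeros(dof)
        for k in range(dof):
            lam = evals[k]
            if k == 0:
                lam = -abs(lam) if lam > 0 else lam
            if abs(lam) < 1e-12:
                continue
            step -= coeffs[k] / lam * evecs[:, k]
        norm = np.linalg.norm(step)
        if norm > max_step:
            step *= max_step / norm
        x = x + step
    g = np.asarray(engine.gradient(x), dtype=float).ravel()
    H = numerical_hessian(engine, x, hessian_step)
    if dof % 3 == 0 and len(masses) == dof // 3:
        vib = harmonic_frequencies(H, masses, geometry=x.reshape(-1, 3))
    else:
        evals = np.linalg.eigvalsh(H)
        freqs = np.sign(evals) * np.sqrt(np.abs(evals))
        vib = VibrationalResult(frequencies=freqs, modes=np.eye(dof),
                                n_imaginary=int((evals < -1e-10).sum()))
    valid = vib.n_imaginary == 1
    msg = ("verified first-order saddle" if valid else
           f"verification failure: n_imaginary={vib.n_imaginary}, expected 1")
    return TSResult(x=x, gradient_norm=float(np.abs(g).max()), vib=vib,
                    valid=valid, message=msg)
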