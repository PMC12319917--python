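"""Trajectory and time-series statistics.

Time-series side: normalized autocorrelation (ACF) with Bartlett
uncertainty bands, exponential ACF fits, statistical inefficiency
``g = 1 + 2 sum_k (1 - k/n) rho_k`` (truncated at the first negative ACF
value), equilibration detection by maximizing the effective sample count
``(n - t0)/g``, and steady-state averages with ``sqrt(g var / n)`` error
bars.

Transport side: mean squared displacement with multiple time origins
(FFT algorithm), diffusion constants from the linear MSD regime
(``MSD = 6 D t`` in three dimensions), the salt diffusivity
``D_salt = 2 D+ D- / (D+ + D-)``, Nernst-Einstein ionic conductivity
``sigma = N e^2 (D+ + D-) / (V k_B T)`` and the cationic transference
number ``t+ = D+ / (D+ + D-)``.

Structure/thermo side: radial distribution functions with coordination
number integrals, linear thermal-expansion coefficients ``alpha =
dL/(L dT)`` per lattice axis, and the lower convex hull of formation
energies over composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import constants
from .errors import ValidationError


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered frames with a fixed time step.

    coordinates: (n_frames, n_atoms, 3) in Angstrom.  ``wrapped`` marks
    coordinates folded into the periodic box; MSD unwraps them via
    minimum-image frame-to-frame displacements (valid while no atom moves
    more than half a box edge per frame).
    """

    coordinates: np.ndarray
    dt: float  # fs per frame
    species: list[str] | None = None
    box: np.ndarray | None = None  # (3,) Angstrom, orthorhombic
    temperature: float | None = None  # K
    wrapped: bool = False
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (frames, atoms, 3)")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.species is None:
            self.species = ["X"] * self.coordinates.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def volume(self) -> float:
        if self.box is None:
            raise ValidationError("trajectory has no periodic box")
        return float(np.prod(self.box))

    def select(self, species: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s == species])

    def unwrapped(self) -> np.ndarray:
        """Coordinates with periodic jumps removed (minimum-image increments)."""
        if not self.wrapped:
            return self.coordinates
        if self.box is None:
            raise ValidationError("wrapped coordinates need a box to unwrap")
        disp = np.diff(self.coordinates, axis=0)
        disp -= self.box * np.round(disp / self.box)
        out = np.empty_like(self.coordinates)
        out[0] = self.coordinates[0]
        np.cumsum(disp, axis=0, out=out[1:])
        out[1:] += self.coordinates[0]
        return out


@dataclass
class SeriesStats:
    mean: float
    stderr: float
    equilibration_index: int
    acf_time_constant: float  # frames
    statistical_inefficiency: float
    n_effective: float
    interval: tuple[float, float] | None = None  # physical time, same unit as dt
    warning: str | None = None


@dataclass
class TransportResult:
    """Single-ion diffusivities and the electrolyte transport numbers."""

    D: dict[str, float] = field(default_factory=dict)  # m^2/s per species
    D_salt: float | None = None
    sigma: float | None = None  # S/m
    t_plus: float | None = None
    N_ions: int | None = None


@dataclass
class ExpansionResult:
    per_axis: dict[str, float]  # K^-1
    average: float
    fit_range: tuple[float, float]


@dataclass
class HullResult:
    points: np.ndarray  # (n, 2): composition x, formation energy
    vertices: np.ndarray  # indices of lower-hull vertices, ordered by x
    distances: np.ndarray  # vertical distance above the hull, >= 0


# ---------------------------------------------------------------------------
# autocorrelation & equilibration
# ---------------------------------------------------------------------------

def acf(series: Sequence[float], max_lag: int | None = None
        ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation with Bartlett uncertainty band.

    Uses the unbiased-normalization estimator
    ``rho_k = [1/(n-k)] sum (x_t - m)(x_{t+k} - m) / c_0`` computed by FFT.
    Returns (rho[0..max_lag], band[0..max_lag]); rho[0] == 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n // 2
    if n < 2 * max_lag:
        raise ValidationError(f"series length {n} < 2*max_lag ({2 * max_lag})")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0:
        raise ValidationError("constant series has no autocorrelation")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    rho = raw / (n - np.arange(max_lag + 1)) / var
    # Bartlett: se(rho_k) = sqrt((1 + 2 sum_{0<j<k} rho_j^2)/n)
    partial = np.concatenate(([0.0, 0.0], np.cumsum(rho[1:-1] ** 2)))
    band = np.sqrt((1.0 + 2.0 * partial) / n)
    band[0] = 0.0
    return rho, band


def fit_acf_exponential(rho: np.ndarray, dt: float = 1.0
                        ) -> tuple[float, np.ndarray]:
    """Least-squares fit of exp(-t/tau) to the ACF up to its first zero crossing.

    Returns tau (in the unit of ``dt`` per lag) and the fitted curve over
    the fit range.
    """
    neg = np.where(rho <= 0.0)[0]
    stop = int(neg[0]) if len(neg) else len(rho)
    if stop < 2:
        raise ValidationError("no positive-lag ACF data to fit")
    t = np.arange(stop) * dt
    y = rho[:stop]
    tau0 = max(float(np.trapezoid(y) * dt), dt)

    def model(tt, tau):
        return np.exp(-tt / tau)

    popt, _ = curve_fit(model, t, y, p0=[tau0], maxfev=10000)
    tau = float(abs(popt[0]))
    return tau, model(t, tau)


def statistical_inefficiency(series: Sequence[float]) -> float:
    """g = 1 + 2 sum_k (1 - k/n) rho_k, truncated at the first negative rho.

    g >= 1 for positively correlated data; the standard error of the mean
    of a correlated series is sqrt(g var / n).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    rho, _ = acf(x, max_lag=n // 2)
    neg = np.where(rho[1:] < 0.0)[0]
    stop = int(neg[0]) + 1 if len(neg) else len(rho)
    k = np.arange(1, stop)
    g = 1.0 + 2.0 * float(((1.0 - k / n) * rho[1:stop]).sum())
    return max(g, 1e-12)


def detect_equilibration(series: Sequence[float], n_candidates: int = 40) -> int:
    """Truncation point t0 maximizing the effective sample count (n - t0)/g.

    Candidate truncation points are an evenly spaced grid over the first
    80% of the series; production statistics should use frames >= t0.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValidationError("series too short for equilibration detection")
    candidates = np.unique(np.linspace(0, int(0.8 * n), n_candidates, dtype=int))
    best_t0, best_neff = 0, -np.inf
    for t0 in candidates:
        tail = x[t0:]
        if len(tail) < 5 or np.ptp(tail) == 0.0:
            continue
        g = statistical_inefficiency(tail)
        neff = (n - t0) / g
        if neff > best_neff:
            best_neff, best_t0 = neff, int(t0)
    return best_t0


def steady_state_average(series: Sequence[float], dt: float = 1.0) -> SeriesStats:
    """Mean +/- stderr over the detected steady-state interval [t0, n)."""
    x = np.asarray(series, dtype=float)
    t0 = detect_equilibration(x)
    tail = x[t0:]
    g = statistical_inefficiency(tail)
    try:
        rho, _ = acf(tail, max_lag=min(len(tail) // 2, 2000))
        tau, _ = fit_acf_exponential(rho)
    except ValidationError:
        tau = float("nan")
    n_eff = len(tail) / g
    stderr = math.sqrt(g * tail.var(ddof=1) / len(tail))
    warning = "fewer than 10 effective samples" if n_eff < 10 else None
    return SeriesStats(
        mean=float(tail.mean()), stderr=float(stderr), equilibration_index=t0,
        acf_time_constant=tau, statistical_inefficiency=float(g),
        n_effective=float(n_eff), interval=(t0 * dt, len(x) * dt), warning=warning,
    )


# ---------------------------------------------------------------------------
# diffusion & ionic transport
# ---------------------------------------------------------------------------

def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """MSD over all time origins for one coordinate series (n,) via FFT."""
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    autocorr = np.fft.irfft(f * np.conj(f), nfft)[:n]
    q = np.cumsum(x**2)
    sq = q[-1]
    # sum_{t0} [x(t0+t)^2 + x(t0)^2] for each lag t
    s1 = np.empty(n)
    s1[0] = 2.0 * sq
    for_t = np.arange(1, n)
    s1[1:] = 2.0 * sq - q[for_t - 1] - (sq - q[n - for_t - 1])
    counts = n - np.arange(n)
    return s1 / counts - 2.0 * autocorr / counts


def msd(trajectory: Trajectory, species: str | None = None,
        max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared displacement over multiple time origins.

    Returns (lag times in fs, MSD in A^2), averaged over the selected atoms
    and all time origins.  Periodic unwrapping is applied when the
    trajectory is marked wrapped.
    """
    if trajectory.n_frames < 2:
        raise ValidationError("need at least two frames for MSD")
    coords = trajectory.unwrapped()
    if species is not None:
        sel = trajectory.select(species)
        if len(sel) == 0:
            raise ValidationError(f"no atoms of species {species!r}")
        coords = coords[:, sel, :]
    n = coords.shape[0]
    if max_lag is None:
        max_lag = n - 1
    total = np.zeros(n)
    for a in range(coords.shape[1]):
        for d in range(3):
            total += _msd_fft_1d(np.ascontiguousarray(coords[:, a, d]))
    total /= coords.shape[1]
    lags = np.arange(n) * trajectory.dt
    return lags[: max_lag + 1], total[: max_lag + 1]


def diffusion_from_msd(
    lags_fs: np.ndarray,
    msd_A2: np.ndarray,
    fit_window: tuple[float, float] = (0.2, 0.8),
) -> float:
    """D (m^2/s) from the slope of the linear MSD regime: D = slope/6.

    ``fit_window`` is the (lo, hi) fraction of the maximum lag used for the
    least-squares line; the default 20-80% skips the short-time ballistic
    regime and the noisy long-lag tail.
    """
    lo = int(fit_window[0] * (len(lags_fs) - 1))
    hi = max(int(fit_window[1] * (len(lags_fs) - 1)), lo + 2)
    if hi > len(lags_fs):
        raise ValidationError("fit window outside available lags")
    slope = np.polyfit(lags_fs[lo:hi], msd_A2[lo:hi], 1)[0]  # A^2/fs
    return float(slope / 6.0 * constants.A2_PER_FS_TO_M2_PER_S)


def salt_diffusivity(D_plus: float, D_minus: float) -> float:
    """Salt diffusion constant 2 D+ D- / (D+ + D-)."""
    if D_plus < 0 or D_minus < 0:
        raise ValidationError("diffusivities must be non-negative")
    if D_plus + D_minus == 0:
        raise ValidationError("at least one diffusivity must be positive")
    return 2.0 * D_plus * D_minus / (D_plus + D_minus)


def ne_conductivity(N_ions: int, V_A3: float, T: float,
                    D_plus: float, D_minus: float) -> float:
    """Nernst-Einstein conductivity sigma = N e^2 (D+ + D-)/(V k_B T), S/m.

    Ignores ion-ion correlations; V in A^3, D in m^2/s.
    """
    if V_A3 <= 0 or T <= 0:
        raise ValidationError("volume and temperature must be positive")
    V = V_A3 * 1e-30  # m^3
    return float(N_ions * constants.E_CHARGE**2 * (D_plus + D_minus)
                 / (V * constants.K_B * T))


def transference_number(D_plus: float, D_minus: float) -> float:
    """Cationic transference number t+ = D+ / (D+ + D-)."""
    if D_plus + D_minus <= 0:
        raise ValidationError("D+ + D- must be positive")
    return float(D_plus / (D_plus + D_minus))


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

def rdf_cn(
    trajectory: Trajectory,
    species_pair: tuple[str, str],
    r_max: float,
    bins: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """g(r) and coordination number CN(r) for a species pair.

    Standard shell normalization under minimum image; CN(r) integrates the
    partner-species density: CN(r) = 4 pi rho_b int_0^r g(s) s^2 ds.
    Returns (bin centres, g, CN).
    """
    if trajectory.box is None:
        raise ValidationError("rdf needs a periodic box")
    box = trajectory.box
    if r_max > box.min() / 2.0 + 1e-9:
        raise ValidationError(
            f"r_max {r_max} exceeds half the smallest box edge ({box.min() / 2:.3f})"
        )
    sel_a = trajectory.select(species_pair[0])
    sel_b = trajectory.select(species_pair[1])
    same = species_pair[0] == species_pair[1]
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValidationError("empty species selection")
    edges = np.linspace(0.0, r_max, bins + 1)
    hist = np.zeros(bins)
    for frame in trajectory.coordinates:
        d = frame[sel_a][:, None, :] - frame[sel_b][None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(-1))
        if same:
            iu = np.triu_indices(len(sel_a), k=1)
            r = r[iu]
        else:
            r = r.ravel()
        hist += np.histogram(r, bins=edges)[0] * (2.0 if same else 1.0)
    n_frames = trajectory.n_frames
    V = trajectory.volume
    rho_b = len(sel_b) / V
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = shell * rho_b * len(sel_a) * n_frames
    if same:
        ideal = shell * (len(sel_a) - 1) / V * len(sel_a) * n_frames
    g = hist / ideal
    centres = 0.5 * (edges[1:] + edges[:-1])
    dens = rho_b if not same else (len(sel_b) - 1) / V
    cn = 4.0 * np.pi * dens * np.cumsum(g * centres**2 * np.diff(edges))
    return centres, g, cn


def first_shell_cn(centres: np.ndarray, g: np.ndarray, cn: np.ndarray
                   ) -> tuple[float, float]:
    """Coordination number at the first minimum of smoothed g(r).

    Smoothing is a window-3 moving average; returns (r_min, CN(r_min)).
    """
    if len(g) < 5:
        raise ValidationError("too few bins")
    gs = np.convolve(g, np.ones(3) / 3.0, mode="same")
    peak = int(np.argmax(gs))
    for i in range(peak + 1, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] <= gs[i + 1]:
            return float(centres[i]), float(cn[i])
    return float(centres[-1]), float(cn[-1])


# ---------------------------------------------------------------------------
# thermal expansion & convex hull
# ---------------------------------------------------------------------------

def expansion_coefficients(
    temperatures: Sequence[float],
    lattice_lengths: dict[str, Sequence[float]],
    T_ref: float | None = None,
) -> ExpansionResult:
    """Per-axis linear expansion alpha = d(L/L_ref)/dT and their mean.

    ``lattice_lengths`` maps axis labels (a, b, c) to lengths at each
    temperature; alpha is the least-squares slope of L(T)/L(T_ref) vs T.
    """
    T = np.asarray(temperatures, dtype=float)
    if len(T) < 2:
        raise ValidationError("need lattice constants at >= 2 temperatures")
    if T_ref is None:
        T_ref = float(T.min())
    i_ref = int(np.argmin(np.abs(T - T_ref)))
    per_axis = {}
    for axis, lengths in lattice_lengths.items():
        L = np.asarray(lengths, dtype=float)
        if len(L) != len(T):
            raise ValidationError(f"axis {axis!r}: length/temperature mismatch")
        per_axis[axis] = float(np.polyfit(T, L / L[i_ref], 1)[0])
    avg = float(np.mean(list(per_axis.values())))
    return ExpansionResult(per_axis, avg, (float(T.min()), float(T.max())))


def average_expansion(per_axis: Sequence[float]) -> float:
    """Arithmetic mean of per-axis expansion coefficients."""
    return float(np.mean(np.asarray(per_axis, dtype=float)))


def lower_hull(points: Sequence[tuple[float, float]]) -> HullResult:
    """Lower convex hull of (composition, formation energy) points.

    Duplicate compositions keep the lower energy.  Each point's distance is
    its vertical height above the hull (0 for hull vertices).  Stable
    phases are exactly the hull vertices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (x, E) pairs")
    # deduplicate x keeping the lower E
    best: dict[float, int] = {}
    for i, (x, e) in enumerate(pts):
        if x not in best or e < pts[best[x], 1]:
            best[x] = i
    keep = sorted(best.values(), key=lambda i: (pts[i, 0], pts[i, 1]))
    if len(keep) < 2:
        raise ValidationError("need at least two distinct compositions")
    xs = pts[keep, 0]
    es = pts[keep, 1]
    # Andrew monotone chain, lower branch
    hull: list[int] = []
    for i in range(len(keep)):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = (xs[hull[-2]], es[hull[-2]]), (xs[hull[-1]], es[hull[-1]])
            if (x2 - x1) * (es[i] - y1) - (y2 - y1) * (xs[i] - x1) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    vert_idx = np.array([keep[i] for i in hull])
    hx, he = pts[vert_idx, 0], pts[vert_idx, 1]
    dist = np.empty(len(pts))
    for i, (x, e) in enumerate(pts):
        e_hull = float(np.interp(x, hx, he))
        dist[i] = max(e - e_hull, 0.0)
    dist[vert_idx] = 0.0
    return HullResult(points=pts, vertices=vert_idx, distances=dist)
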