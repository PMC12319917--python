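"""Equilibrium thermal-conductivity estimators.

Three routes from the same equilibrium heat-current series J(t):

* Green-Kubo: kappa^ab = 1/(k_B T^2 V) * int_0^t <J^a(0) J^b(tau)> dtau,
  with the plateau extracted by fitting kappa_inf (1 - exp(-t/tau_f)) to
  the running integral.
* Helfand moments: G^a(t) = int_0^t J^a dtau; the ensemble-averaged square
  M^ab(t) = <(G^a(t)-G^a(0)) (G^b(t)-G^b(0))> grows linearly with slope
  2 k_B T^2 V kappa^ab, so kappa is the fitted slope / (2 k_B T^2 V).
* Helfand derivative: kappa from the plateau of dM/dt / (2 k_B T^2 V).

The "ensemble" in M is realized by splitting each run into non-overlapping
segments re-originated at G = 0, pooled across independent runs.  All
estimators accept reduced units (k_B = 1) or SI-convertible molecular
units; conversion happens once, at estimate construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .errors import ValidationError


@dataclass
class HeatFluxSeries:
    """Heat-current components per Cartesian axis, plus T, V and k_B.

    J has shape (n_components, n_frames); reduced units use k_B = 1.
    """

    J: np.ndarray
    dt: float
    T: float
    V: float
    k_B: float = 1.0

    def __post_init__(self) -> None:
        self.J = np.atleast_2d(np.asarray(self.J, dtype=float))
        if self.J.shape[0] < 2:
            raise ValidationError("need >= 2 Cartesian flux components")
        if self.T <= 0 or self.V <= 0:
            raise ValidationError("temperature and volume must be positive")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")

    @property
    def prefactor(self) -> float:
        """1/(k_B T^2 V)."""
        return 1.0 / (self.k_B * self.T**2 * self.V)


@dataclass
class KappaEstimate:
    kappa: float
    method: str  # green-kubo | helfand-moment | helfand-derivative
    fit_window: tuple[float, float]
    uncertainty: float = 0.0
    per_run: list = field(default_factory=list)
    flagged: bool = False
    note: str | None = None


def _flux_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unnormalized multi-origin autocovariance <J(0) J(t)> via FFT."""
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return raw / (n - np.arange(max_lag + 1))


def gk_running_integral(flux: HeatFluxSeries, max_lag: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Running Green-Kubo integral kappa(t) per diagonal component.

    Returns (times, kappa[t] per component) where kappa^aa(t) is the
    cumulative trapezoid of the flux autocovariance times 1/(k_B T^2 V).
    """
    n = flux.J.shape[1]
    if n < 2 * max_lag:
        raise ValidationError(f"series length {n} < 2*max_lag ({2 * max_lag})")
    if np.allclose(flux.J.var(axis=1), 0.0):
        raise ValidationError("zero-variance flux has no Green-Kubo integral")
    times = np.arange(max_lag + 1) * flux.dt
    out = np.empty((flux.J.shape[0], max_lag + 1))
    for a, comp in enumerate(flux.J):
        c = _flux_acf(comp, max_lag)
        out[a] = np.concatenate(
            ([0.0], cumulative_trapezoid(c, dx=flux.dt))
        ) * flux.prefactor
    return times, out


def kappa_gk(times: np.ndarray, running: np.ndarray) -> KappaEstimate:
    """Plateau of the running GK integral via a saturating-exponential fit.

    Fits kappa_inf (1 - exp(-t/tau_f)) to each component's running
    integral and averages components for the isotropic estimate; the
    uncertainty is the inter-component scatter (standard error).
    """
    running = np.atleast_2d(running)
    kinfs = []
    flagged = False

    def model(t, kinf, tauf):
        # clipped exponent: the optimizer may probe tiny tau values
        return kinf * (1.0 - np.exp(-np.clip(t / tauf, 0.0, 700.0)))

    for comp in running:
        k0 = float(np.mean(comp[int(0.8 * len(comp)):]))
        tau0 = max(times[-1] / 10.0, times[1] if len(times) > 1 else 1.0)
        try:
            popt, _ = curve_fit(model, times, comp, p0=[k0, tau0], maxfev=20000)
            kinf, tauf = popt
            if not np.isfinite(kinf) or tauf > 100 * times[-1]:
                flagged = True
                kinf = k0
        except RuntimeError:
            flagged = True
            kinf = k0
        kinfs.append(float(kinf))
    kappa = float(np.mean(kinfs))
    unc = float(np.std(kinfs, ddof=1) / np.sqrt(len(kinfs))) if len(kinfs) > 1 else 0.0
    return KappaEstimate(
        kappa=kappa, method="green-kubo", fit_window=(float(times[0]), float(times[-1])),
        uncertainty=unc, per_run=kinfs, flagged=flagged,
        note="saturating-exponential fit did not converge" if flagged else None,
    )


def helfand_moments(
    flux: HeatFluxSeries,
    segment_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Helfand moments G(t) and the ensemble-averaged M(t).

    G^a(t) is the cumulative trapezoid of J^a.  The series is split into
    non-overlapping segments of ``segment_length`` frames, each
    re-originated at G = 0; M^aa(t) averages (G(t) - G(0))^2 over segments
    (the ensemble) for each diagonal component, and the result is the mean
    over components.

    Returns (times, M[t]) with M averaged over diagonal components.
    """
    n = flux.J.shape[1]
    if segment_length is None:
        segment_length = max(n // 10, 2)
    n_seg = n // segment_length
    if n_seg < 1:
        raise ValidationError("series shorter than one segment")
    M = np.zeros(segment_length)
    count = 0
    for comp in flux.J:
        for s in range(n_seg):
            seg = comp[s * segment_length : (s + 1) * segment_length]
            G = np.concatenate(([0.0], cumulative_trapezoid(seg, dx=flux.dt)))
            M += G**2
            count += 1
    M /= count
    times = np.arange(segment_length) * flux.dt
    return times, M


def kappa_helfand(
    times: np.ndarray,
    M: np.ndarray,
    T: float,
    V: float,
    k_B: float = 1.0,
    fit_window: tuple[float, float] = (0.5, 1.0),
) -> KappaEstimate:
    """kappa from the slope of M(t): slope / (2 k_B T^2 V).

    The default window is the latter half of the available times, where
    M(t) has reached its linear regime.
    """
    lo = int(fit_window[0] * (len(times) - 1))
    hi = int(fit_window[1] * (len(times) - 1)) + 1
    if hi - lo < 2:
        raise ValidationError("fit window too narrow")
    slope = float(np.polyfit(times[lo:hi], M[lo:hi], 1)[0])
    kappa = slope / (2.0 * k_B * T**2 * V)
    return KappaEstimate(
        kappa=float(kappa), method="helfand-moment",
        fit_window=(float(times[lo]), float(times[hi - 1])),
        flagged=slope < 0,
        note="negative M(t) slope" if slope < 0 else None,
    )


def kappa_helfand_derivative(
    times: np.ndarray,
    M: np.ndarray,
    T: float,
    V: float,
    k_B: float = 1.0,
    smooth_window: int | None = None,
) -> KappaEstimate:
    """kappa from the plateau of dM/dt / (2 k_B T^2 V).

    M is smoothed with a moving average before numerical differentiation;
    the plateau is the mean of the derivative over the last half of the
    series.  A monotone drift of more than 20% across the plateau region
    flags the estimate.
    """
    if len(times) < 10:
        raise ValidationError("series too short to differentiate")
    if smooth_window is None:
        smooth_window = max(len(M) // 50, 1)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        Ms = np.convolve(M, kernel, mode="valid")
        ts = times[: len(Ms)]
    else:
        Ms, ts = M, times
    dMdt = np.gradient(Ms, ts)
    half = dMdt[len(dMdt) // 2 :]
    plateau = float(np.mean(half))
    q1 = float(np.mean(half[: len(half) // 2]))
    q2 = float(np.mean(half[len(half) // 2 :]))
    drift = abs(q2 - q1) / abs(plateau) if plateau != 0 else np.inf
    flagged = drift > 0.20
    kappa = plateau / (2.0 * k_B * T**2 * V)
    return KappaEstimate(
        kappa=float(kappa), method="helfand-derivative",
        fit_window=(float(ts[len(ts) // 2]), float(ts[-1])),
        flagged=flagged,
        note=f"derivative drift {drift:.1%} exceeds 20%" if flagged else None,
    )


def estimate_all(
    runs: Sequence[HeatFluxSeries],
    max_lag: int | None = None,
    segment_length: int | None = None,
) -> dict[str, KappaEstimate]:
    """All three estimators over independent runs; per-run scatter as error.

    Each run is estimated separately; the reported kappa is the mean over
    runs and the uncertainty the standard error of that mean.
    """
    results: dict[str, list[float]] = {"green-kubo": [], "helfand-moment": [],
                                       "helfand-derivative": []}
    windows: dict[str, tuple] = {}
    if max_lag is None or segment_length is None:
        # scale windows to the flux correlation time so the GK integral is
        # fit where it saturates and M(t) where it is linear
        from .analysis import acf, fit_acf_exponential

        flux0 = runs[0]
        taus = []
        for comp in flux0.J:
            try:
                rho, _ = acf(comp, max_lag=min(flux0.J.shape[1] // 2, 2000))
                taus.append(fit_acf_exponential(rho)[0])
            except ValidationError:
                continue
        tau_frames = float(np.mean(taus)) if taus else 10.0
        n0 = flux0.J.shape[1]
        if max_lag is None:
            max_lag = int(min(n0 // 2, max(20, round(20 * tau_frames))))
        if segment_length is None:
            segment_length = int(min(n0 // 4, max(50, round(100 * tau_frames))))
    for flux in runs:
        n = flux.J.shape[1]
        lag = min(max_lag, n // 2)
        t, run_k = gk_running_integral(flux, lag)
        est = kappa_gk(t, run_k)
        results["green-kubo"].append(est.kappa)
        windows["green-kubo"] = est.fit_window
        tm, M = helfand_moments(flux, segment_length)
        est_m = kappa_helfand(tm, M, flux.T, flux.V, flux.k_B)
        results["helfand-moment"].append(est_m.kappa)
        windows["helfand-moment"] = est_m.fit_window
        est_d = kappa_helfand_derivative(tm, M, flux.T, flux.V, flux.k_B)
        results["helfand-derivative"].append(est_d.kappa)
        windows["helfand-derivative"] = est_d.fit_window
    out = {}
    for method, vals in results.items():
        unc = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[method] = KappaEstimate(
            kappa=float(np.mean(vals)), method=method, fit_window=windows[method],
            uncertainty=unc, per_run=[float(v) for v in vals],
        )
    return out
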