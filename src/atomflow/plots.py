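"""Diagnostic plots written as image files.

Matplotlib is imported lazily with the Agg backend so plotting works in
headless batch jobs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_series_with_mean(series, stats, path, dt: float = 1.0,
                          ylabel: str = "density (g/ml)") -> None:
    """Line plot of a state variable vs time with the steady-state mean.

    The solid horizontal line spans the detected steady-state interval;
    earlier (discarded) frames stay visible for a quick equilibration check.
    """
    plt = _pyplot()
    series = np.asarray(series, dtype=float)
    t = np.arange(len(series)) * dt
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(t, series, lw=0.6, color="tab:red")
    t0 = stats.equilibration_index
    ax.hlines(stats.mean, t0 * dt, t[-1], color="black", lw=1.5,
              label=f"mean {stats.mean:.4g} +/- {stats.stderr:.2g}")
    ax.axvline(t0 * dt, color="gray", ls=":", lw=1)
    ax.set_xlabel("time")
    ax.set_ylabel(ylabel)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_acf_with_fit(rho, band, tau, path, dt: float = 1.0) -> None:
    """ACF with shaded error bounds and the best exponential fit."""
    plt = _pyplot()
    rho = np.asarray(rho, dtype=float)
    t = np.arange(len(rho)) * dt
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(t, rho, color="tab:red", lw=1, label="ACF")
    ax.fill_between(t, rho - band, rho + band, color="tab:red", alpha=0.2)
    ax.plot(t, np.exp(-t / tau), color="dimgray", lw=1.5,
            label=f"exp fit, tau = {tau:.3g}")
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("lag")
    ax.set_ylabel("autocorrelation")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_kappa_running(times, running, estimate, path) -> None:
    """Running Green-Kubo integrals per component with the fitted plateau."""
    plt = _pyplot()
    running = np.atleast_2d(running)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for i, comp in enumerate(running):
        ax.plot(times, comp, lw=0.8, label=f"component {('xyz'[i] if i < 3 else i)}")
    ax.axhline(estimate.kappa, color="black", lw=1.5,
               label=f"kappa = {estimate.kappa:.3g}")
    ax.set_xlabel("upper integration limit")
    ax.set_ylabel("running kappa")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_helfand_moment(times, M, estimate, path) -> None:
    """M(t) with the linear fit whose slope gives the conductivity."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(times, M, lw=0.8, color="tab:blue", label="M(t)")
    lo, hi = estimate.fit_window
    sel = (times >= lo) & (times <= hi)
    if sel.sum() >= 2:
        coef = np.polyfit(times[sel], np.asarray(M)[sel], 1)
        ax.plot(times[sel], np.polyval(coef, times[sel]), color="black",
                lw=1.5, label=f"fit, kappa = {estimate.kappa:.3g}")
    ax.set_xlabel("time")
    ax.set_ylabel("Helfand moment")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
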