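"""Thin plotting helpers for the standard experiment outputs.

Convenience only — every figure is rendered from the tidy tables the
experiments emit, so any plotting stack can be substituted.  Requires
matplotlib (optional dependency)."""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib.pyplot as plt

    return plt


def plot_trace(trace, ax=None):
    """Hit and false-alarm fractions of one replay trace over time."""
    plt = _plt()
    ax = ax or plt.gca()
    ax.plot(trace.t, trace.m / trace.M, label="hits m/M", color="C0")
    ax.plot(trace.t, trace.n / (trace.N - trace.M), label="false alarms", color="C3")
    ax.set(xlabel="time step", ylabel="fraction", ylim=(-0.02, 1.02))
    ax.legend(frameon=False)
    return ax


def plot_success_curve(curve, ax=None, **kw):
    """Replay success rate with binomial error band."""
    plt = _plt()
    ax = ax or plt.gca()
    se = curve.stderr()
    ax.plot(curve.t, curve.rho, **kw)
    ax.fill_between(curve.t, curve.rho - se, curve.rho + se, alpha=0.2)
    ax.set(xlabel="time step", ylabel=r"success rate $\varrho_t$", ylim=(-0.02, 1.02))
    return ax


def plot_phase_diagram(frame, ax=None):
    """Heatmap of a tidy (phi, theta, value) phase-diagram table."""
    plt = _plt()
    ax = ax or plt.gca()
    pivot = frame.pivot(index="theta", columns="phi", values="value")
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, vmin=0, vmax=1)
    plt.colorbar(im, ax=ax, label="value")
    ax.set(xlabel=r"mean coding ratio", ylabel=r"threshold $\theta$")
    return ax


def plot_capacity_curve(curve, ax=None, **kw):
    """T versus P on log-log axes with the fitted power law, if any."""
    plt = _plt()
    ax = ax or plt.gca()
    ax.loglog(curve.P, np.maximum(curve.T, 0.5), "o", **kw)
    if curve.alpha is not None and curve.fit_mask is not None and curve.fit_mask.any():
        Pfit = curve.P[curve.fit_mask]
        A = curve.Q * curve.Pc**curve.alpha if curve.Pc else None
        if A:
            ax.loglog(Pfit, A * Pfit.astype(float) ** -curve.alpha, "--",
                      label=rf"$T\propto P^{{-{curve.alpha:.2f}}}$")
            ax.legend(frameon=False)
    ax.set(xlabel="stored associations P", ylabel="max retrievable length T")
    return ax
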