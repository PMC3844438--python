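"""Two-variable mean-field replay dynamics with instantaneous feedback inhibition.

The macroscopic state of the network during replay of a stored sequence is
summarized by the number of *hits* ``m_t`` (neurons of the target pattern that
fire) and *false alarms* ``n_t`` (neurons outside the target pattern that
fire).  For large networks the total synaptic input to a neuron is
approximately Gaussian, with moments

    mu_on   = cm*m + cm*varsigma*n
    s2_on   = cm*m*(1-cm) + cm*varsigma*n*(1 - cm*varsigma + V2*cm*varsigma*(n-1))
    mu_off  = cm*varsigma*(m+n)
    s2_off  = cm*varsigma*(m+n)*(1 - cm*varsigma + V2*cm*varsigma*(m+n-1))

where ``varsigma`` is the potentiation probability, ``cm`` the morphological
connectivity and ``V2`` the squared variation coefficient of the per-neuron
potentiation probability (learning-induced correlations).  The map advances

    m_{t+1} = M_{t+1}      * Phi((mu_on  - theta_eff)/s_on)
    n_{t+1} = (N - M_{t+1})* Phi((mu_off - theta_eff)/s_off)

with ``theta_eff = theta + h(m_t + n_t)``: instantaneous feedback inhibition
raises the firing threshold in proportion to the current total activity,
either linearly, ``h(x) = b*x`` with ``b = cm*varsigma``, or through a
supralinear sigmoid that stays below ``b*x`` for activities under the
operating point ``phi0*N`` and is exactly linear above it.

Hits and false alarms are propagated as real numbers (expectation values);
pattern sizes enter as real-valued ``M_t = f_t*N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .connectivity import schedule_stats, varsigma_exact
from .distributions import PatternSizeVector

__all__ = [
    "MeanFieldParams",
    "MeanFieldTrace",
    "input_moments",
    "inhibition",
    "step",
    "run_replay",
    "run_replay_ensemble",
    "params_for_phi",
]


@dataclass(frozen=True)
class MeanFieldParams:
    """Parameters of the mean-field replay map.

    b defaults to cm*varsigma (the balanced inhibitory weight used throughout);
    phi0 sets the operating point phi0*N of the nonlinear inhibition and is
    required only in that mode.
    """

    N: int
    cm: float
    theta: float
    varsigma: float
    V2: float = 0.0
    b: float | None = None
    inhibition: str = "linear"  # "linear" | "nonlinear"
    phi0: float | None = None

    def __post_init__(self):
        if not 0.0 < self.cm <= 1.0:
            raise ValueError("require 0 < cm <= 1")
        if self.theta < 0.0:
            raise ValueError("require theta >= 0")
        if not 0.0 <= self.varsigma <= 1.0:
            raise ValueError("require 0 <= varsigma <= 1")
        if self.V2 < 0.0:
            raise ValueError("require V2 >= 0")
        if self.inhibition not in ("linear", "nonlinear"):
            raise ValueError(f"unknown inhibition mode {self.inhibition!r}")
        if self.b is None:
            object.__setattr__(self, "b", self.cm * self.varsigma)
        if self.inhibition == "nonlinear":
            if self.phi0 is None:
                raise ValueError("nonlinear inhibition requires phi0")
            lam = 1e-4 / self.phi0
            if lam * self.phi0 * self.N <= 1.0:
                raise ValueError(
                    "nonlinear inhibition undefined: lambda*phi0*N must exceed 1"
                )


@dataclass
class MeanFieldTrace:
    """Tidy record of one mean-field replay run (index t = 0..Q)."""

    t: np.ndarray
    M: np.ndarray
    m: np.ndarray
    n: np.ndarray
    gamma: np.ndarray
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "M": self.M, "m": self.m, "n": self.n, "gamma": self.gamma}
        )


def input_moments(m, n, p: MeanFieldParams):
    """Gaussian input moments (mu_on, s2_on, mu_off, s2_off) at state (m, n).

    Array-valued m, n broadcast elementwise.  The V2 terms capture the
    covariance of potentiated inputs induced by shared activation schedules;
    note they enter only through the noise population of the On moments.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    cs = p.cm * p.varsigma
    x = m + n
    mu_on = p.cm * m + cs * n
    s2_on = p.cm * m * (1.0 - p.cm) + cs * n * (1.0 - cs + p.V2 * cs * (n - 1.0))
    mu_off = cs * x
    s2_off = cs * x * (1.0 - cs + p.V2 * cs * (x - 1.0))
    return mu_on, np.maximum(s2_on, 0.0), mu_off, np.maximum(s2_off, 0.0)


def _nonlinear_constants(p: MeanFieldParams) -> tuple[float, float, float]:
    """(kappa, nu, lam) of the sigmoid branch, chosen so h matches value and
    slope b of the linear branch at the operating point x = phi0*N."""
    lam = 1e-4 / p.phi0
    xop = p.phi0 * p.N
    kappa = p.b * lam * xop**2 / (lam * xop - 1.0)
    nu = xop - math.log(lam * xop - 1.0) / lam
    return kappa, nu, lam


def inhibition(x, p: MeanFieldParams):
    """Inhibitory threshold shift h(x) for total activity x = m + n."""
    x = np.asarray(x, dtype=float)
    if p.inhibition == "linear":
        return p.b * x
    kappa, nu, lam = _nonlinear_constants(p)
    xop = p.phi0 * p.N
    sig = kappa / (1.0 + np.exp(-lam * (x - nu)))
    return np.where(x <= xop, sig, p.b * x)


def _phi_cdf(mu, sigma2, theta_eff):
    """Phi((mu - theta_eff)/sigma) with the zero-variance limit taken as a hard
    threshold: 1 if mu > theta_eff, 1/2 at equality, 0 below."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    diff = mu - np.asarray(theta_eff, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0.0, diff / np.sqrt(np.where(sigma2 > 0, sigma2, 1.0)), 0.0)
    hard = np.where(diff > 0.0, 1.0, np.where(diff < 0.0, 0.0, 0.5))
    return np.where(sigma2 > 0.0, ndtr(z), hard)


def step(m, n, M_next, p: MeanFieldParams):
    """One mean-field update; returns (m_next, n_next) for pattern size M_next."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    M_next = np.asarray(M_next, dtype=float)
    theta_eff = p.theta + inhibition(m + n, p)
    mu_on, s2_on, mu_off, s2_off = input_moments(m, n, p)
    m_next = M_next * _phi_cdf(mu_on, s2_on, theta_eff)
    n_next = (p.N - M_next) * _phi_cdf(mu_off, s2_off, theta_eff)
    return m_next, n_next


def params_for_phi(
    phi: PatternSizeVector,
    cm: float,
    theta: float,
    inhibition_mode: str = "linear",
    phi0: float | None = None,
    b: float | None = None,
) -> MeanFieldParams:
    """Mean-field parameters with varsigma and V2 realized from a specific phi.

    The potentiation probability fed to the map is the exact varsigma of the
    sampled vector (not the ensemble mean), and b = cm*varsigma follows suit.
    """
    st = schedule_stats(phi)
    return MeanFieldParams(
        N=phi.N,
        cm=cm,
        theta=theta,
        varsigma=st.varsigma,
        V2=st.V2,
        b=b,
        inhibition=inhibition_mode,
        phi0=phi0,
    )


def run_replay(
    phi: PatternSizeVector,
    p: MeanFieldParams,
    Q: int,
    m0: float | None = None,
    n0: float = 0.0,
    integer_sizes: bool = False,
) -> MeanFieldTrace:
    """Iterate the mean-field map along the first Q associations of phi.

    The run starts from the intact first pattern (m_0 = M_0, n_0 = 0) unless a
    partial cue is given, and records the retrieval quality
    Gamma_t = m_t/M_t - n_t/(N - M_t) at every step.
    """
    if Q > phi.P:
        raise ValueError("Q must not exceed the number of stored associations")
    M = phi.sizes(integer=integer_sizes)[: Q + 1].astype(float)
    m = np.empty(Q + 1)
    n = np.empty(Q + 1)
    m[0] = M[0] if m0 is None else m0
    n[0] = n0
    for t in range(Q):
        m[t + 1], n[t + 1] = step(m[t], n[t], M[t + 1], p)
    gamma = m / M - n / (p.N - M)
    return MeanFieldTrace(t=np.arange(Q + 1), M=M, m=m, n=n, gamma=gamma, N=p.N)


def run_replay_ensemble(
    M_mat: np.ndarray,
    N: int,
    cm: float,
    theta: float,
    varsigma: np.ndarray,
    V2: np.ndarray,
    Q: int,
    b: np.ndarray | None = None,
    inhibition_mode: str = "linear",
    phi0: float | None = None,
):
    """Vectorized replay of R realizations at once.

    M_mat is (R, >= Q+1) of real-valued pattern sizes; varsigma, V2 (and b,
    default cm*varsigma) are per-realization scalars.  Returns (m, n, gamma)
    arrays of shape (R, Q+1).  Semantically identical to looping
    :func:`run_replay` over rows; used by the ensemble experiments where the
    per-row map would dominate runtime.
    """
    M_mat = np.asarray(M_mat, dtype=float)
    R = M_mat.shape[0]
    varsigma = np.broadcast_to(np.asarray(varsigma, dtype=float), (R,))
    V2 = np.broadcast_to(np.asarray(V2, dtype=float), (R,))
    b = cm * varsigma if b is None else np.broadcast_to(np.asarray(b, float), (R,))
    cs = cm * varsigma

    if inhibition_mode == "nonlinear":
        if phi0 is None:
            raise ValueError("nonlinear inhibition requires phi0")
        lam = 1e-4 / phi0
        xop = phi0 * N
        if lam * xop <= 1.0:
            raise ValueError("nonlinear inhibition undefined: lambda*phi0*N <= 1")
        kappa = b * lam * xop**2 / (lam * xop - 1.0)
        nu = xop - math.log(lam * xop - 1.0) / lam

    m = np.empty((R, Q + 1))
    n = np.empty((R, Q + 1))
    m[:, 0] = M_mat[:, 0]
    n[:, 0] = 0.0
    for t in range(Q):
        mt, nt = m[:, t], n[:, t]
        x = mt + nt
        if inhibition_mode == "linear":
            h = b * x
        else:
            sig = kappa / (1.0 + np.exp(-lam * (x - nu)))
            h = np.where(x <= xop, sig, b * x)
        theta_eff = theta + h
        mu_on = cm * mt + cs * nt
        s2_on = cm * mt * (1.0 - cm) + cs * nt * (1.0 - cs + V2 * cs * (nt - 1.0))
        mu_off = cs * x
        s2_off = cs * x * (1.0 - cs + V2 * cs * (x - 1.0))
        Mn = M_mat[:, t + 1]
        m[:, t + 1] = Mn * _phi_cdf(mu_on, s2_on, theta_eff)
        n[:, t + 1] = (N - Mn) * _phi_cdf(mu_off, s2_off, theta_eff)
    Msl = M_mat[:, : Q + 1]
    gamma = m / Msl - n / (N - Msl)
    return m, n, gamma
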