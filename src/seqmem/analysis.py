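"""Replay experiments: success rates, capacity curves, phase diagrams,
termination statistics.

All experiments share one ensemble engine: each realization draws a fresh
coding-ratio vector, either of fixed length P or extended until the realized
potentiation probability reaches a target connectivity (per-realization
calibration), and the mean-field map is then iterated on that vector with the
realized varsigma, V2 and b = cm*varsigma.  Success of a step is defined by
the retrieval quality Gamma_t = m_t/M_t - n_t/(N-M_t) exceeding 1/2; the
replay success rate rho_t is the fraction of realizations succeeding at step
t, and T90 is the length of the initial prefix over which rho stays strictly
above 90 %.  The maximum retrievable sequence length T maximizes T90 over a
grid of firing thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import varsigma_exact
from .distributions import CodingRatioSpec, _as_rng
from .meanfield import run_replay_ensemble

__all__ = [
    "SuccessCurve",
    "CapacityCurve",
    "TerminationScatter",
    "retrieval_quality",
    "success_rate",
    "t90",
    "max_retrievable_length",
    "max_P_with_T_at_least",
    "phase_diagram",
    "capacity_sweep",
    "termination_scatter",
    "sample_phi_ensemble",
]

SUCCESS_GAMMA = 0.5   # Gamma_t > 0.5 counts as a successfully replayed step
T90_LEVEL = 0.9       # rho_t must stay strictly above this


def retrieval_quality(m, n, M, N):
    """Gamma = m/M - n/(N-M): hit fraction minus false-alarm fraction."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0) or np.any(M >= N):
        raise ValueError("require 0 < M < N")
    return m / M - n / (N - M)


@dataclass
class SuccessCurve:
    """Replay success rate rho_t over time (t = 0 is the cue, rho_0 = 1)."""

    t: np.ndarray
    rho: np.ndarray
    n_realizations: int

    def stderr(self) -> np.ndarray:
        """Binomial standard error of each rho_t."""
        return np.sqrt(self.rho * (1.0 - self.rho) / self.n_realizations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "rho": self.rho, "stderr": self.stderr()}
        )


@dataclass
class CapacityCurve:
    """Maximum retrievable sequence length T versus stored associations P."""

    P: np.ndarray
    c: np.ndarray           # measured mean connectivity cm*<varsigma> per P
    T: np.ndarray
    Q: int
    Pc: float | None = None     # power-law fit intersects the T = Q plateau here
    alpha: float | None = None  # power-law exponent of the decreasing branch
    fit_mask: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"P": self.P, "c": self.c, "T": self.T})


@dataclass
class TerminationScatter:
    """Pattern-size pairs (M_tau, M_tau+1) at the last successful step tau."""

    M_tau: np.ndarray
    M_tau_next: np.ndarray
    frac_above: float       # fraction of failures with M_tau+1 > M_tau
    n_failed: int
    n_completed: int        # runs that never failed within Q (excluded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"M_tau": self.M_tau, "M_tau_next": self.M_tau_next})


# ---------------------------------------------------------------------------
# ensemble engine
# ---------------------------------------------------------------------------

def sample_phi_ensemble(
    spec: CodingRatioSpec,
    n_real: int,
    N: int,
    seed,
    P: int | None = None,
    c_target: float | None = None,
    cm: float | None = None,
    L_min: int = 0,
    chunk: int = 1024,
):
    """Draw n_real coding-ratio vectors, fixed-P or calibrated to c_target.

    Returns ``(f_mat, P_arr)`` where ``f_mat`` is (n_real, L) with rows
    padded beyond each realization's own P+1 patterns (padding repeats the
    mean; rows are only consumed up to min(Q, P)), and ``P_arr`` holds the
    per-realization association counts.  With ``c_target`` given, each row is
    extended pattern by pattern until its realized varsigma reaches
    c_target/cm (vectorized over realizations).  Invalid draws (f >= 1 or
    empty integer pattern) are rejected and redrawn.
    """
    rng = _as_rng(seed)

    def draw(shape):
        f = spec.sample(shape, rng)
        bad = (f >= 1.0) | (np.rint(f * N) < 1.0)
        tries = 0
        while np.any(bad):
            tries += 1
            if tries > 1000:
                raise RuntimeError("resampling cap exceeded")
            f[bad] = spec.sample(int(bad.sum()), rng)
            bad = (f >= 1.0) | (np.rint(f * N) < 1.0)
        return f

    if (P is None) == (c_target is None):
        raise ValueError("give exactly one of P and c_target")
    if P is not None:
        L = max(P + 1, L_min)
        f = draw((n_real, P + 1))
        if L > P + 1:
            f = np.hstack([f, np.full((n_real, L - P - 1), spec.phi0)])
        return f, np.full(n_real, P, dtype=int)

    if cm is None:
        raise ValueError("c_target requires cm")
    target = c_target / cm
    log_thresh = math.log1p(-target)
    # grow in geometrically enlarging blocks until every realization crossed
    block = max(256, L_min)
    f = draw((n_real, block))
    logs = np.log1p(-f[:, 1:] * f[:, :-1])
    cum = np.cumsum(logs, axis=1)
    while True:
        crossed = cum[:, -1] <= log_thresh
        if np.all(crossed):
            break
        block = f.shape[1]  # double the horizon each round
        grow = draw((n_real, block))
        new_logs = np.log1p(
            -np.hstack([f[:, -1:], grow[:, :-1]]) * grow
        )
        f = np.hstack([f, grow])
        cum = np.hstack([cum, cum[:, -1:] + np.cumsum(new_logs, axis=1)])
    # first association index where the threshold is crossed -> P = idx + 1
    idx = np.argmax(cum <= log_thresh, axis=1)
    P_arr = idx + 1
    return f, P_arr


def _gamma_ensemble(
    spec: CodingRatioSpec,
    *,
    N: int,
    cm: float,
    theta,
    Q: int,
    n_real: int,
    seed,
    P: int | None = None,
    c_target: float | None = None,
    inhibition: str = "linear",
    phi0: float | None = None,
    chunk: int = 2000,
    return_M: bool = False,
):
    """Gamma trajectories (n_real, Q+1) for one or many thetas.

    theta may be a scalar or a sequence; the same phi draws are reused across
    thetas (common random numbers), so threshold sweeps compare like with
    like.  Returns gamma of shape (n_theta, n_real, Q+1), squeezed to
    (n_real, Q+1) for scalar theta; optionally also the pattern-size matrix.
    """
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    streams = ss.spawn(max(1, (n_real + chunk - 1) // chunk))
    gammas = np.empty((thetas.size, n_real, Q + 1))
    Ms = np.empty((n_real, Q + 1)) if return_M else None
    done = 0
    for st in streams:
        r = min(chunk, n_real - done)
        if r <= 0:
            break
        rng = np.random.default_rng(st)
        f, P_arr = sample_phi_ensemble(
            spec, r, N, rng, P=P, c_target=c_target, cm=cm, L_min=Q + 1
        )
        if np.any(P_arr < Q):
            raise ValueError("calibrated P fell below the replay length Q")
        # realized per-row varsigma and V2 over each row's own P associations
        pair = f[:, 1:] * f[:, :-1]
        lg1 = np.cumsum(np.log1p(-pair), axis=1)
        prev = f[:, :-1]
        lg2 = np.cumsum(np.log1p(-f[:, 1:] * (2.0 * prev - prev * prev)), axis=1)
        take = P_arr - 1
        rows = np.arange(r)
        vs = -np.expm1(lg1[rows, take])
        e2 = 2.0 * vs - 1.0 + np.exp(lg2[rows, take])
        with np.errstate(invalid="ignore", divide="ignore"):
            V2 = np.where(vs > 0.0, np.maximum(0.0, (e2 - vs * vs)) / (vs * vs) ** 1, 0.0)
        M_mat = f[:, : Q + 1] * N
        if return_M:
            Ms[done : done + r] = M_mat
        for i, th in enumerate(thetas):
            _, _, g = run_replay_ensemble(
                M_mat, N, cm, float(th), vs, V2, Q,
                inhibition_mode=inhibition, phi0=phi0,
            )
            gammas[i, done : done + r] = g
        done += r
    scalar_theta = np.ndim(theta) == 0
    out = gammas[0] if scalar_theta else gammas
    return (out, Ms) if return_M else out


def success_rate(
    spec: CodingRatioSpec,
    *,
    N: int,
    cm: float,
    theta: float,
    Q: int,
    n_real: int,
    seed,
    P: int | None = None,
    c_target: float | None = None,
    inhibition: str = "linear",
    phi0: float | None = None,
) -> SuccessCurve:
    """Replay success rate rho_t over an ensemble of fresh phi realizations.

    Each realization draws its own coding-ratio vector (and, when c_target is
    given, its own calibrated P) and runs the mean-field replay; rho_t is the
    fraction with Gamma_t > 0.5.
    """
    if n_real < 1:
        raise ValueError("n_real >= 1 required")
    g = _gamma_ensemble(
        spec, N=N, cm=cm, theta=theta, Q=Q, n_real=n_real, seed=seed,
        P=P, c_target=c_target, inhibition=inhibition, phi0=phi0,
    )
    rho = (g > SUCCESS_GAMMA).mean(axis=0)
    return SuccessCurve(t=np.arange(Q + 1), rho=rho, n_realizations=n_real)


def t90(curve: SuccessCurve, level: float = T90_LEVEL) -> int:
    """Longest prefix with rho strictly above the level (first dip ends it).

    Counts time steps after the cue: a curve that stays above the level for
    the whole run returns Q.
    """
    rho = np.asarray(curve.rho, dtype=float)
    below = np.nonzero(~(rho[1:] > level))[0]
    return int(below[0]) if below.size else rho.size - 1


def max_retrievable_length(
    spec: CodingRatioSpec,
    *,
    N: int,
    cm: float,
    theta_grid,
    Q: int,
    n_real: int,
    seed,
    P: int | None = None,
    c_target: float | None = None,
    inhibition: str = "linear",
    phi0: float | None = None,
    return_details: bool = False,
):
    """T = max over the theta grid of T90 (same phi draws across thetas)."""
    thetas = np.asarray(list(theta_grid), dtype=float)
    if thetas.size == 0:
        raise ValueError("theta grid must be nonempty")
    g = _gamma_ensemble(
        spec, N=N, cm=cm, theta=thetas, Q=Q, n_real=n_real, seed=seed,
        P=P, c_target=c_target, inhibition=inhibition, phi0=phi0,
    )
    rho = (g > SUCCESS_GAMMA).mean(axis=1)  # (n_theta, Q+1)
    t90s = np.empty(thetas.size, dtype=int)
    for i in range(thetas.size):
        t90s[i] = t90(SuccessCurve(np.arange(Q + 1), rho[i], n_real))
    T = int(t90s.max())
    if return_details:
        return T, thetas[int(np.argmax(t90s))], t90s
    return T


def max_P_with_T_at_least(
    spec: CodingRatioSpec,
    T_min: int,
    *,
    N: int,
    cm: float,
    theta_grid,
    n_real: int,
    seed,
    P_start: int,
    inhibition: str = "linear",
    rel_tol: float = 0.02,
):
    """Largest P at which the network still retrieves sequences of length T_min.

    Brackets the breakdown by doubling/halving from P_start and bisects to the
    given relative resolution.  Each probe evaluates T(P) with Q = T_min + 2
    (enough to decide T >= T_min) on its own deterministic sub-seed, so the
    search is reproducible.
    """
    Q = T_min + 2
    ss = np.random.SeedSequence(seed)

    def ok(Pval, sub):
        T = max_retrievable_length(
            spec, N=N, cm=cm, theta_grid=theta_grid, Q=Q,
            n_real=n_real, seed=sub, P=Pval, inhibition=inhibition,
        )
        return T >= T_min

    streams = iter(ss.spawn(200))
    lo = hi = None
    Pval = P_start
    if ok(Pval, next(streams)):
        lo = Pval
        while True:
            Pval *= 2
            if not ok(Pval, next(streams)):
                hi = Pval
                break
            lo = Pval
    else:
        hi = Pval
        while True:
            Pval = max(1, Pval // 2)
            if ok(Pval, next(streams)):
                lo = Pval
                break
            hi = Pval
            if Pval == 1:
                return 0
    while hi - lo > max(1, int(rel_tol * lo)):
        mid = (lo + hi) // 2
        if ok(mid, next(streams)):
            lo = mid
        else:
            hi = mid
    return lo


def phase_diagram(
    spec_for,
    phi_grid,
    theta_grid,
    *,
    N: int,
    cm: float,
    c_target: float,
    t_eval: int = 100,
    n_real: int = 100,
    seed=0,
    metric: str = "rho",
    inhibition: str = "linear",
) -> pd.DataFrame:
    """Success-rate (or mean-quality) map over a (phi, theta) grid.

    ``spec_for(phi)`` must return the coding-ratio spec for one grid column
    (e.g. a gamma spec with mean phi, or a triangular spec with mode phi).
    Each cell reports rho at t_eval (metric="rho", the wedge maps) or the mean
    Gamma at t_eval (metric="gamma").  P is calibrated per realization to
    c_target.  Returns a tidy frame with columns phi, theta, value.
    """
    if metric not in ("rho", "gamma"):
        raise ValueError("metric must be 'rho' or 'gamma'")
    ss = np.random.SeedSequence(seed)
    phi_grid = list(phi_grid)
    rows = []
    for phi_val, sub in zip(phi_grid, ss.spawn(len(phi_grid))):
        spec = spec_for(phi_val)
        phi0 = spec.phi0 if inhibition == "nonlinear" else None
        g = _gamma_ensemble(
            spec, N=N, cm=cm, theta=np.asarray(theta_grid, float),
            Q=t_eval, n_real=n_real, seed=sub, c_target=c_target,
            inhibition=inhibition, phi0=phi0,
        )
        last = g[:, :, t_eval]
        if metric == "rho":
            vals = (last > SUCCESS_GAMMA).mean(axis=1)
        else:
            vals = last.mean(axis=1)
        for th, v in zip(theta_grid, vals):
            rows.append({"phi": phi_val, "theta": th, "value": float(v)})
    return pd.DataFrame(rows)


def capacity_sweep(
    spec: CodingRatioSpec,
    *,
    N: int,
    cm: float,
    P_grid,
    theta_grid,
    Q: int,
    n_real: int,
    seed,
    inhibition: str = "linear",
) -> CapacityCurve:
    """T(P) over a grid of association counts, with a power-law fit.

    The decreasing branch (points past the argmax of T with 0 < T < Q) is fit
    by least squares in log-log space, giving the exponent alpha of
    T ~ P^-alpha; the cutoff capacity Pc is where the fitted line meets the
    plateau T = Q.  The fit is skipped (Pc = alpha = None) with fewer than
    three branch points.
    """
    from .connectivity import ensemble_moments

    P_grid = np.asarray(list(P_grid), dtype=int)
    if np.any(np.diff(P_grid) <= 0):
        raise ValueError("P_grid must be strictly increasing")
    ss = np.random.SeedSequence(seed)
    Ts = np.empty(P_grid.size, dtype=int)
    cs = np.empty(P_grid.size)
    for i, (Pv, sub) in enumerate(zip(P_grid, ss.spawn(P_grid.size))):
        Ts[i] = max_retrievable_length(
            spec, N=N, cm=cm, theta_grid=theta_grid, Q=Q,
            n_real=n_real, seed=sub, P=int(Pv), inhibition=inhibition,
        )
        cs[i] = cm * ensemble_moments(spec, int(Pv))[0]
    Pc, alpha, mask = fit_capacity_power_law(P_grid, Ts, Q)
    return CapacityCurve(
        P=P_grid, c=cs, T=Ts, Q=Q, Pc=Pc, alpha=alpha, fit_mask=mask
    )


def fit_capacity_power_law(P, T, Q: int):
    """Least-squares power law T ~ P^-alpha on the decreasing branch.

    The branch is the points past the argmax of T with 0 < T < Q (neither the
    plateau nor total failure).  Returns (Pc, alpha, mask); Pc is where the
    fitted line meets T = Q.  With fewer than three branch points the fit is
    skipped and (None, None, mask) returned.
    """
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    i0 = int(np.argmax(T))
    mask = np.zeros(P.size, dtype=bool)
    mask[i0 + 1 :] = (T[i0 + 1 :] > 0) & (T[i0 + 1 :] < Q)
    if mask.sum() < 3:
        return None, None, mask
    slope, intercept = np.polyfit(np.log(P[mask]), np.log(T[mask]), 1)
    alpha = -float(slope)
    Pc = float(np.exp((intercept - math.log(Q)) / alpha)) if alpha > 0 else None
    return Pc, alpha, mask


def termination_scatter(
    spec: CodingRatioSpec,
    *,
    N: int,
    cm: float,
    theta: float,
    Q: int,
    n_real: int,
    seed,
    c_target: float | None = None,
    P: int | None = None,
    inhibition: str = "linear",
) -> TerminationScatter:
    """Pattern sizes flanking the point of replay failure.

    For each realization, tau is the last step before the first failure
    (Gamma <= 0.5); the pair (M_tau, M_tau+1) records the sizes of the last
    correctly replayed pattern and its successor.  Runs that never fail within
    Q are excluded from the scatter and counted separately.  ``frac_above`` is
    the fraction of failures with M_tau+1 > M_tau, i.e. failures at a
    small-to-big transition.
    """
    g, Ms = _gamma_ensemble(
        spec, N=N, cm=cm, theta=theta, Q=Q, n_real=n_real, seed=seed,
        P=P, c_target=c_target, inhibition=inhibition, return_M=True,
    )
    failed_any = ~(g > SUCCESS_GAMMA)
    failed_any[:, 0] = False  # the cue itself always succeeds
    has_fail = failed_any.any(axis=1)
    first_fail = np.argmax(failed_any, axis=1)
    tau = first_fail[has_fail] - 1
    rows = np.nonzero(has_fail)[0]
    M_tau = Ms[rows, tau]
    M_next = Ms[rows, tau + 1]
    n_failed = int(rows.size)
    frac = float(np.mean(M_next > M_tau)) if n_failed else math.nan
    return TerminationScatter(
        M_tau=M_tau,
        M_tau_next=M_next,
        frac_above=frac,
        n_failed=n_failed,
        n_completed=int(n_real - n_failed),
    )
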