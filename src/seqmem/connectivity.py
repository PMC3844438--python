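"""Potentiation statistics of Willshaw sequence learning with variable sparseness.

After storing a sequence of binary patterns with the clipped Hebbian
(Willshaw) rule, a synapse is potentiated iff its presynaptic neuron fires in
some pattern ``k`` and its postsynaptic neuron in pattern ``k+1``.  For a
coding-ratio vector ``phi = (f_0, ..., f_P)`` the probability that a given
synapse is potentiated is

    varsigma(phi) = 1 - prod_{k=1..P} (1 - f_k * f_{k-1}),

generalizing the classical homogeneous relation ``c/cm = 1 - (1-f^2)^P``.

This module provides

* the exact per-realization statistics ``varsigma`` and the squared variation
  coefficient ``V^2`` of the per-neuron potentiation probability over
  activation schedules (the source of learning-induced input correlations);
* the ensemble mean and variance of ``varsigma`` over random coding-ratio
  vectors, computed exactly from the first four moments of p_phi by a chain
  (transfer) recursion, plus an independent alternating-series evaluation and
  a Monte-Carlo sampler used as cross-checks;
* the run-combinatorics ``n_j(P, k)`` entering the series expansion;
* calibration of the association count P to a target mean connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import CodingRatioSpec, PatternSizeVector, _as_rng

__all__ = [
    "ConnectivityStats",
    "varsigma_exact",
    "willshaw_P",
    "schedule_stats",
    "n_combinations",
    "ensemble_moments",
    "ensemble_mean_series",
    "sample_varsigma_ensemble",
    "calibrate_P",
]


def _f_array(phi) -> np.ndarray:
    if isinstance(phi, PatternSizeVector):
        return phi.f
    return np.asarray(phi, dtype=float)


@dataclass(frozen=True)
class ConnectivityStats:
    """Per-realization and ensemble potentiation statistics.

    varsigma      : potentiation probability of phi (or <varsigma> proxy)
    V2            : squared variation coefficient of varsigma_A over schedules
    mean_varsigma : ensemble mean over random phi (None if not computed)
    var_varsigma  : ensemble variance over random phi (None if not computed)
    """

    varsigma: float
    V2: float
    mean_varsigma: float | None = None
    var_varsigma: float | None = None

    def effective_connectivity(self, cm: float) -> float:
        return cm * self.varsigma


def varsigma_exact(phi) -> float:
    """Potentiation probability 1 - prod(1 - f_k f_{k-1}) of one phi vector.

    Evaluated through log1p for numerical stability at large P.
    """
    f = _f_array(phi)
    if f.size < 2:
        raise ValueError("need at least one association (two coding ratios)")
    return -float(np.expm1(np.sum(np.log1p(-f[1:] * f[:-1]))))


def willshaw_P(c: float, cm: float, f: float) -> float:
    """Classical homogeneous capacity P = log(1 - c/cm) / log(1 - f^2).

    Number of associations after which a homogeneous Willshaw network with
    coding ratio ``f`` and morphological connectivity ``cm`` reaches effective
    connectivity ``c``.  Real-valued; callers round as needed.
    """
    if not 0.0 < cm <= 1.0:
        raise ValueError("require 0 < cm <= 1")
    if not 0.0 <= c < cm:
        raise ValueError("require 0 <= c < cm")
    if not 0.0 < f < 1.0:
        raise ValueError("require 0 < f < 1")
    if c == 0.0:
        return 0.0
    return math.log1p(-c / cm) / math.log1p(-f * f)


def schedule_stats(phi) -> ConnectivityStats:
    """Exact varsigma, E[varsigma_A^2] and V^2 for one coding-ratio vector.

    The per-neuron potentiation probability varsigma_A depends on the neuron's
    activation schedule A (which patterns it joins).  Averaging the closed
    product forms over schedules yields

        E[varsigma_A]   = varsigma(phi)
        E[varsigma_A^2] = 2*varsigma - 1 + prod_k (1 - f_k*(2 f_{k-1} - f_{k-1}^2))

    and ``V2 = (E[varsigma_A^2] - varsigma^2) / varsigma^2`` (floored at 0
    against roundoff).  V2 quantifies the learning-induced correlations of
    potentiated inputs converging on one neuron.
    """
    f = _f_array(phi)
    vs = varsigma_exact(f)
    prev = f[:-1]
    log_prod = np.sum(np.log1p(-f[1:] * (2.0 * prev - prev * prev)))
    e2 = 2.0 * vs - 1.0 + float(np.exp(log_prod))
    if vs == 0.0:
        v2 = 0.0
    else:
        v2 = max(0.0, (e2 - vs * vs) / (vs * vs))
    return ConnectivityStats(varsigma=vs, V2=v2)


def n_combinations(P: int, k: int, j: int) -> int:
    """Number of k-combinations of P ordered elements with exactly j maximal
    runs of adjacent elements:

        n_j(P, k) = C(P-k+1, j) * C(k-1, k-j),   0 if j > min(k, P-k+1).
    """
    if not (1 <= k <= P) or j < 1:
        raise ValueError("require 1 <= k <= P and j >= 1")
    if j > min(k, P - k + 1):
        return 0
    return math.comb(P - k + 1, j) * math.comb(k - 1, k - j)


# ---------------------------------------------------------------------------
# ensemble moments over random phi
# ---------------------------------------------------------------------------

def _chain_mean_product(mu1: float, mu2: float, P: int) -> float:
    """E[prod_{k=1..P} (1 - f_k f_{k-1})] for i.i.d. f with raw moments mu1, mu2.

    The conditional expectation given the last coding ratio is affine in it,
    so integrating out one factor at a time gives an exact two-term linear
    recursion (no alternating-series cancellation, stable to arbitrary P).
    """
    a, b = 1.0, -mu1  # E[1 - f_1 f_0 | f_1] = 1 - mu1 * f_1
    for _ in range(P - 1):
        a, b = a + b * mu1, -(a * mu1 + b * mu2)
    return a + b * mu1


def _chain_mean_square_product(
    mu1: float, mu2: float, mu3: float, mu4: float, P: int
) -> float:
    """E[prod_{k=1..P} (1 - f_k f_{k-1})^2]; quadratic-polynomial analogue of
    :func:`_chain_mean_product`, requiring raw moments up to order four."""
    a, b, c = 1.0, -2.0 * mu1, mu2  # E[(1 - f_1 f_0)^2 | f_1]
    for _ in range(P - 1):
        a, b, c = (
            a + b * mu1 + c * mu2,
            -2.0 * (a * mu1 + b * mu2 + c * mu3),
            a * mu2 + b * mu3 + c * mu4,
        )
    return a + b * mu1 + c * mu2


def ensemble_moments(spec: CodingRatioSpec, P: int) -> tuple[float, float]:
    """Mean and variance of varsigma over the ensemble of coding-ratio vectors.

    Returns ``(<varsigma>, sigma_varsigma^2)`` where the expectation runs over
    P+1 i.i.d. coding ratios from ``spec``.  Both are computed exactly from the
    first four raw moments of p_phi via the chain recursion; the variance is
    floored at zero against roundoff.  For the degenerate spec this reduces to
    ``<varsigma> = 1 - (1 - phi0^2)^P`` and zero variance.
    """
    if P < 1:
        raise ValueError("require P >= 1")
    mu1, mu2, mu3, mu4 = distribution_moments_cached(spec)
    e1 = _chain_mean_product(mu1, mu2, P)
    e2 = _chain_mean_square_product(mu1, mu2, mu3, mu4, P)
    mean = 1.0 - e1
    var = max(0.0, e2 - e1 * e1)
    return mean, var


def distribution_moments_cached(spec: CodingRatioSpec):
    # tiny convenience to avoid importing the name in two places
    from .distributions import distribution_moments

    return distribution_moments(spec)


def ensemble_mean_series(spec: CodingRatioSpec, P: int) -> float:
    """<varsigma> by the alternating series over run combinatorics,

        <varsigma> = -sum_{k=1..P} sum_{j=1..k} (-1)^k n_j(P,k) <f>^{2j} <f^2>^{k-j}.

    Terms are accumulated in log-magnitude form (binomials via lgamma) to
    avoid overflow.  Kept as an independent cross-check of
    :func:`ensemble_moments`; cost is O(P^2), so intended for moderate P.
    """
    mu1, mu2 = distribution_moments_cached(spec)[:2]
    l1, l2 = math.log(mu1), math.log(mu2)
    total = 0.0
    for k in range(1, P + 1):
        inner = 0.0
        jmax = min(k, P - k + 1)
        for j in range(1, jmax + 1):
            ln = (
                math.lgamma(P - k + 2)
                - math.lgamma(j + 1)
                - math.lgamma(P - k + 2 - j)
                + math.lgamma(k)
                - math.lgamma(k - j + 1)
                - math.lgamma(j)
            )
            inner += math.exp(ln + 2 * j * l1 + (k - j) * l2)
        total += -((-1.0) ** k) * inner
    return total


def sample_varsigma_ensemble(
    spec: CodingRatioSpec, P: int, n: int, seed, chunk: int = 4096
) -> np.ndarray:
    """Monte-Carlo draws of varsigma(phi) for n random coding-ratio vectors."""
    rng = _as_rng(seed)
    out = np.empty(n)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        f = spec.sample((m, P + 1), rng)
        out[done : done + m] = -np.expm1(
            np.sum(np.log1p(-f[:, 1:] * f[:, :-1]), axis=1)
        )
        done += m
    return out


# ---------------------------------------------------------------------------
# calibration of P to a target connectivity
# ---------------------------------------------------------------------------

def calibrate_P(
    spec: CodingRatioSpec,
    c_target: float,
    cm: float,
    mode: str = "per_realization",
    seed=None,
    N: int | None = None,
    max_P: int = 10_000_000,
):
    """Find the association count P that reaches mean connectivity c_target.

    mode="per_realization":
        Sample coding ratios one pattern at a time and stop at the first P for
        which the realized varsigma(phi) >= c_target/cm.  Returns
        ``(P, PatternSizeVector)`` — the vector actually used, so downstream
        replay runs on exactly the calibrated sequence.  Requires ``N``.

    mode="ensemble":
        Smallest P with ensemble mean <varsigma> >= c_target/cm, located by
        bisection on the monotone mean from :func:`ensemble_moments`.
        Returns ``P`` only.
    """
    if not 0.0 < c_target < cm:
        raise ValueError("require 0 < c_target < cm")
    target = c_target / cm
    if mode == "ensemble":
        lo, hi = 0, 1
        while ensemble_moments(spec, hi)[0] < target:
            lo, hi = hi, hi * 2
            if hi > max_P:
                raise RuntimeError("c_target/cm unreachable within max_P")
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ensemble_moments(spec, mid)[0] >= target:
                hi = mid
            else:
                lo = mid
        return hi
    if mode != "per_realization":
        raise ValueError(f"unknown mode {mode!r}")
    if N is None:
        raise ValueError("per_realization mode requires N")
    rng = _as_rng(seed)
    log_thresh = math.log1p(-target)  # stop once sum log(1 - f_k f_{k-1}) <= this
    block = 4096
    fs = []
    f_prev = None
    log_acc = 0.0
    P = 0
    while True:
        f = spec.sample(block, rng)
        bad = (f >= 1.0) | (np.rint(f * N) < 1.0)
        tries = 0
        while np.any(bad):
            tries += 1
            if tries > 1000:
                raise RuntimeError("resampling cap exceeded during calibration")
            f[bad] = spec.sample(int(bad.sum()), rng)
            bad = (f >= 1.0) | (np.rint(f * N) < 1.0)
        if f_prev is None:
            pair_prev = np.concatenate(([np.nan], f[:-1]))
            logs = np.log1p(-f[1:] * f[:-1])
            cum = log_acc + np.cumsum(logs)
            offset = 1  # f[0] is the cue, contributes no association
        else:
            prev = np.concatenate(([f_prev], f[:-1]))
            logs = np.log1p(-f * prev)
            cum = log_acc + np.cumsum(logs)
            offset = 0
        hit = np.nonzero(cum <= log_thresh)[0]
        if hit.size:
            stop = int(hit[0])
            fs.append(f[: stop + 1 + (offset == 1)])
            P += stop + 1
            break
        fs.append(f)
        P += f.size - offset
        log_acc = float(cum[-1])
        f_prev = float(f[-1])
        if P > max_P:
            raise RuntimeError("c_target/cm unreachable within max_P")
    phi = PatternSizeVector(f=np.concatenate(fs), N=N)
    assert phi.P == P
    return P, phi
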