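"""Full binary-neuron network: Willshaw learning plus threshold dynamics.

This is the ground-truth simulator against which the mean-field map is
validated.  Neurons are binary threshold units updated synchronously,

    x_i(t+1) = Theta( sum_j w_ij s_ij x_j(t) - theta - h(|x(t)|) ),

where ``w`` is a Bernoulli(cm) morphological mask, ``s`` the clipped Hebbian
synaptic state (potentiated iff pre fires in pattern k and post in pattern
k+1 for some association k), and ``h`` the instantaneous feedback inhibition
driven by the total activity at time t (same linear/nonlinear forms as the
mean field).  A neuron exactly at threshold fires (Theta(0) = 1 by default);
self-connections are excluded.

Only the morphological synapses are materialized: learning intersects the
Bernoulli edge sample with the potentiation condition, evaluated through
bit-packed activation schedules, and stores the effective weights as a sparse
matrix.  This keeps N = 10^4-scale validation runs within ordinary memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .distributions import _as_rng
from .meanfield import MeanFieldParams, inhibition as mf_inhibition

__all__ = [
    "BinaryNetwork",
    "ActivityTrace",
    "generate_patterns",
    "learn_willshaw",
    "simulate",
]


def generate_patterns(M, N: int, seed) -> list[np.ndarray]:
    """Random binary patterns as sorted index arrays.

    Pattern k activates exactly M[k] neurons chosen uniformly without
    replacement, independently across patterns.
    """
    rng = _as_rng(seed)
    M = np.atleast_1d(np.asarray(M, dtype=int))
    if np.any(M < 1) or np.any(M > N):
        raise ValueError("pattern sizes must lie in [1, N]")
    return [np.sort(rng.choice(N, size=int(Mk), replace=False)) for Mk in M]


def _pack_schedules(patterns: list[np.ndarray], N: int):
    """Bit-packed pre/post activation schedules over the P associations.

    pre[i]  has bit k set iff neuron i is active in pattern k   (k = 0..P-1)
    post[i] has bit k set iff neuron i is active in pattern k+1
    Returned as (N, W) uint64 arrays, W = ceil(P/64).
    """
    P = len(patterns) - 1
    W = (P + 63) // 64
    pre = np.zeros((N, W), dtype=np.uint64)
    post = np.zeros((N, W), dtype=np.uint64)
    for k in range(P):
        w, bit = divmod(k, 64)
        mask = np.uint64(1 << bit)
        pre[patterns[k], w] |= mask
        post[patterns[k + 1], w] |= mask
    return pre, post


@dataclass
class BinaryNetwork:
    """A learned network: sparse effective weights plus its stored sequence."""

    N: int
    cm: float
    patterns: list[np.ndarray]
    J: sp.csr_matrix          # effective weights w_ij * s_ij (0/1)
    n_morph: int              # number of morphological synapses sampled
    n_potentiated: int        # of those, how many are potentiated
    theta: float | None = None
    b: float | None = None

    @property
    def P(self) -> int:
        return len(self.patterns) - 1

    @property
    def potentiation_fraction(self) -> float:
        """Measured fraction of potentiated synapses among morphological ones
        (the empirical counterpart of varsigma)."""
        return self.n_potentiated / self.n_morph

    @property
    def effective_connectivity(self) -> float:
        return self.cm * self.potentiation_fraction


def learn_willshaw(
    patterns: list[np.ndarray],
    cm: float,
    seed,
    N: int | None = None,
    row_chunk: int = 256,
) -> BinaryNetwork:
    """Store a pattern sequence with the clipped Hebbian rule under dilution.

    The morphological mask is i.i.d. Bernoulli(cm) with the diagonal excluded
    (no autapses).  A morphological synapse j -> i is potentiated iff the
    pre/post activation schedules of j and i share at least one association,
    which is evaluated by ANDing the bit-packed schedules.  Learning is an OR
    over associations, hence idempotent and order-insensitive given the
    sequence.
    """
    if len(patterns) < 2:
        raise ValueError("need at least two patterns (one association)")
    if not 0.0 < cm <= 1.0:
        raise ValueError("require 0 < cm <= 1")
    if N is None:
        N = int(max(p.max() for p in patterns)) + 1
    rng = _as_rng(seed)
    pre, post = _pack_schedules(patterns, N)

    indptr = np.zeros(N + 1, dtype=np.int64)
    cols_out = []
    n_morph = 0
    n_pot = 0
    for lo in range(0, N, row_chunk):
        hi = min(lo + row_chunk, N)
        block = rng.random((hi - lo, N)) < cm
        block[:, lo:hi][np.eye(hi - lo, dtype=bool)] = False
        rows, cols = np.nonzero(block)
        n_morph += rows.size
        # potentiated iff post-schedule of the row neuron intersects the
        # pre-schedule of the column neuron
        hit = np.any(post[lo + rows] & pre[cols], axis=1)
        rows, cols = rows[hit], cols[hit]
        n_pot += rows.size
        counts = np.bincount(rows, minlength=hi - lo)
        indptr[lo + 1 : hi + 1] = indptr[lo] + np.cumsum(counts)
        cols_out.append(cols.astype(np.int32))
    indices = np.concatenate(cols_out) if cols_out else np.empty(0, np.int32)
    data = np.ones(indices.size, dtype=np.float32)
    J = sp.csr_matrix((data, indices, indptr), shape=(N, N))
    return BinaryNetwork(
        N=N, cm=cm, patterns=patterns, J=J, n_morph=n_morph, n_potentiated=n_pot
    )


@dataclass
class ActivityTrace:
    """Hits/false alarms of a binary-network run (same schema as the mean field)."""

    t: np.ndarray
    M: np.ndarray
    m: np.ndarray
    n: np.ndarray
    gamma: np.ndarray
    N: int
    x_final: np.ndarray | None = None
    states: list[np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "M": self.M, "m": self.m, "n": self.n, "gamma": self.gamma}
        )


def simulate(
    net: BinaryNetwork,
    Q: int,
    seed=None,
    theta: float | None = None,
    b: float | None = None,
    inhibition_mode: str = "linear",
    phi0: float | None = None,
    x0: np.ndarray | None = None,
    fire_at_threshold: bool = True,
    store_states: bool = False,
) -> ActivityTrace:
    """Run the thresholded dynamics for Q steps, cueing with pattern 0.

    theta/b override the values stored on the network; b defaults to
    cm * potentiation_fraction (the realized balanced inhibitory weight).  The
    dynamics are deterministic; ``seed`` is accepted for interface symmetry
    with the stochastic experiments but unused.  Hits m_t and false alarms n_t
    are counted against the stored pattern xi_t.
    """
    if Q > net.P:
        raise ValueError("Q must not exceed the number of stored associations")
    theta = net.theta if theta is None else theta
    if theta is None:
        raise ValueError("theta must be given (on the network or the call)")
    b = (net.b if net.b is not None else net.effective_connectivity) if b is None else b
    params = MeanFieldParams(
        N=net.N,
        cm=net.cm,
        theta=theta,
        varsigma=net.potentiation_fraction,
        b=b,
        inhibition=inhibition_mode,
        phi0=phi0,
    )
    x = np.zeros(net.N, dtype=bool)
    x[net.patterns[0] if x0 is None else x0] = True
    M = np.array([p.size for p in net.patterns[: Q + 1]], dtype=int)
    m = np.empty(Q + 1, dtype=int)
    n = np.empty(Q + 1, dtype=int)
    states = [] if store_states else None

    def count(xv, t):
        mt = int(xv[net.patterns[t]].sum())
        return mt, int(xv.sum()) - mt

    m[0], n[0] = count(x, 0)
    if store_states:
        states.append(x.copy())
    for t in range(Q):
        total = int(x.sum())
        theta_eff = theta + float(mf_inhibition(total, params))
        drive = net.J @ x.astype(np.float32)
        if fire_at_threshold:
            x = drive >= theta_eff - 1e-9
        else:
            x = drive > theta_eff + 1e-9
        m[t + 1], n[t + 1] = count(x, t + 1)
        if store_states:
            states.append(x.copy())
    gamma = m / M - n / (net.N - M)
    return ActivityTrace(
        t=np.arange(Q + 1),
        M=M,
        m=m,
        n=n,
        gamma=gamma,
        N=net.N,
        x_final=x,
        states=states,
    )
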