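"""Coding-ratio distributions for inhomogeneous pattern sizes.

A stored binary pattern activates a fraction ``f`` (the *coding ratio*) of the
``N`` neurons in the network.  Inhomogeneous sparseness means that each pattern
in a stored sequence draws its own coding ratio from a distribution
``p_phi(f)``.  Two families are supported:

* ``gamma`` — a Gamma distribution parameterized by its mean ``phi0`` and
  standard deviation ``sigma_phi`` (shape ``phi0**2/sigma_phi**2``, scale
  ``sigma_phi**2/phi0``).  ``sigma_phi = 0`` degenerates to the classical
  homogeneous model in which every pattern has size ``phi0 * N``.
* ``triangular`` — triangular densities with the mode at ``phi_max``, used to
  study the effect of skewness in the size distribution.  The ``symmetric``
  variant is an isosceles triangle centred on the mode; the ``negative`` /
  ``positive`` variants are one-sided (right-angled) triangles entirely below /
  above the mode.  In all three cases the half-width is chosen so the standard
  deviation equals ``sigma_phi`` exactly; the mean offset of the one-sided
  triangles from the mode is then ``sqrt(2)*sigma_phi`` (this is a property of
  the triangular shape, not a free parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CodingRatioSpec",
    "PatternSizeVector",
    "sample_phi",
    "distribution_moments",
    "make_triangular",
]

Family = Literal["gamma", "triangular"]
Skew = Literal["negative", "symmetric", "positive"]

#: resampling cap for draws that violate 0 < f < 1 or produce empty patterns
_MAX_REJECTIONS = 1000


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CodingRatioSpec:
    """Specification of a coding-ratio distribution p_phi(f).

    Parameters
    ----------
    family:
        ``"gamma"`` or ``"triangular"``.
    phi0:
        Mean coding ratio (dimensionless, 0 < phi0 < 1).  For the triangular
        family this is derived from ``phi_max`` and the skew; use
        :func:`make_triangular` to construct triangular specs.
    sigma_phi:
        Standard deviation of the coding ratio (>= 0).  Zero is legal and
        denotes the degenerate (homogeneous) distribution.
    phi_max:
        Mode of the triangular density (unused for gamma).
    skew:
        Skew direction for the triangular family.
    """

    family: Family
    phi0: float
    sigma_phi: float
    phi_max: float | None = None
    skew: Skew = "symmetric"

    def __post_init__(self):
        if self.family not in ("gamma", "triangular"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 < self.phi0 < 1.0:
            raise ValueError("phi0 must lie in (0, 1)")
        if self.sigma_phi < 0.0:
            raise ValueError("sigma_phi must be >= 0")
        if self.family == "triangular":
            if self.phi_max is None or self.phi_max <= 0.0:
                raise ValueError("triangular family requires phi_max > 0")
            if self.skew not in ("negative", "symmetric", "positive"):
                raise ValueError(f"unknown skew {self.skew!r}")
            lo, hi = self.support
            if not (0.0 < lo and hi < 1.0):
                raise ValueError(
                    f"triangular support [{lo:.4g}, {hi:.4g}] leaves (0, 1)"
                )

    # -- geometry ---------------------------------------------------------
    @property
    def degenerate(self) -> bool:
        return self.sigma_phi == 0.0

    @property
    def support(self) -> tuple[float, float]:
        """Support of the density (closed interval endpoints)."""
        if self.family == "gamma":
            return (0.0, math.inf) if not self.degenerate else (self.phi0, self.phi0)
        w_sym = math.sqrt(6.0) * self.sigma_phi
        w_one = 3.0 * math.sqrt(2.0) * self.sigma_phi
        if self.skew == "symmetric":
            return (self.phi_max - w_sym, self.phi_max + w_sym)
        if self.skew == "negative":
            return (self.phi_max - w_one, self.phi_max)
        return (self.phi_max, self.phi_max + w_one)

    def frozen_dist(self):
        """The scipy frozen distribution (undefined for the degenerate case)."""
        if self.degenerate:
            raise ValueError("degenerate spec has no continuous density")
        if self.family == "gamma":
            shape = self.phi0**2 / self.sigma_phi**2
            scale = self.sigma_phi**2 / self.phi0
            return stats.gamma(shape, scale=scale)
        lo, hi = self.support
        scale = hi - lo
        c = {"negative": 1.0, "symmetric": 0.5, "positive": 0.0}[self.skew]
        return stats.triang(c, loc=lo, scale=scale)

    # -- sampling ---------------------------------------------------------
    def sample(self, size: int, rng) -> np.ndarray:
        """Draw ``size`` i.i.d. coding ratios (no truncation applied)."""
        rng = _as_rng(rng)
        if self.degenerate:
            return np.full(size, self.phi0)
        if self.family == "gamma":
            shape = self.phi0**2 / self.sigma_phi**2
            scale = self.sigma_phi**2 / self.phi0
            return rng.gamma(shape, scale, size=size)
        lo, hi = self.support
        c = {"negative": hi, "symmetric": self.phi_max, "positive": lo}[self.skew]
        return rng.triangular(lo, c, hi, size=size)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"family": self.family, "phi0": self.phi0, "sigma_phi": self.sigma_phi}
        if self.family == "triangular":
            d["phi_max"] = self.phi_max
            d["skew"] = self.skew
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CodingRatioSpec":
        if d.get("family") == "triangular" and "phi0" not in d:
            return make_triangular(d["phi_max"], d["sigma_phi"], d.get("skew", "symmetric"))
        return cls(
            family=d["family"],
            phi0=float(d["phi0"]),
            sigma_phi=float(d["sigma_phi"]),
            phi_max=d.get("phi_max"),
            skew=d.get("skew", "symmetric"),
        )


@dataclass(frozen=True)
class PatternSizeVector:
    """One realization of the coding-ratio vector phi = (f_0, ..., f_P).

    Association ``k`` (k = 1..P) links pattern ``k-1`` to pattern ``k``; the
    entry ``f[0]`` is the cue pattern's coding ratio.  Pattern sizes come in
    two flavours: the integer sizes ``M`` (``round(f*N)`` clamped to >= 1) used
    by the binary network, and the real-valued sizes ``M_real = f*N`` used by
    the mean-field map, which treats sizes as continuous expectation values.
    """

    f: np.ndarray
    N: int

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.f, dtype=float))
        object.__setattr__(self, "f", f)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("phi needs at least two entries (one association)")
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("coding ratios must lie in (0, 1)")

    @property
    def P(self) -> int:
        """Number of stored associations."""
        return self.f.size - 1

    @property
    def M(self) -> np.ndarray:
        """Integer pattern sizes, round(f*N) clamped to [1, N]."""
        return np.clip(np.rint(self.f * self.N).astype(int), 1, self.N)

    @property
    def M_real(self) -> np.ndarray:
        """Real-valued pattern sizes f*N (mean-field convention)."""
        return self.f * self.N

    def sizes(self, integer: bool = False) -> np.ndarray:
        return self.M if integer else self.M_real


def sample_phi(spec: CodingRatioSpec, P: int, N: int, seed) -> PatternSizeVector:
    """Sample a coding-ratio vector of P associations (P+1 patterns).

    Draws are i.i.d. from ``spec``; draws with ``f >= 1`` or with
    ``round(f*N) < 1`` (empty pattern) are rejected and redrawn, with a cap of
    1000 rejections per slot.
    """
    if P < 1 or N < 1:
        raise ValueError("require P >= 1 and N >= 1")
    rng = _as_rng(seed)
    f = spec.sample(P + 1, rng)
    bad = (f >= 1.0) | (np.rint(f * N) < 1.0)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > _MAX_REJECTIONS:
            raise RuntimeError(
                "resampling cap exceeded: spec produces mostly invalid coding ratios"
            )
        f[bad] = spec.sample(int(bad.sum()), rng)
        bad = (f >= 1.0) | (np.rint(f * N) < 1.0)
    return PatternSizeVector(f=f, N=N)


def distribution_moments(spec: CodingRatioSpec) -> tuple[float, float, float, float]:
    """First four raw moments <f>, <f^2>, <f^3>, <f^4> of the spec.

    Gamma moments are closed-form in (phi0, sigma_phi); triangular moments are
    delegated to the scipy density (numerical).  For the degenerate case the
    k-th moment is ``phi0**k``.
    """
    if spec.degenerate:
        p = spec.phi0
        return (p, p**2, p**3, p**4)
    if spec.family == "gamma":
        p, s2 = spec.phi0, spec.sigma_phi**2
        m1 = p
        m2 = s2 + p**2
        m3 = 2.0 * s2**2 / p + 3.0 * s2 * p + p**3
        m4 = 6.0 * s2**3 / p**2 + 11.0 * s2**2 + 6.0 * s2 * p**2 + p**4
        return (m1, m2, m3, m4)
    dist = spec.frozen_dist()
    return tuple(float(dist.moment(k)) for k in range(1, 5))


def make_triangular(phi_max: float, sigma_phi: float, skew: Skew) -> CodingRatioSpec:
    """Build a triangular coding-ratio spec with mode phi_max and sd sigma_phi.

    ``symmetric`` is the isosceles triangle on ``phi_max ± sqrt(6)*sigma_phi``
    (mean = mode).  ``negative`` / ``positive`` are one-sided triangles on
    ``[phi_max - 3*sqrt(2)*sigma_phi, phi_max]`` / its mirror image, with mean
    ``phi_max ∓ sqrt(2)*sigma_phi``.  Raises if the implied support leaves
    (0, 1).
    """
    if phi_max <= 0.0 or sigma_phi <= 0.0:
        raise ValueError("require phi_max > 0 and sigma_phi > 0")
    if skew == "symmetric":
        mean = phi_max
    elif skew == "negative":
        mean = phi_max - math.sqrt(2.0) * sigma_phi
    elif skew == "positive":
        mean = phi_max + math.sqrt(2.0) * sigma_phi
    else:
        raise ValueError(f"unknown skew {skew!r}")
    return CodingRatioSpec(
        family="triangular",
        phi0=mean,
        sigma_phi=sigma_phi,
        phi_max=phi_max,
        skew=skew,
    )
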