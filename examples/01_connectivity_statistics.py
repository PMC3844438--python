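"""Potentiation statistics under inhomogeneous Willshaw learning.

Computes the classical homogeneous capacity, the exact potentiation
probability of a sampled coding-ratio vector, and the analytic ensemble
moments of varsigma against a Monte-Carlo histogram.
"""

import numpy as np

import seqmem as sm
from seqmem.connectivity import sample_varsigma_ensemble

# classical homogeneous capacity: how many associations until c = 0.05?
P_classical = sm.willshaw_P(c=0.05, cm=0.1, f=0.01)
print(f"homogeneous capacity P(c=0.05, cm=0.1, f=0.01) = {P_classical:.1f}")

# one inhomogeneous realization: 10 % variation coefficient
spec = sm.CodingRatioSpec("gamma", phi0=0.01, sigma_phi=0.001)
phi = sm.sample_phi(spec, P=2000, N=100_000, seed=1)
stats = sm.schedule_stats(phi.f)
print(f"sampled phi (P=2000): varsigma = {stats.varsigma:.5f}, V^2 = {stats.V2:.3e}")

# ensemble mean/variance of varsigma vs Monte Carlo (the analytic curves
# that describe the spread of connectivity over network realizations)
for P in (10, 200, 2000):
    mean, var = sm.ensemble_moments(spec, P)
    mc = sample_varsigma_ensemble(spec, P, 50_000, seed=2)
    print(
        f"P={P:5d}: <varsigma> = {mean:.5e} (MC {mc.mean():.5e}), "
        f"sd = {np.sqrt(var):.2e} (MC {mc.std():.2e})"
    )
# The analytic ensemble moments should match the Monte-Carlo columns to
# within sampling error; the relative spread of varsigma grows with P.
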