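"""Shared fixtures: reference parameter sets and pre-built binary networks.

The mean-field experiments run at the reference scale N = 1e5 (cheap: the map
is two scalar equations).  Full binary-network fixtures are built at reduced
N with coding ratios chosen so the stable-replay wedge exists at that scale;
they are session-scoped because Willshaw learning over the Bernoulli
morphology is the expensive step.
"""

from __future__ import annotations

import numpy as np
import pytest

import seqmem as sm


@pytest.fixture(scope="session")
def reference_scale():
    """Reference mean-field parameters: N=1e5, cm=0.1, c=0.05, phi0=0.01."""
    return {"N": 100_000, "cm": 0.1, "c": 0.05, "phi0": 0.01}


@pytest.fixture(scope="session")
def homogeneous_phi(reference_scale):
    """Homogeneous coding-ratio vector calibrated to c=0.05 (P=6932)."""
    spec = sm.CodingRatioSpec("gamma", reference_scale["phi0"], 0.0)
    P, phi = sm.calibrate_P(
        spec, reference_scale["c"], reference_scale["cm"], "per_realization",
        seed=0, N=reference_scale["N"],
    )
    return phi


@pytest.fixture(scope="session")
def scaled_cell():
    """A stable-replay cell that exists at N=1e4: f=0.1, c=0.02, theta=44.

    At reduced network size the wedge shifts: sparser codes cannot separate
    signal from noise, so validation uses a denser code (f=0.1) and a lower
    noise connectivity (c=0.02, varsigma=0.2).  theta=44 sits mid-wedge
    (mean-field Gamma ~ 1), theta=150 is clearly silent.
    """
    N, cm, f, c = 10_000, 0.1, 0.1, 0.02
    P = round(sm.willshaw_P(c, cm, f))
    phi = sm.PatternSizeVector(f=np.full(P + 1, f), N=N)
    return {
        "N": N, "cm": cm, "f": f, "c": c, "P": P, "phi": phi,
        "theta_stable": 44.0, "theta_silent": 150.0, "Q": 15,
    }


@pytest.fixture(scope="session")
def scaled_networks(scaled_cell):
    """Six independently learned binary networks of the scaled stable cell."""
    nets = []
    for s in range(6):
        pats = sm.generate_patterns(
            scaled_cell["phi"].M, scaled_cell["N"], seed=1000 + s
        )
        nets.append(
            sm.learn_willshaw(pats, scaled_cell["cm"], seed=2000 + s, N=scaled_cell["N"])
        )
    return nets
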