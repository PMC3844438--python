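"""Which size transitions kill replay: small-to-big or big-to-small?

For each failed replay, records the sizes (M_tau, M_tau+1) of the last
correctly replayed pattern and its successor, at the two edges of the
stability wedge.
"""

import seqmem as sm

spec = sm.CodingRatioSpec("gamma", phi0=0.01, sigma_phi=0.0015)  # 15 %

for theta, edge in ((30.0, "high-threshold (silence-prone)"),
                    (25.0, "low-threshold (explosion-prone)")):
    sc = sm.termination_scatter(
        spec, N=100_000, cm=0.1, theta=theta, Q=100,
        n_real=2000, seed=7, c_target=0.05,
    )
    print(
        f"theta={theta:4.0f} [{edge}]: {sc.n_failed} failures, "
        f"{100 * sc.frac_above:.1f} % at small-to-big transitions"
    )
# At the high-threshold edge ~80 % of failures follow a small pattern that
# could not drive its (larger) successor; at the low-threshold edge the two
# directions are roughly balanced, because feedback inhibition compensates
# for oversized patterns but nothing compensates for undersized ones.
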