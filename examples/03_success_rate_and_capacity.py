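"""Replay success rates and the stability-capacity trade-off.

Estimates the success rate rho_t over fresh coding-ratio realizations, the
maximum retrievable sequence length T = max_theta T90, and a reduced capacity
sweep with its power-law fit.
"""

import seqmem as sm

N, cm = 100_000, 0.1
spec = sm.CodingRatioSpec("gamma", phi0=0.01, sigma_phi=0.0025)  # 25 %

curve = sm.success_rate(
    spec, N=N, cm=cm, theta=28.0, Q=100, n_real=100, seed=4, c_target=0.05
)
print(f"success at t=5: {curve.rho[5]:.2f}; at t=100: {curve.rho[100]:.2f}; "
      f"T90 = {sm.t90(curve)}")

T = sm.max_retrievable_length(
    spec, N=N, cm=cm, theta_grid=range(20, 41), Q=50, n_real=100, seed=5,
    c_target=0.05,
)
print(f"max retrievable length at c=0.05: T = {T}")

sweep = sm.capacity_sweep(
    spec, N=N, cm=cm, P_grid=[500, 1000, 2000, 4000, 5000, 6000, 8000, 12000],
    theta_grid=range(15, 46), Q=30, n_real=60, seed=6,
)
print(sweep.to_frame().to_string(index=False))
print(f"fitted exponent alpha = {sweep.alpha and round(sweep.alpha, 2)}, "
      f"cutoff capacity Pc = {sweep.Pc and round(sweep.Pc)}")
# T stays at the plateau (full sequence) for small P and falls off as a power
# law past the cutoff: storing more associations buys capacity at the cost of
# retrievable sequence length.
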