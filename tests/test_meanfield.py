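"""Mean-field replay map: input moments, inhibition, fixed points, regimes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

import seqmem as sm
from seqmem.meanfield import MeanFieldParams, run_replay_ensemble


def make_params(**kw):
    base = dict(N=100_000, cm=0.1, theta=26.0, varsigma=0.5, V2=0.0)
    base.update(kw)
    return MeanFieldParams(**base)


class TestInputMoments:
    def test_pure_signal_binomial(self):
        p = make_params()
        mu_on, s2_on, _, _ = sm.input_moments(1000.0, 0.0, p)
        assert mu_on == pytest.approx(0.1 * 1000)
        assert s2_on == pytest.approx(0.1 * 1000 * 0.9)

    def test_silent_network_all_zero(self):
        p = make_params()
        assert sm.input_moments(0.0, 0.0, p) == pytest.approx((0.0, 0.0, 0.0, 0.0))

    def test_against_binomial_mixture_sampling(self):
        """V2=0 moments equal those of the explicit input model: On inputs are
        Binomial(m, cm) + Binomial(n, cm*varsigma), Off inputs
        Binomial(m+n, cm*varsigma)."""
        m, n, cm, vs = 1000, 50, 0.1, 0.5
        p = make_params(cm=cm, varsigma=vs)
        rng = np.random.default_rng(42)
        draws = 200_000
        on = rng.binomial(m, cm, draws) + rng.binomial(n, cm * vs, draws)
        off = rng.binomial(m + n, cm * vs, draws)
        mu_on, s2_on, mu_off, s2_off = sm.input_moments(float(m), float(n), p)
        assert abs(mu_on - on.mean()) < 3 * on.std() / np.sqrt(draws)
        assert abs(mu_off - off.mean()) < 3 * off.std() / np.sqrt(draws)
        assert s2_on == pytest.approx(on.var(), rel=0.02)
        assert s2_off == pytest.approx(off.var(), rel=0.02)

    def test_correlation_term_increases_off_variance(self):
        p0 = make_params(V2=0.0)
        p1 = make_params(V2=0.01)
        assert sm.input_moments(500.0, 500.0, p1)[3] > sm.input_moments(500.0, 500.0, p0)[3]


class TestInhibition:
    def test_linear_proportionality(self):
        p = make_params(b=0.05)
        assert sm.inhibition(1000.0, p) == pytest.approx(50.0)

    def test_nonlinear_constants_and_continuity(self):
        """For b=0.05, phi0=0.01, N=1e5: lambda=0.01, nu ~ 780.28,
        kappa ~ 55.56, and h is continuous with slope b at x = phi0*N."""
        from seqmem.meanfield import _nonlinear_constants

        p = make_params(b=0.05, inhibition="nonlinear", phi0=0.01)
        kappa, nu, lam = _nonlinear_constants(p)
        assert lam == pytest.approx(0.01)
        assert nu == pytest.approx(1000 - 100 * np.log(9), rel=1e-12)
        assert kappa == pytest.approx(500 / 9, rel=1e-12)
        xop = 1000.0
        assert sm.inhibition(xop, p) == pytest.approx(0.05 * xop, rel=1e-10)
        # slope continuity: numeric derivative on both sides equals b
        eps = 1e-4
        left = (sm.inhibition(xop, p) - sm.inhibition(xop - eps, p)) / eps
        right = (sm.inhibition(xop + eps, p) - sm.inhibition(xop, p)) / eps
        assert left == pytest.approx(0.05, rel=1e-5)
        assert right == pytest.approx(0.05, rel=1e-5)

    def test_supralinear_below_operating_point(self):
        """The sigmoid branch stays below b*x: weaker inhibition (an effective
        boost) whenever activity is under phi0*N."""
        p = make_params(b=0.05, inhibition="nonlinear", phi0=0.01)
        x = np.linspace(1.0, 999.0, 200)
        assert np.all(sm.inhibition(x, p) < 0.05 * x)
        assert np.all(sm.inhibition(x, p) >= 0.0)

    def test_undefined_operating_point_raises(self):
        # lambda*phi0*N = 1e-4 * N <= 1 breaks the construction
        with pytest.raises(ValueError):
            make_params(N=9_000, inhibition="nonlinear", phi0=0.01)

    def test_b_defaults_to_cm_varsigma(self):
        p = make_params(cm=0.1, varsigma=0.5)
        assert p.b == pytest.approx(0.05)


class TestStep:
    def test_silent_state_absorbing(self):
        p = make_params(theta=10.0)
        m, n = sm.step(0.0, 0.0, 1000.0, p)
        assert m == 0.0 and n == 0.0

    def test_phi_of_zero_is_half(self):
        # mu_on == theta_eff -> half the target pattern fires
        p = make_params(theta=100.0, b=0.0, V2=0.0)
        m, _ = sm.step(1000.0, 0.0, 500.0, p)
        assert m == pytest.approx(250.0 * 2 * ndtr(0.0), rel=1e-12)  # = 250

    def test_zero_variance_hard_threshold(self):
        p = make_params(cm=1.0, theta=5.0, b=0.0, varsigma=0.0)
        # cm=1, n=0: sigma_on = 0, mu_on = m
        m_hi, _ = sm.step(6.0, 0.0, 100.0, p)
        m_lo, _ = sm.step(4.0, 0.0, 100.0, p)
        m_eq, _ = sm.step(5.0, 0.0, 100.0, p)
        assert (m_hi, m_lo, m_eq) == (100.0, 0.0, 50.0)

    @given(
        m=st.floats(0, 1000),
        n=st.floats(0, 5000),
        dtheta=st.floats(0.1, 20),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_threshold(self, m, n, dtheta):
        """Raising theta never increases the next hits or false alarms."""
        p_lo = make_params(theta=20.0, V2=0.005)
        p_hi = make_params(theta=20.0 + dtheta, V2=0.005)
        m1, n1 = sm.step(m, n, 1000.0, p_lo)
        m2, n2 = sm.step(m, n, 1000.0, p_hi)
        assert m2 <= m1 + 1e-9
        assert n2 <= n1 + 1e-9


def independent_homogeneous_map(m, n, M, N, cm, c, theta, steps):
    """Homogeneous-model reference map, written directly from the definition:
    signal inputs Binomial(m, cm), noise inputs Binomial(n, c), threshold
    shifted by b*(m+n) with b=c; no schedule correlations."""
    out = [(m, n)]
    for _ in range(steps):
        x = m + n
        th = theta + c * x
        mu_on, s_on = cm * m + c * n, np.sqrt(cm * m * (1 - cm) + c * n * (1 - c))
        mu_off, s_off = c * x, np.sqrt(c * x * (1 - c))
        m = M * (ndtr((mu_on - th) / s_on) if s_on > 0 else float(mu_on >= th))
        n = (N - M) * (ndtr((mu_off - th) / s_off) if s_off > 0 else float(mu_off >= th))
        out.append((m, n))
    return out


class TestReplay:
    def test_matches_independent_homogeneous_implementation(self):
        """With V2=0 and constant sizes the map reduces to the homogeneous
        model; compare against a from-scratch implementation of that model."""
        N, cm, vs, theta = 100_000, 0.1, 0.5, 27.0
        phi = sm.PatternSizeVector(f=np.full(51, 0.01), N=N)
        p = MeanFieldParams(N=N, cm=cm, theta=theta, varsigma=vs, V2=0.0)
        tr = sm.run_replay(phi, p, 50)
        ref = independent_homogeneous_map(
            1000.0, 0.0, 1000.0, N, cm, cm * vs, theta, 50
        )
        ref_m = np.array([r[0] for r in ref])
        ref_n = np.array([r[1] for r in ref])
        assert np.allclose(tr.m, ref_m, rtol=1e-12)
        assert np.allclose(tr.n, ref_n, rtol=1e-12)

    def test_stable_wedge_homogeneous(self, homogeneous_phi, reference_scale):
        """Mid-wedge threshold: the calibrated homogeneous network replays the
        full 100-step sequence with near-perfect quality."""
        p = sm.params_for_phi(homogeneous_phi, reference_scale["cm"], 28.0)
        tr = sm.run_replay(homogeneous_phi, p, 100)
        assert np.all(tr.gamma > 0.9)
        assert tr.m[-1] / tr.M[-1] > 0.95
        assert tr.n[-1] / (reference_scale["N"] - tr.M[-1]) < 0.01

    def test_threshold_dominates_gives_silence(self, homogeneous_phi, reference_scale):
        p = sm.params_for_phi(homogeneous_phi, reference_scale["cm"], 90.0)
        tr = sm.run_replay(homogeneous_phi, p, 20)
        # Gaussian tails leave a sub-neuron residue at t=1; gone by t=2
        assert tr.m[1] < 0.1 and tr.n[1] < 0.1
        assert np.all(tr.m[2:] < 1e-9) and np.all(tr.n[2:] < 1e-9)
        assert np.all(np.abs(tr.gamma[1:]) < 1e-4)

    def test_bounds_preserved(self, reference_scale):
        """0 <= m <= M and 0 <= n <= N-M at every step, across regimes."""
        spec = sm.CodingRatioSpec("gamma", 0.01, 0.002)
        for theta in (22.0, 26.0, 30.0, 40.0):
            P, phi = sm.calibrate_P(spec, 0.05, 0.1, "per_realization", seed=9, N=reference_scale["N"])
            p = sm.params_for_phi(phi, reference_scale["cm"], theta)
            tr = sm.run_replay(phi, p, 100)
            assert np.all(tr.m >= 0) and np.all(tr.m <= tr.M + 1e-9)
            assert np.all(tr.n >= 0) and np.all(tr.n <= reference_scale["N"] - tr.M + 1e-9)
            assert np.all(np.abs(tr.gamma) <= 1 + 1e-12)

    def test_epileptic_state_half_active(self, reference_scale):
        """Low threshold with 20 % size variation: balanced excitation and
        linear feedback inhibition pin both populations near one half."""
        spec = sm.CodingRatioSpec("gamma", 0.01, 0.002)
        saturated = 0
        for seed in range(5):
            P, phi = sm.calibrate_P(spec, 0.05, 0.1, "per_realization", seed=seed, N=reference_scale["N"])
            p = sm.params_for_phi(phi, reference_scale["cm"], 24.0)
            tr = sm.run_replay(phi, p, 100)
            frac_hit = tr.m[-1] / tr.M[-1]
            frac_fa = tr.n[-1] / (reference_scale["N"] - tr.M[-1])
            if frac_hit + frac_fa > 0.5:  # entered the saturated state
                saturated += 1
                assert 0.4 < frac_hit < 0.6
                assert 0.4 < frac_fa < 0.6
        assert saturated >= 3

    def test_partial_cue_option(self, homogeneous_phi, reference_scale):
        p = sm.params_for_phi(homogeneous_phi, reference_scale["cm"], 28.0)
        tr = sm.run_replay(homogeneous_phi, p, 10, m0=800.0)
        assert tr.m[0] == 800.0
        assert tr.gamma[-1] > 0.9  # recovers from a degraded cue mid-wedge

    def test_vectorized_ensemble_matches_scalar_loop(self, reference_scale):
        """run_replay_ensemble is an exact vectorization of run_replay."""
        spec = sm.CodingRatioSpec("gamma", 0.01, 0.0015)
        N, cm = reference_scale["N"], reference_scale["cm"]
        rows = []
        Ms, vss, v2s = [], [], []
        for s in range(4):
            phi = sm.sample_phi(spec, 60, N, seed=100 + s)
            stats = sm.schedule_stats(phi.f)
            p = MeanFieldParams(N=N, cm=cm, theta=27.0, varsigma=stats.varsigma, V2=stats.V2)
            rows.append(sm.run_replay(phi, p, 50))
            Ms.append(phi.M_real[:51])
            vss.append(stats.varsigma)
            v2s.append(stats.V2)
        m, n, g = run_replay_ensemble(
            np.array(Ms), N, cm, 27.0, np.array(vss), np.array(v2s), 50
        )
        for i, tr in enumerate(rows):
            assert np.allclose(m[i], tr.m, rtol=1e-12, atol=1e-9)
            assert np.allclose(n[i], tr.n, rtol=1e-12, atol=1e-9)
            assert np.allclose(g[i], tr.gamma, rtol=1e-10, atol=1e-10)
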