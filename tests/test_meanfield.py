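import numpy as np
import pytest
from scipy.special import erfc

from adexmf import (
    ModelParams,
    NodeState,
    find_fixed_points,
    meanfield_derivatives,
    membrane_moments,
    transfer_function,
)

# --- independent transcription of the membrane-moment formulas -------------
# (kept deliberately separate from the package implementation)

RATE_EPS = 1e-3  # documented floor on presynaptic rates


def oracle_moments(nu_e_tot, nu_i, W_pA, p, population="e"):
    K_e, K_i = p.K_e, p.K_i
    fe = nu_e_tot * K_e + RATE_EPS
    fi = nu_i * K_i + RATE_EPS
    Qe, Qi = p.Q_e * 1e-9, p.Q_i * 1e-9
    te, ti = p.tau_syn_e * 1e-3, p.tau_syn_i * 1e-3
    Ee, Ei = p.E_exc * 1e-3, p.E_inh * 1e-3
    gL, Cm = p.g_L * 1e-9, p.C_m * 1e-12
    EL = (p.E_L_e if population == "e" else p.E_L_i) * 1e-3
    W = W_pA * 1e-12
    mu_Ge, mu_Gi = Qe * te * fe, Qi * ti * fi
    mu_G = gL + mu_Ge + mu_Gi
    mu_V = (mu_Ge * Ee + mu_Gi * Ei + gL * EL - W) / mu_G
    tau_m = Cm / mu_G
    Ue = Qe / mu_G * (Ee - mu_V)
    Ui = Qi / mu_G * (Ei - mu_V)
    se, si = fe * (Ue * te) ** 2, fi * (Ui * ti) ** 2
    sigma_V = np.sqrt(se / (2 * (te + tau_m)) + si / (2 * (ti + tau_m)))
    tau_V = (se + si) / (se / (te + tau_m) + si / (ti + tau_m))
    return mu_V * 1e3, sigma_V * 1e3, tau_V * 1e3


def oracle_threshold_mV(mu_V, sigma_V, tau_V, coeffs, p):
    V = (mu_V + 60.0) / 10.0
    S = (sigma_V - 4.0) / 6.0
    T = tau_V * 1e-3 * (p.g_L * 1e-9) / (p.C_m * 1e-12) - 0.5
    P = coeffs
    return 1e3 * (
        P[0] + P[1] * V + P[2] * S + P[3] * T + P[4] * V**2 + P[5] * S**2
        + P[6] * T**2 + P[7] * V * S + P[8] * V * T + P[9] * S * T
    )


class TestMembraneMoments:
    def test_leak_only_limit(self, params):
        mu_V, sigma_V, tau_V = membrane_moments(0.0, 0.0, 0.0, params)
        assert mu_V == pytest.approx(params.E_L_e, abs=1e-3)
        assert sigma_V >= 0
        assert tau_V > 0

    def test_adaptation_hyperpolarizes(self, params):
        mu0, _, _ = membrane_moments(0.0, 0.0, 0.0, params)
        mu1, _, _ = membrane_moments(0.0, 0.0, 200.0, params)
        assert mu1 < mu0 < params.E_L_e + 1e-3

    def test_matches_independent_transcription(self, params):
        for args in [(10.0, 10.0, 0.0), (3.0, 7.0, 120.0), (0.5, 0.0, 30.0)]:
            got = membrane_moments(*args, params)
            want = oracle_moments(*args, params)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-12)

    def test_inhibitory_population_uses_its_leak(self, params):
        mu_i, _, _ = membrane_moments(0.0, 0.0, 0.0, params, population="i")
        assert mu_i == pytest.approx(params.E_L_i, abs=1e-3)

    def test_negative_rate_rejected(self, params):
        with pytest.raises(ValueError):
            membrane_moments(-1.0, 0.0, 0.0, params)


class TestTransferFunction:
    def test_erfc_form_against_oracle(self, params, tfs):
        tf_e = tfs[0]
        for ne, ni, w in [(5.0, 5.0, 0.0), (20.0, 10.0, 100.0), (1.0, 0.1, 0.0)]:
            mu_V, sigma_V, tau_V = oracle_moments(ne, ni, w, params)
            vthr = oracle_threshold_mV(mu_V, sigma_V, tau_V, tf_e.coeffs, params)
            expected = erfc((vthr - mu_V) / (np.sqrt(2) * sigma_V)) / (2 * tau_V * 1e-3)
            expected = min(expected, 1e3 / params.T_refrac)
            got = transfer_function(ne, ni, w, params, tf_e)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_saturation_near_refractory_limit(self, params, tfs):
        rate = transfer_function(500.0, 0.0, 0.0, params, tfs[0])
        assert 170.0 <= rate <= 1e3 / params.T_refrac

    def test_strong_inhibition_silences(self, params, tfs):
        rate = transfer_function(0.0, 100.0, 0.0, params, tfs[0])
        assert rate < 0.1

    def test_monotone_in_excitatory_input(self, params, tfs):
        grid = np.linspace(0.0, 200.0, 200)
        rates = np.array([transfer_function(x, 10.0, 0.0, params, tfs[0]) for x in grid])
        assert np.all(np.diff(rates) >= -1e-9)

    def test_monotone_nonincreasing_in_adaptation(self, params, tfs):
        grid = np.linspace(0.0, 500.0, 200)
        rates = np.array([transfer_function(10.0, 10.0, w, params, tfs[0]) for w in grid])
        assert np.all(np.diff(rates) <= 1e-9)

    def test_rates_within_refractory_bound(self, params, tfs):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ne, ni = rng.uniform(0, 300), rng.uniform(0, 300)
            w = rng.uniform(0, 1000)
            for tf in tfs:
                r = transfer_function(ne, ni, w, params, tf)
                assert 0.0 <= r <= 1e3 / params.T_refrac


class TestDerivatives:
    def test_adaptation_stationary_closed_form(self, tfs):
        # stationary adaptation at clamped rate: W* = b_e * tau_w * nu_e
        p = ModelParams(b_e=60.0, tau_w=500.0, a=0.0)
        w_star = p.b_e * p.tau_w * 10.0 * 1e-3  # pA
        assert w_star == pytest.approx(300.0)
        s = NodeState(nu_e=10.0, nu_i=10.0, W_e=w_star)
        ds = meanfield_derivatives(s, 0.0, p, *tfs)
        assert ds.W_e == pytest.approx(0.0, abs=1e-12)

    def test_adaptation_relaxation_recovers_closed_form(self, tfs):
        p = ModelParams(b_e=60.0, tau_w=500.0)
        s = NodeState(nu_e=10.0, nu_i=10.0, W_e=0.0)
        dt = 1.0  # ms
        for _ in range(int(10 * p.tau_w / dt)):
            ds = meanfield_derivatives(s, 0.0, p, *tfs)
            s.W_e += ds.W_e * dt
        assert s.W_e == pytest.approx(300.0, rel=0.01)

    def test_zero_covariance_reduces_to_first_order(self, params, tfs):
        s = NodeState(nu_e=5.0, nu_i=8.0, c_ee=0, c_ei=0, c_ii=0, W_e=50.0, W_i=0)
        ds = meanfield_derivatives(s, 2.0, params, *tfs)
        F_e = transfer_function(s.nu_e + 2.0, s.nu_i, s.W_e, params, tfs[0])
        F_i = transfer_function(s.nu_e + 2.0, s.nu_i, s.W_i, params, tfs[1])
        assert ds.nu_e == pytest.approx((F_e - s.nu_e) / params.T, rel=1e-6)
        assert ds.nu_i == pytest.approx((F_i - s.nu_i) / params.T, rel=1e-6)

    def test_hessian_term_shifts_rate_derivative(self, params, tfs):
        s0 = NodeState(nu_e=5.0, nu_i=8.0)
        s1 = NodeState(nu_e=5.0, nu_i=8.0, c_ee=1.0, c_ei=0.5, c_ii=1.0)
        d0 = meanfield_derivatives(s0, 2.0, params, *tfs)
        d1 = meanfield_derivatives(s1, 2.0, params, *tfs)
        assert d0.nu_e != pytest.approx(d1.nu_e, abs=1e-12)


class TestFixedPoints:
    def test_down_state_hyperpolarized(self, tfs):
        p = ModelParams(E_L_e=-80.0, E_L_i=-80.0, b_e=0.0, T=19.0)
        fps = find_fixed_points(0.0, p, tfs)
        stable_down = [s for s, ok in fps if ok and s.nu_e < 1.0]
        assert stable_down

    def test_up_state_depolarized(self, tfs):
        p = ModelParams(E_L_e=-64.0, E_L_i=-64.0, b_e=0.0, T=19.0)
        fps = find_fixed_points(1.5, p, tfs)
        ups = [s for s, ok in fps if ok and 0.0 < s.nu_e <= 50.0]
        assert ups

    def test_paroxysmal_state_excitation_dominated(self, tfs):
        p = ModelParams(E_L_e=-60.0, E_L_i=-80.0, b_e=0.0, T=19.0)
        fps = find_fixed_points(0.0, p, tfs)
        parox = [s for s, ok in fps if ok and s.nu_e > 175.0]
        assert parox

    def test_residual_small_at_down_fixed_point(self, tfs):
        p = ModelParams(E_L_e=-80.0, E_L_i=-80.0, b_e=0.0, T=19.0)
        fps = find_fixed_points(0.0, p, tfs)
        down = min((s for s, ok in fps if ok), key=lambda s: s.nu_e)
        ds = meanfield_derivatives(down, 0.0, p, *tfs)
        assert np.abs(ds.as_array()).max() < 1e-8

    def test_stable_point_is_quiescent_under_integration(self, tfs):
        # integrating the noiseless node from a stable fixed point for 2 s
        # moves nu_e by < 0.1 Hz
        from adexmf.connectome import Connectome
        from adexmf.network import SimulationConfig, simulate

        p = ModelParams(E_L_e=-60.0, E_L_i=-80.0, b_e=0.0, T=19.0)
        fps = find_fixed_points(0.0, p, tfs)
        parox = [s for s, ok in fps if ok and s.nu_e > 175.0][0]
        c1 = Connectome(np.ones((1, 1)), np.zeros((1, 1)))
        cfg = SimulationConfig(duration=2000.0, transient=0.0, S=0.0,
                               nu_drive=0.0, sigma=0.0, seed=0)
        ts = simulate(c1, cfg, p, tfs, initial_state=parox)
        assert abs(ts.nu_e[-1, 0] - parox.nu_e) < 0.1
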