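"""Mean-field reduction: elementary functions against independent
oracles, fixed points, attractor enumeration and basin bisection."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfcx

from wagernet.meanfield import (
    MeanFieldParams,
    basin_boundary,
    classify_state,
    condition_rates,
    drives,
    enumerate_attractors,
    mu_sigma,
    psi,
    solve_fixed_point,
    transfer,
)


def psi_oracle(nu_hz: float, p: MeanFieldParams, n_terms: int = 40) -> float:
    """Exact-rational direct evaluation of the saturating NMDA series,
    using the alternating binomial sum for T_n (safe with Fractions)."""
    nu = Fraction(nu_hz).limit_denominator(10**6) / 1000
    tr = Fraction(p.tau_NMDA_rise)
    td = Fraction(p.tau_NMDA_decay)
    tn_ = Fraction(p.tau_NMDA)
    al = Fraction(p.alpha)
    ntau = nu * tn_
    total = Fraction(0)
    for n in range(1, n_terms + 1):
        Tn = Fraction(0)
        for k in range(n + 1):
            Tn += ((-1) ** k * math.comb(n, k)
                   * tr * (1 + ntau) / (tr * (1 + ntau) + k * td))
        total += (-al * tr) ** n * Tn / math.factorial(n + 1)
    val = ntau / (1 + ntau) * (1 + total / (1 + ntau))
    return float(val)


class TestPsi:
    def test_zero_rate(self, mf_params):
        assert psi(0.0, mf_params) == 0.0

    @pytest.mark.parametrize("nu", [0.5, 3.0, 10.0, 30.0, 80.0])
    def test_matches_exact_series_oracle(self, mf_params, nu):
        assert psi(nu, mf_params) == pytest.approx(
            psi_oracle(nu, mf_params), rel=1e-9)

    def test_strictly_increasing(self, mf_params):
        grid = np.linspace(0.0, 100.0, 201)
        vals = np.asarray(psi(grid, mf_params))
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals <= 1.0)


class TestDrives:
    def test_zero_rates_zero_drives(self, mf_params):
        a, n, g = drives(np.zeros(5), mf_params)
        assert np.all(a == 0) and np.all(n == 0) and np.all(g == 0)

    def test_weighted_sum_against_hand_computation(self, mf_params):
        nu = np.array([3.0, 5.0, 2.0, 4.0, 9.0])
        a, n, g = drives(nu, mf_params)
        W, r = mf_params.weights, mf_params.r
        # onto pool L (index 0), direct summation
        expect_a = sum(r[j] * W[j, 0] * nu[j] / 1e3 for j in range(4))
        expect_n = sum(r[j] * W[j, 0] * psi(nu[j], mf_params) for j in range(4))
        assert a[0] == pytest.approx(expect_a, rel=1e-12)
        assert n[0] == pytest.approx(expect_n, rel=1e-12)
        assert g[0] == pytest.approx(nu[4] / 1e3, rel=1e-12)

    def test_inhibitory_drive_uses_unit_weight(self, mf_params):
        nu = np.array([0.0, 0.0, 0.0, 0.0, 12.0])
        _, _, g = drives(nu, mf_params)
        assert np.allclose(g, 12.0 / 1e3)


def mu_sigma_oracle(nu, V_avg, p, lam):
    """Independent transcription of the potential statistics."""
    nu = np.asarray(nu, float) / 1e3
    lam = np.asarray(lam, float)
    nu_ext = (p.nu_ext + lam) / 1e3
    r, W = p.r, p.weights
    psis = np.array([psi(v * 1e3, p) for v in nu[:4]])
    nA = np.array([(r * nu[:4] * W[:4, x]).sum() for x in range(5)])
    nN = np.array([(r * psis * W[:4, x]).sum() for x in range(5)])
    nG = W[4] * nu[4]
    J = 1 + p.gamma * np.exp(-p.beta * np.asarray(V_avg))
    rho1 = p.gN_NE_over_gm / J
    rho2 = p.beta * p.gN_NE_over_gm * (np.asarray(V_avg) - p.V_E) * (J - 1) / J**2
    S = 1 + p.T_ext * nu_ext + p.T_AMPA * nA + (rho1 + rho2) * nN + p.T_I * nG
    mu = ((p.T_ext * nu_ext + p.T_AMPA * nA + rho1 * nN) * p.V_E
          + rho2 * nN * np.asarray(V_avg) + p.T_I * nG * p.V_I + p.V_L) / S
    tau = p.C_m * 1e3 / (p.g_m * S)
    sig = np.sqrt(p.g_ext**2 * (np.asarray(V_avg) - p.V_E)**2 * nu_ext
                  * p.tau_AMPA**2 * tau / (p.g_m**2 * p.tau_m**2))
    return mu, sig, S, tau


class TestMuSigma:
    def test_leak_only_limit(self, mf_params):
        import dataclasses
        p0 = dataclasses.replace(mf_params, nu_ext=0.0)
        st = mu_sigma(np.zeros(5), np.full(5, -52.5), p0)
        assert np.allclose(st.S, 1.0)
        assert np.allclose(st.mu, p0.V_L)
        assert np.allclose(st.sigma, 0.0)

    def test_matches_independent_transcription(self, mf_params):
        nu = np.array([3.1, 2.9, 2.5, 2.4, 8.3])
        V = np.array([-52.0, -52.1, -52.4, -52.5, -53.0])
        lam = condition_rates("stimulus", 50.0, 14.0)
        st = mu_sigma(nu, V, mf_params, lam)
        mu, sig, S, tau = mu_sigma_oracle(nu, V, mf_params, lam)
        assert np.allclose(st.mu, mu, rtol=1e-10)
        assert np.allclose(st.sigma, sig, rtol=1e-10)
        assert np.allclose(st.S, S, rtol=1e-10)
        assert np.allclose(st.tau, tau, rtol=1e-10)


class TestTransfer:
    def test_deeply_subthreshold_silent(self):
        nu = transfer(-100.0, 1.0, 10.0, 2.0, 2.0, -50.0, -55.0)
        assert nu < 1e-6

    def test_refractory_ceiling(self):
        for mu in (-60.0, -50.0, -30.0, 0.0):
            nu = transfer(mu, 4.0, 5.0, 2.0, 2.0, -50.0, -55.0)
            assert 0.0 <= nu <= 1e3 / 2.0

    @pytest.mark.parametrize("mu,sigma", [
        (-56.0, 2.0), (-53.0, 3.0), (-51.0, 1.5), (-49.5, 4.0), (-45.0, 2.5),
    ])
    def test_against_adaptive_quadrature_oracle(self, mu, sigma):
        tau_x, tau_rp, tau_ampa = 7.5, 2.0, 2.0
        v_thr, v_reset = -50.0, -55.0
        k = tau_ampa / tau_x
        a = (v_thr - mu) / sigma * (1 + 0.5 * k) + 1.03 * math.sqrt(k) - 0.5 * k
        b = (v_reset - mu) / sigma
        integral, err = quad(lambda u: math.sqrt(math.pi) * erfcx(-u), b, a,
                             limit=400, epsabs=1e-13, epsrel=1e-12)
        expect = 1e3 / (tau_rp + tau_x * integral)
        got = transfer(mu, sigma, tau_x, tau_rp, tau_ampa, v_thr, v_reset)
        assert got == pytest.approx(expect, rel=1e-6)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            transfer(-52.0, 0.0, 10.0, 2.0, 2.0, -50.0, -55.0)


class TestFixedPoints:
    def test_spontaneous_state_near_3hz(self, mf_params):
        fp = solve_fixed_point([3, 3, 3, 3, 9], mf_params,
                               lam=condition_rates("delay", 0.0, 0.0))
        assert fp.stable
        assert fp.classification == "spontaneous"
        assert fp.nu[0] == pytest.approx(3.0, abs=1.0)
        assert fp.nu[0] == pytest.approx(fp.nu[1], abs=1e-3)

    def test_sure_attractor_low_direction_pools(self, mf_params):
        fp = solve_fixed_point([2, 2, 45, 3, 9], mf_params,
                               lam=condition_rates("sure", 0.0, 0.0))
        assert fp.classification == "decision_S"
        assert fp.nu[0] == pytest.approx(2.0, abs=1.0)
        assert fp.nu[2] > 20.0

    def test_mirrored_initial_conditions_give_mirrored_fixed_points(self, mf_params):
        lam = condition_rates("stimulus", 50.0, 0.0)
        a = solve_fixed_point([40, 5, 2, 4, 12], mf_params, lam=lam)
        b = solve_fixed_point([5, 40, 2, 4, 12], mf_params, lam=lam)
        assert a.classification == "decision_L"
        assert b.classification == "decision_R"
        assert a.nu[0] == pytest.approx(b.nu[1], abs=1e-3)
        assert a.nu[1] == pytest.approx(b.nu[0], abs=1e-3)

    def test_every_residual_small(self, mf_params):
        fp = solve_fixed_point([25.1, 24.9, 2, 5, 15], mf_params,
                               lam=condition_rates("stimulus", 50.0, 0.0))
        assert fp.stable
        assert fp.residual < 1e-3

    def test_invalid_initial_rates_rejected(self, mf_params):
        with pytest.raises(ValueError):
            solve_fixed_point([-1, 3, 3, 3, 9], mf_params)
        with pytest.raises(ValueError):
            solve_fixed_point([3, 3, 3], mf_params)


class TestAttractorEnumeration:
    def test_bistable_regime_two_decision_attractors(self, mf_params):
        land = enumerate_attractors(mf_params, 15.0, 0.0, "stimulus")
        assert land.classes == {"decision_L", "decision_R"}

    def test_multistable_regime_includes_mixed(self, mf_params):
        land = enumerate_attractors(mf_params, 50.0, 0.0, "stimulus")
        assert {"decision_L", "decision_R", "mixed"} <= land.classes

    def test_delay_condition_memory_attractors(self, mf_params):
        land = enumerate_attractors(mf_params, 0.0, 0.0, "delay")
        assert land.classes == {"spontaneous", "decision_L", "decision_R"}

    def test_deduplication(self, mf_params):
        land = enumerate_attractors(
            mf_params, 50.0, 0.0, "stimulus",
            init_grid=[(40.0, 2.0, 2.0), (41.0, 2.5, 2.0), (39.0, 3.0, 2.0)])
        assert len(land.fixed_points) == 1


class TestClassification:
    def test_labels(self):
        assert classify_state(np.array([2, 2, 2, 3, 8])) == "spontaneous"
        assert classify_state(np.array([35, 2, 1, 4, 13])) == "decision_L"
        assert classify_state(np.array([2, 35, 1, 4, 13])) == "decision_R"
        assert classify_state(np.array([1, 1, 33, 4, 13])) == "decision_S"
        assert classify_state(np.array([19, 19.5, 1, 5, 16])) == "mixed"
        assert classify_state(np.array([19, 35, 1, 5, 16])) == "other"


class TestBasins:
    def test_mirror_symmetry_and_two_sided_probes(self, mf_params,
                                                  l50_landscape):
        fp_L = l50_landscape["fp_L"]
        pts_L = l50_landscape["pts_L"]
        pts_R = l50_landscape["pts_R"]
        assert len(pts_L) >= 4 and len(pts_R) >= 4
        # mirror image across the diagonal, pointwise up to bisection
        # precision (compare sorted swapped coordinates)
        mirrored = np.sort(pts_R[:, ::-1], axis=0)
        direct = np.sort(pts_L, axis=0)
        n = min(len(mirrored), len(direct))
        assert np.allclose(direct[:n], mirrored[:n], atol=0.5)

        # definition check: points straddling the boundary converge to
        # different attractors
        base = fp_L.nu.copy()
        p = pts_L[0]
        d = p - base[:2]
        d /= np.linalg.norm(d)
        lam = condition_rates("stimulus", 50.0, 0.0)
        inside = base.copy()
        inside[:2] = p - 0.15 * d
        outside = base.copy()
        outside[:2] = p + 0.15 * d
        fp_in = solve_fixed_point(inside, mf_params, lam=lam)
        fp_out = solve_fixed_point(outside, mf_params, lam=lam)
        assert fp_in.classification == "decision_L"
        assert fp_out.classification != "decision_L"
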