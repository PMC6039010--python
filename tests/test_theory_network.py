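import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import phaselag as pl
from phaselag.model import DelaySpec, FrequencySpec, StrengthSpec
from phaselag.theory_network import SyncSolution, quadrant

TWO_PI = 2.0 * np.pi


class TestNormalizeAngles:
    def test_joint_pi_shift(self):
        a, b = pl.normalize_angles(2.0, 2.0)
        assert a == pytest.approx(2.0 - np.pi)
        assert b == pytest.approx(2.0 - np.pi)

    def test_right_half_plane_unchanged(self):
        assert pl.normalize_angles(0.4, 0.2) == (pytest.approx(0.4),
                                                 pytest.approx(0.2))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(tm=st.floats(-6.0, 6.0), td=st.floats(-6.0, 6.0),
           phi=st.floats(-np.pi, np.pi))
    def test_sine_sum_identity_preserved(self, tm, td, phi):
        a, b = pl.normalize_angles(tm, td)
        orig = 2 * np.sin(phi + tm) * np.cos(td)
        new = 2 * np.sin(phi + a) * np.cos(b)
        assert new == pytest.approx(orig, abs=1e-12)
        assert np.cos(a) >= 0


class TestClusterOffset:
    @pytest.mark.parametrize("angle,expected", [
        (0.3 * np.pi, 0.0),
        (0.8 * np.pi, np.pi),
        (2.3 * np.pi, 0.0),           # periodicity + 2 n pi
    ])
    def test_branch_rule(self, angle, expected):
        psi2, marginal = pl.cluster_offset(Omega=angle, tau2=1.0)
        assert psi2 == expected and not marginal

    def test_boundary_flagged_marginal(self):
        _, marginal = pl.cluster_offset(Omega=np.pi / 2, tau2=1.0)
        assert marginal


class TestQuadrant:
    def test_interior_angles(self):
        assert quadrant(0.3)[0] == 1
        assert quadrant(2.0)[0] == 2
        assert quadrant(3.5)[0] == 3
        assert quadrant(5.5)[0] == 4

    def test_boundary_goes_to_lower_quadrant(self):
        q, marginal = quadrant(np.pi / 2)
        assert q == 1 and marginal
        q, marginal = quadrant(np.pi)
        assert q == 2 and marginal


class TestSyncFrequencyNetwork:
    def test_zero_delay_root_is_mu(self):
        d = DelaySpec(kind="single", tau1=0.0, tau2=0.0)
        sols = pl.sync_frequency_network(TWO_PI, 1.0, 6.0, d, "random",
                                         r=0.5)
        assert len(sols) == 1
        assert sols[0].Omega == pytest.approx(TWO_PI, abs=1e-9)

    def test_depressed_frequency_for_short_delays(self):
        # mu = 1 Hz, tau = [0.02, 0.37], K = 6: stable root below mu
        d = DelaySpec(kind="bimodal_random", tau1=0.02, tau2=0.37)
        sols = pl.sync_frequency_network(TWO_PI, 1.0, 6.0, d, "random")
        stable = [s for s in sols if s.stable]
        assert stable and all(s.Omega < TWO_PI for s in stable)

    def test_antiphase_root_above_mu_for_clustered(self):
        # tau = [0.04, 0.27], K = 7: stable anti-phase root with Omega > mu
        d = DelaySpec(kind="bimodal_clustered", tau1=0.04, tau2=0.27)
        sols = pl.sync_frequency_network(TWO_PI, 1.0, 7.0, d, "clustered")
        anti = [s for s in sols if s.regime == "anti_phase" and s.stable]
        assert anti and all(s.Omega > TWO_PI for s in anti)
        assert all(s.psi2 == np.pi for s in anti)

    def test_cosolve_agrees_with_oa_integration(self):
        d = DelaySpec(kind="bimodal_random", tau1=0.02, tau2=0.37)
        sols = pl.sync_frequency_network(TWO_PI, 1.0, 6.0, d, "random")
        oa = pl.oa_integrate(TWO_PI, 1.0, 6.0, d, "random", t_final=200.0)
        assert oa.converged
        best = min(sols, key=lambda s: abs(s.Omega - oa.Omega_steady))
        assert best.stable
        assert best.Omega == pytest.approx(oa.Omega_steady, abs=1e-2)
        assert best.r == pytest.approx(oa.r_steady, abs=1e-3)


class TestRelativePhases:
    def _sol(self, Omega, r, regime, tm, td):
        na, nb = pl.normalize_angles(Omega * tm, Omega * td)
        return SyncSolution(Omega=Omega, r=r, regime=regime,
                            psi2=0.0 if regime == "in_phase" else np.pi,
                            stable=True,
                            quadrants=(quadrant(Omega * (tm - td))[0],
                                       quadrant(Omega * (tm + td))[0]),
                            tau_mean_angle=na, tau_halfdiff_angle=nb)

    def test_node_at_locked_frequency(self):
        sol = self._sol(5.0, 0.7, "in_phase", 0.1, 0.05)
        pred = pl.relative_phases(np.array([3.0]), 5.0, sol)
        assert pred.phi[0] == pytest.approx(-sol.tau_mean_angle)
        sol_a = self._sol(5.0, 0.7, "anti_phase", 0.1, 0.05)
        pred_a = pl.relative_phases(np.array([3.0]), 5.0, sol_a)
        assert (pred_a.phi[0] + sol_a.tau_mean_angle
                ) == pytest.approx(np.pi / 2)

    def test_branch_containment_in_phase(self):
        sol = self._sol(5.0, 0.6, "in_phase", 0.1, 0.08)
        K = np.linspace(1.0, 10.0, 30)
        pred = pl.relative_phases(K, 5.3, sol)
        v = pred.phi[pred.entrained] + sol.tau_mean_angle
        assert np.all((v > -np.pi / 2) & (v < np.pi / 2))

    def test_branch_containment_anti_phase(self):
        # half-difference angle in (-pi/2, pi/2): branch (0, pi)
        sol = self._sol(5.0, 0.6, "anti_phase", 0.1, 0.25)
        K = np.linspace(1.0, 10.0, 30)
        pred = pl.relative_phases(K, 5.3, sol)
        v = np.mod(pred.phi[pred.entrained] + sol.tau_mean_angle,
                   2 * np.pi)
        assert np.all((v > 0) & (v < np.pi))
        # half-difference angle in (pi/2, 3pi/2): branch (pi, 2 pi)
        sol2 = self._sol(5.0, 0.6, "anti_phase", 0.1, 0.35)
        pred2 = pl.relative_phases(K, 5.3, sol2)
        v2 = np.mod(pred2.phi[pred2.entrained] + sol2.tau_mean_angle,
                    2 * np.pi)
        assert np.all((v2 > np.pi) & (v2 < 2 * np.pi))

    def test_not_entrained_marked_nan(self):
        sol = self._sol(5.0, 0.5, "in_phase", 0.1, 0.05)
        pred = pl.relative_phases(np.array([0.01, 10.0]), 6.0, sol)
        assert not pred.entrained[0] and np.isnan(pred.phi[0])
        assert pred.entrained[1] and np.isfinite(pred.phi[1])

    def test_monotonicity_matches_trend_direction(self):
        """For identical mean frequency, predicted phases are monotone in
        node strength in the direction the trend tables give."""
        for regime, tm, td, Om in [("in_phase", 0.195, 0.175, 4.06),
                                   ("anti_phase", 0.155, 0.115, 7.83)]:
            sol = self._sol(Om, 0.7, regime, tm, td)
            K = np.linspace(2.0, 20.0, 40)
            pred = pl.relative_phases(K, TWO_PI, sol)
            phi = pred.phi[pred.entrained]
            dphi = np.diff(phi)
            labels = pl.trend_classify(*sol.quadrants,
                                       layout="random" if regime ==
                                       "in_phase" else "clustered")
            if "decreasing" in labels and "increasing" not in labels:
                assert np.all(dphi < 0)
            if "increasing" in labels and "decreasing" not in labels:
                assert np.all(dphi > 0)
            # direction consistent with the sign of mu - Omega
            assert np.all(dphi < 0) if Om < TWO_PI else np.all(dphi > 0)

    def test_prediction_invariant_under_angle_transformation(self):
        """Shifting both delay angles by pi (the sine-sum transformation)
        leaves predicted phases unchanged."""
        Om, r = 4.0, 0.6
        tm, td = 2.0, 1.9                      # left half-plane pair
        na, nb = pl.normalize_angles(tm, td)
        raw = SyncSolution(Omega=Om, r=r, regime="in_phase", psi2=0.0,
                           stable=True, quadrants=(1, 1),
                           tau_mean_angle=tm, tau_halfdiff_angle=td)
        norm = SyncSolution(Omega=Om, r=r, regime="in_phase", psi2=0.0,
                            stable=True, quadrants=(1, 1),
                            tau_mean_angle=na, tau_halfdiff_angle=nb)
        K = np.linspace(1.0, 8.0, 17)
        p_raw = pl.relative_phases(K, 4.3, raw)
        p_norm = pl.relative_phases(K, 4.3, norm)
        np.testing.assert_array_equal(p_raw.entrained, p_norm.entrained)
        m = p_raw.entrained
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (p_raw.phi[m] - p_norm.phi[m]))),
            0.0, atol=1e-10)

    def test_antiphase_cross_cluster_ordering(self):
        """With the pi offset added to the second cluster, the weakest
        nodes of one cluster sit angularly closest to the strongest of the
        other."""
        sol = self._sol(7.83, 0.7, "anti_phase", 0.155, 0.115)
        K = np.linspace(3.0, 20.0, 10)
        pred = pl.relative_phases(K, TWO_PI, sol)
        assert np.all(pred.entrained)
        phi1 = pred.phi                      # cluster I
        phi2 = pred.phi + sol.psi2           # cluster II

        def dist(a, b):
            return abs(float(np.angle(np.exp(1j * (a - b)))))

        weak1, strong1 = phi1[0], phi1[-1]
        weak2, strong2 = phi2[0], phi2[-1]
        assert dist(weak1, strong2) < dist(strong1, strong2)
        assert dist(strong1, weak2) < dist(weak1, weak2)


class TestTrendClassify:
    def test_table_cells(self):
        assert pl.trend_classify(1, 1, "random") == ("decreasing",)
        assert pl.trend_classify(2, 3, "random") == ("unstable",)
        assert pl.trend_classify(4, 1, "random") == ("increasing",)
        both = pl.trend_classify(4, 2, "clustered")
        assert "increasing" in both and "decreasing" in both
        assert pl.trend_classify(1, 1, "clustered") == ("decreasing",)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pl.trend_classify(0, 1, "random")
        with pytest.raises(ValueError):
            pl.trend_classify(1, 1, "ring")


class TestOAIntegration:
    def test_subcritical_coupling_decays_to_incoherence(self):
        d = DelaySpec(kind="single", tau1=0.0)
        res = pl.oa_integrate(TWO_PI, 1.0, K=0.5, delay=d, t_final=50.0)
        assert res.r_steady < 1e-3

    def test_zero_delay_fixed_point_closed_form(self):
        """Steady r matches the zero-delay OA fixed point found by
        brute-force root finding, to 1e-6."""
        gamma, K = 1.0, 6.0
        d = DelaySpec(kind="single", tau1=0.0)
        res = pl.oa_integrate(TWO_PI, gamma, K, d, t_final=50.0, dt=1e-4)
        # oracle: fixed point of dr/dt = -gamma r + K/2 r (1 - r^2)
        r_star = brentq(lambda r: -gamma * r + 0.5 * K * r * (1 - r * r),
                        1e-3, 1.0)
        assert res.converged
        assert res.r_steady == pytest.approx(r_star, abs=1e-6)
        assert res.Omega_steady == pytest.approx(TWO_PI, abs=1e-3)

    def test_oa_matches_direct_network_simulation(self):
        """Steady (r, Omega) of the reduction matches N=300 Lorentzian
        network simulations within 5%, averaged over the seeds that reach
        steady partial synchronization (the reduction's validity regime —
        runs with strongly fluctuating coherence are standing-wave-like
        states outside it)."""
        d = DelaySpec(kind="bimodal_random", tau1=0.02, tau2=0.37)
        oa = pl.oa_integrate(TWO_PI, 1.0, 6.0, d, "random", t_final=150.0)
        rs, oms = [], []
        for seed in (1, 2, 3, 4, 5):
            net = pl.build_network(
                300, FrequencySpec(kind="lorentzian", mu=TWO_PI, gamma=1.0),
                StrengthSpec(K=6.0), d, D=0.0, seed=seed)
            tr = pl.integrate(net, 150.0, seed=seed, warmup=40.0)
            op = pl.order_parameters(tr, net)
            if op.r.std() < 0.1 * op.r.mean():      # steady runs only
                rs.append(float(op.r.mean()))
                oms.append(float(np.mean(op.Omega_inst)))
        assert len(rs) >= 3
        assert np.mean(rs) == pytest.approx(oa.r_steady, rel=0.05)
        assert np.mean(oms) == pytest.approx(oa.Omega_steady, rel=0.05)

    def test_clustered_antiphase_attractor(self):
        d = DelaySpec(kind="bimodal_clustered", tau1=0.04, tau2=0.27)
        res = pl.oa_integrate(TWO_PI, 1.0, 7.0, d, "clustered",
                              z0=[0.5, -0.5], t_final=150.0)
        assert res.converged
        offset = abs(np.angle(res.z[0][-1] * np.conj(res.z[1][-1])))
        assert offset == pytest.approx(np.pi, abs=1e-3)
        assert res.Omega_steady > TWO_PI
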