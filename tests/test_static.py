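import numpy as np
import pytest

from effcond.errors import SingularityError
from effcond.statics import (TwoPortParams, effective_conductance_exact,
                             exact_soma_voltage, exact_syn_current,
                             first_order_expansion_error, im_solve,
                             iv_line_exact, iv_line_first_order,
                             no_transform_witness, sim_error_prediction,
                             sim_solve)


def brute_force_port_solve(p, gE, gI, I_inj):
    """Independent oracle: solve the raw five-unknown port system.

    Unknowns (I_E, I_I, V_E, V_I, V_S) satisfy Ohm's law at each synapse
    and the three superposition equations through the K matrix.
    """
    A = np.array([
        # I_E + gE V_E = gE epsE
        [1.0, 0.0, gE, 0.0, 0.0],
        # I_I + gI V_I = gI epsI
        [0.0, 1.0, 0.0, gI, 0.0],
        # V_E - K_EE I_E - K_IE I_I = K_SE I_inj
        [-p.K_EE, -p.K_EI, 1.0, 0.0, 0.0],
        [-p.K_EI, -p.K_II, 0.0, 1.0, 0.0],
        [-p.K_ES, -p.K_IS, 0.0, 0.0, 1.0],
    ])
    rhs = np.array([gE * p.eps_E, gI * p.eps_I,
                    p.K_ES * I_inj, p.K_IS * I_inj, p.K_SS * I_inj])
    I_E, I_I, V_E, V_I, V_S = np.linalg.solve(A, rhs)
    return V_S, I_E, I_I


def random_params(rng):
    # positive definite-ish passive values with K_qS below the diagonals
    k_ss = rng.uniform(20, 200)
    k_ee = rng.uniform(k_ss, 500)
    k_ii = rng.uniform(k_ss, 500)
    k_es = rng.uniform(2, k_ss)
    k_is = rng.uniform(2, k_ss)
    k_ei = rng.uniform(2, min(k_ee, k_ii))
    return TwoPortParams(K_EE=k_ee, K_II=k_ii, K_SS=k_ss, K_ES=k_es,
                         K_IS=k_is, K_EI=k_ei, eps_E=70.0, eps_I=-10.0)


class TestEffectiveConductance:
    def test_soma_input_returns_local_conductance(self):
        for g in (1e-4, 1e-3, 5e-3, 2e-2):
            g_eff = effective_conductance_exact(g, K_qS=80.0, K_SS=80.0,
                                                K_qq=80.0, eps_q=70.0)
            assert g_eff == pytest.approx(g, rel=1e-12)

    def test_zero_conductance(self):
        assert effective_conductance_exact(0.0, 50.0, 80.0, 120.0, 70.0) == 0.0

    def test_small_g_slope_is_prefactor(self):
        # finite-difference slope at g -> 0 approaches K_qS/K_SS with a
        # deviation shrinking linearly in g
        k_qs, k_ss = 40.0, 100.0
        s1 = effective_conductance_exact(1e-6, k_qs, k_ss, 300.0, 70.0) / 1e-6
        s2 = effective_conductance_exact(1e-7, k_qs, k_ss, 300.0, 70.0) / 1e-7
        assert s1 == pytest.approx(k_qs / k_ss, rel=1e-3)
        assert s2 == pytest.approx(k_qs / k_ss, rel=1e-4)
        dev_ratio = abs(s1 - k_qs / k_ss) / abs(s2 - k_qs / k_ss)
        assert dev_ratio == pytest.approx(10.0, rel=0.2)

    def test_negative_local_conductance_rejected(self):
        with pytest.raises(ValueError):
            effective_conductance_exact(-1e-3, 40.0, 100.0, 300.0, 70.0)


class TestFirstOrderExpansionError:
    @pytest.mark.parametrize("x,expected", [(0.3, 0.09), (0.0, 0.0),
                                            (0.1, 0.01)])
    def test_known_values(self, x, expected):
        assert first_order_expansion_error(x) == pytest.approx(
            expected, abs=1e-15)

    def test_is_x_squared_everywhere(self):
        rng = np.random.default_rng(0)
        for x in rng.uniform(-0.999, 0.999, size=200):
            assert first_order_expansion_error(x) == pytest.approx(
                x * x, rel=1e-12, abs=1e-15)

    def test_domain_boundary(self):
        with pytest.raises(ValueError):
            first_order_expansion_error(1.0)


class TestExactThreePort:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = random_params(rng)
            gE = rng.uniform(0, 5e-2)
            gI = rng.uniform(0, 5e-2)
            I_inj = rng.uniform(-1.0, 1.0)
            v_ref, _, _ = brute_force_port_solve(p, gE, gI, I_inj)
            v = exact_soma_voltage(p, gE, gI, I_inj)
            i_syn = exact_syn_current(p, gE, gI, I_inj)
            assert v == pytest.approx(v_ref, rel=1e-10, abs=1e-12)
            assert i_syn == pytest.approx(v_ref / p.K_SS - I_inj,
                                          rel=1e-10, abs=1e-12)

    def test_pure_excitation_reduces_to_single_input_form(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        gE = 2e-3
        v = exact_soma_voltage(p, gE, 0.0, 0.0)
        assert v == pytest.approx(gE * p.K_ES * p.eps_E / (1 + gE * p.K_EE),
                                  rel=1e-12)
        i = exact_syn_current(p, gE, 0.0, 0.0)
        assert i == pytest.approx(
            gE * p.eps_E * p.K_ES / ((1 + gE * p.K_EE) * p.K_SS), rel=1e-12)

    def test_no_synapse_no_measured_current(self):
        rng = np.random.default_rng(2)
        p = random_params(rng)
        for I_inj in (-0.5, 0.0, 0.8):
            assert exact_soma_voltage(p, 0.0, 0.0, I_inj) == pytest.approx(
                p.K_SS * I_inj, rel=1e-12)
            assert abs(exact_syn_current(p, 0.0, 0.0, I_inj)) < 1e-14


class TestIVLine:
    def test_zero_conductance_gives_zero_line(self):
        rng = np.random.default_rng(3)
        line = iv_line_exact(random_params(rng), 0.0, 0.0)
        assert line.k == 0.0 and line.b == 0.0

    def test_identity_against_injection_sweep(self):
        # I_syn = -k V_S + b must hold for arbitrary injected current
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = random_params(rng)
            gE, gI = rng.uniform(0, 2e-2, size=2)
            line = iv_line_exact(p, gE, gI)
            for I_inj in np.linspace(-1.0, 1.0, 5):
                v = exact_soma_voltage(p, gE, gI, I_inj)
                i = exact_syn_current(p, gE, gI, I_inj)
                assert i == pytest.approx(-line.k * v + line.b,
                                          rel=1e-9, abs=1e-12)

    def test_regression_over_sweep_recovers_line(self):
        rng = np.random.default_rng(5)
        p = random_params(rng)
        gE, gI = 3e-3, 5e-3
        line = iv_line_exact(p, gE, gI)
        vs = [exact_soma_voltage(p, gE, gI, i) for i in (-1, -0.5, 0, 0.5, 1)]
        cur = [exact_syn_current(p, gE, gI, i) for i in (-1, -0.5, 0, 0.5, 1)]
        slope, intercept = np.polyfit(vs, cur, 1)
        assert -slope == pytest.approx(line.k, rel=1e-9)
        assert intercept == pytest.approx(line.b, rel=1e-9)

    def test_first_order_soma_reduction(self):
        p = TwoPortParams(K_EE=80.0, K_II=80.0, K_SS=80.0, K_ES=80.0,
                          K_IS=80.0, K_EI=80.0, eps_E=70.0, eps_I=-10.0)
        gE, gI = 2e-3, 4e-3
        line = iv_line_first_order(p, gE, gI)
        assert line.k == pytest.approx(gE + gI, rel=1e-12)
        assert line.b == pytest.approx(gE * 70.0 + gI * -10.0, rel=1e-12)

    def test_first_order_printed_arithmetic(self):
        p = TwoPortParams(K_EE=100.0, K_II=100.0, K_SS=100.0, K_ES=50.0,
                          K_IS=50.0, K_EI=100.0, eps_E=70.0, eps_I=-10.0)
        line = iv_line_first_order(p, 2e-3, 4e-3)
        assert line.k == pytest.approx(1.5e-3, rel=1e-12)
        assert line.b == pytest.approx(0.05, rel=1e-12)

    def test_colocated_small_g_slope(self):
        # K_ES = K_IS = 0.2 K_SS: slope prefactor is 0.04
        p = TwoPortParams.co_located(alpha=0.2, K_SS=100.0, K_local=300.0)
        gE = gI = 1e-5
        line = iv_line_exact(p, gE, gI)
        assert line.k == pytest.approx(0.04 * (gE + gI), rel=1e-2)

    def test_exact_to_first_order_error_scales_quadratically(self):
        # g K_local must be well below 1 for the asymptotic rate to show
        p = TwoPortParams.co_located(alpha=0.5, K_SS=100.0, K_local=250.0)
        errs = []
        for scale in (1.0, 0.5, 0.25):
            gE, gI = 2e-4 * scale, 4e-4 * scale
            ex = iv_line_exact(p, gE, gI)
            fo = iv_line_first_order(p, gE, gI)
            errs.append(abs(ex.b - fo.b))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)


class TestSolvers:
    def test_sim_solve_linear_system(self):
        sol = sim_solve(6e-3, 0.1, 70.0, -10.0)
        assert sol.g_E == pytest.approx(2e-3, rel=1e-12)
        assert sol.g_I == pytest.approx(4e-3, rel=1e-12)
        assert not sol.negative

    def test_sim_solve_pure_soma_excitation(self):
        gE = 3e-3
        sol = sim_solve(gE, gE * 70.0, 70.0, -10.0)
        assert sol.g_E == pytest.approx(gE, rel=1e-12)
        assert abs(sol.g_I) < 1e-18

    def test_sim_solve_negative_conductance_from_colocated_exact_line(self):
        # K_ES = K_IS = 0.2 K_SS: applying SIM to exact I-V parameters of a
        # physical conductance pair yields an unphysical negative gI
        p = TwoPortParams.co_located(alpha=0.2, K_SS=100.0, K_local=300.0)
        found_negative = False
        for gE in (1e-3, 2e-3, 4e-3):
            for gI in (0.5e-3, 1e-3, 2e-3):
                line = iv_line_exact(p, gE, gI)
                sol = sim_solve(line.k, line.b, p.eps_E, p.eps_I)
                found_negative |= (sol.g_I < 0 and sol.negative)
        assert found_negative

    def test_sim_solve_degenerate_reversals(self):
        with pytest.raises(SingularityError):
            sim_solve(1e-3, 0.1, 70.0, 70.0)

    def test_im_solve_two_intercepts(self):
        gE, gI = im_solve(0.1, 0.06, 70.0, -10.0, -20.0)
        assert gE == pytest.approx(2e-3, rel=1e-12)
        assert gI == pytest.approx(4e-3, rel=1e-12)

    def test_im_solve_equal_intercepts_means_pure_excitation(self):
        gE, gI = im_solve(0.14, 0.14, 70.0, -10.0, -20.0)
        assert gI == 0.0
        assert gE == pytest.approx(0.14 / 70.0, rel=1e-12)

    def test_im_solve_degenerate_reversals(self):
        with pytest.raises(SingularityError):
            im_solve(0.1, 0.06, 70.0, -10.0, -10.0)

    def test_im_static_recovery_error_scales_quadratically(self):
        # generate intercepts from the exact line at two inhibitory
        # reversals; IM recovery error against the first-order effective
        # conductances shrinks ~4x when g is halved
        k_ss, k_local = 100.0, 250.0
        for alpha in (0.2, 0.5, 0.8):
            errors = []
            for scale in (1.0, 0.5):
                gE, gI = 1e-3 * scale, 1.6e-3 * scale
                p1 = TwoPortParams.co_located(alpha, k_ss, k_local,
                                              eps_I=-10.0)
                p2 = TwoPortParams.co_located(alpha, k_ss, k_local,
                                              eps_I=-20.0)
                b = iv_line_exact(p1, gE, gI).b
                b_prime = iv_line_exact(p2, gE, gI).b
                gE_im, gI_im = im_solve(b, b_prime, 70.0, -10.0, -20.0)
                errors.append(abs(gE_im - alpha * gE) + abs(gI_im - alpha * gI))
            assert errors[0] / errors[1] > 3.0


class TestSimErrorLaws:
    def test_no_distortion_at_unit_prefactor(self):
        assert sim_error_prediction(1e-3, 1.0, 70.0, -10.0) == (0.0, 0.0)

    def test_printed_example(self):
        dgE, dgI = sim_error_prediction(1e-3, 0.2, 70.0, -10.0)
        assert dgE == pytest.approx(-0.5e-3, rel=1e-12)
        assert dgI == pytest.approx(-3.5e-3, rel=1e-12)

    def test_error_ratio_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            k = rng.uniform(1e-4, 1e-2)
            alpha = rng.uniform(0.05, 1.0)
            eps_E = rng.uniform(40, 100)
            eps_I = rng.uniform(-40, -5)
            dgE, dgI = sim_error_prediction(k, alpha, eps_E, eps_I)
            assert dgE / dgI == pytest.approx(-eps_I / eps_E, rel=1e-12)
            assert dgE <= 0 and dgI <= 0

    def test_matches_sim_solve_on_first_order_line(self):
        # applying SIM to the co-located first-order line reproduces the
        # closed-form error expressions exactly
        gE_eff, gI_eff = 2e-3, 4e-3
        for alpha in (0.2, 0.5, 0.9):
            k = alpha * (gE_eff + gI_eff)
            b = gE_eff * 70.0 + gI_eff * -10.0
            sol = sim_solve(k, b, 70.0, -10.0)
            dgE, dgI = sim_error_prediction(k, alpha, 70.0, -10.0)
            assert sol.g_E - gE_eff == pytest.approx(dgE, rel=1e-10,
                                                     abs=1e-18)
            assert sol.g_I - gI_eff == pytest.approx(dgI, rel=1e-10,
                                                     abs=1e-18)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            sim_error_prediction(1e-3, 0.0, 70.0, -10.0)


class TestNoTransformWitness:
    def test_soma_inputs_are_consistent(self):
        p = TwoPortParams(K_EE=80.0, K_II=80.0, K_SS=80.0, K_ES=80.0,
                          K_IS=80.0, K_EI=80.0)
        w = no_transform_witness(p)
        assert w.F1_slope == w.F1_intercept == 1.0
        assert w.G1_slope == w.G1_intercept == 1.0
        assert not w.contradiction

    def test_dendritic_input_forces_contradiction(self):
        p = TwoPortParams(K_EE=200.0, K_II=200.0, K_SS=100.0, K_ES=50.0,
                          K_IS=30.0, K_EI=150.0)
        w = no_transform_witness(p)
        assert w.F1_slope == pytest.approx(0.25)
        assert w.F1_intercept == pytest.approx(0.5)
        assert w.contradiction

    def test_every_non_soma_site_of_a_cable_is_contradictory(
            self, ball_and_stick_model):
        from effcond.transfer import prefactor_map
        pm = prefactor_map(ball_and_stick_model)
        for ratio in pm.ratio[pm.distance > 0]:
            p = TwoPortParams(K_EE=200.0, K_II=200.0, K_SS=100.0,
                              K_ES=100.0 * ratio, K_IS=100.0 * ratio,
                              K_EI=150.0)
            w = no_transform_witness(p)
            assert w.F1_slope < w.F1_intercept
            assert w.contradiction
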