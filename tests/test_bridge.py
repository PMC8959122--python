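"""Bridge solver: worked examples, independent oracles, structural invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import statebridge as sb
from statebridge.errors import (
    ConvergenceError,
    InfeasibleMarginalError,
    SupportViolationError,
)

from .conftest import random_instance
from .oracles import bruteforce_cost_k2, constrained_cost, kl, path_kl_by_enumeration


def pv(*p):
    return sb.ProbabilityVector(np.array(p))


class TestUncontrolledJoint:
    def test_identity_kernel_is_absorbing(self):
        Q = sb.uncontrolled_joint(pv(1, 0), sb.TransitionMatrix(np.eye(2)), T=5)
        np.testing.assert_array_equal(Q.joint, [[1, 0], [0, 0]])

    def test_one_step_is_direct_product(self):
        K = sb.TransitionMatrix([[0.9, 0.1], [0.2, 0.8]])
        Q = sb.uncontrolled_joint(pv(0.5, 0.5), K, T=1)
        np.testing.assert_allclose(Q.joint, [[0.45, 0.05], [0.10, 0.40]], atol=1e-15)

    def test_two_step_matches_path_enumeration(self):
        K = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([0.5, 0.5])
        Q = sb.uncontrolled_joint(pv(*pi), sb.TransitionMatrix(K), T=2)
        expected = np.zeros((2, 2))
        for i in range(2):  # enumerate all 2-step paths i -> m -> j
            for m in range(2):
                for j in range(2):
                    expected[i, j] += pi[i] * K[i, m] * K[m, j]
        np.testing.assert_allclose(Q.joint, expected, atol=1e-15)
        assert Q.joint.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            sb.uncontrolled_joint(pv(0.5, 0.5), sb.TransitionMatrix(np.eye(2)), T=0)


class TestKLDivergence:
    def test_identical_distributions_have_zero_divergence(self):
        Q = np.array([[0.4, 0.1], [0.2, 0.3]])
        assert sb.kl_divergence(Q, Q) == 0.0

    def test_hand_computed_value(self):
        P = np.array([[0.5, 0.0], [0.0, 0.5]])
        Q = np.full((2, 2), 0.25)
        assert sb.kl_divergence(P, Q) == pytest.approx(np.log(2), abs=1e-12)

    def test_support_violation_is_loud(self):
        P = np.array([[0.5, 0.5], [0.0, 0.0]])
        Q = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(SupportViolationError):
            sb.kl_divergence(P, Q)


class TestSolveBridge:
    def test_matching_marginals_need_no_control(self):
        _, _, Q, _ = random_instance(np.random.default_rng(0), k=4)
        sol = sb.solve_bridge(Q.row_marginal(), Q.col_marginal(), Q)
        assert sol.cost <= 1e-10
        np.testing.assert_allclose(sol.optimal_joint.joint, Q.joint, atol=1e-8)

    def test_memoryless_chain_closed_form(self):
        # identical kernel rows r: the coupling separates and the cost is
        # exactly KL(target || r)
        pi, r, tgt = np.array([0.6, 0.4]), np.array([0.5, 0.5]), np.array([0.9, 0.1])
        Q = sb.JointEndpointDistribution(np.outer(pi, r))
        sol = sb.solve_bridge(pv(*pi), pv(*tgt), Q)
        np.testing.assert_allclose(sol.optimal_joint.joint, np.outer(pi, tgt), atol=1e-9)
        assert sol.cost == pytest.approx(0.9 * np.log(1.8) + 0.1 * np.log(0.2), abs=1e-10)

    def test_k2_instance_matches_1d_bruteforce(self):
        Q = sb.JointEndpointDistribution(np.array([[0.4, 0.1], [0.2, 0.3]]))
        sol = sb.solve_bridge(pv(0.5, 0.5), pv(0.7, 0.3), Q)
        assert sol.cost == pytest.approx(
            bruteforce_cost_k2(np.array([0.5, 0.5]), np.array([0.7, 0.3]), Q.joint),
            abs=1e-6,
        )

    @pytest.mark.parametrize("k,seed", [(2, 0), (3, 1), (3, 2), (5, 3)])
    def test_random_instances_match_constrained_optimizer(self, k, seed):
        pi, tgt, Q, _ = random_instance(np.random.default_rng(seed), k)
        sol = sb.solve_bridge(pi, tgt, Q)
        assert sol.cost == pytest.approx(
            constrained_cost(pi.probs, tgt.probs, Q.joint), abs=1e-6
        )

    def test_marginal_constraints_and_gibbs_form(self):
        rng = np.random.default_rng(42)
        for k in (2, 5, 11):
            pi, tgt, Q, _ = random_instance(rng, k, zero_frac=0.3)
            sol = sb.solve_bridge(pi, tgt, Q)
            P = sol.optimal_joint.joint
            assert np.max(np.abs(P.sum(axis=1) - pi.probs)) <= sol.tol
            assert np.max(np.abs(P.sum(axis=0) - tgt.probs)) <= sol.tol
            # zeros of Q preserved exactly
            assert np.all(P[Q.joint == 0] == 0)
            # Gibbs structure: log(P/Q) - alpha_i - beta_j constant on support
            support = (Q.joint > 0) & (P > 0)
            resid = (
                np.log(P[support] / Q.joint[support])
                - sol.alpha[np.nonzero(support)[0]]
                - sol.beta[np.nonzero(support)[1]]
            )
            assert np.ptp(resid) <= 1e-8

    def test_deterministic_bitwise(self):
        pi, tgt, Q, _ = random_instance(np.random.default_rng(5), k=6)
        s1 = sb.solve_bridge(pi, tgt, Q)
        s2 = sb.solve_bridge(pi, tgt, Q)
        assert s1.cost == s2.cost
        assert np.array_equal(s1.optimal_joint.joint, s2.optimal_joint.joint)
        assert np.array_equal(s1.alpha, s2.alpha)

    def test_infeasible_target_names_state(self):
        # state 1 unreachable: Q has a zero column
        Q = sb.JointEndpointDistribution(np.array([[0.6, 0.0], [0.4, 0.0]]))
        with pytest.raises(InfeasibleMarginalError) as exc:
            sb.solve_bridge(pv(0.6, 0.4), pv(0.5, 0.5), Q)
        assert 1 in exc.value.states

    def test_nonconvergence_carries_residual(self):
        # feasible marginals but incompatible support pattern: Sinkhorn cycles
        Q = sb.JointEndpointDistribution(np.array([[0.5, 0.0], [0.0, 0.5]]))
        with pytest.raises(ConvergenceError) as exc:
            sb.solve_bridge(pv(1 / 3, 2 / 3), pv(0.7, 0.3), Q, max_iter=500)
        assert exc.value.residual > 0

    def test_smoothing_restores_feasibility(self):
        Q = sb.JointEndpointDistribution(np.array([[0.5, 0.0], [0.0, 0.5]]))
        sol = sb.solve_bridge(pv(1 / 3, 2 / 3), pv(0.7, 0.3), Q, smoothing=0.01)
        assert sol.converged and sol.cost > 0


class TestTransitionCost:
    def test_uncontrolled_image_costs_nothing(self):
        K = sb.TransitionMatrix([[0.7, 0.3], [0.4, 0.6]])
        pi = pv(0.25, 0.75)
        image = pv(*(pi.probs @ K.kernel))
        assert sb.transition_cost(pi, image, K, T=1) <= 1e-10

    def test_symmetric_joint_gives_symmetric_cost(self):
        # symmetric Q: transposition maps pi->pi' onto pi'->pi
        Q = np.array([[0.3, 0.15], [0.15, 0.4]])
        pi_q = Q.sum(axis=1)
        kernel = sb.TransitionMatrix(Q / pi_q[:, None])
        a, b = pv(0.5, 0.5), pv(0.85, 0.15)
        # same Q regardless of direction requires solving on the fixed joint
        jq = sb.JointEndpointDistribution(Q)
        c_ab = sb.solve_bridge(a, b, jq).cost
        c_ba = sb.solve_bridge(b, a, jq).cost
        assert c_ab == pytest.approx(c_ba, abs=1e-10)
        del kernel

    def test_cost_is_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pi, tgt, _, kernel = random_instance(rng, k=4)
            assert sb.transition_cost(pi, tgt, kernel, T=1) >= 0


class TestReconstructFullPath:
    def test_horizon_one_path_is_the_coupling_itself(self):
        pi, tgt, Q, kernel = random_instance(np.random.default_rng(3), k=3)
        sol = sb.solve_bridge(pi, tgt, Q)
        path = sb.reconstruct_full_path(sol, kernel, T=1)
        np.testing.assert_allclose(path.initial.probs, pi.probs, atol=1e-9)
        joint = path.initial.probs[:, None] * path.kernels[0]
        np.testing.assert_allclose(joint, sol.optimal_joint.joint, atol=1e-9)

    @pytest.mark.parametrize("k,T,seed", [(2, 2, 0), (3, 3, 1), (4, 4, 2), (2, 4, 3)])
    def test_full_path_kl_equals_endpoint_cost(self, k, T, seed):
        # the reconstructed path keeps the baseline bridge in its interior,
        # so its KL to the uncontrolled path collapses to the endpoint term
        pi, _, _, kernel = random_instance(np.random.default_rng(seed), k)
        tgt = sb.ProbabilityVector(np.random.default_rng(seed + 100).dirichlet(np.ones(k)))
        Q = sb.uncontrolled_joint(pi, kernel, T)
        sol = sb.solve_bridge(pi, tgt, Q)
        p_path = sb.reconstruct_full_path(sol, kernel, T)
        q_path = sb.PathDistribution(initial=pi, kernels=(kernel.kernel,) * T)
        assert path_kl_by_enumeration(p_path, q_path) == pytest.approx(sol.cost, abs=1e-10)

    def test_terminal_marginal_hits_target(self):
        rng = np.random.default_rng(9)
        pi, _, _, kernel = random_instance(rng, k=3)
        tgt = sb.ProbabilityVector(rng.dirichlet(np.ones(3)))
        Q = sb.uncontrolled_joint(pi, kernel, 3)
        sol = sb.solve_bridge(pi, tgt, Q)
        path = sb.reconstruct_full_path(sol, kernel, T=3)
        np.testing.assert_allclose(path.marginal(3).probs, tgt.probs, atol=1e-10)

    def test_inconsistent_kernel_rejected(self):
        pi, tgt, Q, _ = random_instance(np.random.default_rng(1), k=2)
        sol = sb.solve_bridge(pi, tgt, Q)
        with pytest.raises(InfeasibleMarginalError):
            sb.reconstruct_full_path(sol, sb.TransitionMatrix(np.eye(2)), T=1)


class TestOTIdentity:
    def test_uniform_case(self):
        U = np.full((2, 2), 0.25)
        kl_, transport, entropy = sb.ot_identity_check(U, U)
        assert kl_ == pytest.approx(0, abs=1e-15)
        assert transport == pytest.approx(np.log(4), abs=1e-12)
        assert entropy == pytest.approx(np.log(4), abs=1e-12)

    def test_identity_holds_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            P = rng.dirichlet(np.ones(k * k)).reshape(k, k)
            Q = rng.dirichlet(np.ones(k * k)).reshape(k, k)
            kl_, transport, entropy = sb.ot_identity_check(P, Q)
            assert kl_ == pytest.approx(transport - entropy, abs=1e-12)
            assert kl_ == pytest.approx(kl(P, Q), abs=1e-12)


@given(st.integers(0, 2**31 - 1), st.integers(2, 6))
def test_memoryless_kernel_cost_is_target_kl_property(seed, k):
    """Identical kernel rows r collapse the bridge cost to KL(pi' || r)."""
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(np.ones(k))
    pi = sb.ProbabilityVector(rng.dirichlet(np.ones(k)))
    tgt = rng.dirichlet(np.ones(k))
    kernel = sb.TransitionMatrix(np.tile(r, (k, 1)))
    cost = sb.transition_cost(pi, sb.ProbabilityVector(tgt), kernel, T=1)
    assert cost == pytest.approx(kl(tgt, r), abs=1e-10)


@given(st.integers(0, 2**31 - 1))
def test_bridge_solution_invariants_property(seed):
    """Marginals met, zeros preserved, cost nonnegative, OT identity holds."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 10))
    pi, tgt, Q, _ = random_instance(rng, k, zero_frac=0.2)
    sol = sb.solve_bridge(pi, tgt, Q)
    P = sol.optimal_joint.joint
    assert sol.cost >= 0
    assert sol.residual <= sol.tol
    assert np.all(P[Q.joint == 0] == 0)
    kl_, transport, entropy = sb.ot_identity_check(P, Q.joint)
    assert kl_ == pytest.approx(transport - entropy, abs=1e-12)
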