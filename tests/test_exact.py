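import numpy as np
import pytest
from scipy.stats import poisson

from crnpf import fixtures
from crnpf.equilibrium import solve_complex_balanced
from crnpf.exact import (
    build_generator,
    distribution_distance,
    solve_stationary,
    ssa_simulate,
    stationarity_residual,
)
from crnpf.kinetics import KineticsSpec, ThetaFunction
from crnpf.network import alpha_partition, build_network
from crnpf.product_form import (
    DiscreteDistribution,
    ProductFormMeasure,
    StateClass,
    normalize,
)


def _birth_death_kinetics():
    return KineticsSpec(
        mode="theta_product", thetas={"S": ThetaFunction.from_expression("x")}
    )


class TestBuildGenerator:
    def test_birth_death_tridiagonal(self, birth_death):
        chain = build_generator(
            birth_death, KineticsSpec(mode="mass_action"), StateClass(box=(5,))
        )
        A = chain.generator.toarray()
        assert np.all(np.triu(A, 2) == 0) and np.all(np.tril(A, -2) == 0)
        np.testing.assert_allclose(A.sum(axis=1), 0.0, atol=1e-12)
        assert A[0, 1] == 3.0 and A[2, 1] == 2.0

    def test_three_state_class_chain(self, reversible_pair):
        cls = StateClass(box=(4, 2), linear_invariants=(((1, 2), 4),))
        chain = build_generator(
            reversible_pair, KineticsSpec(mode="mass_action"), cls
        )
        assert chain.n_states == 3
        np.testing.assert_allclose(
            chain.generator.toarray().sum(axis=1), 0.0, atol=1e-12
        )

    def test_offdiagonals_nonnegative(self, full_system):
        net, kin = full_system
        chain = build_generator(net, kin, StateClass(box=(30, 20)))
        A = chain.generator.tocoo()
        off = A.data[A.row != A.col]
        assert np.all(off >= 0)

    def test_empty_class_raises(self, birth_death):
        with pytest.raises(ValueError, match="empty"):
            build_generator(
                birth_death,
                KineticsSpec(mode="mass_action"),
                StateClass(box=(3,), linear_invariants=(((1,), 7),)),
            )


class TestSolveStationary:
    def test_truncated_poisson(self, birth_death):
        chain = build_generator(
            birth_death, KineticsSpec(mode="mass_action"), StateClass(box=(40,))
        )
        dist = solve_stationary(chain)
        expected = poisson.pmf(np.arange(41), 3.0)
        expected /= expected.sum()
        np.testing.assert_allclose(dist.probs, expected, rtol=1e-9, atol=1e-16)

    def test_three_state_chain_hand_solve(self, reversible_pair):
        # class x1 + 2*x2 = 4: states (0,2),(2,1),(4,0); birth-death in x2
        cls = StateClass(box=(4, 2), linear_invariants=(((1, 2), 4),))
        chain = build_generator(reversible_pair, KineticsSpec(mode="mass_action"), cls)
        dist = solve_stationary(chain)
        # detailed balance: pi(2,1)*lam_dim(2) = pi(0,2)*lam_dis(2), etc.
        w = np.array([1.0, 0.0, 0.0])  # unnormalized, built from (4,0) upward
        w[1] = w[0] * (4 * 3) / 1.0  # dim rate at x1=4 / dis rate at x2=1
        w[2] = w[1] * (2 * 1) / 2.0
        w /= w.sum()
        np.testing.assert_allclose(dist.probs, w[::-1], rtol=1e-12)

    def test_multiple_closed_classes_rejected(self, reversible_pair):
        # the full box splits into parity classes of x1
        chain = build_generator(
            reversible_pair, KineticsSpec(mode="mass_action"), StateClass(box=(6, 3))
        )
        with pytest.raises(ValueError, match="closed communicating classes"):
            solve_stationary(chain)

    def test_enumeration_permutation_invariance(self, birth_death):
        from crnpf.exact import TruncatedChain

        chain = build_generator(
            birth_death, KineticsSpec(mode="mass_action"), StateClass(box=(30,))
        )
        dist = solve_stationary(chain)
        rng = np.random.default_rng(3)
        perm = rng.permutation(chain.n_states)
        shuffled = TruncatedChain(
            states=chain.states[perm],
            generator=chain.generator[perm][:, perm].tocsr(),
            net=chain.net,
            kinetics=chain.kinetics,
        )
        dist2 = solve_stationary(shuffled)
        np.testing.assert_allclose(dist2.probs, dist.probs[perm], atol=1e-10)


class TestStationarityResidual:
    def test_product_form_satisfies_balance(self, constrained_system):
        net, kin = constrained_system
        ap = alpha_partition(net)
        eq = solve_complex_balanced(net, constraint=((1.0, 2.0), 1.0))
        cls = StateClass(box=(30, 15), linear_invariants=(((1, 2), 30),))
        dist = normalize(ProductFormMeasure.from_kinetics(eq.c, kin, net, ap), cls)
        assert stationarity_residual(dist, net, kin, ap) < 1e-10

    def test_uniform_distribution_fails_balance(self, birth_death):
        states = np.arange(20)[:, None]
        dist = DiscreteDistribution(states=states, probs=np.full(20, 1 / 20))
        res = stationarity_residual(dist, birth_death, KineticsSpec(mode="mass_action"))
        assert res > 0.01

    def test_solver_output_self_consistent(self, full_system):
        net, kin = full_system
        chain = build_generator(net, kin, StateClass(box=(40, 25)))
        dist = solve_stationary(chain)
        scale = np.abs(chain.generator.diagonal()).max()
        assert stationarity_residual(dist, net, kin) <= 1e-10 * scale


class TestSSA:
    def test_absorbed_state_constant_trajectory(self):
        # 2S -> 0 from x=1: no reaction can fire
        net = build_network(
            ["S"], [{"reactants": {"S": 2}, "products": {}, "rate_constant": 1.0}]
        )
        out = ssa_simulate(net, KineticsSpec(mode="mass_action"), (1,), 5.0, seed=0)
        assert out["n_jumps"] == 0
        assert out["occupancy"] == {(1,): 1.0}

    def test_reproducible_given_seed(self, birth_death):
        kin = KineticsSpec(mode="mass_action")
        a = ssa_simulate(birth_death, kin, (0,), 50.0, seed=11)
        b = ssa_simulate(birth_death, kin, (0,), 50.0, seed=11)
        assert a["occupancy"] == b["occupancy"]
        assert a["n_jumps"] == b["n_jumps"]

    def test_occupancy_converges_to_poisson(self, birth_death):
        kin = KineticsSpec(mode="mass_action")
        box = StateClass(box=(30,))
        expected = poisson.pmf(np.arange(31), 3.0)
        expected /= expected.sum()
        tvs = []
        for t_end in (50.0, 200.0, 800.0):
            # average over seeds: the trend is in expectation, not per-seed
            tv = np.mean([
                distribution_distance(
                    ssa_simulate(birth_death, kin, (3,), t_end, seed=s,
                                 cls=box)["occupancy_dist"].probs,
                    expected,
                    "total_variation",
                )
                for s in range(4)
            ])
            tvs.append(tv)
        assert tvs[2] < tvs[0]
        assert tvs[2] < 0.05

    def test_fast_path_agrees_with_generic_path(self, birth_death):
        kin = KineticsSpec(mode="mass_action")
        box = StateClass(box=(25,))
        fast = ssa_simulate(birth_death, kin, (0,), 400.0, seed=5, cls=box)
        slow = ssa_simulate(birth_death, kin, (0,), 400.0, seed=5)
        probs_slow = np.zeros(26)
        for state, frac in slow["occupancy"].items():
            probs_slow[state[0]] += frac
        tv = distribution_distance(
            fast["occupancy_dist"].probs, probs_slow, "total_variation"
        )
        assert tv < 0.1  # different sample paths, same law

    def test_constrained_class_occupancy_matches_product_form(
        self, constrained_system
    ):
        net, kin = constrained_system
        ap = alpha_partition(net)
        s = 30
        cls = StateClass(box=(s, s // 2), linear_invariants=(((1, 2), s),))
        eq = solve_complex_balanced(net, constraint=((1.0, 2.0), 1.0))
        pf = normalize(ProductFormMeasure.from_kinetics(eq.c, kin, net, ap), cls)
        out = ssa_simulate(net, kin, (s, 0), 30.0, seed=2, ap=ap, cls=cls)
        tv = distribution_distance(
            out["occupancy_dist"].probs, pf.probs, "total_variation"
        )
        assert tv < 0.05


class TestDistributionDistance:
    def test_identical(self):
        p = np.array([0.2, 0.8])
        assert distribution_distance(p, p, "relative_l2") == 0.0
        assert distribution_distance(p, p, "total_variation") == 0.0

    def test_disjoint_total_variation(self):
        assert distribution_distance((1.0, 0.0), (0.0, 1.0), "total_variation") == 1.0

    def test_reference_in_denominator(self):
        p = np.array([0.5, 0.5])
        q = np.array([1.0, 0.0])
        assert distribution_distance(p, q, "relative_l2") == pytest.approx(
            np.linalg.norm(p - q) / 1.0
        )

    def test_support_mismatch(self):
        with pytest.raises(ValueError, match="support mismatch"):
            distribution_distance((0.5, 0.5), (0.2, 0.3, 0.5))

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown distance"):
            distribution_distance((1.0,), (1.0,), "hellinger")
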