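import math

import numpy as np
import pytest

from crnpf import fixtures
from crnpf.kinetics import (
    KineticsError,
    KineticsSpec,
    ThetaDomainError,
    ThetaFunction,
    compile_theta_expression,
    factorization_check,
    mass_action_intensity,
    phi_from_theta,
    propensities,
    theta_intensity,
    validate_assumption1,
)
from crnpf.network import alpha_partition, build_network


class TestMassAction:
    def test_dimerization_at_five(self, reversible_pair):
        assert mass_action_intensity(reversible_pair, 0, (5, 0)) == 20.0

    def test_zero_below_source_count(self, reversible_pair):
        assert mass_action_intensity(reversible_pair, 0, (1, 0)) == 0.0
        assert mass_action_intensity(reversible_pair, 1, (4, 0)) == 0.0

    def test_full_system_dimerization_rate(self, full_system, dimer_params):
        net, kin = full_system
        k1 = dimer_params["k1"]
        for x1 in range(8):
            assert theta_intensity(kin, net, None, 0, (x1, 3)) == pytest.approx(
                k1 * x1 * (x1 - 1)
            )

    def test_vectorized_matches_scalar(self, full_system):
        net, kin = full_system
        X = np.array([[0, 0], [1, 2], [5, 3], [10, 7]])
        lam = propensities(net, kin, X)
        for j, x in enumerate(X):
            for k in range(net.K):
                assert lam[j, k] == pytest.approx(mass_action_intensity(net, k, x))


class TestThetaIntensity:
    def test_three_species_fourth_order_reaction(self):
        net, kin = fixtures.intensity_network9()
        ap = alpha_partition(net)
        t1, t2 = kin.thetas["S1"], kin.thetas["S2"]
        kappa3 = net.reactions[2].rate_constant
        for x in [(4, 2, 0), (6, 3, 1), (5, 2, 2), (9, 4, 0)]:
            expected = kappa3 * t1(x[0]) * t1(x[0] - 2) * t2(x[1]) * t2(x[1] - 1)
            assert theta_intensity(kin, net, ap, 2, x) == pytest.approx(expected)

    def test_identity_theta_reduces_to_mass_action(self, reversible_pair):
        kin = KineticsSpec(
            mode="theta_product",
            thetas={
                "S1": ThetaFunction.from_expression("x"),
                "S2": ThetaFunction.from_expression("x"),
            },
        )
        for x1 in range(6):
            for x2 in range(4):
                for k in range(2):
                    assert theta_intensity(kin, reversible_pair, None, k, (x1, x2)) == (
                        pytest.approx(mass_action_intensity(reversible_pair, k, (x1, x2)))
                    )

    def test_constrained_dimerization_rate(self, constrained_system):
        net, kin = constrained_system
        ap = alpha_partition(net)
        # theta1(5) = 5*4 + 1500 with the benchmark parameters
        assert theta_intensity(kin, net, ap, 0, (5, 0)) == pytest.approx(1520.0)

    def test_alpha_one_everywhere_collapses_to_plain_product(self, birth_death):
        kin = KineticsSpec(
            mode="alpha_theta_product",
            thetas={"S": ThetaFunction.from_expression("x")},
        )
        ap = alpha_partition(birth_death)
        assert ap.alpha == (1,)
        for x in range(5):
            assert theta_intensity(kin, birth_death, ap, 1, (x,)) == pytest.approx(
                float(x)
            )

    def test_indivisible_source_count_raises(self):
        net = build_network(
            ["S"],
            [
                {"reactants": {"S": 2}, "products": {}, "rate_constant": 1.0},
                {"reactants": {}, "products": {"S": 2}, "rate_constant": 1.0},
            ],
        )
        kin = KineticsSpec(
            mode="alpha_theta_product",
            thetas={"S": ThetaFunction.from_expression("x*(x-1)", alpha=2)},
        )

        class FakeAp:
            alpha = (4,)

        with pytest.raises(KineticsError, match="divisible"):
            theta_intensity(kin, net, FakeAp(), 0, (6,))

    def test_zero_outside_lattice_every_mode(self, constrained_system):
        net, kin = constrained_system
        ap = alpha_partition(net)
        # dimerization needs two molecules; theta1 vanishes at 0 and 1
        assert theta_intensity(kin, net, ap, 0, (0, 5)) == 0.0
        assert theta_intensity(kin, net, ap, 0, (1, 5)) == 0.0
        assert theta_intensity(kin, net, ap, 1, (3, 0)) == 0.0


class TestAssumption1:
    def test_valid_window_two_choice(self):
        net, kin = fixtures.intensity_network9()
        ap = alpha_partition(net)
        report = validate_assumption1(kin, net, ap, zmax=50)
        assert report.ok, report.violations

    def test_identity_theta_with_alpha_two_invalid(self):
        net = build_network(
            ["S"],
            [
                {"reactants": {"S": 2}, "products": {}, "rate_constant": 1.0},
                {"reactants": {}, "products": {"S": 2}, "rate_constant": 1.0},
            ],
        )
        kin = KineticsSpec(
            mode="alpha_theta_product",
            thetas={"S": ThetaFunction.from_expression("x", alpha=2)},
        )
        ap = alpha_partition(net)
        report = validate_assumption1(kin, net, ap, zmax=20)
        assert not report.ok
        assert any("theta(1)" in v for v in report.violations)

    def test_divisibility_violation_reported(self):
        net = build_network(
            ["S"],
            [
                {"reactants": {"S": 2}, "products": {}, "rate_constant": 1.0},
                {"reactants": {"S": 3}, "products": {"S": 1}, "rate_constant": 1.0},
            ],
        )
        # force alpha=2 against a count-3 source
        class FakeAp:
            alpha = (2,)

        kin = KineticsSpec(
            mode="alpha_theta_product",
            thetas={"S": ThetaFunction.from_expression("x*(x-1)", alpha=2)},
        )
        report = validate_assumption1(kin, net, FakeAp(), zmax=10)
        assert not report.ok
        assert any("not divisible" in v for v in report.violations)


class TestPhiRecursion:
    def test_falling_factorial_theta_gives_identity_phi(self):
        theta = ThetaFunction.from_expression("x*(x-1)", alpha=2)
        phi = phi_from_theta(theta, zmax=30)
        assert np.allclose(phi.values, np.arange(31))

    def test_window_product_reproduces_theta(self):
        for seed, alpha in [(0, 1), (1, 2), (2, 3)]:
            theta = fixtures.random_theta(alpha, zmax=80, seed=seed)
            phi = phi_from_theta(theta, zmax=80)
            tvals = theta.tabulate(80)
            for z in range(alpha, 81):
                window = np.prod(phi.values[z - alpha + 1 : z + 1])
                assert window == pytest.approx(tvals[z], rel=1e-12)

    def test_oscillating_theta_matches_closed_form(self):
        # closed form: phi(x) = C^(2 mod(x,2) - 1)
        #   * prod theta(x - 2i) / prod theta(x - 2i - 1)
        base = ThetaFunction.from_expression(fixtures.PARITY_THETA_EXPR, alpha=2)
        tv = base.tabulate(220)
        for C in (1.0, 2.5):
            phi = phi_from_theta(base, zmax=200, C=C)
            for x in range(1, 201):
                num = C ** (2 * (x % 2) - 1)
                num *= np.prod([tv[x - 2 * i] for i in range(x // 2)])
                den = np.prod([tv[x - 2 * i - 1] for i in range((x - 1) // 2)])
                assert phi.values[x] == pytest.approx(num / den, rel=1e-9)

    def test_factorization_check_small(self):
        theta = ThetaFunction.from_expression("x*(x-1)", alpha=2)
        phi = phi_from_theta(theta, zmax=210)
        assert factorization_check(theta, phi, 200) < 1e-9

    def test_factorization_z6_by_hand(self):
        # theta=z(z-1) gives phi(z)=z, so at z=6 both sides of the telescoped
        # identity equal 6! = theta(6)*theta(4)*theta(2) = 30*12*2 = 720
        theta = ThetaFunction.from_expression("x*(x-1)", alpha=2)
        phi = phi_from_theta(theta, zmax=10)
        lhs = np.prod(phi.values[1:7])
        rhs = 30.0 * 12.0 * 2.0
        assert lhs == pytest.approx(720.0) == pytest.approx(rhs)

    def test_both_sides_one_below_alpha(self):
        theta = fixtures.random_theta(3, zmax=20, seed=5)
        phi = phi_from_theta(theta, zmax=20)
        for z in (1, 2):
            assert np.prod(phi.values[1 : z + 1]) == pytest.approx(phi.values[z])
        # empty products at z < alpha: the telescoped identity is 1 = 1
        assert factorization_check(theta, phi, 2) == 0.0

    def test_oscillating_example_factorization(self):
        base = ThetaFunction.from_expression(fixtures.PARITY_THETA_EXPR, alpha=2)
        phi = phi_from_theta(base, zmax=210)
        assert factorization_check(base, phi, 200) < 1e-9

    def test_rebuilding_theta_from_phi(self):
        theta = fixtures.random_theta(3, zmax=60, seed=42)
        phi = phi_from_theta(theta, zmax=60)
        rebuilt = np.array(
            [np.prod(phi.values[max(z - 2, 0) : z + 1]) if z >= 3 else 0.0
             for z in range(61)]
        )
        tvals = theta.tabulate(60)
        np.testing.assert_allclose(rebuilt[3:], tvals[3:], rtol=1e-12)

    def test_bad_C_rejected(self):
        theta = ThetaFunction.from_expression("x*(x-1)", alpha=2)
        with pytest.raises(KineticsError):
            phi_from_theta(theta, zmax=10, C=0.0)


class TestThetaRules:
    def test_expression_names(self):
        fn = compile_theta_expression("ind(x > 1) * (10 + x + 6*sin(pi*x/5))")
        x = np.array([0, 1, 2, 5])
        out = fn(x)
        assert out[0] == 0.0 and out[1] == 0.0
        assert out[2] == pytest.approx(12 + 6 * math.sin(2 * math.pi / 5))

    def test_unknown_name_rejected(self):
        with pytest.raises(KineticsError, match="unknown name"):
            compile_theta_expression("x + evil(x)")

    def test_table_beyond_end_raises(self):
        theta = ThetaFunction.from_table([0.0, 1.0, 2.0])
        assert theta(2) == 2.0
        with pytest.raises(ThetaDomainError):
            theta(3)

    def test_negative_arguments_are_zero(self):
        theta = ThetaFunction.from_expression("x + 5")
        assert theta(-1) == 0.0
        np.testing.assert_array_equal(theta(np.array([-3, -1])), [0.0, 0.0])

    def test_unknown_mode_rejected(self):
        with pytest.raises(KineticsError):
            KineticsSpec(mode="guess")
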