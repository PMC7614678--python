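"""Sample-size solvers: closed forms, the ALC integer search, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from cpssd import (
    CollectivePrior,
    CriterionSpec,
    DesignSpec,
    acc_known,
    acc_unknown,
    alc_known,
    alc_unknown,
    apvc_known,
    apvc_unknown,
    comparison_modes,
    effective_size,
    expected_hpd_length,
    get_scenario,
    per_group_from_effective,
    posterior_known_variance,
    variance_prior_from_collective,
)


class TestEffectiveSize:
    @pytest.mark.parametrize("na, nb, e", [(21, 21, 10.5), (10, 30, 7.5)])
    def test_values(self, na, nb, e):
        assert effective_size(na, nb) == pytest.approx(e)

    @given(e=st.floats(0.5, 500), ratio=st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_inversion(self, e, ratio):
        na, nb = per_group_from_effective(e, ratio)
        assert nb / na == pytest.approx(ratio, rel=1e-12)
        assert effective_size(na, nb) == pytest.approx(e, rel=1e-12)


class TestCriterionSpec:
    def test_field_requirements(self):
        with pytest.raises(ValueError):
            CriterionSpec("acc", hpd_length=0.65)  # no coverage
        with pytest.raises(ValueError):
            CriterionSpec("apvc")  # no target
        with pytest.raises(ValueError):
            CriterionSpec("acc", hpd_length=-1, coverage=0.95)


class TestKnownVariance:
    def test_expert_prior_total(self, expert_prior, acc_spec):
        res = acc_known(expert_prior, acc_spec, 0.35)
        assert res.continuous_total == pytest.approx(41.8, abs=0.05)
        assert res.integer_total == 42
        assert not res.binding

    def test_binding_when_prior_suffices(self, acc_spec):
        # 4 z^2 / l0^2 <= 1/V  =>  zero sample size
        z = acc_spec.z
        v_small = acc_spec.hpd_length**2 / (4 * z**2) * 0.9
        res = acc_known(CollectivePrior(0.0, v_small), acc_spec, 0.35)
        assert res.binding and res.continuous_total == 0.0 and res.integer_total == 0

    def test_vague_prior_limit_matches_classical_width_formula(self, acc_spec):
        res = acc_known(CollectivePrior(0.0, 1e9), acc_spec, 0.35)
        classical = 16 * acc_spec.z**2 * 0.35 / acc_spec.hpd_length**2
        assert res.continuous_total == pytest.approx(classical, rel=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_alc_known_delegates_to_acc(self, seed):
        rng = np.random.default_rng(seed)
        prior = CollectivePrior(float(rng.normal()), float(rng.uniform(0.05, 2)))
        length = float(rng.uniform(0.2, 1.5))
        cov = float(rng.uniform(0.8, 0.99))
        sig = float(rng.uniform(0.1, 2))
        a = acc_known(prior, CriterionSpec("acc", hpd_length=length, coverage=cov), sig)
        b = alc_known(prior, CriterionSpec("alc", hpd_length=length, coverage=cov), sig)
        assert a.continuous_total == b.continuous_total
        assert a.integer_total == b.integer_total

    def test_apvc_binding(self, expert_prior):
        res = apvc_known(
            expert_prior, CriterionSpec("apvc", variance_target=0.2), 0.35
        )
        assert res.binding  # eps0 > V

    def test_apvc_against_root_finding_oracle(self, expert_prior, apvc_spec):
        """The closed form agrees with numerically solving
        posterior-variance(N) = eps0 through the posterior update."""
        res = apvc_known(expert_prior, apvc_spec, 0.35)

        def post_var(total):
            return posterior_known_variance(
                expert_prior, 0.0, DesignSpec.equal(total), 0.35
            ).variance - apvc_spec.variance_target

        root = optimize.brentq(post_var, 1.0, 10_000.0)
        assert res.continuous_total == pytest.approx(root, rel=1e-10)

    def test_apvc_linear_in_sigma(self, expert_prior, apvc_spec):
        r1 = apvc_known(expert_prior, apvc_spec, 0.35).continuous_total
        r2 = apvc_known(expert_prior, apvc_spec, 0.70).continuous_total
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_allocation_ratio(self, expert_prior, acc_spec):
        res = acc_known(expert_prior, acc_spec, 0.35, allocation_ratio=3.0)
        na, nb = res.continuous_per_group
        assert nb / na == pytest.approx(3.0, rel=1e-9)
        e_required = acc_known(expert_prior, acc_spec, 0.35).diagnostics[
            "required_effective_size"
        ]
        assert effective_size(na, nb) == pytest.approx(e_required, rel=1e-9)


class TestVariancePriorFromCollective:
    def test_expert_example_parameters(self):
        # shape c/2 = 2.500 and scale c V / 2 = 0.385 at V = 0.154, c = 5
        vp = variance_prior_from_collective(CollectivePrior(0.0, 0.154), 5.0)
        assert vp.c / 2 == pytest.approx(2.500)
        assert vp.scale == pytest.approx(0.385, abs=5e-4)

    def test_mean_formula(self):
        v = 0.2
        assert variance_prior_from_collective(
            CollectivePrior(0.0, v), 3.0
        ).mean_sigma0_sq == pytest.approx(3 * v)
        assert variance_prior_from_collective(
            CollectivePrior(0.0, v), 1e8
        ).mean_sigma0_sq == pytest.approx(v, rel=1e-6)


class TestUnknownVariance:
    def test_acc_expert_prior(self, expert_prior, acc_spec):
        vp = variance_prior_from_collective(expert_prior, 5.0)
        res = acc_unknown(expert_prior, acc_spec, vp)
        assert res.continuous_total == pytest.approx(30.7, abs=0.05)

    def test_acc_divergent_configuration(self, acc_spec):
        cp = get_scenario("config3_RWI").collective_prior()
        vp = variance_prior_from_collective(cp, 3.0)
        res = acc_unknown(cp, acc_spec, vp)
        assert res.continuous_total == pytest.approx(116.8, abs=0.1)

    def test_acc_higher_coverage(self):
        cp = get_scenario("config3_RWI").collective_prior()
        vp = variance_prior_from_collective(cp, 3.0)
        for cov, expected in ((0.975, 156.5), (0.90, 78.7)):
            spec = CriterionSpec("acc", hpd_length=0.65, coverage=cov)
            assert acc_unknown(cp, spec, vp).continuous_total == pytest.approx(
                expected, abs=0.1
            )

    def test_acc_requires_finite_mean(self, expert_prior, acc_spec):
        vp = variance_prior_from_collective(expert_prior, 2.0)
        with pytest.raises(ValueError, match="c > 2"):
            acc_unknown(expert_prior, acc_spec, vp)

    def test_acc_large_c_limit(self, expert_prior, acc_spec):
        vp = variance_prior_from_collective(expert_prior, 1e6)
        known = acc_known(expert_prior, acc_spec, expert_prior.variance)
        unknown = acc_unknown(expert_prior, acc_spec, vp)
        assert unknown.continuous_total == pytest.approx(
            known.continuous_total, rel=1e-4
        )

    def test_apvc_expert_prior(self, expert_prior, apvc_spec):
        vp = variance_prior_from_collective(expert_prior, 5.0)
        res = apvc_unknown(expert_prior, apvc_spec, vp)
        assert res.continuous_total == pytest.approx(27.6, abs=0.05)

    def test_apvc_binding_and_limit(self, expert_prior):
        vp = variance_prior_from_collective(expert_prior, 5.0)
        assert apvc_unknown(
            expert_prior, CriterionSpec("apvc", variance_target=0.2), vp
        ).binding
        vp_big = variance_prior_from_collective(expert_prior, 1e6)
        spec = CriterionSpec("apvc", variance_target=0.03)
        known = apvc_known(expert_prior, spec, expert_prior.variance)
        assert apvc_unknown(expert_prior, spec, vp_big).continuous_total == pytest.approx(
            known.continuous_total, rel=1e-4
        )


class TestALCSearch:
    def test_expert_prior_total(self, expert_prior, alc_spec):
        vp = variance_prior_from_collective(expert_prior, 5.0)
        assert alc_unknown(expert_prior, alc_spec, vp).integer_total == 24

    def test_divergent_configuration_total(self, alc_spec):
        cp = get_scenario("config3_RWI").collective_prior()
        vp = variance_prior_from_collective(cp, 3.0)
        assert alc_unknown(cp, alc_spec, vp).integer_total == 65

    def test_boundary_is_sharp(self, expert_prior, alc_spec):
        """The criterion holds at the returned total and fails one below."""
        vp = variance_prior_from_collective(expert_prior, 5.0)
        res = alc_unknown(expert_prior, alc_spec, vp)
        n = res.integer_total
        at = expected_hpd_length(
            expert_prior.variance, effective_size(n / 2, n / 2), vp, 0.95
        )
        m = n - 1
        below = expected_hpd_length(
            expert_prior.variance,
            effective_size(math.floor(m / 2), math.ceil(m / 2)),
            vp,
            0.95,
        )
        assert at <= alc_spec.hpd_length < below
        assert res.diagnostics["expected_length_at_solution"] == pytest.approx(at)

    def test_known_variance_limit(self, expert_prior, alc_spec):
        """With the variance prior collapsed, the search agrees with the
        known-variance closed form to within one unit."""
        vp = variance_prior_from_collective(expert_prior, 1e6)
        res = alc_unknown(expert_prior, alc_spec, vp)
        known = alc_known(expert_prior, alc_spec, expert_prior.variance)
        assert abs(res.integer_total - known.integer_total) <= 1

    def test_even_step_policy(self, expert_prior, alc_spec):
        vp = variance_prior_from_collective(expert_prior, 5.0)
        res = alc_unknown(expert_prior, alc_spec, vp, step=2)
        assert res.integer_total % 2 == 0
        assert res.integer_total >= alc_unknown(expert_prior, alc_spec, vp).integer_total

    def test_binding_prior(self, alc_spec):
        prior = CollectivePrior(0.0, 0.01)
        vp = variance_prior_from_collective(prior, 5.0)
        assert alc_unknown(prior, alc_spec, vp).binding

    @pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")
    def test_unreachable_target_raises(self, expert_prior):
        # the extreme target drives the quadrature into roundoff territory,
        # which is exactly the regime the error path must survive
        vp = variance_prior_from_collective(expert_prior, 5.0)
        spec = CriterionSpec("alc", hpd_length=1e-4, coverage=0.95)
        with pytest.raises(ArithmeticError, match="unreachable"):
            alc_unknown(expert_prior, spec, vp, n_max=10_000)


class TestMonotonicity:
    def test_acc_decreasing_in_length_increasing_in_coverage(self, expert_prior):
        totals_l = [
            acc_known(
                expert_prior, CriterionSpec("acc", hpd_length=l, coverage=0.95), 0.35
            ).continuous_total
            for l in (0.5, 0.65, 0.8)
        ]
        assert totals_l[0] > totals_l[1] > totals_l[2]
        totals_c = [
            acc_known(
                expert_prior, CriterionSpec("acc", hpd_length=0.65, coverage=c), 0.35
            ).continuous_total
            for c in (0.90, 0.95, 0.99)
        ]
        assert totals_c[0] < totals_c[1] < totals_c[2]

    def test_apvc_decreasing_in_target(self, expert_prior):
        totals = [
            apvc_known(
                expert_prior, CriterionSpec("apvc", variance_target=e), 0.35
            ).continuous_total
            for e in (0.02, 0.03, 0.05)
        ]
        assert totals[0] > totals[1] > totals[2]

    def test_totals_decrease_in_c(self, acc_spec, alc_spec, apvc_spec):
        """Larger prior degrees of freedom tie sigma0^2 closer to V and
        shrink the required sample size for every criterion."""
        cp = get_scenario("config1_RWI").collective_prior()
        cs = [3.0, 5.0, 10.0, 30.0]
        acc = [
            acc_unknown(cp, acc_spec, variance_prior_from_collective(cp, c)).continuous_total
            for c in cs
        ]
        apvc = [
            apvc_unknown(cp, apvc_spec, variance_prior_from_collective(cp, c)).continuous_total
            for c in cs
        ]
        alc = [
            alc_unknown(cp, alc_spec, variance_prior_from_collective(cp, c)).integer_total
            for c in cs
        ]
        assert all(a > b for a, b in zip(acc, acc[1:]))
        assert all(a > b for a, b in zip(apvc, apvc[1:]))
        assert all(a >= b for a, b in zip(alc, alc[1:]))

    @pytest.mark.parametrize("c", [3.0, 5.0])
    def test_alc_no_larger_than_acc(self, c, acc_spec, alc_spec):
        """Jensen's inequality: E[sigma_N] <= sqrt(E[sigma_N^2]) makes the
        ALC total at matching (l, alpha) at most the ACC total."""
        for cfg in (1, 2, 3, 4):
            for rw in ("I", "II"):
                cp = get_scenario(f"config{cfg}_RW{rw}").collective_prior()
                vp = variance_prior_from_collective(cp, c)
                acc_total = acc_unknown(cp, acc_spec, vp).integer_total
                alc_total = alc_unknown(cp, alc_spec, vp).integer_total
                assert alc_total <= acc_total


class TestComparisonModes:
    def test_no_borrowing_divergent_configuration(self, acc_spec):
        sc = get_scenario("config3_RWI")
        table = comparison_modes(
            list(sc.sources), sc.spec, acc_spec, variance="unknown", c=3.0
        )
        t = table.set_index("mode")["continuous_total"]
        assert t["no_borrowing"] == pytest.approx(232.2, abs=0.1)
        assert t["robust"] == pytest.approx(116.8, abs=0.1)

    @pytest.mark.parametrize("variance", ["known", "unknown"])
    def test_robust_bounded_by_extremes(self, variance, acc_spec, apvc_spec):
        """Robust totals lie between no-robustification and no-borrowing."""
        kwargs = {"sigma0_sq": 0.35} if variance == "known" else {"c": 3.0}
        for cfg in (1, 2, 3, 4):
            for rw in ("I", "II"):
                sc = get_scenario(f"config{cfg}_RW{rw}")
                for crit in (acc_spec, apvc_spec):
                    t = comparison_modes(
                        list(sc.sources), sc.spec, crit, variance=variance,
                        modes=("robust", "no_robustification", "no_borrowing"),
                        **kwargs,
                    ).set_index("mode")["continuous_total"]
                    assert t["no_robustification"] <= t["robust"] <= t["no_borrowing"]

    def test_optimal_mode_known_variance(self, acc_spec):
        sc = get_scenario("config1_RWI")
        cp = sc.collective_prior()
        t = comparison_modes(
            list(sc.sources), sc.spec, acc_spec, variance="known", sigma0_sq=0.35,
            modes=("optimal",),
        )
        expected = acc_known(cp, acc_spec, cp.variance).continuous_total
        assert t["continuous_total"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_single_source_uses_most_informative(self, acc_spec):
        sc = get_scenario("config1_RWI")
        t = comparison_modes(
            list(sc.sources), sc.spec, acc_spec, variance="known", sigma0_sq=0.35,
            modes=("single_source",),
        )
        # most informative summary of configuration 1 is N(-0.37, 0.22)
        assert t["prior_mean"].iloc[0] == pytest.approx(-0.37)
        assert t["prior_variance"].iloc[0] == pytest.approx(0.22)


class TestStochasticConsistency:
    def test_mc_average_coverage_at_acc_design(self, expert_prior, acc_spec):
        """At the ACC solution the simulated average coverage meets 1-alpha."""
        from cpssd import simulate_average_properties

        vp = variance_prior_from_collective(expert_prior, 5.0)
        res = acc_unknown(expert_prior, acc_spec, vp)
        design = DesignSpec.equal(res.integer_total)
        rep = simulate_average_properties(
            expert_prior, design, vp, acc_spec, reps=100_000, seed=11
        )
        assert rep.avg_coverage >= 0.95 - 3 * rep.se_coverage

    def test_mc_average_length_at_alc_design(self, expert_prior, alc_spec):
        from cpssd import simulate_average_properties

        vp = variance_prior_from_collective(expert_prior, 5.0)
        res = alc_unknown(expert_prior, alc_spec, vp)
        design = DesignSpec.equal(res.integer_total)
        rep = simulate_average_properties(
            expert_prior, design, vp, alc_spec, reps=100_000, seed=12
        )
        assert rep.avg_length <= 0.65 + 3 * rep.se_length
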