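"""Fitness functional: quadrature, closed forms, decompositions."""

import math

import numpy as np
import pytest

from sleepdyn import (
    ExposureMode,
    Scenario,
    SyntheticSpec,
    decompose_fitness,
    fitness_closed_form,
    fitness_quadrature,
    harmonic_product_integral,
    long_run_growth_rate,
    random_environment,
    random_sleep_strategy,
    riemann_fitness_oracle,
    scenario_setup,
    secular_slope_numeric,
)

PI = math.pi
B, G = 5.0, 2.5


class TestQuadrature:
    def test_constant_rates_linear_growth(self, constant_env, waking):
        # expected value frozen from the trivially integrable constant case,
        # cross-checked against a 1e6-step Riemann sum
        r = fitness_quadrature(constant_env, waking, ExposureMode.NEUTRAL, 10.0)
        assert r == pytest.approx(25.0, rel=1e-10)
        oracle = riemann_fitness_oracle(
            constant_env, waking, ExposureMode.NEUTRAL, 10.0, n_steps=1_000_000
        )
        assert r == pytest.approx(oracle, abs=1e-4)

    def test_zero_horizon(self, constant_env, full_sleep):
        assert fitness_quadrature(constant_env, full_sleep, ExposureMode.SAFE, 0.0) == 0.0

    def test_oscillating_birth_whole_period(self):
        env, s, mode = scenario_setup(Scenario("var-birth", "sleeping"))
        r = fitness_quadrature(env, s, mode, 2.0 * PI)
        assert r == pytest.approx(10.0 * PI, rel=1e-10)

    def test_rejects_bad_arguments(self, constant_env, waking):
        with pytest.raises(ValueError):
            fitness_quadrature(constant_env, waking, ExposureMode.NEUTRAL, -1.0)
        with pytest.raises(ValueError):
            fitness_quadrature(constant_env, waking, ExposureMode.NEUTRAL, 1.0, tol=0.0)


class TestHarmonicProductIntegral:
    def test_fully_modulated_secular_coefficient(self):
        """Secular part of int B(1+cos(r-g))(1+cos(r-q)): B(1 + cos(g-q)/2)."""
        g, q = PI / 5, 1.1
        res = harmonic_product_integral(B, 1.0, g, 1.0, q)
        expected = B * (1.0 + 0.5 * math.sin(q) * math.sin(g) + 0.5 * math.cos(g) * math.cos(q))
        assert res.linear_coeff == pytest.approx(expected, abs=1e-14)

    def test_constant_integrand(self):
        res = harmonic_product_integral(3.0, 0.0, 0.0, 0.0, 0.0)
        assert res.linear_coeff == 3.0
        assert res.harmonic_terms == ()
        assert float(res(7.0)) == pytest.approx(21.0)

    def test_squared_cosine_over_period(self):
        # int_0^{2pi} (1+cos)^2 = 3pi (frozen from a 1e6-step Riemann sum)
        res = harmonic_product_integral(1.0, 1.0, 0.0, 1.0, 0.0)
        assert float(res(2.0 * PI)) == pytest.approx(3.0 * PI, rel=1e-12)

    def test_vanishes_at_zero(self):
        res = harmonic_product_integral(2.0, 0.8, 0.3, 0.5, 2.1)
        assert float(res(0.0)) == pytest.approx(0.0, abs=1e-14)

    def test_oscillation_bound_holds(self):
        res = harmonic_product_integral(2.0, 1.0, 0.4, 1.0, 2.2)
        t = np.linspace(0.0, 200.0, 4001)
        assert np.all(np.abs(res(t) - res.linear_coeff * t) <= res.oscillation_bound + 1e-12)


class TestClosedForms:
    @pytest.mark.parametrize(
        "scenario, variant, t, expected",
        [
            ("const-const", "waking", 4.0, 10.0),  # (B-G)t
            ("const-const", "sleeping", 4.0, 10.0 + 5.0 * math.sin(4.0)),  # + B sin t
            ("var-birth", "waking", 4.0, 10.0 + 5.0 * math.sin(4.0)),
            (
                "var-birth",
                "sleeping",
                4.0,
                1.5 * B * 4.0 - G * 4.0 + 2 * B * math.sin(4.0) + 0.25 * B * math.sin(8.0),
            ),
            ("var-birth", "sleeping", 2.0 * PI, 10.0 * PI),
            ("const-birth-var-mortality", "waking", 4.0, 10.0 - G * math.sin(4.0)),
            ("const-birth-var-mortality", "safe", PI / 2, 3.75 * PI / 2),  # 5.89049
            ("const-birth-var-mortality", "vulnerable", PI / 2, 3.75 * PI / 2),
        ],
    )
    def test_printed_forms(self, scenario, variant, t, expected):
        sc = Scenario(scenario, variant, B=B, Gamma=G)
        assert fitness_closed_form(sc, t) == pytest.approx(expected, rel=1e-12)

    def test_out_of_phase_waking_form(self):
        """r1 = (B-G)t + B cos g sin t - B sin g cos t - G sin t + B sin g."""
        g, t = PI / 3, 7.7
        sc = Scenario("var-both", "waking", B=B, Gamma=G, g=g)
        expected = (
            (B - G) * t
            + B * math.cos(g) * math.sin(t)
            - B * math.sin(g) * math.cos(t)
            - G * math.sin(t)
            + B * math.sin(g)
        )
        assert fitness_closed_form(sc, t) == pytest.approx(expected, rel=1e-12)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario("var-everything", "waking")
        with pytest.raises(ValueError):
            Scenario("var-both", "sleeping")  # wrong variant name for this family


class TestDecomposition:
    def test_out_of_phase_waking_secular(self):
        d = decompose_fitness(Scenario("var-both", "waking", B=B, Gamma=G, g=1.0))
        assert d.linear_coeff == pytest.approx(B - G, abs=1e-14)

    def test_out_of_phase_safe_secular(self):
        d = decompose_fitness(
            Scenario("var-both", "safe", B=B, Gamma=G, g=PI / 3, phase=PI / 2)
        )
        assert d.linear_coeff == pytest.approx(G + G * math.sin(PI / 3), abs=1e-12)
        # cross-check: least-squares slope of the quadrature fitness
        env, s, mode = scenario_setup(
            Scenario("var-both", "safe", B=B, Gamma=G, g=PI / 3, phase=PI / 2)
        )
        assert secular_slope_numeric(env, s, mode, n_periods=100) == pytest.approx(
            d.linear_coeff, rel=1e-9
        )

    def test_constant_environment_sleep_is_neutral(self):
        d = decompose_fitness(Scenario("const-const", "sleeping", B=B, Gamma=G))
        assert long_run_growth_rate(d) == pytest.approx(2.5, abs=1e-14)

    def test_long_run_rate_matches_quadrature_at_large_t(self):
        for name, variant, expected in [
            ("const-const", "waking", B - G),
            ("var-birth", "sleeping", 1.5 * B - G),
        ]:
            sc = Scenario(name, variant, B=B, Gamma=G)
            env, s, mode = scenario_setup(sc)
            horizon = 1.0e4
            slope = fitness_quadrature(env, s, mode, horizon, tol=1e-11) / horizon
            assert long_run_growth_rate(decompose_fitness(sc)) == pytest.approx(
                expected, abs=1e-12
            )
            assert slope == pytest.approx(expected, rel=1e-4)

    def test_reconstruction_vanishes_at_zero_every_scenario(self):
        from sleepdyn.fitness import SCENARIOS

        for name, variants in SCENARIOS.items():
            for variant in variants:
                d = decompose_fitness(
                    Scenario(name, variant, B=B, Gamma=G, g=PI / 3, phase=PI / 2)
                )
                assert float(d(0.0)) == pytest.approx(0.0, abs=1e-12)
                t = np.linspace(0.0, 80.0, 1601)
                assert np.all(
                    np.abs(d(t) - d.linear_coeff * t) <= d.oscillation_bound + 1e-10
                )

    def test_additivity_in_birth_and_mortality(self):
        """r is linear in beta and gamma separately: r(B,G) = r(B,0) + r(0,G)."""
        t = np.linspace(0.0, 50.0, 501)
        for variant in ("waking", "safe", "vulnerable"):
            kw = dict(g=PI / 3, phase=PI / 2)
            full = decompose_fitness(Scenario("var-both", variant, B=B, Gamma=G, **kw))
            births = decompose_fitness(Scenario("var-both", variant, B=B, Gamma=0.0, **kw))
            deaths = decompose_fitness(Scenario("var-both", variant, B=0.0, Gamma=G, **kw))
            np.testing.assert_allclose(full(t), births(t) + deaths(t), atol=1e-10)

    def test_sigma_zero_collapses_to_waking(self):
        """At sigma=0 the sleeping forms reduce to the waking ones.

        Holds for activity-coupled and safe-exposure terms (s == 1 makes the
        weighting trivial); the vulnerable weighting is excluded because
        max s - s vanishes identically at sigma = 0, abolishing mortality —
        the degenerate case the waking-baseline convention avoids.
        """
        t = np.linspace(0.0, 40.0, 401)
        for name, variant in [
            ("const-const", "sleeping"),
            ("var-birth", "sleeping"),
            ("const-birth-var-mortality", "safe"),
            ("var-both", "safe"),
        ]:
            wake = decompose_fitness(Scenario(name, "waking", B=B, Gamma=G, g=PI / 3))
            flat = decompose_fitness(
                Scenario(name, variant, B=B, Gamma=G, g=PI / 3, sigma=0.0, phase=PI / 2)
            )
            np.testing.assert_allclose(flat(t), wake(t), atol=1e-10)


class TestQuadratureClosedFormAgreement:
    @pytest.mark.parametrize("g", [0.0, PI / 3, 5 * PI / 3])
    def test_agreement_on_random_times(self, g):
        rng = np.random.default_rng(7)
        from sleepdyn.fitness import SCENARIOS

        for name, variants in SCENARIOS.items():
            for variant in variants:
                sc = Scenario(name, variant, B=B, Gamma=G, g=g, phase=PI / 2)
                d = decompose_fitness(sc)
                env, s, mode = scenario_setup(sc)
                for t in rng.uniform(0.0, 50.0, size=5):
                    q = fitness_quadrature(env, s, mode, float(t))
                    c = float(d(t))
                    assert q == pytest.approx(c, rel=1e-8, abs=1e-9)


class TestTabulatedOracle:
    def test_quadrature_matches_riemann_oracle_on_synthetic_environments(self):
        for seed in range(3):
            spec = SyntheticSpec(seed=seed)
            env = random_environment(spec)
            strat = random_sleep_strategy(spec)
            mode = list(ExposureMode)[seed % 3]
            t = 2.0 * spec.period
            q = fitness_quadrature(env, strat, mode, t)
            o = riemann_fitness_oracle(env, strat, mode, t, n_steps=1_000_000)
            assert q == pytest.approx(o, rel=1e-6)
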