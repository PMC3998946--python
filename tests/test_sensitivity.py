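"""Scenario engine: overrides, built-in battery, sweeps, tornado, PSA."""

import numpy as np
import pytest

from fibersavings import (
    ScenarioPathError,
    ScenarioSpec,
    builtin_table2_scenarios,
    default_base_case,
    one_way_sweep,
    probabilistic_sa,
    run_model,
    run_scenario,
    tornado,
)


class TestRunScenario:
    def test_base_never_mutated(self, adult_cfg):
        snapshot = adult_cfg.model_copy(deep=True)
        run_scenario(
            adult_cfg,
            ScenarioSpec(
                "x",
                {
                    "strata.adult_male.responder_frac": 0.5,
                    "shift": {15.0: 1.0},
                    "dose_response.per_gram_reduction": 0.03,
                },
            ),
        )
        assert adult_cfg == snapshot

    def test_empty_overrides_equal_base(self, adult_cfg):
        assert run_scenario(
            adult_cfg, ScenarioSpec("noop", {})
        ).total_annual_savings == pytest.approx(
            run_model(adult_cfg).total_annual_savings, rel=1e-15
        )

    @pytest.mark.parametrize(
        "path",
        [
            "strata.adult_male.nonsense",
            "strata.no_such_stratum.rx_frac",
            "dose_response.nope.deep",
            "not_a_field",
        ],
    )
    def test_bad_path_raises_naming_path(self, adult_cfg, path):
        with pytest.raises(ScenarioPathError) as exc:
            run_scenario(adult_cfg, ScenarioSpec("bad", {path: 0.5}))
        assert path in str(exc.value)

    def test_override_value_validated(self, adult_cfg):
        with pytest.raises(Exception, match="responder_frac"):
            run_scenario(
                adult_cfg,
                ScenarioSpec("bad", {"strata.adult_male.responder_frac": 1.5}),
            )


class TestBuiltinScenarios:
    def test_thirteen_scenarios(self):
        specs = builtin_table2_scenarios()
        assert len(specs) == 13
        assert len({s.name for s in specs}) == 13

    def test_uptake_spec_shift(self):
        spec = next(
            s for s in builtin_table2_scenarios() if s.name == "uptake_25pct_3g"
        )
        assert spec.overrides == {"shift": {0.0: 0.75, 3.0: 0.25}}

    def test_best_case_overrides(self):
        spec = next(
            s for s in builtin_table2_scenarios() if s.name == "multivariate_best"
        )
        ov = spec.overrides
        assert ov["strata.adult_male.pct_meeting_recs"] == 0.01
        assert ov["strata.adult_female.constipation_prev"] == 0.07
        assert ov["dose_response.per_gram_reduction"] == 0.03
        assert ov["strata.adult_male.rx_frac"] == 1.0
        assert ov["shift"] == {15.0: 1.0}

    def test_pediatric_scenario_switches_scope(self, adult_cfg):
        spec = next(
            s for s in builtin_table2_scenarios() if s.name == "pediatric_6g"
        )
        result = run_scenario(adult_cfg, spec)
        assert set(result.per_stratum) == {"pediatric_male", "pediatric_female"}


class TestOneWaySweep:
    def test_cost_sweep_strictly_increasing(self, adult_cfg):
        base_cost = 10786.15
        values = [0.5 * base_cost, base_cost, 1.5 * base_cost]
        table = one_way_sweep(
            adult_cfg, "strata.adult_male.rx_annual_cost", values
        )
        savings = [r["total_annual_savings"] for r in table.rows]
        assert savings == sorted(savings)
        assert savings[0] < savings[1] < savings[2]

    def test_single_base_value_row_equals_base(self, adult_cfg):
        table = one_way_sweep(
            adult_cfg, "strata.adult_male.responder_frac", [0.85]
        )
        assert table.rows[0]["total_annual_savings"] == pytest.approx(
            run_model(adult_cfg).total_annual_savings, rel=1e-15
        )

    def test_prevalence_sweep_exact_ratios(self, adult_cfg):
        # prevalence enters the chain linearly, so sweeping it across both
        # strata must scale total savings by exactly the same ratios
        def total_at(p):
            spec = ScenarioSpec(
                "p",
                {
                    "strata.adult_male.constipation_prev": p,
                    "strata.adult_female.constipation_prev": p,
                },
            )
            return run_scenario(adult_cfg, spec).total_annual_savings

        s1, s46, s7 = total_at(0.01), total_at(0.046), total_at(0.07)
        assert s1 / s46 == pytest.approx(1 / 4.6, rel=1e-12)
        assert s7 / s46 == pytest.approx(7 / 4.6, rel=1e-12)

    def test_rows_ordered_as_given(self, adult_cfg):
        values = [0.07, 0.01, 0.046]
        table = one_way_sweep(
            adult_cfg, "strata.adult_male.constipation_prev", values
        )
        assert [r["name"] for r in table.rows] == [
            f"strata.adult_male.constipation_prev={v}" for v in values
        ]


class TestTornado:
    def test_degenerate_range_last_and_complete(self, adult_cfg):
        ranges = {
            "dose_response.per_gram_reduction": (0.01, 0.03),
            "strata.adult_male.responder_frac": (0.85, 0.85),
        }
        rows = tornado(adult_cfg, ranges)
        assert len(rows) == len(ranges)
        assert rows[-1]["path"] == "strata.adult_male.responder_frac"
        assert rows[-1]["range"] == 0.0

    def test_dose_response_outranks_responder(self, adult_cfg):
        # both ranges computed by direct model evaluation; dr spans further
        def both(path, lo, hi):
            a = run_scenario(adult_cfg, ScenarioSpec("a", {path: lo}))
            b = run_scenario(adult_cfg, ScenarioSpec("b", {path: hi}))
            return abs(b.total_annual_savings - a.total_annual_savings)

        dr_range = both("dose_response.per_gram_reduction", 0.01, 0.03)
        resp_range = both("strata.adult_male.responder_frac", 0.50, 1.0)
        assert dr_range > resp_range
        rows = tornado(
            adult_cfg,
            {
                "dose_response.per_gram_reduction": (0.01, 0.03),
                "strata.adult_male.responder_frac": (0.50, 1.0),
            },
        )
        assert rows[0]["path"] == "dose_response.per_gram_reduction"
        assert rows[0]["range"] == pytest.approx(dr_range, rel=1e-12)

    def test_linear_parameter_range_matches_finite_difference(self, adult_cfg):
        path = "strata.adult_male.responder_frac"
        lo, hi = 0.6, 0.9
        rows = tornado(adult_cfg, {path: (lo, hi)})
        # slope from a small finite difference, scaled to the full interval
        eps = 1e-4
        a = run_scenario(adult_cfg, ScenarioSpec("a", {path: 0.75})).total_annual_savings
        b = run_scenario(
            adult_cfg, ScenarioSpec("b", {path: 0.75 + eps})
        ).total_annual_savings
        slope = (b - a) / eps
        assert rows[0]["range"] == pytest.approx(slope * (hi - lo), rel=1e-6)


class TestProbabilisticSA:
    def test_degenerate_distributions_reproduce_base(self, adult_cfg):
        base = run_model(adult_cfg).total_annual_savings
        out = probabilistic_sa(
            adult_cfg,
            {
                "strata.adult_male.responder_frac": ("fixed", 0.85),
                "dose_response.per_gram_reduction": ("uniform", 0.019, 0.019),
            },
            n_draws=20,
            seed=7,
        )
        assert np.allclose(out["draws"]["total_annual_savings"], base)
        # identical draws: sd is zero up to ulp-level noise in the mean
        assert out["sd"] <= 1e-9 * out["mean"]

    def test_same_seed_identical_draws(self, adult_cfg):
        dists = {"strata.adult_male.responder_frac": ("uniform", 0.5, 1.0)}
        a = probabilistic_sa(adult_cfg, dists, 50, seed=3)
        b = probabilistic_sa(adult_cfg, dists, 50, seed=3)
        assert a["draws"].equals(b["draws"])
        assert a["mean"] == b["mean"]

    def test_uniform_responder_mean_matches_linearity(self, adult_cfg):
        # savings is linear in responder_frac, so E[savings] equals
        # savings at the distribution mean, up to Monte Carlo error
        dists = {
            "strata.adult_male.responder_frac": ("uniform", 0.5, 1.0),
            "strata.adult_female.responder_frac": ("uniform", 0.5, 1.0),
        }
        out = probabilistic_sa(adult_cfg, dists, 10_000, seed=11)
        expected = run_scenario(
            adult_cfg,
            ScenarioSpec(
                "mid",
                {
                    "strata.adult_male.responder_frac": 0.75,
                    "strata.adult_female.responder_frac": 0.75,
                },
            ),
        ).total_annual_savings
        se = out["sd"] / np.sqrt(10_000)
        assert abs(out["mean"] - expected) < 3 * se

    def test_triangular_and_beta_families_supported(self, adult_cfg):
        out = probabilistic_sa(
            adult_cfg,
            {
                "dose_response.per_gram_reduction": ("triangular", 0.01, 0.019, 0.03),
                "strata.adult_male.constipation_prev": ("beta", 4.6, 95.4),
            },
            n_draws=100,
            seed=5,
        )
        assert len(out["draws"]) == 100
        assert out["quantiles"][0.5] > 0

    def test_unsupported_family_rejected(self, adult_cfg):
        with pytest.raises(ValueError, match="unsupported distribution"):
            probabilistic_sa(
                adult_cfg,
                {"dose_response.per_gram_reduction": ("lognormal", 0, 1)},
                10,
                seed=1,
            )

    def test_zero_draws_rejected(self, adult_cfg):
        with pytest.raises(ValueError, match="n_draws"):
            probabilistic_sa(adult_cfg, {}, 0, seed=1)
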