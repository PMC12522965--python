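import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icdcea.parameters import (
    FALLBACK_FRACTION,
    InfeasibleMomentsError,
    SchemaError,
    ValidationError,
    beta_from_moments,
    ci95_bounds,
    default_parameter_set,
    draw_at,
    fixed_spec,
    gamma_from_moments,
    load_parameter_table,
    mean_draw,
    parameter_frame,
    sample_parameters,
    sample_spec,
)
from icdcea.states import Arm, HealthState


class TestBetaFromMoments:
    def test_published_hosp_death_probability(self):
        # frozen from alpha = m*nu, beta = (1-m)*nu, nu = m(1-m)/sd^2 - 1
        spec = beta_from_moments(0.178, 0.008)
        assert spec.family == "beta"
        assert spec.shape1 == pytest.approx(406.7633750, rel=1e-9)
        assert spec.shape2 == pytest.approx(1878.4241250, rel=1e-9)

    def test_monte_carlo_moments(self):
        spec = beta_from_moments(0.178, 0.008)
        rng = np.random.default_rng(7)
        draws = rng.beta(spec.shape1, spec.shape2, size=1_000_000)
        se_mean = 0.008 / 1000.0
        assert abs(draws.mean() - 0.178) < 3 * se_mean
        # SE of the sample SD ~ sd / sqrt(2(n-1))
        assert abs(draws.std(ddof=1) - 0.008) < 3 * 0.008 / math.sqrt(2e6 - 2)

    def test_boundary_sd_infeasible(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.5, 0.5)

    def test_zero_sd_degenerates_to_fixed(self):
        spec = beta_from_moments(0.75, 0.0)
        assert spec.is_fixed and spec.mean == 0.75

    def test_mean_outside_unit_interval(self):
        with pytest.raises(ValidationError):
            beta_from_moments(1.2, 0.01)

    @given(
        mean=st.floats(0.01, 0.99),
        frac=st.floats(0.01, 0.8),
    )
    @settings(max_examples=200)
    def test_moment_round_trip(self, mean, frac):
        sd = frac * math.sqrt(mean * (1.0 - mean))
        spec = beta_from_moments(mean, sd)
        m, s = spec.analytic_moments()
        assert m == pytest.approx(mean, rel=1e-9)
        assert s == pytest.approx(sd, rel=1e-9)


class TestGammaFromMoments:
    def test_published_well_cost(self):
        spec = gamma_from_moments(3398.0, 1105.0)
        assert spec.shape1 == pytest.approx(9.456320714154092, rel=1e-12)
        assert spec.shape2 == pytest.approx(359.3363743378458, rel=1e-12)

    def test_monte_carlo_moments(self):
        spec = gamma_from_moments(3398.0, 1105.0)
        rng = np.random.default_rng(11)
        draws = rng.gamma(spec.shape1, spec.shape2, size=1_000_000)
        assert abs(draws.mean() - 3398.0) < 3 * 1105.0 / 1000.0

    def test_death_cost_has_no_sd(self):
        assert gamma_from_moments(2777.0, 0.0).is_fixed

    def test_negative_mean(self):
        with pytest.raises(ValidationError):
            gamma_from_moments(-5.0, 1.0)

    @given(mean=st.floats(1.0, 1e5), sd=st.floats(0.1, 1e4))
    @settings(max_examples=200)
    def test_moment_round_trip(self, mean, sd):
        spec = gamma_from_moments(mean, sd)
        m, s = spec.analytic_moments()
        assert m == pytest.approx(mean, rel=1e-9)
        assert s == pytest.approx(sd, rel=1e-9)


class TestCI95Bounds:
    def test_probability_bounds(self):
        spec = beta_from_moments(0.284, 0.009)
        assert ci95_bounds(spec, "probability") == pytest.approx((0.26636, 0.30164))

    def test_utility_upper_clamped(self):
        spec = beta_from_moments(0.845, 0.124)
        low, high = ci95_bounds(spec, "utility")
        assert low == pytest.approx(0.60196)
        assert high == 1.0

    def test_sdless_cost_fallback(self):
        low, high = ci95_bounds(fixed_spec(2777.0), "cost")
        assert (low, high) == pytest.approx((2082.75, 3471.25))

    def test_symmetry_before_clamping(self):
        spec = beta_from_moments(0.4, 0.1)
        low, high = ci95_bounds(spec, "probability")
        assert high - spec.mean == pytest.approx(spec.mean - low)

    def test_fallback_fraction_documented(self):
        assert FALLBACK_FRACTION == 0.25


class TestLoader:
    def test_default_set_matches_published_table(self, default_params):
        spec = default_params.spec("tp_icd_hosp_to_death")
        assert spec.family == "beta"
        assert spec.mean == 0.178 and spec.sd == 0.008
        assert default_params.spec("cost_pharm_well").mean == 741.0
        assert default_params.spec("cost_pharm_well").sd == 1246.0
        assert default_params.settings.wtp == 13_002.0
        assert default_params.settings.discount_rate_cost == 0.06
        assert default_params.settings.discount_rate_outcome == 0.03

    def test_invalid_utility_rejected(self, tmp_path):
        path = tmp_path / "params.csv"
        path.write_text(
            "parameter_id,arm,category,source_state,target_state,mean,sd,distribution\n"
            "util_icd_well,icd,utility,well,,1.2,,fixed\n"
        )
        with pytest.raises(ValidationError, match="util_icd_well"):
            load_parameter_table(path)

    def test_beta_infeasible_sd_rejected(self, tmp_path):
        path = tmp_path / "params.csv"
        path.write_text(
            "parameter_id,arm,category,source_state,target_state,mean,sd,distribution\n"
            "util_icd_well,icd,utility,well,,0.5,0.6,beta\n"
        )
        with pytest.raises(ValidationError, match="util_icd_well"):
            load_parameter_table(path)

    def test_missing_free_block_flagged_uncalibrated(self, tmp_path, default_params):
        frame = parameter_frame(default_params)
        frame = frame[~frame.parameter_id.str.contains("well_to")]
        path = tmp_path / "params.csv"
        frame.to_csv(path, index=False)
        ps = load_parameter_table(path)
        assert not ps.free_calibrated
        # documented calibratable defaults still present
        assert "tp_icd_well_to_compl" in ps.rows

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "params.csv"
        path.write_text("parameter_id,arm\nx,icd\n")
        with pytest.raises(SchemaError):
            load_parameter_table(path)

    def test_strict_mode_requires_mandatory_rows(self, tmp_path, default_params):
        frame = parameter_frame(default_params)
        frame = frame[frame.parameter_id != "cost_icd_well"]
        path = tmp_path / "params.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="cost_icd_well"):
            load_parameter_table(path, strict=True)

    def test_settings_overrides(self, tmp_path, default_params):
        frame = parameter_frame(default_params)
        path = tmp_path / "params.csv"
        frame.to_csv(path, index=False)
        ps = load_parameter_table(path, settings={"wtp": 20_000.0, "seed": 1})
        assert ps.settings.wtp == 20_000.0 and ps.settings.seed == 1

    def test_yaml_settings_block(self, tmp_path, default_params):
        frame = parameter_frame(default_params)
        params_path = tmp_path / "params.csv"
        frame.to_csv(params_path, index=False)
        settings_path = tmp_path / "settings.yaml"
        settings_path.write_text(
            "wtp: 15000\ndiscount_rate_cost: 0.05\ndiscount_range: [0.02, 0.08]\n"
        )
        ps = load_parameter_table(params_path, settings_path=settings_path)
        assert ps.settings.wtp == 15_000.0
        assert ps.settings.discount_rate_cost == 0.05
        assert ps.settings.discount_range == (0.02, 0.08)
        with pytest.raises(SchemaError, match="unknown settings"):
            bad = tmp_path / "bad.yaml"
            bad.write_text("nonsense_key: 1\n")
            load_parameter_table(params_path, settings_path=bad)

    def test_exit_rowsum_validated(self, tmp_path, default_params):
        frame = parameter_frame(default_params)
        frame.loc[frame.parameter_id == "tp_icd_hosp_to_well", "mean"] = 0.9
        path = tmp_path / "params.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="E_ROWSUM"):
            load_parameter_table(path)


class TestSampling:
    def test_all_fixed_returns_means(self, zero_sd_params):
        rng = np.random.default_rng(0)
        draw = sample_parameters(zero_sd_params, rng)
        base = mean_draw(zero_sd_params)
        assert draw.values == base.values

    def test_reproducible_given_seed(self, default_params):
        d1 = sample_parameters(default_params, np.random.default_rng(42))
        d2 = sample_parameters(default_params, np.random.default_rng(42))
        assert d1.values == d2.values

    def test_marginal_moments_of_hosp_death_pharm(self, default_params):
        spec = default_params.spec("tp_pharm_hosp_to_death")
        rng = np.random.default_rng(3)
        draws = np.array(
            [sample_spec(spec, rng) for _ in range(100_000)]
        )
        assert abs(draws.mean() - 0.284) < 3 * 0.009 / math.sqrt(100_000)
        assert abs(draws.std(ddof=1) - 0.009) < 3 * 0.009 / math.sqrt(2 * 100_000 - 2)

    def test_exit_groups_renormalized(self, default_params):
        for seed in range(50):
            draw = sample_parameters(default_params, np.random.default_rng(seed))
            v = draw.values
            assert v["tp_icd_hosp_to_well"] + v["tp_icd_hosp_to_death"] == pytest.approx(1.0)
            assert (
                v["tp_icd_compl_to_well"]
                + v["tp_icd_compl_to_rejection"]
                + v["tp_icd_compl_to_death"]
            ) == pytest.approx(1.0)
            assert v["tp_pharm_hosp_to_well"] + v["tp_pharm_hosp_to_death"] == pytest.approx(1.0)
            for pid, val in v.items():
                row = default_params.rows[pid]
                if row.category in ("transition", "utility"):
                    assert 0.0 <= val <= 1.0
                else:
                    assert val >= 0.0

    def test_smallest_sibling_held_fixed(self, default_params):
        draw = sample_parameters(default_params, np.random.default_rng(5))
        assert draw.values["tp_icd_compl_to_rejection"] == 0.022

    def test_free_transitions_never_sampled(self, default_params):
        draw = sample_parameters(default_params, np.random.default_rng(9))
        for pid in ("tp_icd_well_to_compl", "tp_pharm_well_to_hosp"):
            assert draw.values[pid] == default_params.mean(pid)

    def test_draw_at_renormalizes_override(self, default_params):
        draw = draw_at(default_params, {"tp_icd_hosp_to_death": 0.3})
        assert draw.values["tp_icd_hosp_to_well"] == pytest.approx(0.7)

    def test_rejection_reuses_hospitalization_rewards(self, default_params):
        draw = mean_draw(default_params)
        assert draw.cost(default_params, Arm.ICD, HealthState.REJECTION) == 2925.0
        assert draw.utility(default_params, Arm.ICD, HealthState.REJECTION) == 0.725
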