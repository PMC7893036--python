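"""AICc, Akaike weights, conditional R², marginal means, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotrack.config import PlantedCoefficients, default_config
from thermotrack.models import (
    ModelSpec,
    aicc,
    akaike_weights,
    build_selection_table,
    conditional_r2,
    fit_candidates,
    fit_mixed,
    marginal_means,
    nakagawa_r2,
    seasonal_contrast,
)
from thermotrack.simulate import simulate_daily_responses

# Published coefficient tables used throughout (reporting scale,
# reference levels drought / gemsbok)
AMPLITUDE = PlantedCoefficients(2.2, -0.08, 1.0, -1.03, "identity")
T_MAX = PlantedCoefficients(39.84, -0.21, 0.03, -0.14, "identity")
LOG_ACTIVITY = PlantedCoefficients(0.89, -0.07, -0.13, 0.52, "log")
HEAT_PROP = PlantedCoefficients(0.13, 0.05, -0.01, -0.05, "response-proportion")
TRAVEL = PlantedCoefficients(0.06, 1.57, 4.68, 0.37, "response-rate")


# ---------------------------------------------------------------------------
# AICc


def test_aicc_closed_form():
    assert aicc(-100.0, k=4, n=50) == pytest.approx(208.0 + 40.0 / 45.0)


def test_aicc_with_zero_parameters_is_minus_twice_loglik():
    assert aicc(-123.4, k=0, n=50) == pytest.approx(246.8)


def test_aicc_approaches_aic_for_large_n():
    aic = -2 * (-100.0) + 2 * 4
    assert aicc(-100.0, k=4, n=10**9) == pytest.approx(aic, abs=1e-6)


def test_aicc_penalty_monotone_in_k():
    vals = [aicc(-100.0, k=k, n=50) for k in range(1, 10)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_aicc_undefined_for_tiny_n():
    with pytest.raises(ValueError, match="undefined"):
        aicc(-100.0, k=4, n=5)


# ---------------------------------------------------------------------------
# Akaike weights


def test_weights_for_two_point_gap():
    t = akaike_weights([100.0, 102.0])
    e = math.exp(-1.0)
    assert t["weight"].tolist() == pytest.approx([1 / (1 + e), e / (1 + e)], abs=1e-9)
    assert t["weight"].tolist() == pytest.approx([0.731, 0.269], abs=5e-4)
    assert t["plausible"].tolist() == [True, False]


def test_single_model_has_weight_one():
    t = akaike_weights([250.0])
    assert t["weight"].iloc[0] == 1.0 and bool(t["plausible"].iloc[0])


def test_tied_models_share_weight():
    t = akaike_weights([100.0, 100.0])
    assert t["weight"].tolist() == pytest.approx([0.5, 0.5])
    assert t["plausible"].all()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    aiccs=st.lists(st.floats(-500, 500), min_size=1, max_size=8),
    shift=st.floats(-100, 100),
)
def test_weights_sum_to_one_and_are_shift_invariant(aiccs, shift):
    t1 = akaike_weights(aiccs)
    t2 = akaike_weights([a + shift for a in aiccs])
    assert t1["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    assert t1["weight"].tolist() == pytest.approx(t2["weight"].tolist(), abs=1e-9)
    assert t1["delta_aicc"].min() == 0.0
    assert t1["plausible"].any()


# ---------------------------------------------------------------------------
# Conditional R²


def test_conditional_r2_direct_substitution():
    assert nakagawa_r2(1.0, 1.0, 2.0) == pytest.approx(0.5)


def test_conditional_r2_limits():
    assert nakagawa_r2(1.0, 1.0, 1e-12) == pytest.approx(1.0, abs=1e-9)
    assert nakagawa_r2(0.0, 0.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        nakagawa_r2(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Fitting on planted data


@pytest.fixture(scope="module")
def amplitude_daily():
    cfg = default_config(rng_seed=90125)
    daily, _ = simulate_daily_responses(cfg, responses=["t_amplitude"])
    return daily


def test_zero_noise_fit_reproduces_planted_coefficients(small_config):
    cfg = small_config.zero_noise()
    daily, _ = simulate_daily_responses(cfg, responses=["t_amplitude"])
    fit = fit_mixed(ModelSpec.for_response("t_amplitude", variance_by_cell=False), daily)
    assert fit.estimates["intercept"] == pytest.approx(2.2, abs=1e-6)
    assert fit.estimates["season"] == pytest.approx(-0.08, abs=1e-6)
    assert fit.estimates["species"] == pytest.approx(1.0, abs=1e-6)
    assert fit.estimates["interaction"] == pytest.approx(-1.03, abs=1e-6)


def test_single_season_data_is_a_specification_error(amplitude_daily):
    drought_only = amplitude_daily[amplitude_daily["season"] == "drought"]
    with pytest.raises(ValueError, match="both seasons"):
        fit_mixed(ModelSpec.for_response("t_amplitude"), drought_only)


def test_selection_table_prefers_global_model_with_interaction(amplitude_daily):
    fits = fit_candidates("t_amplitude", amplitude_daily)
    table = build_selection_table(fits)
    assert table.iloc[0]["model"] == "global"  # the planted interaction is large
    assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
    assert ((table["conditional_r2"] >= 0) & (table["conditional_r2"] <= 1)).all()


def test_conditional_r2_of_fit_in_unit_interval(amplitude_daily):
    fit = fit_mixed(ModelSpec.for_response("t_amplitude"), amplitude_daily)
    assert 0.0 < conditional_r2(fit) < 1.0


# ---------------------------------------------------------------------------
# Marginal means


def test_identity_link_reference_cell_equals_intercept(amplitude_daily):
    fit = fit_mixed(ModelSpec.for_response("t_amplitude"), amplitude_daily)
    mm = marginal_means(fit)
    ref = mm[(mm.species == "gemsbok") & (mm.season == "drought")].iloc[0]
    assert ref["mean"] == pytest.approx(fit.estimates["intercept"], abs=1e-9)


def test_log_link_cell_prediction_is_exponentiated_linear_predictor():
    cfg = default_config(rng_seed=5150, n_gemsbok=3, n_wildebeest=3)
    daily, _ = simulate_daily_responses(cfg, responses=["travel_hours"])
    fit = fit_mixed(ModelSpec.for_response("travel_hours"), daily)
    mm = marginal_means(fit)
    beta = fit.result.beta
    cell = mm[(mm.species == "wildebeest") & (mm.season == "non-drought")].iloc[0]
    assert cell["mean"] == pytest.approx(math.exp(beta.sum()), rel=1e-9)


def test_marginal_means_reject_levels_absent_from_model(amplitude_daily):
    fit = fit_mixed(ModelSpec.for_response("t_amplitude", fixed="season"), amplitude_daily)
    with pytest.raises(ValueError, match="absent"):
        marginal_means(fit, grid=[("wildebeest", "drought")])


def test_proportion_scale_cells_reconstruct_published_percentages():
    # response-proportion tables are additive: gemsbok non-drought cell
    # 0.13 + 0.05 = 0.18 and wildebeest drought cell 0.13 - 0.01 = 0.12
    assert HEAT_PROP.cell_mean("gemsbok", "non-drought") == pytest.approx(0.18)
    assert HEAT_PROP.cell_mean("wildebeest", "drought") == pytest.approx(0.12)


# ---------------------------------------------------------------------------
# Seasonal contrasts


def test_gemsbok_tmax_seasonal_increase_matches_published_value():
    # drought minus non-drought = -beta_season = +0.21 °C (printed 0.2 °C)
    assert seasonal_contrast(T_MAX, "gemsbok") == pytest.approx(0.21)


def test_wildebeest_activity_drop_matches_published_percentage():
    # exp(-(-0.07 + 0.52)) - 1 = -36.2% (printed -36%)
    change = seasonal_contrast(LOG_ACTIVITY, "wildebeest")
    assert change == pytest.approx(math.exp(-0.45) - 1.0, abs=1e-12)
    assert change == pytest.approx(-0.362, abs=5e-4)


def test_all_zero_table_gives_zero_change_on_any_scale():
    for scale in ("identity", "log", "response-proportion"):
        zero = {"intercept": 0.0, "season": 0.0, "species": 0.0, "interaction": 0.0, "scale": scale}
        for sp in ("gemsbok", "wildebeest"):
            assert seasonal_contrast(zero, sp) == 0.0


def test_contrast_antisymmetric_in_direction():
    a = seasonal_contrast(AMPLITUDE, "wildebeest", "drought-minus-non-drought")
    b = seasonal_contrast(AMPLITUDE, "wildebeest", "non-drought-minus-drought")
    assert a == pytest.approx(-b)
    # log scale: the two directions are multiplicative inverses
    f = seasonal_contrast(LOG_ACTIVITY, "wildebeest", "drought-minus-non-drought")
    r = seasonal_contrast(LOG_ACTIVITY, "wildebeest", "non-drought-minus-drought")
    assert (1.0 + f) * (1.0 + r) == pytest.approx(1.0)


def test_rate_scale_contrast_uses_rate_ratios():
    # wildebeest drought-vs-non-drought rate change: 1/(1.57*0.37) - 1
    change = seasonal_contrast(TRAVEL, "wildebeest")
    assert change == pytest.approx(1.0 / (1.57 * 0.37) - 1.0)


def test_unknown_scale_tag_is_rejected():
    with pytest.raises(ValueError):
        seasonal_contrast({"season": 0.1, "interaction": 0.0, "scale": "bogus"}, "gemsbok")
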