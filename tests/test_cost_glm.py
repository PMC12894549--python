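"""Gamma GLM cost model: closed-form identities, recovery, surface prediction."""

import numpy as np
import pandas as pd
import pytest

from miburden import SyntheticCohortConfig, generate_cohort
from miburden.cost_glm import (
    CostModelSpec,
    estimate_group_costs,
    fit_gamma_glm,
    predict_cost_surface,
)
from miburden.errors import DataError, ModelError, ValidationError
from miburden.synthetic import CostMeanSurface


def test_intercept_only_equals_person_year_weighted_mean(cohort_50k):
    model = fit_gamma_glm(cohort_50k, CostModelSpec())
    fitted = model.predict(cohort_50k.head(1))[0]
    wmean = np.average(cohort_50k["annual_cost"], weights=cohort_50k["person_years"])
    assert abs(fitted - wmean) / wmean < 1e-6


def test_single_binary_covariate_reproduces_weighted_group_means(cohort_small):
    model = fit_gamma_glm(cohort_small, CostModelSpec(categorical=("sex",)))
    for sex in ("male", "female"):
        sub = cohort_small[cohort_small["sex"] == sex]
        wmean = np.average(sub["annual_cost"], weights=sub["person_years"])
        est, _, _ = model.marginal_mean(cohort_small, {"sex": sex})
        assert abs(est - wmean) / wmean < 1e-6


def test_fitted_means_invariant_to_link_sign(cohort_small):
    spec = CostModelSpec(categorical=("mi_type",), spline_terms={"age_mid": 3})
    mu_pos = fit_gamma_glm(cohort_small, spec).predict(cohort_small)
    mu_neg = fit_gamma_glm(
        cohort_small, CostModelSpec(categorical=("mi_type",), spline_terms={"age_mid": 3}, link="neg_inverse")
    ).predict(cohort_small)
    np.testing.assert_allclose(mu_pos, mu_neg, rtol=1e-8)


def test_negative_costs_rejected_naming_rows(cohort_small):
    bad = cohort_small.copy()
    bad.loc[bad.index[5], "annual_cost"] = -10.0
    with pytest.raises(DataError, match="5"):
        fit_gamma_glm(bad, CostModelSpec())


def test_zero_cost_policy_shift_and_drop(cohort_small):
    data = cohort_small.copy()
    data.loc[data.index[:10], "annual_cost"] = 0.0
    shifted = fit_gamma_glm(data, CostModelSpec(zero_policy="shift"))
    dropped = fit_gamma_glm(data, CostModelSpec(zero_policy="drop"))
    assert shifted.predict(data.head(1))[0] != dropped.predict(data.head(1))[0]


@pytest.fixture(scope="module")
def estimates(cohort_50k):
    return estimate_group_costs(cohort_50k)


class TestGroupCosts:
    def test_table_structure_mirrors_exposure_set(self, estimates):
        assert list(estimates.columns) == [
            "variable", "level", "n", "person_years",
            "unadjusted", "unadj_lb", "unadj_ub",
            "adjusted", "adj_lb", "adj_ub",
        ]
        by_var = estimates.groupby("variable")["level"].count().to_dict()
        assert by_var["Overall"] == 1
        assert by_var["mi_type"] == 2
        assert by_var["sex"] == 2
        assert by_var["age_group"] == 6
        assert by_var["hypertension"] == 2
        assert by_var["diabetes"] == 2
        assert by_var["irsd_quintile"] == 5
        assert by_var["follow_up_year"] == 6

    def test_intervals_bracket_points(self, estimates):
        assert (estimates["unadj_lb"] <= estimates["unadjusted"]).all()
        assert (estimates["unadjusted"] <= estimates["unadj_ub"]).all()
        assert (estimates["adj_lb"] <= estimates["adjusted"]).all()
        assert (estimates["adjusted"] <= estimates["adj_ub"]).all()
        assert (estimates["n"] > 0).all()
        assert (estimates["person_years"] > 0).all()

    def test_follow_up_decay_recovered(self, estimates):
        fy = estimates[estimates["variable"] == "follow_up_year"].set_index("level")
        ratio = fy.loc[2, "unadjusted"] / fy.loc[1, "unadjusted"]
        # generator decays the mean cost by 0.88 per follow-up year
        rel_se = np.sqrt(
            (fy.loc[1, "unadj_ub"] - fy.loc[1, "unadjusted"]) ** 2 / fy.loc[1, "unadjusted"] ** 2
            + (fy.loc[2, "unadj_ub"] - fy.loc[2, "unadjusted"]) ** 2 / fy.loc[2, "unadjusted"] ** 2
        ) / 1.96
        assert abs(ratio - 0.88) < 3 * rel_se * ratio + 1e-9

    def test_costs_decline_with_follow_up(self, estimates):
        fy = estimates[estimates["variable"] == "follow_up_year"].sort_values("level")
        assert (np.diff(fy["adjusted"]) < 0).all()


def test_degenerate_constant_cost_recovered():
    data = pd.DataFrame(
        {
            "person_id": np.arange(100),
            "age_mid": 62.0,
            "sex": "male",
            "mi_type": "NSTEMI",
            "diabetes": 0,
            "hypertension": 1,
            "irsd_quintile": 3,
            "follow_up_year": 1,
            "annual_cost": 5_000.0,
            "person_years": 1.0,
        }
    )
    model = fit_gamma_glm(data, CostModelSpec())
    assert abs(model.predict(data.head(1))[0] - 5_000.0) < 1e-6


class TestCostSurface:
    def test_flat_generator_gives_flat_surface(self):
        # age- and follow-up-flat generator on a balanced, age-uniform
        # cohort: the fitted surface reproduces the constant.  Individual
        # extrapolated corner cells carry 3-6% prediction SE at this sample
        # size, so the 2% recovery bound applies to the mean absolute cell
        # deviation; the grand mean is tighter.
        from miburden.synthetic import AGE_BANDS

        flat = CostMeanSurface(
            base_mean=12_000.0, age_slope=0.0, follow_up_decay=1.0,
            female_mult=1.0, stemi_mult=1.0, diabetes_mult=1.0,
            hypertension_mult=1.0, irsd_mults=(1.0,) * 5,
        )
        cohort = generate_cohort(
            SyntheticCohortConfig(
                n_people=40_000, seed=17, male_fraction=0.5,
                age_band_probs=tuple([1.0 / len(AGE_BANDS)] * len(AGE_BANDS)),
                cost_mean_surface=flat,
            )
        )
        surface = predict_cost_surface(cohort)
        deviation = np.abs(surface.values - 12_000.0) / 12_000.0
        assert deviation.mean() < 0.02
        assert abs(surface.values.mean() - 12_000.0) / 12_000.0 < 0.01

    def test_grid_complete_and_declining_in_follow_up(self, cohort_50k):
        surface = predict_cost_surface(cohort_50k)
        assert surface.values.shape == (2, 70, 6)
        assert np.all(np.isfinite(surface.values))
        assert np.all(surface.values > 0)
        # generator decay < 1: year 1 exceeds year 6 at every male age
        assert np.all(surface.values[0, :, 0] > surface.values[0, :, 5])

    def test_single_sex_cohort_rejected(self, cohort_small):
        males = cohort_small[cohort_small["sex"] == "male"]
        with pytest.raises(ValidationError, match="both sexes"):
            predict_cost_surface(males)
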