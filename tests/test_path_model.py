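"""Path-model layer: DAG validation, system fitting, comparison, moderation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import growthpaths as gp
from growthpaths.exceptions import CycleError, ValidationError
from growthpaths.model import BF, BMI, BMIZ, BW, OW, RWG
from growthpaths.model import test_moderation as moderation_report


class TestStandardPathways:
    def test_bmiz_structure(self):
        spec = gp.standard_pathways("bmiz_child")
        assert spec.endogenous() == [BW, BF, RWG, BMIZ]
        assert spec.families[BW] == "gaussian"
        assert spec.families[BF] == spec.families[RWG] == "logit"
        assert spec.families[BMIZ] == "gaussian"
        assert len(spec.edges) == 10

    def test_overweight_structure(self):
        spec = gp.standard_pathways("overweight")
        assert spec.families[OW] == "logit"
        assert spec.endogenous() == [BW, BF, RWG, OW]

    def test_education_appended_everywhere(self):
        spec = gp.standard_pathways("bmiz_child", with_education=True)
        for node in spec.endogenous():
            assert "maternal_education" in spec.covariates[node]

    def test_covariate_placement(self):
        spec = gp.standard_pathways("bmiz_child")
        assert "age_infancy" in spec.covariates[RWG]
        assert "age_child" in spec.covariates[BMIZ]
        assert "age_infancy" not in spec.covariates[BW]
        assert "age_child" not in spec.covariates[BF]

    def test_topological_order_unique(self):
        spec = gp.standard_pathways("bmiz_child")
        assert gp.validate_dag(spec) == [BMI, BW, BF, RWG, BMIZ]

    def test_yaml_round_trip(self):
        spec = gp.standard_pathways("overweight", with_education=True)
        again = gp.PathSpec.from_yaml(spec.to_yaml())
        assert again.edges == spec.edges
        assert again.covariates == spec.covariates
        assert again.outcome == spec.outcome


class TestValidateDag:
    def test_cycle_named(self):
        spec = gp.PathSpec(
            families={"a": "exogenous", "b": "gaussian", "c": "gaussian", "d": "gaussian"},
            edges=(("a", "b"), ("b", "c"), ("c", "d"), ("d", "b")),
            exposure="a", outcome="d",
        )
        with pytest.raises(CycleError, match="cycle"):
            gp.validate_dag(spec)

    def test_exposure_with_parents_rejected(self):
        with pytest.raises(ValidationError, match="exposure"):
            gp.PathSpec(families={"a": "exogenous", "b": "gaussian"},
                        edges=(("b", "a"),), exposure="a", outcome="b")

    def test_isolated_node_excluded_from_ordering(self):
        spec = gp.PathSpec(
            families={"a": "exogenous", "b": "gaussian", "lonely": "gaussian"},
            edges=(("a", "b"),), exposure="a", outcome="b",
        )
        assert gp.validate_dag(spec) == ["a", "b"]


class TestFitPathModel:
    def test_null_generator_recovers_zero_edges(self, params):
        data = gp.generate_pooled(params.null_edges(), seed=3)
        for outcome in ("bmiz_child", "overweight"):
            model = gp.GeneralizedPathModel(outcome=outcome).fit(data)
            for parent, child in model.spec_.edges:
                z = model.edge_coef(parent, child) / model.edge_se(parent, child)
                assert abs(z) < 3.9, f"{parent}->{child} not within sampling error of 0"

    def test_fixture_recovery_single_seed(self, fitted_bmiz):
        # strongest binary edge: birth weight -> rapid weight gain, log(0.14)
        coef = fitted_bmiz.edge_coef(BW, RWG)
        assert coef == pytest.approx(np.log(0.14), abs=0.25)

    def test_total_loglik_is_sum_of_equations(self, fitted_bmiz):
        total = sum(eq.loglik for eq in fitted_bmiz.equations_.values())
        assert fitted_bmiz.loglik_ == pytest.approx(total, rel=1e-12)

    def test_row_order_invariance(self, params):
        data = gp.generate_pooled(params, seed=5, scale=0.1)
        frame = data.data
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = gp.GeneralizedPathModel(outcome="bmiz_child").fit(frame)
        b = gp.GeneralizedPathModel(outcome="bmiz_child").fit(shuffled)
        for node in a.equations_:
            pd.testing.assert_series_equal(a.equations_[node].params,
                                           b.equations_[node].params, atol=1e-9, rtol=0)

    def test_single_cohort_drops_dummies_with_notice(self, params):
        data = gp.generate_pooled(params, seed=6, scale=0.2)
        one = data.data[data.data["cohort_id"] == "LIMIT"]
        with pytest.warns(UserWarning, match="cohort indicator|constant column"):
            model = gp.GeneralizedPathModel(outcome="bmiz_child").fit(one)
        for eq in model.equations_.values():
            assert not any(c.startswith("cohort_id[") for c in eq.params.index)

    def test_equationwise_ml_equals_joint_ml(self, rng):
        """Brute-force joint optimization cannot beat equation-wise ML (n=40)."""
        n = 40
        x = rng.normal(size=n)
        m = (rng.random(n) < 1 / (1 + np.exp(-(0.4 + 0.9 * x)))).astype(float)
        y = 0.5 + 0.8 * x + 1.2 * m + rng.normal(size=n)
        frame = pd.DataFrame({"x": x, "m": m, "y": y})
        spec = gp.PathSpec(
            families={"x": "exogenous", "m": "logit", "y": "gaussian"},
            edges=(("x", "m"), ("x", "y"), ("m", "y")),
            exposure="x", outcome="y",
        )
        model = gp.GeneralizedPathModel(spec=spec).fit(frame)

        Xm = np.column_stack([np.ones(n), x])
        Xy = np.column_stack([np.ones(n), x, m])

        def neg_joint(theta):
            bm, by, log_s2 = theta[:2], theta[2:5], theta[5]
            eta = Xm @ bm
            ll_m = m @ eta - np.logaddexp(0, eta).sum()
            resid = y - Xy @ by
            s2 = np.exp(log_s2)
            ll_y = -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * resid @ resid / s2
            return -(ll_m + ll_y)

        theta0 = np.concatenate([
            model.equations_["m"].params.to_numpy(),
            model.equations_["y"].params.to_numpy(),
            [np.log(model.equations_["y"].scale)],
        ])
        best = minimize(neg_joint, theta0, method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert -best.fun <= model.loglik_ + 1e-6
        # and the optimizer cannot improve on the equation-wise optimum
        assert -best.fun == pytest.approx(model.loglik_, abs=1e-6)


class TestCompareModels:
    def test_full_model_preferred_with_strong_edge(self, pooled_full):
        full = gp.standard_pathways("bmiz_child")
        reduced = gp.PathSpec(
            families=dict(full.families),
            edges=tuple(e for e in full.edges if e != (RWG, BMIZ)),
            covariates=dict(full.covariates), outcome=BMIZ, exposure=BMI,
        )
        table = gp.compare_models([full, reduced], pooled_full)
        assert table.loc[0, "aic"] < table.loc[1, "aic"]
        assert table.loc[0, "rank_aic"] == 1
        (stat, df, p) = table.attrs["lrt"][(1, 0)]
        assert df == 1 and stat > 10 and p < 1e-3

    def test_identical_specs_tie(self, pooled_small):
        spec = gp.standard_pathways("bmiz_child")
        table = gp.compare_models([spec, spec], pooled_small)
        assert table["rank_aic"].tolist() == [1, 1]

    def test_non_nested_pair_has_no_lrt(self, pooled_small):
        full = gp.standard_pathways("bmiz_child")
        a = gp.PathSpec(families=dict(full.families),
                        edges=tuple(e for e in full.edges if e != (RWG, BMIZ)),
                        covariates=dict(full.covariates), outcome=BMIZ, exposure=BMI)
        b = gp.PathSpec(families=dict(full.families),
                        edges=tuple(e for e in full.edges if e != (BF, BMIZ)),
                        covariates=dict(full.covariates), outcome=BMIZ, exposure=BMI)
        table = gp.compare_models([a, b], pooled_small)
        assert table.attrs["lrt"] == {}
        assert {"aic", "bic"} <= set(table.columns)

    def test_different_case_sets_rejected(self, params):
        data = gp.generate_pooled(params, seed=9, scale=0.1).data
        with_edu = gp.standard_pathways("bmiz_child", with_education=True)
        without = gp.standard_pathways("bmiz_child")
        data.loc[:20, "maternal_education"] = np.nan
        with pytest.raises(ValidationError, match="complete-case"):
            gp.compare_models([with_edu, without], data)


class TestModeration:
    def test_null_data_verdict(self, pooled_full):
        spec = gp.standard_pathways("bmiz_child")
        report = moderation_report(spec, pooled_full, "sex")
        assert set(report.index) == set(spec.endogenous())
        assert report.attrs["verdict"] == "no moderation"

    def test_strong_interaction_flagged(self, params):
        data = gp.generate_pooled(params, seed=12).data.copy()
        data["bmiz_child"] = data["bmiz_child"] + 1.5 * data["sex"] * data["rwg"]
        spec = gp.standard_pathways("bmiz_child")
        report = moderation_report(spec, data, "sex")
        assert report.attrs["verdict"] == "moderation"
        assert report.loc["bmiz_child", "flagged"]

    def test_moderator_collinear_with_covariate(self, pooled_small):
        frame = pooled_small.data.copy()
        frame["sex_copy"] = frame["sex"]
        spec = gp.standard_pathways("bmiz_child")
        with pytest.raises(ValidationError, match="collinear"):
            moderation_report(spec, frame, "sex_copy")


def test_dot_export_one_label_per_edge(fitted_bmiz):
    dot = fitted_bmiz.to_dot()
    assert dot.count("->") == len(fitted_bmiz.spec_.edges)
    assert 'label="OR=' in dot and 'label="β=' in dot


def test_sklearn_protocol(fitted_bmiz):
    from sklearn.base import clone
    params = fitted_bmiz.get_params()
    assert params["outcome"] == "bmiz_child"
    fresh = clone(gp.GeneralizedPathModel(outcome="overweight"))
    assert fresh.get_params()["outcome"] == "overweight"
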