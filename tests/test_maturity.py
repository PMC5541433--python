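import numpy as np
import pandas as pd
import pytest

from micromat.maturity import (
    AgeModelConfig,
    MaturityCurve,
    compute_immi,
    fit_age_model,
    fit_maturity_curve,
    predict_microbiota_age,
    rank_taxa_by_importance,
    select_feature_count,
)
from micromat.tablesio import AbundanceTable

FAST = dict(n_trees=30, n_importance_iters=2, cv_folds=3, seed=0)


def age_table(rng, n_samples=24, n_noise=4):
    """One taxon tracking age exactly (pre-closure), plus i.i.d. noise taxa."""
    ages = np.tile([1, 7, 14, 21, 28, 35], n_samples // 6)
    rows = {"tracker": ages * 0.01 + 0.05}
    for i in range(n_noise):
        rows[f"noise{i}"] = rng.uniform(0.01, 0.5, size=n_samples)
    df = pd.DataFrame(rows, index=[f"s{j:02d}" for j in range(n_samples)]).T
    return AbundanceTable(df, kind="counts"), ages


class TestConfig:
    def test_defaults(self):
        cfg = AgeModelConfig()
        assert cfg.n_trees == 5000
        assert cfg.n_importance_iters == 100
        assert cfg.cv_folds == 10
        assert cfg.mtry(30) == 10  # floor(p/3)
        assert cfg.mtry(2) == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            AgeModelConfig(n_trees=0)
        with pytest.raises(ValueError):
            AgeModelConfig(mtry_fraction=1.5)
        with pytest.raises(ValueError):
            AgeModelConfig(cv_folds=1)
        with pytest.raises(ValueError):
            AgeModelConfig(importance="magic")


class TestRanking:
    def test_tracker_outranks_noise(self, rng):
        wins = 0
        for seed in range(10):
            table, ages = age_table(np.random.default_rng(seed))
            cfg = AgeModelConfig(**{**FAST, "seed": seed})
            ranked = rank_taxa_by_importance(table, ages, cfg)
            wins += ranked[0][0] == "tracker"
        assert wins >= 9

    def test_sample_order_invariance(self, rng):
        table, ages = age_table(rng)
        cfg = AgeModelConfig(**FAST)
        r1 = rank_taxa_by_importance(table, ages, cfg)
        perm = np.random.default_rng(1).permutation(table.n_samples)
        shuffled = AbundanceTable(table.data.iloc[:, perm], kind=table.kind)
        r2 = rank_taxa_by_importance(shuffled, np.asarray(ages)[perm], cfg)
        assert r1 == r2

    def test_constant_age_rejected(self, rng):
        table, _ = age_table(rng)
        with pytest.raises(ValueError, match="distinct ages"):
            rank_taxa_by_importance(table, [7] * table.n_samples, AgeModelConfig(**FAST))

    def test_too_few_samples_for_folds(self, rng):
        table, ages = age_table(rng)
        small = AbundanceTable(table.data.iloc[:, :4], kind="counts")
        with pytest.raises(ValueError, match="cv_folds"):
            rank_taxa_by_importance(small, ages[:4], AgeModelConfig(n_trees=10, cv_folds=10))


class TestFeatureSelection:
    def test_single_candidate(self, rng):
        table, ages = age_table(rng, n_noise=0)
        cfg = AgeModelConfig(**FAST)
        ranked = rank_taxa_by_importance(table, ages, cfg)
        k, curve = select_feature_count(table, ages, ranked, cfg)
        assert k == 1 and set(curve) == {1}

    def test_k_star_is_minimal_within_tolerance(self, rng):
        table, ages = age_table(rng)
        cfg = AgeModelConfig(**FAST)
        ranked = rank_taxa_by_importance(table, ages, cfg)
        k, curve = select_feature_count(table, ages, ranked, cfg)
        best = min(curve.values())
        assert curve[k] <= (1 + cfg.cv_tolerance) * best
        smaller = [kk for kk in curve if kk < k]
        assert all(curve[kk] > (1 + cfg.cv_tolerance) * best for kk in smaller)


class TestFitAndPredict:
    def test_mtry_and_ntree_wiring(self, rng):
        table, ages = age_table(rng, n_noise=5)  # p = 6
        cfg = AgeModelConfig(n_trees=25, n_importance_iters=1, cv_folds=2, seed=1)
        model = fit_age_model(table, ages, 6, cfg)
        assert model.forest.n_estimators == 25
        assert model.forest.max_features == 2  # floor(6/3)

    def test_constant_target_predicts_exactly(self, rng):
        table, _ = age_table(rng)
        cfg = AgeModelConfig(n_trees=15, n_importance_iters=1, cv_folds=2, seed=1)
        model = fit_age_model(table, [9.0] * table.n_samples, 2, cfg)
        preds = predict_microbiota_age(model, table, use_oob_for_training=False)
        assert np.allclose(preds, 9.0)

    def test_predictions_within_training_range(self, rng):
        table, ages = age_table(rng)
        cfg = AgeModelConfig(**FAST)
        model = fit_age_model(table, ages, 3, cfg)
        preds = predict_microbiota_age(model, table)
        assert preds.min() >= min(ages) and preds.max() <= max(ages)

    def test_duplicate_sample_identical_prediction(self, rng):
        table, ages = age_table(rng)
        cfg = AgeModelConfig(**FAST)
        model = fit_age_model(table, ages, 3, cfg)
        dup = table.data.copy()
        dup["clone"] = dup["s00"]
        preds = predict_microbiota_age(
            model, AbundanceTable(dup, kind="counts"), use_oob_for_training=False
        )
        assert preds["clone"] == preds["s00"]

    def test_missing_taxon_imputed_with_warning(self, rng):
        table, ages = age_table(rng)
        cfg = AgeModelConfig(**FAST)
        model = fit_age_model(table, ages, 3, cfg)
        reduced = AbundanceTable(table.data.iloc[1:], kind="counts")
        with pytest.warns(UserWarning, match="imputed"):
            predict_microbiota_age(model, reduced)

    def test_oob_r2_reported(self, rng):
        table, ages = age_table(rng, n_samples=36)
        cfg = AgeModelConfig(n_trees=100, n_importance_iters=1, cv_folds=3, seed=2)
        model = fit_age_model(table, ages, 1, cfg)
        assert 0.0 <= model.train_r2 <= 1.0
        assert model.train_r2 > 0.5  # tracker taxon is a clean signal


class TestMaturityCurve:
    def test_linear_predictions_analytic_plateau(self):
        ages = np.arange(1.0, 43.0)
        curve = fit_maturity_curve(ages, ages, delta=0.05)
        target = 0.95 * curve.fitted_microbiota_age.max()
        expected = curve.grid_ages[np.argmax(curve.fitted_microbiota_age >= target)]
        assert curve.plateau_age == expected
        assert curve.plateau_age == pytest.approx(40.0, abs=1.0)

    def test_logistic_crossing_oracle(self):
        # asymptote 40, midpoint 15, rate 0.4 -> (1-delta) crossing at
        # t = 15 + ln(0.95 * max / (max*(1-0.95...)))/0.4; computed numerically
        ages = np.arange(1.0, 43.0)
        preds = 40.0 / (1.0 + np.exp(-0.4 * (ages - 15.0)))
        curve = fit_maturity_curve(ages, preds, delta=0.05)
        fmax = preds.max()
        analytic = ages[np.argmax(preds >= 0.95 * fmax)]
        assert abs(curve.plateau_age - analytic) <= 2.0

    def test_plateau_defines_full_maturity(self):
        ages = np.arange(1.0, 43.0)
        preds = np.minimum(ages, 30.0)
        curve = fit_maturity_curve(ages, preds, delta=0.05)
        assert curve.plateau_value == pytest.approx(
            curve.fitted_microbiota_age[int(curve.plateau_age - curve.grid_ages[0])]
        )

    def test_replicated_ages_collapsed(self):
        ages = np.repeat([1, 7, 14, 21, 28], 3)
        preds = ages + np.tile([-0.5, 0.0, 0.5], 5)
        curve = fit_maturity_curve(ages, preds)
        assert curve.grid_ages[0] == 1.0 and curve.grid_ages[-1] == 28.0

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_maturity_curve([1, 1, 7, 7, 14], [1, 2, 3, 4, 5])


class TestImmi:
    def make_curve(self, values, group="g", model_id="m", delta=0.05):
        grid = np.arange(1.0, 1.0 + len(values))
        values = np.asarray(values, dtype=float)
        target = (1 - delta) * values.max()
        i = int(np.argmax(values >= target))
        return MaturityCurve(group, grid, values, float(grid[i]), float(values[i]),
                             delta, model_id)

    def test_self_immi_is_plateau_age(self):
        ctrl = self.make_curve(np.minimum(np.arange(1.0, 43.0), 30.0), "control")
        res = compute_immi(ctrl, ctrl)
        assert res.immi_days == ctrl.plateau_age
        assert not res.censored

    def test_censored_when_never_reached(self):
        ctrl = self.make_curve(np.minimum(np.arange(1.0, 43.0), 30.0), "control")
        low = self.make_curve(np.full(42, 10.0), "slow")
        res = compute_immi(ctrl, low)
        assert res.censored and res.immi_days == 42.0

    def test_model_provenance_enforced(self):
        a = self.make_curve(np.arange(1.0, 10.0), model_id="m1")
        b = self.make_curve(np.arange(1.0, 10.0), model_id="m2")
        with pytest.raises(ValueError, match="different age models"):
            compute_immi(a, b)

    def test_warped_curve_crosses_earlier(self):
        ages = np.arange(1.0, 43.0)
        ctrl = self.make_curve(40 / (1 + np.exp(-0.4 * (ages - 15))), "control")
        fast = self.make_curve(40 / (1 + np.exp(-0.8 * (ages - 7.5))), "fast")
        res_fast = compute_immi(ctrl, fast)
        res_ctrl = compute_immi(ctrl, ctrl)
        assert res_fast.immi_days < res_ctrl.immi_days
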