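"""Classifier, arm comparison, balance and sensitivity analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netrx.evaluate import (
    ClassifierSpec,
    age_stratified_sensitivity,
    compare_arms,
    covariate_balance,
    predict_ideation,
    train_classifier,
)
from netrx.trial import DeactivationConfig, TrialState


def _step_ideation(items, catalog):
    """Deterministic step function of the Distress mean."""
    d = items[catalog.members("DST")].mean(axis=1).to_numpy()
    return np.clip(np.floor((d - 1.0) * 1.2), 0, 5).astype(int)


class TestClassifier:
    def test_separable_construction_learned_accurately(self, catalog, cohort2000):
        items = cohort2000.items.iloc[:1200]
        y = _step_ideation(items, catalog)
        clf = train_classifier(items, y, ClassifierSpec(seed=0, l2=0.05))
        assert clf.test_accuracy >= 0.95

    def test_shuffled_labels_fall_to_majority_rate(self, catalog, cohort313):
        rng = np.random.default_rng(0)
        y = rng.permutation(cohort313.ideation)
        clf = train_classifier(cohort313.items, y, ClassifierSpec(seed=0))
        majority = np.bincount(y).max() / len(y)
        assert abs(clf.test_accuracy - majority) <= 0.10

    def test_single_class_rejected(self, cohort313):
        with pytest.raises(ValueError, match="stratification error"):
            train_classifier(
                cohort313.items, np.zeros(len(cohort313.items), dtype=int)
            )

    def test_deterministic_given_seed(self, cohort313):
        a = train_classifier(cohort313.items, cohort313.ideation, ClassifierSpec(seed=4))
        b = train_classifier(cohort313.items, cohort313.ideation, ClassifierSpec(seed=4))
        assert a.cv_accuracy == b.cv_accuracy
        assert a.test_accuracy == b.test_accuracy

    def test_rare_top_level_does_not_break_training(self, catalog, cohort313):
        y = cohort313.ideation.copy()
        y[:] = np.where(y > 1, 1, y)
        y[0] = 5  # a single member at the top level
        clf = train_classifier(cohort313.items, y, ClassifierSpec(seed=1))
        assert 0.0 <= clf.test_accuracy <= 1.0


class TestPrediction:
    def test_identity_input_reproduces_baseline_predictions(self, catalog, cohort313):
        clf = train_classifier(cohort313.items, cohort313.ideation, ClassifierSpec(seed=2))
        arm = np.repeat("control", len(cohort313.items))
        stratum = np.where(cohort313.sa == 1, "SA+", "SA-")
        p0 = predict_ideation(clf, cohort313.items, arm, stratum, time="T0")
        p1 = predict_ideation(clf, cohort313.items, arm, stratum, time="T1")
        assert np.array_equal(p0.table.predicted, p1.table.predicted)

    def test_out_of_range_profile_rejected(self, cohort313):
        clf = train_classifier(cohort313.items, cohort313.ideation, ClassifierSpec(seed=2))
        bad = cohort313.items.astype(float).copy()
        bad.iloc[0, 0] = 9.0
        with pytest.raises(ValueError, match="1..7"):
            predict_ideation(
                clf, bad, np.repeat("control", len(bad)), np.repeat("SA-", len(bad))
            )

    def test_frequency_tables_normalize(self, catalog, cohort313):
        clf = train_classifier(cohort313.items, cohort313.ideation, ClassifierSpec(seed=2))
        arm = np.where(np.arange(len(cohort313.items)) % 2 == 0, "intervention", "control")
        stratum = np.where(cohort313.sa == 1, "SA+", "SA-")
        pred = predict_ideation(clf, cohort313.items, arm, stratum)
        freq = pred.frequencies()
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-9)

    def test_prediction_invariant_to_row_order(self, cohort313):
        clf = train_classifier(cohort313.items, cohort313.ideation, ClassifierSpec(seed=2))
        arm = np.repeat("control", len(cohort313.items))
        stratum = np.repeat("SA-", len(cohort313.items))
        perm = np.random.default_rng(0).permutation(len(cohort313.items))
        direct = predict_ideation(clf, cohort313.items, arm, stratum).table.predicted
        shuffled = predict_ideation(
            clf, cohort313.items.iloc[perm], arm, stratum
        ).table.predicted
        assert np.array_equal(direct.to_numpy()[perm], shuffled.to_numpy())


class TestCompareArms:
    def test_identical_multisets_give_p_one(self):
        x = np.array([0, 0, 1, 2, 3])
        res = compare_arms(x, x.copy())
        assert res.p_value == 1.0

    def test_complete_separation(self):
        res = compare_arms(np.zeros(50), np.full(50, 3))
        assert res.p_value < 1e-10
        assert res.rank_biserial < 0

    def test_constant_equal_arms_degenerate_case(self):
        res = compare_arms(np.ones(10), np.ones(12))
        assert res.p_value == 1.0
        assert res.u_statistic == pytest.approx(60.0)

    def test_normal_approximation_close_to_exact_enumeration(self):
        """Oracle: exact permutation p by enumerating all C(16, 8)
        splits of the pooled sample."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            pooled = rng.integers(0, 4, 16).astype(float)
            x, y = pooled[:8], pooled[8:]
            res = compare_arms(x, y)

            def u_stat(xs, ys):
                return sum(
                    (a > b) + 0.5 * (a == b) for a in xs for b in ys
                )

            obs = u_stat(x, y)
            mid = 8 * 8 / 2
            count = total = 0
            for combo in itertools.combinations(range(16), 8):
                xs = pooled[list(combo)]
                ys = pooled[[i for i in range(16) if i not in combo]]
                u = u_stat(xs, ys)
                count += abs(u - mid) >= abs(obs - mid) - 1e-12
                total += 1
            exact = count / total
            if np.ptp(pooled) == 0:
                continue
            assert abs(res.p_value - exact) <= 0.005


def _toy_trial(n=120, seed=0):
    rng = np.random.default_rng(seed)
    items = pd.DataFrame(
        rng.integers(1, 8, size=(n, 4)), columns=["G2", "G3", "G4", "G6"]
    )
    arm = np.where(np.arange(n) % 2 == 0, "intervention", "control")
    stratum = np.where(rng.random(n) < 0.4, "SA+", "SA-")
    cov = pd.DataFrame({"AGE": rng.integers(18, 66, n).astype(float),
                        "SEX": rng.integers(0, 2, n).astype(float)})
    return TrialState(
        t0=items, t1=items.copy(), arm=arm, stratum=stratum, covariates=cov,
        config=DeactivationConfig(),
    )


class TestBalanceAndSensitivity:
    def test_identical_arms_have_zero_smd(self):
        trial = _toy_trial()
        trial.covariates["AGE"] = 30.0 + (trial.stratum == "SA+")
        out = covariate_balance(trial, ["AGE"])
        by_stratum = out[out.stratum != "ALL"]
        assert np.allclose(by_stratum.smd, 0.0)

    def test_unit_separation_gives_smd_one(self):
        trial = _toy_trial()
        rng = np.random.default_rng(1)
        noise = rng.standard_normal(len(trial.t0))
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        trial.covariates["AGE"] = noise + (trial.arm == "intervention")
        out = covariate_balance(trial, ["AGE"])
        full = out[(out.stratum == "ALL") & (out.covariate == "AGE")].smd.iloc[0]
        assert full == pytest.approx(1.0, abs=0.1)

    def test_randomization_keeps_smd_small_mostly(self, catalog, cohort313):
        from netrx.trial import stratified_randomize

        ok = 0
        runs = 60
        stratum = np.where(cohort313.sa == 1, "SA+", "SA-")
        cov = pd.DataFrame({"AGE": cohort313.age, "SEX": cohort313.sex.astype(float)})
        for seed in range(runs):
            arm = stratified_randomize(len(cov), stratum, seed=seed)
            trial = TrialState(
                t0=cohort313.items, t1=cohort313.items, arm=arm, stratum=stratum,
                covariates=cov,
            )
            out = covariate_balance(trial, ["AGE"])
            ok += (out[out.stratum != "ALL"].smd.abs() < 0.3).all()
        assert ok >= 0.85 * runs

    def test_age_split_tie_rule_degenerate_case(self):
        trial = _toy_trial()
        trial.covariates["AGE"] = 30.0
        pred = predictions_for(trial)
        out = age_stratified_sensitivity(trial, pred, pred)
        young = out[out.age_half == "younger"]
        old = out[out.age_half == "older"]
        assert (old.n == 0).all()
        assert young.n.sum() == len(trial.t0)

    def test_cell_bookkeeping(self):
        trial = _toy_trial(seed=3)
        pred = predictions_for(trial)
        out = age_stratified_sensitivity(trial, pred, pred)
        assert out.n.sum() == len(trial.t0)
        valid = out.dropna(subset=["p0_t0"])
        assert ((valid.p0_t0 >= 0) & (valid.p0_t0 <= 1)).all()
        # identical predictions at T0/T1 give zero change
        assert np.allclose(valid.p0_change, 0.0)


def predictions_for(trial):
    from netrx.evaluate import PredictedIdeation

    rng = np.random.default_rng(0)
    return PredictedIdeation(
        table=pd.DataFrame(
            {
                "predicted": rng.integers(0, 3, len(trial.t0)),
                "arm": trial.arm,
                "stratum": trial.stratum,
                "time": "T0",
            }
        )
    )
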