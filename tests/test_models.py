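import numpy as np
import pytest

from gaitfatigue.io import ConfigError, ContractError
from gaitfatigue.features import FEATURE_NAMES, FORCE_FEATURES, IMU_FEATURES, WindowSample
from gaitfatigue.models import (
    SOURCES,
    default_model_spec,
    kfold_misclassification,
    losocv_evaluate,
    samples_to_arrays,
    sequential_forward_select,
    single_feature_accuracy,
    tune_hyperparameters,
)
from gaitfatigue.simulate import simulate_feature_cohort


def _two_clusters(n=200, d=12.0, p=2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = np.tile([0, 1], n // 2)
    X[y == 1, 0] += d
    return X, y


def _samples_from_xy(X, y, groups):
    names = [f"f{j}" for j in range(X.shape[1])]
    out = []
    for i in range(X.shape[0]):
        out.append(
            WindowSample(
                participant_id=str(groups[i]),
                state_label="fatigue" if y[i] else "non_fatigue",
                window_start_s=float(i),
                n_cycles=5,
                features=dict(zip(names, X[i])),
            )
        )
    return out, names


class TestKfoldMisclassification:
    def test_separable_clusters_reach_zero(self):
        X, y = _two_clusters()
        for family in ("NB", "KNN", "DT", "SVM"):
            assert kfold_misclassification(X, y, default_model_spec(family)) == 0.0

    def test_randomized_labels_near_half(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 4))
        y = rng.permutation(np.repeat([0, 1], 200))
        rate = kfold_misclassification(X, y, default_model_spec("NB"), seed=7)
        # binomial(400, 1/2) 99% interval around 0.5
        assert abs(rate - 0.5) < 0.065

    def test_rate_complements_pooled_accuracy(self):
        X, y = _two_clusters(n=120, d=1.0, seed=3)
        from sklearn.model_selection import StratifiedKFold
        from gaitfatigue.models import build_estimator

        spec = default_model_spec("NB")
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        correct = 0
        for tr, te in skf.split(X, y):
            est = build_estimator(spec)
            est.fit(X[tr], y[tr])
            correct += int(np.sum(est.predict(X[te]) == y[te]))
        rate = kfold_misclassification(X, y, spec, k=5, seed=0)
        assert rate == pytest.approx(1.0 - correct / len(y))

    def test_class_thinner_than_k_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ContractError):
            kfold_misclassification(X, y, default_model_spec("NB"), k=5)


def _brute_force_best_single(X, y, model, k=5, seed=0):
    rates = [
        kfold_misclassification(X[:, [j]], y, model, k=k, seed=seed)
        for j in range(X.shape[1])
    ]
    return int(np.argmin(rates))  # argmin takes the first minimum, as SFS must


class TestSequentialForwardSelect:
    def test_only_informative_feature_selected_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 6))
        y = np.repeat([0, 1], 100)
        X[y == 1, 3] += 6.0
        trace = sequential_forward_select(X, y, default_model_spec("NB"))
        assert trace.selected[0] == "f3"
        assert trace.step_rates[0] < 0.05

    def test_pure_noise_stops_early_near_chance(self):
        # chance fluctuations of the CV rate can admit a couple of noise
        # features, but selection must stop quickly and stay near chance
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 8))
        y = np.repeat([0, 1], 150)
        trace = sequential_forward_select(X, y, default_model_spec("NB"), seed=5)
        assert trace.stopped_at <= 3
        assert trace.final_rate >= trace.baseline_rate - 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_first_step_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(150, 7))
        y = np.repeat([0, 1], 75)
        X[y == 1] += rng.uniform(0, 1.0, 7)
        spec = default_model_spec("NB")
        trace = sequential_forward_select(X, y, spec, seed=seed)
        j = _brute_force_best_single(X, y, spec, seed=seed)
        if trace.selected:
            assert trace.selected[0] == f"f{j}"

    def test_full_greedy_path_reproducible_by_bruteforce(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(160, 6))
        y = np.repeat([0, 1], 80)
        X[y == 1, 1] += 1.5
        X[y == 1, 4] += 1.2
        spec = default_model_spec("NB")
        trace = sequential_forward_select(X, y, spec, seed=2)
        # replay greedy with an independent loop
        chosen: list[int] = []
        current = 0.5
        while True:
            rates = {
                j: kfold_misclassification(X[:, chosen + [j]], y, spec, seed=2)
                for j in range(6)
                if j not in chosen
            }
            j_best = min(rates, key=lambda j: (rates[j], j))
            if not rates[j_best] < current:
                break
            chosen.append(j_best)
            current = rates[j_best]
        assert trace.selected == [f"f{j}" for j in chosen]

    def test_rates_strictly_decrease_along_trace(self):
        samples = simulate_feature_cohort(
            n_participants=6, windows_per_state=50, seed=8
        )
        X, y, _ = samples_to_arrays(samples)
        trace = sequential_forward_select(
            X, y, default_model_spec("NB"), feature_names=list(FEATURE_NAMES)
        )
        rates = [trace.baseline_rate] + trace.step_rates
        assert all(b < a for a, b in zip(rates, rates[1:]))


class TestTuneHyperparameters:
    def test_budget_one_returns_default(self):
        X, y = _two_clusters(n=100)
        spec = tune_hyperparameters(X, y, "SVM", budget=1)
        assert spec == default_model_spec("SVM")

    def test_separable_svm_reaches_zero(self):
        X, y = _two_clusters(n=100)
        spec = tune_hyperparameters(X, y, "SVM", budget=4, seed=1)
        assert kfold_misclassification(X, y, spec) == 0.0

    def test_incumbent_never_worse_than_default(self):
        X, y = _two_clusters(n=150, d=1.0, seed=9)
        for family in ("NB", "KNN", "DT", "SVM"):
            tuned = tune_hyperparameters(X, y, family, budget=8, seed=3)
            r_tuned = kfold_misclassification(X, y, tuned, seed=3)
            r_default = kfold_misclassification(
                X, y, default_model_spec(family), seed=3
            )
            assert r_tuned <= r_default

    def test_zero_budget_rejected(self):
        with pytest.raises(ConfigError):
            tune_hyperparameters(np.zeros((10, 1)), np.zeros(10), "NB", budget=0)


class TestLosocv:
    def test_two_separable_participants_are_perfect(self):
        X, y = _two_clusters(n=80, d=12.0)
        groups = np.array(["A"] * 40 + ["B"] * 40)
        samples, names = _samples_from_xy(X, y, groups)
        res = losocv_evaluate(samples, names, default_model_spec("SVM"))
        assert res.accuracy == 1.0
        assert res.per_participant_accuracy == {"A": 1.0, "B": 1.0}

    def test_fold_count_equals_participant_count(self):
        samples = simulate_feature_cohort(
            n_participants=18, windows_per_state=5, seed=1
        )
        res = losocv_evaluate(
            samples, list(FEATURE_NAMES[:3]), default_model_spec("NB")
        )
        assert len(res.per_participant_accuracy) == 18

    def test_pooled_accuracy_is_sample_weighted_mean(self):
        samples = simulate_feature_cohort(n_participants=5, windows_per_state=8, seed=2)
        res = losocv_evaluate(samples, ["Imp_MA"], default_model_spec("NB"))
        per = res.per_participant_accuracy
        weighted = np.mean([per[s.participant_id] for s in samples])
        assert res.accuracy == pytest.approx(weighted)

    def test_single_participant_rejected(self):
        samples = simulate_feature_cohort(n_participants=2, windows_per_state=4, seed=0)
        solo = [s for s in samples if s.participant_id == "P01"]
        with pytest.raises(ContractError):
            losocv_evaluate(solo, ["Imp_MA"], default_model_spec("NB"))

    def test_standardization_fits_on_training_folds_only(self):
        # leakage tripwire: per-fold scaler means must differ from the
        # whole-dataset mean whenever the fold excludes distinctive samples
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = np.tile([0, 1], 30)
        groups = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        X[groups == "C"] += 5.0
        samples, names = _samples_from_xy(X, y, groups)
        res = losocv_evaluate(samples, names, default_model_spec("SVM"))
        global_mean = X.mean(axis=0)
        for pid, mean in res.fold_scaler_means.items():
            assert not np.allclose(mean, global_mean, atol=1e-3)


class TestSingleFeatureAndSources:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # NB on zero variance
    def test_constant_feature_gives_majority_share(self):
        samples = simulate_feature_cohort(n_participants=4, windows_per_state=10, seed=6)
        for s in samples:
            s.features["CT_H"] = 1.0
        acc = single_feature_accuracy(samples, "CT_H", default_model_spec("NB"))
        assert acc == pytest.approx(0.5)  # balanced classes

    def test_strongly_shifted_feature_is_informative(self):
        samples = simulate_feature_cohort(
            n_participants=6, windows_per_state=40, effect_d=3.0, seed=9
        )
        acc = single_feature_accuracy(samples, "Imp_MA", default_model_spec("NB"))
        assert acc > 0.8

    def test_noise_feature_near_chance(self):
        samples = simulate_feature_cohort(
            n_participants=6, windows_per_state=100, between_sd=0.0, seed=12
        )
        acc = single_feature_accuracy(samples, "CT_Hx", default_model_spec("NB"))
        assert abs(acc - 0.5) < 0.06

    def test_unknown_feature_rejected(self):
        samples = simulate_feature_cohort(n_participants=2, windows_per_state=4, seed=0)
        with pytest.raises(KeyError):
            single_feature_accuracy(samples, "nope", default_model_spec("NB"))

    def test_source_partition_is_28_and_21(self):
        assert len(SOURCES["force_only"]) == 28
        assert len(SOURCES["imu_only"]) == 21
        assert set(SOURCES["dual"]) == set(FORCE_FEATURES) | set(IMU_FEATURES)
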