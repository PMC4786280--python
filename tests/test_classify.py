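import numpy as np
import pandas as pd
import pytest

from sliscreen.classify import (
    evaluate_loocv,
    evaluate_voting_loocv,
    fit_hm_limits,
    hm_classify,
    spearman_select,
    vote_classify,
)
from sliscreen.som import som_classify, som_train


def _gaussian_clouds(n_per_arm=100, sep=6.0, dim=5, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n_per_arm, dim))
    X1 = rng.standard_normal((n_per_arm, dim))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    y = np.array(["control"] * n_per_arm + ["case"] * n_per_arm)
    return X, y


class TestHM:
    def test_inside_one_box(self):
        limits = fit_hm_limits(
            np.array([[0.0], [1.0], [10.0], [11.0]]),
            ["control", "control", "case", "case"],
        )
        assert hm_classify(np.array([0.5]), limits) == ("control", False)
        assert hm_classify(np.array([10.5]), limits) == ("case", False)

    def test_inside_both_boxes_flagged(self):
        limits = fit_hm_limits(
            np.array([[0.0], [10.0], [5.0], [15.0]]),
            ["control", "control", "case", "case"],
        )
        group, flagged = hm_classify(np.array([7.0]), limits)
        assert flagged
        # 7 is 2 inside the case box [5,15] but 3 inside control [0,10]
        assert group == "control"

    def test_outside_both_nearest_box(self):
        limits = fit_hm_limits(
            np.array([[0.0], [1.0], [10.0], [11.0]]),
            ["control", "control", "case", "case"],
        )
        group, flagged = hm_classify(np.array([8.5]), limits)
        assert (group, flagged) == ("case", True)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="case"):
            fit_hm_limits(np.array([[0.0], [1.0]]), ["control", "control"])


class TestSOM:
    def test_separated_clouds_high_accuracy_any_init(self):
        X, y = _gaussian_clouds(seed=1)
        X_test, y_test = _gaussian_clouds(n_per_arm=50, seed=2)
        for scheme in ("random", "minmax", "mean"):
            model = som_train(X, y, init_scheme=scheme, seed=3, epochs=60)
            pred = [som_classify(x, model) for x in X_test]
            acc = np.mean(np.asarray(pred) == y_test)
            assert acc >= 0.95, scheme

    def test_deterministic_codebooks(self):
        X, y = _gaussian_clouds(n_per_arm=30, seed=4)
        a = som_train(X, y, seed=7, epochs=20)
        b = som_train(X, y, seed=7, epochs=20)
        assert np.array_equal(a.codebook, b.codebook)
        assert list(a.unit_labels) == list(b.unit_labels)

    def test_codebook_vector_maps_to_its_unit_label(self):
        X, y = _gaussian_clouds(n_per_arm=30, seed=5)
        model = som_train(X, y, seed=1, epochs=20)
        for u in (0, 17, 63):
            raw = model.codebook[u] * model.feature_std + model.feature_mean
            assert som_classify(raw, model) == model.unit_labels[u]

    def test_both_groups_labeled_on_two_group_data(self):
        X, y = _gaussian_clouds(n_per_arm=50, seed=6)
        model = som_train(X, y, seed=2, epochs=40)
        assert set(model.unit_labels) == {"control", "case"}

    def test_single_group_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError, match="both groups"):
            som_train(X, ["control"] * 20)

    def test_dimension_mismatch_rejected(self):
        X, y = _gaussian_clouds(n_per_arm=20, seed=8)
        model = som_train(X, y, seed=1, epochs=10)
        with pytest.raises(ValueError, match="shape"):
            som_classify(np.zeros(3), model)

    def test_mean_init_no_worse_than_random_at_tiny_budget(self):
        """With a single training epoch on moderately separated clouds,
        codebooks seeded at the group means classify at least as well (on
        average over seeds) as randomly initialized ones."""
        X_test, y_test = _gaussian_clouds(n_per_arm=50, sep=3.0, seed=99)

        def mean_acc(scheme):
            accs = []
            for seed in range(10):
                X, y = _gaussian_clouds(n_per_arm=100, sep=3.0, seed=seed)
                m = som_train(X, y, init_scheme=scheme, seed=seed, epochs=1)
                pred = np.asarray([som_classify(x, m) for x in X_test])
                accs.append(np.mean(pred == y_test))
            return float(np.mean(accs))

        assert mean_acc("mean") >= mean_acc("random") - 0.02


class TestSpearmanSelect:
    def _frame(self, X):
        return pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(X.shape[1])])

    def test_label_equal_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        y = np.array(["control"] * 10 + ["case"] * 10)
        X = rng.standard_normal((20, 5))
        X[:, 3] = (y == "case").astype(float)
        names, rho = spearman_select(self._frame(X), y, k=2)
        assert names[0] == "f003"
        assert rho["f003"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = np.array(["control"] * 15 + ["case"] * 15)
        x = rng.standard_normal(30) + 2 * (y == "case")
        X1 = self._frame(x[:, None])
        X2 = self._frame(np.exp(x)[:, None])
        _, rho1 = spearman_select(X1, y, k=1)
        _, rho2 = spearman_select(X2, y, k=1)
        assert rho1.iloc[0] == pytest.approx(rho2.iloc[0])

    def test_constant_feature_rho_zero(self):
        y = np.array(["control"] * 5 + ["case"] * 5)
        X = np.ones((10, 2))
        X[:, 1] = (y == "case").astype(float)
        names, rho = spearman_select(self._frame(X), y, k=1)
        assert rho["f000"] == 0.0
        assert names == ["f001"]

    def test_noise_not_selected_over_signal(self):
        rng = np.random.default_rng(2)
        n = 200
        y = np.array(["control"] * 100 + ["case"] * 100)
        X = rng.standard_normal((n, 20))
        X[:, :5] += 3 * (y == "case")[:, None]
        names, rho = spearman_select(self._frame(X), y, k=5)
        assert set(names) == {f"f{i:03d}" for i in range(5)}
        assert all(abs(rho[f"f{i:03d}"]) < 0.2 for i in range(6, 20))


class TestVoting:
    def _setup(self):
        ref = pd.DataFrame(
            {"a": [0.0, 10.0], "b": [0.0, 10.0]}, index=["control", "case"]
        )
        return {"w": ["a", "b"]}, {"w": ref}

    def test_speaker_at_control_median_unanimous(self):
        selected, refs = self._setup()
        pred, tally = vote_classify({"w": pd.Series({"a": 0.0, "b": 0.0})}, selected, refs)
        assert pred == "control"
        assert tally == {"control": 2, "case": 0}

    def test_argmax_tally(self):
        selected = {"w": [f"x{i}" for i in range(60)]}
        refs = {"w": pd.DataFrame(
            {f"x{i}": [0.0, 10.0] for i in range(60)}, index=["control", "case"]
        )}
        values = pd.Series({f"x{i}": (10.0 if i < 40 else 0.0) for i in range(60)})
        pred, tally = vote_classify({"w": values}, selected, refs)
        assert pred == "case"
        assert tally == {"case": 40, "control": 20}

    def test_no_selection_rejected(self):
        with pytest.raises(ValueError, match="no selected"):
            vote_classify({}, {}, {})

    def test_vote_conservation(self):
        rng = np.random.default_rng(3)
        y = np.array(["control"] * 10 + ["case"] * 10)
        words = {}
        for w in range(3):
            X = rng.standard_normal((20, 40))
            X[y == "case", :5] += 2
            words[f"w{w}"] = pd.DataFrame(
                X, index=[f"s{i}" for i in range(20)],
                columns=[f"f{i:03d}" for i in range(40)],
            )
        res = evaluate_voting_loocv(words, y, k=7)
        for tally in res.votes:
            assert sum(tally.values()) == 7 * 3


class TestLOOCV:
    def test_perfectly_separable_is_100pct(self):
        X, y = _gaussian_clouds(n_per_arm=10, sep=20.0, dim=3, seed=9)
        for method in ("HM", "ANN-mean"):
            res = evaluate_loocv(X, y, method, seed=0, epochs=30)
            assert res.success_rate == 100.0

    def test_label_permutation_equivariance(self):
        X, y = _gaussian_clouds(n_per_arm=8, sep=20.0, dim=3, seed=10)
        res = evaluate_loocv(X, y, "HM")
        y_swapped = np.where(y == "case", "control", "case")
        res_swapped = evaluate_loocv(X, y_swapped, "HM")
        swap = {"case": "control", "control": "case"}
        assert res_swapped.predicted == [swap[p] for p in res.predicted]

    def test_degenerate_cohort_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="degenerate"):
            evaluate_loocv(X, ["control", "control", "case"], "HM")

    def test_resubstitution_mode(self):
        X, y = _gaussian_clouds(n_per_arm=10, sep=20.0, dim=3, seed=13)
        res = evaluate_loocv(X, y, "HM", resubstitution=True)
        assert res.success_rate == 100.0

    def test_voting_loocv_with_informative_features(self):
        rng = np.random.default_rng(14)
        n = 20
        y = np.array(["control"] * 10 + ["case"] * 10)
        words = {}
        for w in range(2):
            X = rng.standard_normal((n, 100))
            X[y == "case", :10] += 2.0
            words[f"w{w}"] = pd.DataFrame(
                X, index=[f"s{i}" for i in range(n)],
                columns=[f"f{i:03d}" for i in range(100)],
            )
        res = evaluate_voting_loocv(words, y, k=10)
        assert res.success_rate >= 90.0
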