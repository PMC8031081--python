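"""Group mean/covariance fits, Mahalanobis profiles, nearest-mean, evaluation."""

import warnings

import numpy as np
import pytest
from scipy import stats

import cdpa
from cdpa import (
    Assignment,
    evaluate,
    fit_group_model,
    fit_group_models,
    mahalanobis_profile,
    nearest_mean_classify,
)
from cdpa.core import CDPAVector
from cdpa.exceptions import SingularModelError, SmallGroupWarning
from cdpa.group_models import DistanceProfile, load_models, save_models


def _vecs(X):
    return [CDPAVector(v=row, site_id=f"v{i}") for i, row in enumerate(X)]


class TestFitGroupModel:
    def test_identical_members_flagged_singular(self):
        X = np.tile(np.arange(6.0), (5, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallGroupWarning)
            m = fit_group_model(_vecs(X), "G")
        assert m.singular
        np.testing.assert_allclose(m.mean, X[0])
        np.testing.assert_allclose(m.covariance, 0, atol=1e-12)

    def test_matches_brute_force_summation(self, rng):
        X = rng.normal(size=(20, 6))
        m = fit_group_model(_vecs(X), "G", ridge=None)
        mean = X.sum(axis=0) / 20
        cov = sum(np.outer(x - mean, x - mean) for x in X) / 19
        np.testing.assert_allclose(m.mean, mean, atol=1e-12)
        np.testing.assert_allclose(m.covariance, cov, atol=1e-12)

    def test_two_member_group_rank_one_singular(self, rng):
        X = rng.normal(size=(2, 6))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallGroupWarning)
            m = fit_group_model(_vecs(X), "G")
        assert m.singular
        assert np.linalg.matrix_rank(m.covariance) <= 1

    def test_singular_without_ridge_raises_on_use(self, rng):
        X = np.tile(rng.normal(size=6), (4, 1))
        m = fit_group_model(_vecs(X), "tiny", ridge=None)
        with pytest.raises(SingularModelError, match="tiny"):
            m.mahalanobis(rng.normal(size=6))

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            fit_group_model(_vecs(np.ones((1, 6))), "G")


class TestMahalanobisProfile:
    def test_zero_at_group_mean(self, rng):
        X = rng.normal(size=(30, 6))
        m = fit_group_model(_vecs(X), "G")
        assert m.mahalanobis(m.mean) == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_is_squared_euclidean(self, rng):
        m = cdpa.GroupModel("G", mean=np.zeros(6), covariance=np.eye(6), n_members=10)
        v = rng.normal(size=6)
        assert m.mahalanobis(v) == pytest.approx(v @ v, rel=1e-12)

    def test_matches_inverse_based_oracle(self, rng):
        A = rng.normal(size=(6, 6))
        cov = A @ A.T + 0.5 * np.eye(6)
        mean = rng.normal(size=6)
        m = cdpa.GroupModel("G", mean=mean, covariance=cov, n_members=50)
        v = rng.normal(size=6)
        dev = v - mean
        oracle = dev @ np.linalg.inv(cov) @ dev
        assert m.mahalanobis(v) == pytest.approx(oracle, rel=1e-10)

    def test_profile_keys_match_model_set(self, rng):
        X = rng.normal(size=(40, 6))
        labels = ["A"] * 20 + ["B"] * 20
        models = fit_group_models(_vecs(X), labels)
        prof = mahalanobis_profile(CDPAVector(v=rng.normal(size=6)), models)
        assert set(prof.distances) == {"A", "B"}
        assert all(np.isfinite(d) and d >= 0 for d in prof.distances.values())

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(60, 6))
        labels = ["A"] * 30 + ["B"] * 30
        models = fit_group_models(_vecs(X), labels, ridge=None)
        T = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        b = rng.normal(size=6)
        Xt = X @ T.T + b
        models_t = fit_group_models(_vecs(Xt), labels, ridge=None)
        for i in range(10):
            d0 = mahalanobis_profile(CDPAVector(v=X[i]), models).distances
            d1 = mahalanobis_profile(CDPAVector(v=Xt[i]), models_t).distances
            for k in d0:
                assert d1[k] == pytest.approx(d0[k], abs=1e-8)


class TestNearestMean:
    def test_unique_minimum(self):
        prof = DistanceProfile("s", {"A": 0.1, "B": 5.0})
        assert nearest_mean_classify(prof) == Assignment("A", tie=False)

    def test_exact_tie_canonical_order_flagged(self):
        prof = DistanceProfile("s", {"PO4": 1.0, "ATP": 1.0})
        out = nearest_mean_classify(prof)
        assert out.label == "ATP" and out.tie

    def test_default_preset_training_error_at_most_5pct(self, default_dataset, fitted_default):
        _, _, profiles = fitted_default
        preds = [nearest_mean_classify(p).label for p in profiles]
        err = np.mean([t != p for t, p in zip(default_dataset.labels, preds)])
        assert err <= 0.05


class TestEvaluate:
    def test_perfect_predictions(self):
        cm = evaluate(["A", "B", "B"], ["A", "B", "B"])
        assert cm.error_rate == 0.0
        assert np.trace(cm.counts) == 3

    def test_all_one_class_over_balanced(self):
        truth = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        cm = evaluate(truth, ["A"] * 15)
        assert cm.error_rate == pytest.approx(2 / 3)

    def test_counts_match_tally_oracle(self, rng):
        labs = ["AMP", "HEM", "PO4"]
        truth = [labs[i] for i in rng.integers(0, 3, 200)]
        pred = [labs[i] for i in rng.integers(0, 3, 200)]
        cm = evaluate(truth, pred)
        for i, ti in enumerate(cm.labels):
            for j, pj in enumerate(cm.labels):
                assert cm.counts[i, j] == sum(
                    1 for t, p in zip(truth, pred) if t == ti and p == pj
                )
        assert cm.counts.sum(axis=1).tolist() == [truth.count(l) for l in cm.labels]

    def test_merge_map_applied_both_sides(self):
        cm = evaluate(
            ["HEM-I", "HEM-II", "PO4"],
            ["HEM-II", "HEM-I", "HEM-I"],
            merge_map={"HEM-I": "HEM", "HEM-II": "HEM"},
        )
        assert cm.error_rate == pytest.approx(1 / 3)


class TestSeparationProperties:
    def test_own_group_distances_stochastically_smaller(self, default_dataset, fitted_default):
        """Own-group Mahalanobis distances sit below other groups' distances
        to that mean (one-sided Mann-Whitney at alpha=0.01 for every group)."""
        _, _, profiles = fitted_default
        labels = default_dataset.labels
        for g in set(labels):
            own = [p.distances[g] for p, l in zip(profiles, labels) if l == g]
            other = [p.distances[g] for p, l in zip(profiles, labels) if l != g]
            res = stats.mannwhitneyu(own, other, alternative="less")
            assert res.pvalue < 0.01, g

    def test_null_preset_error_near_chance_over_50_seeds(self):
        """Identical templates: held-out nearest-mean error averages within
        5 points of (J-1)/J — the classifier finds no signal to exploit."""
        errs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallGroupWarning)
            for seed in range(50):
                train = cdpa.make_preset_dataset("null", seed=seed)
                test = cdpa.make_preset_dataset("null", seed=seed + 1000)
                models = fit_group_models(cdpa.encode_sites(train.sites), train.labels)
                preds = [
                    nearest_mean_classify(mahalanobis_profile(v, models)).label
                    for v in cdpa.encode_sites(test.sites)
                ]
                errs.append(np.mean([t != p for t, p in zip(test.labels, preds)]))
        assert abs(np.mean(errs) - 8 / 9) <= 0.05


class TestModelStore:
    def test_save_load_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(40, 6))
        labels = ["A"] * 20 + ["B"] * 20
        models = fit_group_models(_vecs(X), labels)
        path = tmp_path / "models.json"
        save_models(models, path)
        back = load_models(path)
        for k in models:
            np.testing.assert_allclose(back[k].mean, models[k].mean)
            np.testing.assert_allclose(back[k].covariance, models[k].covariance)
            assert back[k].n_members == models[k].n_members
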