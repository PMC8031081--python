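"""Noise perturbation, outlier flagging, subgroup splitting, classical MDS."""

import warnings

import numpy as np
import pytest
from scipy import stats

import cdpa
from cdpa import (
    NoiseConfig,
    classical_mds,
    flag_outliers,
    perturb_site,
    run_noise_validation,
    split_subgroups,
)
from cdpa.core import CDPAVector
from cdpa.group_models import fit_group_models
from conftest import random_site


class TestPerturbSite:
    def test_zero_tau_bit_identical(self, rng):
        site = random_site(rng)
        out = perturb_site(site, 0.0, rng)
        np.testing.assert_array_equal(out.coords, site.coords)

    def test_fixed_seed_deterministic(self, rng):
        site = random_site(rng)
        a = perturb_site(site, 0.5, np.random.default_rng(7))
        b = perturb_site(site, 0.5, np.random.default_rng(7))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_noise_sd_matches_tau(self):
        site = cdpa.BindingSite("big", np.zeros((10_000, 3)) + 5.0, "X")
        out = perturb_site(site, 0.5, np.random.default_rng(3))
        noise = out.coords - site.coords
        assert 0.49 <= noise.std() <= 0.51

    def test_variance_interpretation_flag(self):
        site = cdpa.BindingSite("big", np.zeros((10_000, 3)), "X")
        out = perturb_site(site, 0.25, np.random.default_rng(3), tau_is_variance=True)
        assert 0.49 <= (out.coords - site.coords).std() <= 0.51

    def test_negative_tau_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_site(random_site(rng), -0.1, rng)


@pytest.fixture(scope="module")
def small_noise_setup():
    ds = cdpa.make_preset_dataset("default", seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vecs = cdpa.encode_sites(ds.sites)
        models = fit_group_models(vecs, ds.labels)
    return ds, vecs, models


class TestNoiseValidation:
    def test_tiny_noise_matches_training_error(self, small_noise_setup):
        ds, vecs, models = small_noise_setup
        preds = [
            cdpa.nearest_mean_classify(cdpa.mahalanobis_profile(v, models)).label
            for v in vecs
        ]
        train_err = np.mean([t != p for t, p in zip(ds.labels, preds)])
        config = NoiseConfig(tau_grid=(0.001,), replications=5, seed=0)
        exp = run_noise_validation(ds.sites, models, config)
        assert abs(exp.mean_curve[0] - train_err) <= 0.02

    def test_error_curve_degrades_with_tau(self, small_noise_setup):
        ds, _, models = small_noise_setup
        config = NoiseConfig(
            tau_grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
            replications=5,
            seed=11,
        )
        exp = run_noise_validation(ds.sites, models, config)
        rho = stats.spearmanr(config.tau_grid, exp.mean_curve)
        assert rho.statistic > 0 and rho.pvalue < 0.05
        assert np.all(exp.errors >= 0) and np.all(exp.errors <= 1)
        assert np.all(exp.band_low <= exp.mean_curve + 1e-12)
        assert np.all(exp.mean_curve <= exp.band_high + 1e-12)

    def test_single_replication_bands_collapse(self, small_noise_setup):
        ds, _, models = small_noise_setup
        config = NoiseConfig(tau_grid=(0.2, 0.5), replications=1, seed=0)
        exp = run_noise_validation(ds.sites, models, config)
        np.testing.assert_array_equal(exp.band_low, exp.mean_curve)
        np.testing.assert_array_equal(exp.band_high, exp.mean_curve)

    def test_identical_seed_bit_reproducible(self, small_noise_setup):
        ds, _, models = small_noise_setup
        config = NoiseConfig(tau_grid=(0.3,), replications=3, seed=42)
        a = run_noise_validation(ds.sites, models, config)
        b = run_noise_validation(ds.sites, models, config)
        np.testing.assert_array_equal(a.errors, b.errors)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(tau_grid=(0.5, 0.2))
        with pytest.raises(ValueError):
            NoiseConfig(tau_grid=(0.0, 0.5))
        with pytest.raises(ValueError):
            NoiseConfig(tau_grid=(0.5,), replications=0)


class TestFlagOutliers:
    def test_gross_outlier_flagged(self, rng):
        X = rng.normal(0, 1.0, size=(40, 6))
        spread = X.std()
        X[7] = X[7] + 50 * spread
        vecs = [CDPAVector(v=row, site_id=f"s{i}") for i, row in enumerate(X)]
        report = flag_outliers({"G": vecs}, alpha=0.001)
        assert report.flagged["G"] == ["s7"]

    def test_clean_gaussian_rarely_flagged(self, rng):
        X = rng.multivariate_normal(np.zeros(6), np.diag([4, 3, 2, 1, 1, 0.5]), 500)
        vecs = [CDPAVector(v=row, site_id=f"s{i}") for i, row in enumerate(X)]
        report = flag_outliers({"G": vecs}, alpha=0.001)
        assert len(report.flagged["G"]) <= 3  # expectation is 0.5

    def test_no_flags_leaves_model_unchanged(self, rng):
        X = rng.normal(size=(100, 6)) * 0.01 + np.arange(6)
        vecs = [CDPAVector(v=row, site_id=f"s{i}") for i, row in enumerate(X)]
        report = flag_outliers({"G": vecs}, alpha=1e-12)
        assert report.flagged["G"] == []

    def test_cap_on_removed_fraction(self, rng):
        # a sixth of the group scattered far out (clustered contamination
        # would mask itself in the fitted covariance): the tail rule wants
        # them all, but removing >10% requires an explicit override
        inliers = rng.normal(0, 1, (40, 6))
        u = rng.normal(size=(8, 6))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        X = np.vstack([inliers, 30 * u])
        vecs = [CDPAVector(v=row, site_id=f"s{i}") for i, row in enumerate(X)]
        with pytest.raises(ValueError, match="max_fraction"):
            flag_outliers({"G": vecs}, alpha=0.001, max_fraction=0.10)
        report = flag_outliers({"G": vecs}, alpha=0.001, max_fraction=0.25)
        assert set(report.flagged["G"]) == {f"s{i}" for i in range(40, 48)}


class TestSplitSubgroups:
    def test_planted_partition_recovered(self, rng):
        A = rng.normal(0, 0.5, size=(20, 6))
        B = rng.normal(10, 0.5, size=(25, 6))
        vecs = [CDPAVector(v=r, site_id=f"a{i}") for i, r in enumerate(A)] + [
            CDPAVector(v=r, site_id=f"b{i}") for i, r in enumerate(B)
        ]
        report = split_subgroups(vecs, "HEM", k=2, seed=0)
        sub = report.subgroups
        a_labels = {sub[f"a{i}"] for i in range(20)}
        b_labels = {sub[f"b{i}"] for i in range(25)}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels
        assert b_labels == {"HEM-I"}  # larger cluster takes the first sublabel

    def test_identical_vectors_fallback(self):
        vecs = [CDPAVector(v=np.ones(6), site_id=f"s{i}") for i in range(30)]
        with pytest.warns(UserWarning, match="no split"):
            report = split_subgroups(vecs, "HEM", k=2, seed=0)
        assert set(report.subgroups.values()) == {"HEM"}

    def test_fixed_seed_deterministic(self, rng):
        X = rng.normal(size=(40, 6))
        vecs = [CDPAVector(v=r, site_id=f"s{i}") for i, r in enumerate(X)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = split_subgroups(vecs, "G", seed=5)
            r2 = split_subgroups(vecs, "G", seed=5)
        assert r1.subgroups == r2.subgroups


class TestClassicalMDS:
    def test_low_rank_input_distances_reproduced(self, rng):
        # vectors in a 3-D affine subspace embed exactly in k=3
        basis = rng.normal(size=(3, 6))
        Z = rng.normal(size=(15, 3))
        X = Z @ basis + rng.normal(size=6)
        vecs = [CDPAVector(v=r, site_id=f"s{i}") for i, r in enumerate(X)]
        emb = classical_mds(vecs, k=3)
        orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        new = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=2
        )
        np.testing.assert_allclose(new, orig, atol=1e-8)

    def test_top_eigenvalues_nonnegative_and_sorted(self, rng):
        X = rng.normal(size=(20, 6))
        vecs = [CDPAVector(v=r, site_id=f"s{i}") for i, r in enumerate(X)]
        emb = classical_mds(vecs, k=2)
        assert emb.eigenvalues[0] >= emb.eigenvalues[1] >= 0
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0, atol=1e-8)

    def test_matches_gram_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(18, 6))
        vecs = [CDPAVector(v=r, site_id=f"s{i}") for i, r in enumerate(X)]
        emb = classical_mds(vecs, k=2)
        # oracle: centre the data, eigendecompose the centred Gram matrix
        Xc = X - X.mean(axis=0)
        G = Xc @ Xc.T
        w, V = np.linalg.eigh(G)
        idx = np.argsort(w)[::-1][:2]
        oracle = V[:, idx] * np.sqrt(w[idx])
        d_emb = np.linalg.norm(emb.coordinates[:, None] - emb.coordinates[None, :], axis=2)
        d_orc = np.linalg.norm(oracle[:, None] - oracle[None, :], axis=2)
        np.testing.assert_allclose(d_emb, d_orc, atol=1e-8)

    def test_too_few_points_rejected(self, rng):
        vecs = [CDPAVector(v=rng.normal(size=6), site_id="a"), CDPAVector(v=rng.normal(size=6), site_id="b")]
        with pytest.raises(ValueError):
            classical_mds(vecs, k=2)
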