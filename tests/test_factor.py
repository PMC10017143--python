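"""Factor extraction, rotation, fit indices and scores against closed-form
constructions and planted-structure recovery."""

import numpy as np
import pytest

from rxpatterns.correlation import CorrelationModel, correlation
from rxpatterns.factor import (
    extract,
    factor_scores,
    fit_indices,
    match_columns,
    ml_discrepancy,
    tucker_congruence,
)
from rxpatterns.synthetic import PlantedFactorSpec, block_loadings, sample_indicator_matrix
from rxpatterns.utils import InvalidSpecError, child_rng


def _corr_model(R, n_obs=500, columns=None):
    R = np.asarray(R, dtype=float)
    return CorrelationModel(
        matrix=R,
        method="pearson",
        n_obs=n_obs,
        columns=columns or [f"V{j}" for j in range(R.shape[0])],
    )


def _exact_one_factor(lam):
    lam = np.asarray(lam, dtype=float)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


class TestExtraction:
    @pytest.mark.parametrize("method", ["minres", "ml"])
    def test_recovers_exact_one_factor_structure(self, method):
        """R = lambda lambda' + Psi with lambda = (.8,.7,.6,.5,.4,.45) is
        reproduced to 1e-4."""
        lam_true = np.array([0.8, 0.7, 0.6, 0.5, 0.4, 0.45])
        corr = _corr_model(_exact_one_factor(lam_true))
        model = extract(corr, 1, method=method, rotation="none")
        assert np.abs(model.loadings.ravel() - lam_true).max() < 1e-4
        assert np.abs(model.uniquenesses - (1 - lam_true**2)).max() < 1e-4

    def test_identity_correlation_no_common_variance(self):
        corr = _corr_model(np.eye(8))
        model = extract(corr, 1, rotation="none")
        assert np.abs(model.loadings).max() < 1e-3
        assert np.abs(model.uniquenesses - 1.0).max() < 0.01

    def test_oblique_two_factor_recovery(self):
        """Binary data from a planted oblique 2-factor model at n=5000:
        Tucker congruence >= 0.95 per factor after column matching."""
        lam, phi, codes = block_loadings(2, 8, 0.8, 0.35)
        fs = PlantedFactorSpec(1, codes, lam, phi, np.full(16, 0.2))
        presence, _ = sample_indicator_matrix(fs, 5000, child_rng(0, 6))
        corr = correlation(presence.astype(int), method="tetrachoric")
        model = extract(corr, 2, rotation="oblimin")
        _, cong = match_columns(model.loadings, lam)
        assert cong.min() >= 0.95

    def test_communality_plus_uniqueness_is_one(self, period1_matrix):
        corr = correlation(period1_matrix)
        model = extract(corr, 3)
        assert np.abs(model.communalities + model.uniquenesses - 1.0).max() < 1e-6

    def test_sign_convention_largest_loading_positive(self, period1_matrix):
        corr = correlation(period1_matrix)
        model = extract(corr, 3)
        for k in range(3):
            col = model.loadings[:, k]
            assert col[np.abs(col).argmax()] > 0

    def test_explained_variance_ordered_and_bounded(self, period1_matrix):
        corr = correlation(period1_matrix)
        model = extract(corr, 3)
        ev = model.explained_variance
        props = ev["proportion_total"].to_numpy()
        assert np.all(np.diff(props) <= 1e-12)
        assert ev["cumulative_total"].iloc[-1] <= 1.0 + 1e-9

    def test_n_factors_bounds(self):
        corr = _corr_model(np.eye(6))
        with pytest.raises(InvalidSpecError):
            extract(corr, 0)
        with pytest.raises(InvalidSpecError):
            extract(corr, 4)


class TestRotationInvariance:
    def test_rotation_preserves_fit(self):
        """RMSR is identical across none/varimax/oblimin rotations of the
        same extraction (rotation acts within the column space)."""
        lam, phi, codes = block_loadings(2, 6, 0.7, 0.0)
        fs = PlantedFactorSpec(1, codes, lam, phi, np.full(12, 0.3))
        presence, _ = sample_indicator_matrix(fs, 3000, child_rng(0, 7))
        corr = correlation(presence.astype(int))
        rmsrs = [
            fit_indices(extract(corr, 2, rotation=rot)).rmsr
            for rot in ("none", "varimax", "oblimin")
        ]
        assert max(rmsrs) - min(rmsrs) < 1e-8


class TestFitIndices:
    def test_perfect_model_zero_rmsr_rmsea(self):
        lam_true = np.array([0.8, 0.7, 0.6, 0.5, 0.45, 0.4])
        corr = _corr_model(_exact_one_factor(lam_true))
        model = extract(corr, 1, rotation="none")
        fit = fit_indices(model)
        assert fit.rmsr == pytest.approx(0.0, abs=1e-5)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-5)
        assert fit.good_fit
        # TLI reaches (and can slightly exceed) 1 when the model reproduces R
        assert fit.tli >= 0.99

    def test_good_fit_flag_follows_rmsea_threshold(self):
        # a deliberately misspecified model: 1 factor for clearly 2-factor data
        lam, phi, codes = block_loadings(2, 6, 0.8, 0.0)
        R = lam @ phi @ lam.T
        np.fill_diagonal(R, 1.0)
        corr = _corr_model(R, n_obs=5000)
        fit = fit_indices(extract(corr, 1, rotation="none"))
        assert fit.rmsea > 0.05 and not fit.good_fit

    def test_tli_reported_on_both_scales(self):
        lam_true = np.array([0.8, 0.7, 0.6, 0.5, 0.45, 0.4])
        corr = _corr_model(_exact_one_factor(lam_true))
        fit = fit_indices(extract(corr, 1, rotation="none"))
        assert fit.tli_x100 == pytest.approx(100 * fit.tli)

    def test_saturated_model_rejected(self):
        # p=3, F=1 has zero degrees of freedom: fit indices are undefined
        corr = _corr_model(_exact_one_factor([0.8, 0.7, 0.6]))
        model = extract(corr, 1, rotation="none")
        with pytest.raises(InvalidSpecError, match="saturated"):
            fit_indices(model)

    def test_ml_discrepancy_zero_at_truth(self):
        R = _exact_one_factor([0.8, 0.7, 0.6])
        assert ml_discrepancy(R, R.copy()) == pytest.approx(0.0, abs=1e-12)


class TestFactorScores:
    def _fitted(self, n=5000, seed=8):
        # moderate indicator prevalence: with rare indicators (<~20%) the
        # phi correlations are too attenuated for any scoring method to
        # track the latent factors closely
        lam, phi, codes = block_loadings(3, 10, 0.8, 0.3)
        fs = PlantedFactorSpec(1, codes, lam, phi, np.full(30, 0.25))
        presence, scores = sample_indicator_matrix(fs, n, child_rng(0, seed))
        x = presence.astype(int)
        corr = correlation(x)
        model = extract(corr, 3, rotation="oblimin")
        return model, x, scores, lam

    def test_scores_centred_on_cohort_mean(self):
        model, x, _, _ = self._fitted(n=1500)
        est = factor_scores(model, x)
        assert np.abs(est.mean(axis=0)).max() < 1e-10

    def test_recovers_true_scores(self):
        """Correlation(estimated, true) >= 0.8 per factor at salient 0.8."""
        model, x, true, lam = self._fitted()
        est = factor_scores(model, x)
        matched_loadings, _ = match_columns(model.loadings, lam)
        # align estimated score columns to the planted factors via loadings
        cong = np.abs(tucker_congruence(lam, model.loadings))
        perm = cong.argmax(axis=1)
        for k in range(3):
            r = abs(np.corrcoef(est[:, perm[k]], true[:, k])[0, 1])
            assert r >= 0.8

    def test_orthogonal_weights_reduce_to_rinv_lambda(self):
        lam_true = np.array([0.8, 0.7, 0.6, 0.5, 0.45, 0.4])
        R = _exact_one_factor(lam_true)
        corr = _corr_model(R)
        model = extract(corr, 1, rotation="none")
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 6))
        est = factor_scores(model, x)
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        expected = z @ np.linalg.solve(R, model.loadings)
        assert np.abs(est - expected).max() < 1e-10

    def test_vocabulary_mismatch_rejected(self):
        model, x, _, _ = self._fitted(n=800)
        with pytest.raises(InvalidSpecError):
            factor_scores(model, x[:, :10])
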