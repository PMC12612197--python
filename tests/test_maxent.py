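"""Hinge basis arithmetic, the L1-penalised Gibbs fit against a
grid-search oracle, the cloglog transform, AUC, and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from deepsdm import (TrainingTable, build_hinge_basis, compute_auc,
                     cross_validate, feature_penalties, fit_maxent,
                     maxent_objective)
from deepsdm.maxent import MaxEntModel


def _table(presence: np.ndarray, background: np.ndarray,
           name: str = "x") -> TrainingTable:
    feats = pd.DataFrame({name: np.concatenate([presence, background])})
    labels = np.concatenate([np.ones(len(presence), dtype=int),
                             np.zeros(len(background), dtype=int)])
    return TrainingTable(features=feats, labels=labels)


def _grid_oracle(F_p, F_b, beta, span=20.0, rounds=6, n_grid=81):
    """Exhaustive grid minimisation of the penalised objective with
    iterative zoom; independent of the fitting code path."""
    p = F_p.shape[1]
    center = np.zeros(p)
    width = span
    best = None
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.array([maxent_objective(lam, F_p, F_b, beta) for lam in pts])
        best = pts[vals.argmin()]
        center = best
        width = width * 2.2 / (n_grid - 1)  # keep the next grid overlapping
    return best


class TestHingeBasis:
    def test_forward_hinge_arithmetic(self):
        x = pd.DataFrame({"v": np.linspace(0.0, 10.0, 11)})
        basis = build_hinge_basis(x, knots_per_covariate=4)
        basis.knots["v"] = np.array([4.0])
        F = basis.transform(pd.DataFrame({"v": [7.0, 3.0, 10.0]}))
        fwd = F[:, 0]
        assert fwd[0] == pytest.approx((7.0 - 4.0) / (10.0 - 4.0))  # 0.5
        assert fwd[1] == 0.0            # below the knot
        assert fwd[2] == 1.0            # at the training max

    def test_reverse_hinge_and_range(self, rng):
        x = pd.DataFrame({"v": rng.uniform(-3, 5, 200)})
        basis = build_hinge_basis(x, knots_per_covariate=10)
        F = basis.transform(x)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_covariate_excluded_with_warning(self, rng):
        x = pd.DataFrame({"flat": np.ones(50), "ok": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="flat"):
            basis = build_hinge_basis(x)
        assert basis.covariates == ["ok"]

    def test_clamping_pins_out_of_range_values(self, rng):
        x = pd.DataFrame({"v": rng.uniform(0, 1, 100)})
        basis = build_hinge_basis(x, knots_per_covariate=5)
        hi = pd.DataFrame({"v": [1e6]})
        at_max = pd.DataFrame({"v": [basis.maxs["v"]]})
        np.testing.assert_array_equal(basis.transform(hi, clamp=True),
                                      basis.transform(at_max))


class TestFitMaxent:
    def test_huge_multiplier_zeroes_all_weights(self, rng):
        tr = _table(rng.uniform(0, 1, 50), rng.uniform(0, 1, 200))
        model = fit_maxent(tr, multiplier=1e6)
        assert np.all(model.weights == 0.0)
        assert model.entropy == pytest.approx(np.log(tr.b), rel=1e-9)

    def test_no_signal_gives_near_zero_weights(self, rng):
        shared = rng.uniform(0, 1, 400)
        tr = _table(shared[:100], shared[100:])
        model = fit_maxent(tr, multiplier=2.0)
        # only sampling noise separates the classes: weights stay small
        # and predictions stay near the uniform-model score 1 - 1/e
        assert np.abs(model.weights).sum() < 1.0
        scores = model.predict(tr.features)
        assert np.abs(scores - (1.0 - np.exp(-1.0))).max() < 0.15

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_grid_oracle_on_tiny_problems(self, trial):
        """Fitted weights agree with exhaustive minimisation of the
        explicit objective on problems small enough to enumerate."""
        rng = np.random.default_rng(100 + trial)
        B = int(rng.integers(4, 10))
        m = int(rng.integers(3, 8))
        n_feat = int(rng.integers(1, 3))
        F_b = rng.random((B, n_feat)).round(1)
        F_p = F_b[rng.integers(0, B, size=m)]
        beta = feature_penalties(F_p, multiplier=2.0)
        lam_star = _grid_oracle(F_p, F_b, beta)

        class _IdentityBasis:
            covariates = [f"f{j}" for j in range(n_feat)]
            def transform(self, X, clamp=False):
                return X[self.covariates].to_numpy(dtype=float)

        feats = pd.DataFrame(np.vstack([F_p, F_b]),
                             columns=[f"f{j}" for j in range(n_feat)])
        labels = np.concatenate([np.ones(m, int), np.zeros(B, int)])
        tr = TrainingTable(features=feats, labels=labels)
        model = fit_maxent(tr, basis=_IdentityBasis(), multiplier=2.0,
                           tolerance=1e-12)
        np.testing.assert_allclose(model.weights, lam_star, atol=1e-3)

    def test_objective_nonincreasing_over_iterations(self, rng):
        tr = _table(rng.normal(1.0, 0.3, 80), rng.normal(0.0, 1.0, 300))
        seen = []
        fit_maxent(tr, multiplier=2.0, callback=seen.append)
        diffs = np.diff(seen)
        assert (diffs <= 1e-8).all()

    def test_l1_norm_shrinks_with_multiplier(self, rng):
        tr = _table(rng.normal(1.0, 0.3, 80), rng.normal(0.0, 1.0, 300))
        norms = [np.abs(fit_maxent(tr, multiplier=mult).weights).sum()
                 for mult in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_kl_to_true_gibbs_shrinks_with_sample_size(self):
        """Presences drawn from a known Gibbs density on a small discrete
        landscape: with a light penalty, the fitted background
        distribution approaches the truth as m grows."""
        rng = np.random.default_rng(3)
        B = 40
        F_b = rng.random((B, 2))
        lam_true = np.array([2.0, -1.5])
        q_true = np.exp(F_b @ lam_true)
        q_true /= q_true.sum()

        def fit_kl(m):
            idx = rng.choice(B, size=m, p=q_true)
            feats = pd.DataFrame(np.vstack([F_b[idx], F_b]),
                                 columns=["f0", "f1"])
            labels = np.concatenate([np.ones(m, int), np.zeros(B, int)])

            class _Identity:
                covariates = ["f0", "f1"]
                def transform(self, X, clamp=False):
                    return X[self.covariates].to_numpy(dtype=float)

            model = fit_maxent(TrainingTable(features=feats, labels=labels),
                               basis=_Identity(), multiplier=0.01)
            q_fit = np.exp(F_b @ model.weights - model.log_z)
            return float(np.sum(q_true * np.log(q_true / q_fit)))

        assert fit_kl(10_000) < fit_kl(100)

    def test_serialisation_roundtrip(self, rng, tmp_path):
        tr = _table(rng.normal(1.0, 0.3, 60), rng.normal(0.0, 1.0, 200))
        model = fit_maxent(tr, multiplier=2.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = MaxEntModel.from_json(path)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))


class TestPredict:
    def test_uniform_model_cloglog_closed_form(self, rng):
        tr = _table(rng.uniform(0, 1, 40), rng.uniform(0, 1, 160))
        model = fit_maxent(tr, multiplier=1e9)  # forces lambda = 0
        scores = model.predict(tr.features)
        np.testing.assert_allclose(scores, 1.0 - np.exp(-1.0), atol=1e-12)

    def test_scores_strictly_monotone_in_linear_score(self, rng):
        tr = _table(rng.normal(1.0, 0.3, 80), rng.normal(0.0, 1.0, 300))
        model = fit_maxent(tr, multiplier=2.0)
        X = pd.DataFrame({"x": np.linspace(-2, 2, 200)})
        eta = model.linear_score(X)
        s = model.predict(X)
        order = np.argsort(eta)
        assert (np.diff(s[order]) >= 0).all()
        assert ((s > 0) & (s < 1)).all()


class TestAuc:
    def test_examples(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert compute_auc([0.5], [0.5]) == 0.5
        assert compute_auc([0.9, 0.4], [0.6, 0.2]) == 0.75

    @pytest.mark.parametrize("trial", range(20))
    def test_equals_brute_force_pair_count(self, trial):
        rng = np.random.default_rng(trial)
        pos = rng.integers(0, 8, size=rng.integers(1, 20)) / 8  # ties likely
        neg = rng.integers(0, 8, size=rng.integers(1, 20)) / 8
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert compute_auc(pos, neg) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12)


class TestCrossValidate:
    def test_seeded_determinism(self, rng):
        tr = _table(rng.normal(1.0, 0.3, 60), rng.normal(0.0, 1.0, 240))
        a = cross_validate(tr, k=3, seed=5)
        b = cross_validate(tr, k=3, seed=5)
        assert a.fold_auc == b.fold_auc
        np.testing.assert_array_equal(a.presence_folds, b.presence_folds)

    def test_separable_species_scores_high(self, rng):
        tr = _table(rng.normal(3.0, 0.2, 90), rng.normal(0.0, 0.5, 400))
        cv = cross_validate(tr, k=3, seed=1)
        assert cv.mean_auc > 0.95

    def test_label_permutation_null(self, rng):
        scores = rng.normal(size=2000)
        labels = np.zeros(2000, int)
        labels[rng.choice(2000, 400, replace=False)] = 1
        tr = TrainingTable(features=pd.DataFrame({"x": scores}), labels=labels)
        cv = cross_validate(tr, k=3, seed=2)
        assert 0.45 <= cv.mean_auc <= 0.55

    def test_too_few_presences_rejected(self, rng):
        tr = _table(np.array([0.5, 0.6]), rng.uniform(0, 1, 50))
        with pytest.raises(ValueError, match="presences"):
            cross_validate(tr, k=3, seed=0)

    def test_folds_partition_both_classes(self, rng):
        tr = _table(rng.normal(1.0, 0.3, 61), rng.normal(0.0, 1.0, 239))
        cv = cross_validate(tr, k=3, seed=7)
        assert len(cv.presence_folds) == 61
        assert len(cv.background_folds) == 239
        assert set(cv.presence_folds) == {0, 1, 2}
        assert set(cv.background_folds) == {0, 1, 2}
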