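import numpy as np
import pytest

from hyperflux.discriminate import (
    canonical_projection,
    evaluate_pairwise,
    one_sd_ellipse,
    roc_auc,
    train_linear_classifier,
)
from hyperflux.features import mann_whitney_u
from hyperflux.pipeline import IA_GROUPS, RA_GROUPS


def _fisher_parts(X, y, names, shrinkage=1e-3):
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    Za, Zb = Z[y == names[0]], Z[y == names[1]]
    d = Zb.mean(axis=0) - Za.mean(axis=0)
    Sw = (Za - Za.mean(0)).T @ (Za - Za.mean(0)) + (Zb - Zb.mean(0)).T @ (Zb - Zb.mean(0))
    Sw = Sw + shrinkage * np.trace(Sw) / Z.shape[1] * np.eye(Z.shape[1])
    return d, Sw


def fisher_ratio(w, X, y, names, shrinkage=1e-3):
    """Fisher criterion of a direction on standardised features (oracle)."""
    d, Sw = _fisher_parts(X, y, names, shrinkage)
    return float((d @ w) ** 2 / (w @ Sw @ w))


def grid_search_direction(X, y, dirs, rng, names=("A", "B")):
    """Brute-force Fisher-direction search, independent of any eigensolve.

    Evaluates the Fisher ratio on the supplied global direction grid,
    then twice more on grids resampled inside a shrinking cone around
    the running best.
    """
    d, Sw = _fisher_parts(X, y, names)
    pool = dirs
    best = None
    for stage in range(3):
        ratios = (pool @ d) ** 2 / np.einsum("ij,jk,ik->i", pool, Sw, pool)
        best = pool[int(np.argmax(ratios))]
        pool = best[None, :] + (0.2 / 3**stage) * rng.normal(size=(len(dirs), X.shape[1]))
        pool /= np.linalg.norm(pool, axis=1, keepdims=True)
    return best


def _two_group_data(rng, n=40, delta=None):
    delta = np.array([1.5, 0.0, 0.0, 0.0]) if delta is None else delta
    Xa = rng.normal(0, 1, (n, 4))
    Xb = rng.normal(0, 1, (n, 4)) + delta
    X = np.vstack([Xa, Xb])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestCanonicalProjection:
    def test_single_informative_feature_dominates_axis1(self, rng):
        X, y = _two_group_data(rng, n=200)
        proj = canonical_projection(X, y)
        assert abs(proj.loadings[0, 0]) > 0.9

    def test_axis1_matches_grid_search_oracle(self, rng):
        dirs = rng.normal(size=(10_000, 4))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for _ in range(5):
            X, y = _two_group_data(rng, delta=rng.normal(0, 1, 4))
            proj = canonical_projection(X, y)
            best = grid_search_direction(X, y, dirs, rng)
            angle = np.degrees(np.arccos(min(1.0, abs(best @ proj.loadings[:, 0]))))
            assert angle <= 5.0

    def test_identical_means_flagged_degenerate(self, rng):
        Xa = rng.normal(0, 1, (50, 4))
        X = np.vstack([Xa, Xa])
        y = np.array(["A"] * 50 + ["B"] * 50)
        proj = canonical_projection(X, y)
        assert proj.fisher_ratio < 1e-6

    def test_axis1_separates_better_than_random_directions(self, rng):
        X, y = _two_group_data(rng)
        proj = canonical_projection(X, y)
        mu, sd = X.mean(0), X.std(0, ddof=1)
        Z = (X - mu) / sd
        sep1 = abs(Z[y == "B"].mean(0) @ proj.loadings[:, 0] - Z[y == "A"].mean(0) @ proj.loadings[:, 0])
        sw = np.sqrt(fisher_ratio(proj.loadings[:, 0], X, y, ("A", "B")))
        for _ in range(100):
            w = rng.normal(size=4)
            w /= np.linalg.norm(w)
            assert np.sqrt(fisher_ratio(w, X, y, ("A", "B"))) <= sw + 1e-9

    def test_axes_are_orthonormal(self, rng):
        X, y = _two_group_data(rng)
        proj = canonical_projection(X, y)
        L = proj.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(2), atol=1e-9)

    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        y = np.array(["A", "A", "A", "B", "B"])
        with pytest.raises(ValueError, match="fewer than 3"):
            canonical_projection(X, y)


class TestEllipse:
    def test_unit_variance_grid_gives_unit_radii(self, rng):
        pts = rng.normal(0, 1.0, size=(5000, 2))
        e = one_sd_ellipse(pts)
        np.testing.assert_allclose(e.radii, 1.0, atol=0.05)
        np.testing.assert_allclose(e.center, 0.0, atol=0.05)

    def test_identical_points_zero_radii(self):
        pts = np.ones((5, 2))
        e = one_sd_ellipse(pts)
        np.testing.assert_allclose(e.radii, 0.0, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(0, 1, (200, 2)) * np.array([3.0, 0.5])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e1 = one_sd_ellipse(pts)
        e2 = one_sd_ellipse(pts @ R.T)
        np.testing.assert_allclose(e2.center, R @ e1.center, atol=1e-9)
        np.testing.assert_allclose(np.sort(e2.radii), np.sort(e1.radii), atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            one_sd_ellipse(np.zeros((2, 2)))


class TestLinearClassifier:
    def test_separable_groups_perfect_training_accuracy(self, rng):
        X, y = _two_group_data(rng, delta=np.array([8.0, 0, 0, 0]))
        scorer = train_linear_classifier(X, y)
        assert (scorer.predict(X) == y).mean() == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X, y = _two_group_data(rng, n=500, delta=np.zeros(4))
        scorer = train_linear_classifier(X, y)
        acc = (scorer.predict(X) == y).mean()
        assert 0.4 < acc < 0.62  # chance plus in-sample optimism

    def test_invariant_to_feature_rescaling(self, rng):
        X, y = _two_group_data(rng)
        s1 = train_linear_classifier(X, y)
        X2 = X.copy()
        X2[:, 2] = X2[:, 2] * 37.0 + 5.0
        s2 = train_linear_classifier(X2, y)
        r1 = s1.score(X) - s1.threshold
        r2 = s2.score(X2) - s2.threshold
        np.testing.assert_allclose(r1, r2, rtol=1e-8, atol=1e-10)

    def test_empty_group_rejected(self, rng):
        X = rng.normal(size=(4, 4))
        with pytest.raises(ValueError):
            train_linear_classifier(X, np.array(["A"] * 4), group_names=("A", "B"))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1], bool))
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0

    def test_constant_scores_give_half(self):
        roc = roc_auc(np.ones(10), np.array([0, 1] * 5, bool))
        assert roc.auc == pytest.approx(0.5)

    def test_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.normal(size=50)
        labels = rng.uniform(size=50) > 0.5
        roc = roc_auc(scores, labels)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_auc_equals_mann_whitney_u_identity(self, rng):
        for _ in range(20):
            n_pos, n_neg = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            scores = rng.permutation(np.arange(n_pos + n_neg, dtype=float))
            labels = np.zeros(n_pos + n_neg, bool)
            labels[:n_pos] = True
            roc = roc_auc(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            from scipy.stats import rankdata

            ranks = rankdata(np.concatenate([pos, neg]))
            u_pos = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
            assert roc.auc == pytest.approx(u_pos / (n_pos * n_neg), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, bool))


class TestEvaluatePairwise:
    def test_pooled_ia_vs_ra_fibre_resubstitution(self, cohort_table):
        _, roc = evaluate_pairwise(cohort_table, "fibre", IA_GROUPS, RA_GROUPS)
        assert roc.auc >= 0.9

    def test_null_cohort_auc_near_chance(self, null_cohort_table):
        _, roc = evaluate_pairwise(
            null_cohort_table, "fibre", IA_GROUPS, RA_GROUPS, mode="leave-one-patient-out"
        )
        assert 0.4 <= roc.auc <= 0.6

    def test_leave_one_patient_out_close_to_resubstitution(self, cohort_table):
        _, roc_in = evaluate_pairwise(cohort_table, "fibre", IA_GROUPS, RA_GROUPS)
        _, roc_out = evaluate_pairwise(
            cohort_table, "fibre", IA_GROUPS, RA_GROUPS, mode="leave-one-patient-out"
        )
        assert roc_out.auc <= roc_in.auc + 0.05

    def test_absent_group_rejected(self, cohort_table):
        with pytest.raises(ValueError):
            evaluate_pairwise(cohort_table, "fibre", "IA_HIGH", "RA_MID")
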