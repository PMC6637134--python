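"""Rigid-motion fitting, clustering, and MDL model selection."""

import math

import numpy as np
import pytest

import vistrack as vt
from vistrack import motion


def reference_description_length(model, sigma_min=0.1, mu_zero=False):
    """Literal re-evaluation of the MDL components, independent of the
    package implementation (plain-Python double loop)."""
    N = len(model.labels)
    K = model.K
    ln2 = math.log(2)
    L_which = N * math.log2(K + 1) / ln2
    L_out = model.n_outliers * math.log2(model.bbox_area) / ln2
    prod = 1.0
    for Ni in model.cluster_sizes:
        prod *= Ni
    L_model = 3.0 / (2 * ln2) * math.log2(prod)
    L_res = 0.0
    for i in range(K):
        rs = [model.residuals[j] for j in range(N) if model.labels[j] == i]
        Ni = len(rs)
        for ax in range(2):
            vals = [r[ax] for r in rs]
            mu = 0.0 if mu_zero else sum(vals) / Ni
            var = sum((v - mu) ** 2 for v in vals) / Ni
            sd = max(math.sqrt(var), sigma_min)
            L_res += Ni / 2 * math.log(2 * math.pi * sd * sd)
            L_res += sum((v - mu) ** 2 for v in vals) / (2 * sd * sd)
    return L_which + L_out + L_model + L_res


class TestSolveRigid:
    def test_identity(self, rng):
        p = rng.uniform(0, 100, (20, 2))
        tr = vt.solve_rigid(p, p)
        assert abs(tr.rotation) < 1e-12
        assert np.allclose(tr.translation, 0)

    def test_exact_rotation_translation(self, rng):
        p = rng.uniform(-50, 50, (10, 2))
        th = np.deg2rad(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        q = p @ R.T + [4.0, -7.0]
        tr = vt.solve_rigid(p, q)
        assert abs(tr.rotation - th) < 1e-10
        assert np.allclose(tr.translation, [4, -7], atol=1e-9)

    def test_no_reflection(self, rng):
        p = rng.uniform(0, 10, (30, 2))
        q = p * [1, -1]  # a reflection, inexpressible as rotation+translation
        tr = vt.solve_rigid(p, q)
        assert np.linalg.det(tr.matrix) > 0


class TestRansac:
    def test_identity_point_sets(self, rng):
        p = rng.uniform(0, 100, (20, 2))
        tr, flags = vt.fit_procrustes_ransac((p, p), seed=0)
        assert abs(tr.rotation) < 1e-9 and np.allclose(tr.translation, 0, atol=1e-9)
        assert flags.all()
        assert np.allclose(tr.apply(p) - p, 0, atol=1e-9)

    def test_pure_translation(self, rng):
        p = rng.uniform(0, 100, (15, 2))
        tr, flags = vt.fit_procrustes_ransac((p, p + [3, -2]), seed=1)
        assert abs(tr.rotation) < 1e-9
        assert np.allclose(tr.translation, [3, -2], atol=1e-9)
        assert flags.all()

    @pytest.mark.parametrize("seed", range(10))
    def test_cloud_recovery_with_outliers(self, seed):
        p, q, lab = vt.generate_rigid_motion_cloud(
            50,
            [(30.0, (5.0, -3.0), 1.0)],
            noise_sd=0.3,
            outlier_fraction=0.2,
            seed=seed,
        )
        tr, flags = vt.fit_procrustes_ransac((p, q), seed=seed)
        assert abs(np.rad2deg(tr.rotation) - 30) <= 0.5
        assert np.hypot(tr.translation[0] - 5, tr.translation[1] + 3) <= 0.5
        assert (flags == (lab >= 0)).mean() >= 0.95

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            vt.fit_procrustes_ransac((np.zeros((1, 2)), np.zeros((1, 2))))

    def test_degenerate_coincident_points_rejected(self):
        p = np.zeros((5, 2))
        with pytest.raises(ValueError):
            vt.fit_procrustes_ransac((p, p), seed=0)

    def test_refit_not_worse_than_minimal_sample(self, rng):
        """LS refit on the consensus set cannot increase the residual sum."""
        p, q, _ = vt.generate_rigid_motion_cloud(
            40, [(10.0, (2.0, 1.0), 1.0)], noise_sd=0.5, seed=3
        )
        tr, flags = vt.fit_procrustes_ransac((p, q), seed=3)
        refit_res = np.linalg.norm(tr.apply(p[flags]) - q[flags], axis=1)
        # any 2-point exact model on the same inliers has >= residual sum
        i, j = 0, 1
        sub = vt.solve_rigid(p[flags][[i, j]], q[flags][[i, j]])
        sub_res = np.linalg.norm(sub.apply(p[flags]) - q[flags], axis=1)
        assert refit_res.sum() <= sub_res.sum() + 1e-9


class TestClusteredMotion:
    def test_k1_reduces_to_plain_ransac(self, rng):
        p, q, _ = vt.generate_rigid_motion_cloud(
            30, [(5.0, (1.0, 2.0), 1.0)], noise_sd=0.4, seed=2
        )
        model = vt.cluster_motion((p, q), K=1, seed=0)
        tr, flags = vt.fit_procrustes_ransac((p, q), seed=0)
        assert model.transforms[0] == tr
        assert np.array_equal(model.labels >= 0, flags)

    def test_two_groups_recovered_exactly(self):
        p, q, lab = vt.generate_rigid_motion_cloud(
            40,
            [(0.0, (5.0, 0.0), 0.5), (0.0, (-5.0, 0.0), 0.5)],
            noise_sd=0.0,
            seed=4,
        )
        model = vt.cluster_motion((p, q), K=2, seed=4)
        # clustering labels may be permuted relative to ground truth
        t0, t1 = (np.round(t.translation) for t in model.transforms)
        assert {tuple(t0), tuple(t1)} == {(5.0, 0.0), (-5.0, 0.0)}
        for j in (0, 1):
            members = lab[model.labels == j]
            assert len(np.unique(members)) == 1

    def test_infeasible_k_flagged(self):
        p = np.array([[0.0, 0], [1, 0], [2, 0]])
        with pytest.raises(vt.InfeasibleModelError):
            vt.cluster_motion((p, p), K=5, seed=0)

    def test_kmeans_matches_sklearn_objective(self, rng):
        """Independent cross-check: our seeded k-means++ reaches the same
        within-cluster sum of squares as scikit-learn's on easy data."""
        sklearn = pytest.importorskip("sklearn.cluster")
        pts = np.concatenate(
            [rng.normal(c, 1.0, (30, 2)) for c in ((0, 0), (20, 0), (0, 20))]
        )
        _, wcss = motion.kmeans_pp(pts, 3, seed=0)
        km = sklearn.KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert wcss <= km.inertia_ * 1.001


class TestDescriptionLength:
    def _make_model(self, residuals, labels, K, bbox_area, n_outliers):
        labels = np.asarray(labels)
        return motion.ClusteredMotionModel(
            K=K,
            transforms=[motion.RigidTransform2D(0.0, (0.0, 0.0))] * K,
            labels=labels,
            residuals=np.asarray(residuals, float),
            cluster_sizes=np.bincount(labels[labels >= 0], minlength=K),
            n_outliers=n_outliers,
            bbox_area=bbox_area,
        )

    def test_closed_form_components_k1_no_outliers(self):
        res = np.full((8, 2), 0.25)  # residuals all equal to the mean
        model = self._make_model(res, [0] * 8, K=1, bbox_area=100.0, n_outliers=0)
        dl = vt.description_length(model)
        ln2 = math.log(2)
        assert dl.L_outlier == 0.0
        assert dl.L_which_model == pytest.approx(8 * math.log2(2) / ln2)
        # sigma floored: residual deviations are zero
        assert dl.L_residuals == pytest.approx(8 * math.log(2 * math.pi * 0.1**2))

    def test_outlier_term_hand_formula(self):
        res = np.zeros((12, 2))
        labels = [0] * 10 + [-1, -1]
        model = self._make_model(res, labels, K=1, bbox_area=100 * 100, n_outliers=2)
        dl = vt.description_length(model)
        assert dl.L_outlier == pytest.approx(2 * math.log2(10000) / math.log(2))

    def test_mle_sigma_residual_identity(self, rng):
        """With MLE variance the quadratic term sums to N_i/2 per axis."""
        res = rng.normal(0, 2.0, (50, 2))  # sd well above the floor
        model = self._make_model(res, [0] * 50, K=1, bbox_area=500.0, n_outliers=0)
        dl = vt.description_length(model)
        gauss = sum(
            50 / 2 * math.log(2 * math.pi * np.mean((res[:, ax] - res[:, ax].mean()) ** 2))
            for ax in range(2)
        )
        assert dl.L_residuals - gauss == pytest.approx(50 / 2 + 50 / 2)

    def test_each_outlier_costs_log_bbox(self, rng):
        res = rng.normal(0, 1, (20, 2))
        m0 = self._make_model(res, [0] * 20, K=1, bbox_area=300.0, n_outliers=0)
        m1 = self._make_model(res, [0] * 20, K=1, bbox_area=300.0, n_outliers=1)
        d = vt.description_length(m1).L_outlier - vt.description_length(m0).L_outlier
        assert d == pytest.approx(math.log2(300.0) / math.log(2))

    def test_matches_independent_reference(self, rng):
        p, q, _ = vt.generate_rigid_motion_cloud(
            60,
            [(0.0, (4.0, 0.0), 0.5), (0.0, (-4.0, 0.0), 0.5)],
            noise_sd=0.5,
            outlier_fraction=0.1,
            seed=6,
        )
        model = vt.cluster_motion((p, q), K=2, seed=6)
        dl = vt.description_length(model)
        assert dl.DL == pytest.approx(reference_description_length(model), abs=1e-9)
        assert dl.DL == dl.L_which_model + dl.L_outlier + dl.L_model + dl.L_residuals


class TestModelSelection:
    def test_single_rigid_motion_selects_k1(self):
        p, q, _ = vt.generate_rigid_motion_cloud(
            50, [(10.0, (3.0, 1.0), 1.0)], noise_sd=0.0, seed=0
        )
        model, _ = vt.select_motion_model((p, q), seed=0)
        assert model.K == 1

    @pytest.mark.parametrize("true_k", [2, 3])
    def test_separated_motions_select_true_k(self, true_k):
        clusters = [
            (0.0, (5.0, 0.0), 1 / true_k),
            (0.0, (-5.0, 0.0), 1 / true_k),
            (0.0, (0.0, 5.0), 1 / true_k),
        ][:true_k]
        hits = 0
        for seed in range(20):
            p, q, _ = vt.generate_rigid_motion_cloud(
                60, clusters, noise_sd=0.5, seed=seed
            )
            model, _ = vt.select_motion_model((p, q), seed=seed)
            hits += model.K == true_k
        assert hits >= 18

    def test_selected_dl_matches_reference(self):
        p, q, _ = vt.generate_rigid_motion_cloud(
            60,
            [(0.0, (5.0, 0.0), 0.5), (0.0, (-5.0, 0.0), 0.5)],
            noise_sd=0.5,
            seed=9,
        )
        model, dl = vt.select_motion_model((p, q), seed=9)
        assert dl.DL == pytest.approx(reference_description_length(model), abs=1e-9)

    def test_dl_invariant_to_global_translation(self):
        p, q, _ = vt.generate_rigid_motion_cloud(
            40, [(8.0, (2.0, -1.0), 1.0)], noise_sd=0.3, seed=5
        )
        m0 = vt.cluster_motion((p, q), K=1, seed=5, bbox_area=1000.0)
        m1 = vt.cluster_motion((p + 50.0, q + 50.0), K=1, seed=5, bbox_area=1000.0)
        assert vt.description_length(m0).DL == pytest.approx(
            vt.description_length(m1).DL, abs=1e-6
        )
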