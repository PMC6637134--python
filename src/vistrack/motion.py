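"""Clustered rigid-motion models for matched landmarks, selected by MDL.

A single rotation+translation (partial Procrustes superimposition, i.e.
no scaling) captures whole-body movements, but fails when body parts
move independently -- a head turn displaces the snout and ears while the
haunches stay put.  The model here therefore clusters landmark
coordinates with k-means++ (K = 1..5, 10 restarts), fits a rigid
transform per cluster with RANSAC outlier rejection (inlier threshold
10 px), and selects K with a minimum-description-length criterion that
trades the cost of extra clusters and of encoding outliers against the
likelihood of the residuals:

    DL = L_which_model + L_outlier + L_model + L_residuals

    L_which_model = N log2(K+1) / ln 2
    L_outlier     = N_outlier log2(Nx Ny) / ln 2
    L_model       = 3/(2 ln 2) log2(prod_i N_i)
    L_residuals   = sum_i  N_i/2 [ln(2 pi sx_i^2) + ln(2 pi sy_i^2)]
                            + sum_j (x_ij - mu_x_i)^2 / (2 sx_i^2)
                            + sum_j (y_ij - mu_y_i)^2 / (2 sy_i^2)

where Nx*Ny is the area of the bounding box around the animal (outliers
are encoded as unconstrained positions in that box), N_i the inlier
count of cluster i, the factor 3 the parameter count of a rigid
transform (1 rotation + 2 translation), and x_ij, y_ij the residuals of
cluster i with mean mu and maximum-likelihood SD s per axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tracking import MatchedPairs

__all__ = [
    "RigidTransform2D",
    "ClusteredMotionModel",
    "DescriptionLength",
    "InfeasibleModelError",
    "solve_rigid",
    "fit_procrustes_ransac",
    "kmeans_pp",
    "cluster_motion",
    "description_length",
    "select_motion_model",
]

DEFAULT_INLIER_THRESHOLD = 10.0
DEFAULT_RANSAC_ITERATIONS = 200
DEFAULT_N_RESTARTS = 10
DEFAULT_K_RANGE = (1, 5)
SIGMA_MIN = 0.1  # px; floors the MLE residual SD so ln(2 pi s^2) stays finite


class InfeasibleModelError(ValueError):
    """Raised when a K cannot be fitted (e.g. a cluster has < 2 members)."""


@dataclass(frozen=True)
class RigidTransform2D:
    """p1 = R(rotation) p + translation; rotation in (-pi, pi], radians."""

    rotation: float
    translation: tuple[float, float]

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.matrix.T + np.asarray(self.translation)


@dataclass
class ClusteredMotionModel:
    K: int
    transforms: list[RigidTransform2D]
    labels: np.ndarray  # per pair: cluster id, or -1 for outlier
    residuals: np.ndarray  # (n_pairs, 2); valid rows are the inliers
    cluster_sizes: np.ndarray  # inlier count N_i per cluster
    n_outliers: int
    bbox_area: float

    @property
    def n_pairs(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DescriptionLength:
    L_which_model: float
    L_outlier: float
    L_model: float
    L_residuals: float

    @property
    def DL(self) -> float:
        return self.L_which_model + self.L_outlier + self.L_model + self.L_residuals


def solve_rigid(p: np.ndarray, q: np.ndarray) -> RigidTransform2D:
    """Least-squares rotation+translation mapping p onto q (no scaling).

    Standard orthogonal-Procrustes solution via the SVD of the
    cross-covariance, with the determinant correction that excludes
    reflections.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if len(p) < 2 or p.shape != q.shape:
        raise ValueError("need >= 2 point pairs of equal shape")
    pc, qc = p.mean(0), q.mean(0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    theta = math.atan2(R[1, 0], R[0, 0])
    t = qc - R @ pc
    return RigidTransform2D(rotation=theta, translation=(float(t[0]), float(t[1])))


def fit_procrustes_ransac(
    pairs: MatchedPairs | tuple[np.ndarray, np.ndarray],
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
    n_iterations: int = DEFAULT_RANSAC_ITERATIONS,
    seed: int | np.random.Generator = 0,
) -> tuple[RigidTransform2D, np.ndarray]:
    """RANSAC rigid fit: 2-pair hypotheses, consensus, least-squares refit.

    A 2-D rotation+translation is exactly determined by two point pairs,
    so each hypothesis samples two; the consensus-maximal hypothesis
    (ties broken by smaller inlier residual sum) is refitted by
    least squares on its inliers and the inlier flags recomputed.
    """
    if isinstance(pairs, MatchedPairs):
        p, q = pairs.prev, pairs.curr
    else:
        p, q = (np.asarray(a, float) for a in pairs)
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    i0 = rng.integers(0, n, size=n_iterations)
    i1 = rng.integers(0, n, size=n_iterations)
    dp = p[i1] - p[i0]
    dq = q[i1] - q[i0]
    ok = (np.linalg.norm(dp, axis=1) > 1e-9) & (i0 != i1)
    if not ok.any():
        raise ValueError("all RANSAC samples degenerate (coincident points)")
    theta = np.arctan2(dq[:, 1], dq[:, 0]) - np.arctan2(dp[:, 1], dp[:, 0])
    c, s = np.cos(theta), np.sin(theta)
    # t = q0 - R p0 for each hypothesis
    tx = q[i0, 0] - (c * p[i0, 0] - s * p[i0, 1])
    ty = q[i0, 1] - (s * p[i0, 0] + c * p[i0, 1])
    # residuals: hypotheses x points
    px, py = p[:, 0], p[:, 1]
    rx = c[:, None] * px - s[:, None] * py + tx[:, None] - q[:, 0]
    ry = s[:, None] * px + c[:, None] * py + ty[:, None] - q[:, 1]
    r2 = rx**2 + ry**2
    inl = (r2 <= inlier_threshold**2) & ok[:, None]
    counts = inl.sum(1)
    best_count = counts.max()
    if best_count < 2:
        raise ValueError("no RANSAC hypothesis reached consensus")
    cand = np.flatnonzero(counts == best_count)
    sums = np.where(inl[cand], r2[cand], 0.0).sum(1)
    best = cand[np.argmin(sums)]

    flags = inl[best]
    transform = solve_rigid(p[flags], q[flags])
    resid = transform.apply(p) - q
    flags = (resid**2).sum(1) <= inlier_threshold**2
    if flags.sum() >= 2:  # refit once on the recomputed inlier set
        transform = solve_rigid(p[flags], q[flags])
        resid = transform.apply(p) - q
        flags = (resid**2).sum(1) <= inlier_threshold**2
    return transform, flags


def kmeans_pp(
    points: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Seeded k-means++ (best of ``n_restarts`` by within-cluster SS).

    Hand-vectorised Lloyd iterations: the model-selection loop calls this
    dozens of times per frame pair on a few tens of points, so per-call
    overhead matters more than asymptotics here.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if k < 1 or n < k:
        raise InfeasibleModelError(f"cannot form {k} clusters from {n} points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_labels, best_wcss = None, np.inf
    for _ in range(n_restarts):
        centres = np.empty((k, 2))
        centres[0] = pts[rng.integers(n)]
        d2 = ((pts - centres[0]) ** 2).sum(1)
        for j in range(1, k):
            total = d2.sum()
            if total <= 0:
                centres[j] = pts[rng.integers(n)]
            else:
                centres[j] = pts[rng.choice(n, p=d2 / total)]
            d2 = np.minimum(d2, ((pts - centres[j]) ** 2).sum(1))
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            dist = ((pts[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
            new_labels = dist.argmin(1)
            if (new_labels == labels).all() and _ > 0:
                break
            labels = new_labels
            for j in range(k):
                sel = labels == j
                if sel.any():
                    centres[j] = pts[sel].mean(0)
        wcss = ((pts - centres[labels]) ** 2).sum()
        if wcss < best_wcss:
            best_wcss, best_labels = wcss, labels.copy()
    return best_labels, float(best_wcss)


def _bbox_area(points: np.ndarray) -> float:
    span = points.max(0) - points.min(0)
    return float(max(span[0], 1.0) * max(span[1], 1.0))


def cluster_motion(
    pairs: MatchedPairs | tuple[np.ndarray, np.ndarray],
    K: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
    seed: int = 0,
    n_iterations: int = DEFAULT_RANSAC_ITERATIONS,
    bbox_area: float | None = None,
) -> ClusteredMotionModel:
    """Cluster landmark coordinates, then fit a rigid transform per cluster.

    Clustering uses the previous-frame landmark coordinates only (not
    displacement vectors): body parts are spatially coherent, so spatial
    clusters are the natural support of part-wise rigid motion.  RANSAC
    outlier rejection runs separately within each cluster; outliers from
    all clusters are pooled.
    """
    if isinstance(pairs, MatchedPairs):
        p, q = pairs.prev, pairs.curr
    else:
        p, q = (np.asarray(a, float) for a in pairs)
    n = len(p)
    if n < 2 * K:
        raise InfeasibleModelError(f"{n} pairs cannot support {K} clusters of >= 2")
    rng = np.random.default_rng(seed)
    if K == 1:
        labels0 = np.zeros(n, dtype=int)
    else:
        labels0, _ = kmeans_pp(p, K, n_restarts=n_restarts, seed=rng)
    sizes0 = np.bincount(labels0, minlength=K)
    if (sizes0 < 2).any():
        raise InfeasibleModelError(f"K={K}: a cluster has fewer than 2 members")

    transforms: list[RigidTransform2D] = []
    labels = np.full(n, -1, dtype=int)
    residuals = np.full((n, 2), np.nan)
    for j in range(K):
        sel = np.flatnonzero(labels0 == j)
        try:
            tr, flags = fit_procrustes_ransac(
                (p[sel], q[sel]),
                inlier_threshold=inlier_threshold,
                n_iterations=n_iterations,
                seed=rng,
            )
        except ValueError as exc:
            raise InfeasibleModelError(f"K={K}, cluster {j}: {exc}") from exc
        transforms.append(tr)
        inliers = sel[flags]
        labels[inliers] = j
        residuals[inliers] = tr.apply(p[inliers]) - q[inliers]
    cluster_sizes = np.bincount(labels[labels >= 0], minlength=K)
    if (cluster_sizes == 0).any():
        raise InfeasibleModelError(f"K={K}: a cluster lost all inliers")
    return ClusteredMotionModel(
        K=K,
        transforms=transforms,
        labels=labels,
        residuals=residuals,
        cluster_sizes=cluster_sizes,
        n_outliers=int((labels == -1).sum()),
        bbox_area=float(bbox_area) if bbox_area is not None else _bbox_area(p),
    )


def description_length(
    model: ClusteredMotionModel,
    sigma_min: float = SIGMA_MIN,
    mu_zero: bool = False,
) -> DescriptionLength:
    """Evaluate the MDL criterion exactly as defined above (in nats).

    ``mu_zero`` fixes the residual means at zero instead of using the
    empirical per-cluster, per-axis means; the default uses the
    empirical means.  The residual SDs are maximum-likelihood estimates
    floored at ``sigma_min`` (a pure numerical guard for noise-free
    synthetic input).
    """
    if model.bbox_area <= 0:
        raise ValueError("bbox_area must be positive")
    if (model.cluster_sizes == 0).any():
        raise ValueError("every cluster must have at least one inlier")
    N = model.n_pairs
    K = model.K
    ln2 = math.log(2.0)
    L_which = N * math.log2(K + 1) / ln2
    L_out = model.n_outliers * math.log2(model.bbox_area) / ln2
    L_model = (3.0 / (2.0 * ln2)) * sum(math.log2(Ni) for Ni in model.cluster_sizes)
    L_res = 0.0
    for j in range(K):
        res = model.residuals[model.labels == j]
        Ni = len(res)
        for axis in range(2):
            r = res[:, axis]
            mu = 0.0 if mu_zero else float(r.mean())
            sd = max(float(np.sqrt(np.mean((r - mu) ** 2))), sigma_min)
            L_res += Ni / 2.0 * math.log(2.0 * math.pi * sd**2)
            L_res += float(((r - mu) ** 2).sum()) / (2.0 * sd**2)
    return DescriptionLength(
        L_which_model=L_which, L_outlier=L_out, L_model=L_model, L_residuals=L_res
    )


def select_motion_model(
    pairs: MatchedPairs | tuple[np.ndarray, np.ndarray],
    K_range: tuple[int, int] = DEFAULT_K_RANGE,
    n_restarts: int = DEFAULT_N_RESTARTS,
    inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
    seed: int = 0,
    n_iterations: int = DEFAULT_RANSAC_ITERATIONS,
    sigma_min: float = SIGMA_MIN,
    mu_zero: bool = False,
    bbox_area: float | None = None,
) -> tuple[ClusteredMotionModel, DescriptionLength]:
    """Fit every feasible K in ``K_range`` and return the MDL minimiser.

    Ties break toward smaller K (simpler model).  Raises
    :class:`InfeasibleModelError` when no K can be fitted.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(K_range[1] - K_range[0] + 1)
    best: tuple[ClusteredMotionModel, DescriptionLength] | None = None
    for K, ks in zip(range(K_range[0], K_range[1] + 1), child_seeds):
        try:
            model = cluster_motion(
                pairs,
                K,
                n_restarts=n_restarts,
                inlier_threshold=inlier_threshold,
                seed=int(ks),
                n_iterations=n_iterations,
                bbox_area=bbox_area,
            )
        except InfeasibleModelError:
            continue
        dl = description_length(model, sigma_min=sigma_min, mu_zero=mu_zero)
        if best is None or dl.DL < best[1].DL:
            best = (model, dl)
    if best is None:
        raise InfeasibleModelError("no feasible K in range")
    return best
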