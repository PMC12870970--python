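"""Functional PCA of smoothed trajectories and clustering of their scores.

The smoothed nonlinear trajectories live on a regular age grid with no
missingness, so the functional decomposition is computed by direct
eigendecomposition of the sample covariance over the grid with trapezoid-free
uniform quadrature weights (the fast-covariance estimators used for sparse
functional data reduce to this in the dense regular-grid case). Eigenfunction
signs follow a fixed convention — largest-magnitude coefficient positive — so
scores are reproducible across runs.

Clustering of the per-curve scores supports a density-based method (HDBSCAN,
noise labeled 0), fuzzy c-means with the dimension-based fuzzifier estimate,
and k-means with restarts. Cluster-level summaries ("eigenvalues" in the
module-score sense: per-sample PC1 of the cluster's standardized beta values)
feed redundancy merging on the Spearman rho > 0.90 graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from sklearn.cluster import HDBSCAN, KMeans, kmeans_plusplus

from .io import AnalysisConfig, BetaMatrix, ValidationError

__all__ = [
    "SmoothedTrajectorySet",
    "FPCADecomposition",
    "ClusterAssignment",
    "ClusterProfile",
    "run_fpca",
    "cluster_scores",
    "fuzzy_cmeans",
    "estimate_fuzzifier",
    "select_fuzzy_c",
    "select_kmeans_k",
    "recluster_noise",
    "build_cluster_profiles",
    "merge_correlated_clusters",
    "MergeResult",
    "cluster_eigenvalues",
    "mean_cluster_trajectory",
    "compare_cohort_trajectories",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #


@dataclass
class SmoothedTrajectorySet:
    """Smoothed per-CpG curves on a strictly increasing, evenly spaced age grid."""

    cpg_ids: list[str]
    grid: np.ndarray
    curves: np.ndarray  # (n_curves, n_grid)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        steps = np.diff(self.grid)
        if self.grid.size >= 2 and (
            (steps <= 0).any() or not np.allclose(steps, steps[0], rtol=1e-6)
        ):
            raise ValidationError("trajectory grid must be strictly increasing and evenly spaced")
        if not np.isfinite(self.curves).all():
            raise ValidationError("trajectory curves contain non-finite values")
        if self.curves.shape[0] and self.curves.shape != (len(self.cpg_ids), self.grid.size):
            raise ValidationError("curve matrix shape does not match ids x grid")

    def standardized(self) -> np.ndarray:
        """Per-curve z-scores (rows with zero variance become zero vectors)."""
        mu = self.curves.mean(axis=1, keepdims=True)
        sd = self.curves.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return (self.curves - mu) / sd

    def subset(self, cpg_ids: list[str]) -> "SmoothedTrajectorySet":
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        rows = [index[c] for c in cpg_ids]
        return SmoothedTrajectorySet(cpg_ids=list(cpg_ids), grid=self.grid,
                                     curves=self.curves[rows])


@dataclass
class FPCADecomposition:
    grid: np.ndarray
    mean_curve: np.ndarray          # (n_grid,)
    eigenfunctions: np.ndarray      # (n_comp, n_grid), orthonormal under quadrature
    eigenvalues: np.ndarray         # (n_comp,) descending
    scores: np.ndarray              # (n_curves, n_comp)
    pve_cum: np.ndarray             # (n_comp,)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean": self.mean_curve.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scores": self.scores.tolist(),
            "pve_cum": self.pve_cum.tolist(),
        }

    def reconstruct(self) -> np.ndarray:
        h = self.grid[1] - self.grid[0] if self.grid.size > 1 else 1.0
        return self.mean_curve + (self.scores @ self.eigenfunctions) * 1.0


@dataclass
class ClusterAssignment:
    cpg_ids: list[str]
    labels: np.ndarray              # int per CpG; 0 = noise for the density method
    method: str
    memberships: np.ndarray | None = None  # (n, c) row-stochastic, fuzzy only

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cpg_id": self.cpg_ids, "label": self.labels})
        if self.memberships is not None:
            for j in range(self.memberships.shape[1]):
                df[f"membership_{j}"] = self.memberships[:, j]
        return df

    def members(self, label: int) -> list[str]:
        return [c for c, l in zip(self.cpg_ids, self.labels) if l == label]


@dataclass
class ClusterProfile:
    cluster_id: int
    mean_trajectory: np.ndarray
    eigen_sample_scores: np.ndarray
    n_cpgs: int
    cpg_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cluster_id": int(self.cluster_id),
            "n_cpgs": int(self.n_cpgs),
            "mean_trajectory": self.mean_trajectory.tolist(),
            "eigen_sample_scores": self.eigen_sample_scores.tolist(),
        }


# --------------------------------------------------------------------------- #
# FPCA
# --------------------------------------------------------------------------- #


def run_fpca(
    trajectories: SmoothedTrajectorySet,
    config: AnalysisConfig | None = None,
    standardize: bool = True,
    smooth_eigenfunctions: bool = False,
) -> FPCADecomposition:
    """Decompose curves into mean + orthonormal eigenfunctions + scores.

    Components are retained up to the cumulative proportion of variance
    explained in ``config.pve_threshold`` (default 99.99%, keeping
    fine-grained shape information). ``standardize`` centers and scales each
    curve first so clustering sees shapes, not levels. Optional eigenfunction
    smoothing applies a least-squares spline with
    ``min(fpca_knots_cap, floor(fpca_knots_frac * n_grid))`` knots.
    """
    config = config or AnalysisConfig()
    X = trajectories.standardized() if standardize else trajectories.curves.copy()
    n, g = X.shape
    if n < 2:
        raise ValidationError("FPCA needs at least 2 curves")
    if g < 3:
        raise ValidationError("FPCA needs a grid of at least 3 ages")
    h = float(trajectories.grid[1] - trajectories.grid[0])

    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    cov = (Xc.T @ Xc) / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValidationError("curves have zero variance; FPCA undefined")

    pve = np.cumsum(vals) / total
    n_comp = int(np.searchsorted(pve, config.pve_threshold) + 1)
    n_comp = min(n_comp, g, n - 1) or 1

    phi = vecs[:, :n_comp].T / np.sqrt(h)  # orthonormal under h-weighted quadrature
    # sign convention: largest-magnitude coefficient positive
    flip = np.sign(phi[np.arange(n_comp), np.abs(phi).argmax(axis=1)])
    flip[flip == 0] = 1.0
    phi = phi * flip[:, None]

    if smooth_eigenfunctions and g >= 8:
        n_knots = min(config.fpca_knots_cap, int(np.floor(config.fpca_knots_frac * g)))
        phi = np.vstack([_lsq_spline_smooth(trajectories.grid, f, n_knots) for f in phi])

    scores = (Xc @ phi.T) * h
    eigenvalues = vals[:n_comp] * h
    return FPCADecomposition(
        grid=trajectories.grid,
        mean_curve=mean_curve,
        eigenfunctions=phi,
        eigenvalues=eigenvalues,
        scores=scores,
        pve_cum=pve[:n_comp],
    )


def _lsq_spline_smooth(x: np.ndarray, y: np.ndarray, n_knots: int) -> np.ndarray:
    n_interior = max(min(n_knots, x.size - 6), 0)
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else []
    t = np.concatenate([[x[0]] * 4, interior, [x[-1]] * 4])
    spl = interpolate.make_lsq_spline(x, y, t, k=3)
    return spl(x)


# --------------------------------------------------------------------------- #
# fuzzy c-means
# --------------------------------------------------------------------------- #


def estimate_fuzzifier(n_items: int, n_features: int) -> float:
    """Dimension-based fuzzifier estimate of Schwammle & Jensen (2010).

    Always > 1 and decreasing in the feature dimension, so high-dimensional
    inputs get near-crisp memberships.
    """
    if n_items <= 1 or n_features < 1:
        raise ValidationError("need n_items > 1 and n_features >= 1")
    N, D = float(n_items), float(n_features)
    return float(
        1.0
        + (1418.0 / N + 22.05) * D**-2
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float | None = None,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on rows of X. Returns ``(centers, memberships)``.

    Memberships are computed in log space so that near-crisp fuzzifiers
    (m close to 1, typical for wide data) do not overflow. With
    ``n_init > 1`` the run with the lowest objective is kept.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if c > n:
        raise ValidationError(f"c={c} exceeds the number of items ({n})")
    if m is None:
        m = estimate_fuzzifier(n, X.shape[1])
    if m <= 1:
        raise ValidationError(f"fuzzifier must be > 1, got {m}")
    if n_init > 1:
        best = None
        for i in range(n_init):
            centers, u = fuzzy_cmeans(X, c, m=m, seed=seed + i, max_iter=max_iter, tol=tol)
            obj = float((u**m * _sq_dists(X, centers)).sum())
            if best is None or obj < best[0]:
                best = (obj, centers, u)
        return best[1], best[2]
    # D^2-weighted seeding: spreads initial centers across density modes,
    # avoiding the two-centroids-in-one-cluster local optima of uniform init
    centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed % (2**32))
    expo = 1.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = np.maximum(_sq_dists(X, centers), 1e-300)
        logu = -expo * np.log(d2)
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        um = u**m
        new_centers = (um.T @ X) / np.maximum(um.sum(axis=0)[:, None], 1e-300)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            break
    d2 = np.maximum(_sq_dists(X, centers), 1e-300)
    logu = -expo * np.log(d2)
    logu -= logu.max(axis=1, keepdims=True)
    u = np.exp(logu)
    u /= u.sum(axis=1, keepdims=True)
    return centers, u


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.maximum(
        (X**2).sum(axis=1)[:, None] - 2 * X @ C.T + (C**2).sum(axis=1)[None, :], 0.0
    )


def select_fuzzy_c(
    scores: np.ndarray,
    c_range: tuple[int, int] = (2, 20),
    repeats: int = 3,
    m: float | None = None,
    seed: int = 0,
    collapse_factor: float = 0.5,
) -> int:
    """Pick c by the minimum-centroid-distance heuristic over repeated runs.

    For each c the minimum pairwise centroid distance (minimum over
    ``repeats`` seeded runs) is recorded. Once c exceeds the number of real
    clusters, two centroids land in one cluster and the distance collapses
    from inter-cluster to within-cluster scale; the chosen c is the one just
    before the largest relative collapse, provided that drop exceeds
    ``collapse_factor`` (otherwise the distance never collapsed and c_max is
    returned with a warning).
    """
    X = np.asarray(scores, dtype=float)
    c_lo, c_hi = c_range
    c_hi = min(c_hi, X.shape[0] - 1)
    cs = list(range(c_lo, c_hi + 1))
    dmin = []
    for c in cs:
        best = np.inf
        for rep in range(repeats):
            centers, _ = fuzzy_cmeans(X, c, m=m, seed=seed * 1000 + c * 10 + rep)
            d = np.sqrt(_sq_dists(centers, centers))
            np.fill_diagonal(d, np.inf)
            best = min(best, float(d.min()))
        dmin.append(best)
    ratios = [
        dmin[i] / dmin[i - 1] if dmin[i - 1] > 0 else 1.0 for i in range(1, len(cs))
    ]
    if not ratios or min(ratios) >= collapse_factor:
        logger.warning("minimum centroid distance never collapsed; returning c_max=%d", cs[-1])
        return cs[-1]
    return cs[int(np.argmin(ratios))]


def select_kmeans_k(
    scores: np.ndarray,
    k_max: int = 20,
    restarts: int = 25,
    seed: int = 0,
) -> int:
    """Elbow selection on the total within-cluster sum of squares, k = 1..k_max.

    The elbow is the maximum-curvature (second-difference) point of the WCSS
    curve on a log scale: log-WCSS curvature is scale-invariant, so the elbow
    marks where splitting stops paying off multiplicatively rather than the
    first large absolute drop.
    """
    X = np.asarray(scores, dtype=float)
    k_max = min(k_max, X.shape[0])
    wcss = [float(((X - X.mean(axis=0)) ** 2).sum())]
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        wcss.append(float(km.inertia_))
    wcss = np.array(wcss)
    if len(wcss) < 3:
        return len(wcss)
    floor = max(wcss.max() * 1e-12, 1e-300)
    lw = np.log(np.maximum(wcss, floor))
    curvature = lw[:-2] - 2 * lw[1:-1] + lw[2:]  # index i -> k = i + 2
    k_opt = int(np.argmax(curvature) + 2)
    if wcss[0] <= 0 or curvature.max() < 0.05:
        logger.warning("no clear elbow in the WCSS curve; k_opt=%d is weakly supported", k_opt)
    return k_opt


# --------------------------------------------------------------------------- #
# clustering front-end
# --------------------------------------------------------------------------- #


def cluster_scores(
    scores: np.ndarray,
    method: str = "hdbscan",
    cpg_ids: list[str] | None = None,
    seed: int = 0,
    min_cluster_size: int = 5,
    c: int | None = None,
    m: float | None = None,
    k: int | None = None,
    restarts: int = 25,
) -> ClusterAssignment:
    """Cluster FPCA scores (or any feature matrix) by the chosen algorithm.

    density method: noise points get label 0, clusters 1..c. fuzzy: hard label
    = argmax membership (labels 1..c), memberships returned. kmeans: labels
    1..k, ``restarts`` random initialisations.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    ids = cpg_ids if cpg_ids is not None else [f"item_{i}" for i in range(n)]
    if method == "hdbscan":
        if n < min_cluster_size:
            raise ValidationError(f"need at least min_cluster_size={min_cluster_size} items")
        raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)
        labels = np.where(raw < 0, 0, raw + 1)
        return ClusterAssignment(ids, labels.astype(int), "hdbscan")
    if method == "fuzzy":
        if c is None:
            c = select_fuzzy_c(X, m=m, seed=seed)
        if c > n:
            raise ValidationError(f"c={c} exceeds n={n}")
        _, u = fuzzy_cmeans(X, c, m=m, seed=seed, n_init=3)
        labels = u.argmax(axis=1) + 1
        return ClusterAssignment(ids, labels.astype(int), "fuzzy", memberships=u)
    if method == "kmeans":
        if k is None:
            k = select_kmeans_k(X, restarts=restarts, seed=seed)
        if k > n:
            raise ValidationError(f"k={k} exceeds n={n}")
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        if np.unique(km.labels_).size < k:  # empty cluster: re-seeded restart
            logger.warning("empty k-means cluster; re-running with a shifted seed")
            km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + 1).fit(X)
        return ClusterAssignment(ids, (km.labels_ + 1).astype(int), "kmeans")
    raise ValidationError(f"unknown clustering method {method!r}")


def recluster_noise(
    assignment: ClusterAssignment,
    scores: np.ndarray,
    target_label: int,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> ClusterAssignment:
    """Re-cluster one density-based cluster in its score subspace.

    Sub-clusters of target t get labels 10*t, 10*t + 1, ... (the first holds
    points the refinement still calls noise). A homogeneous target — at most
    one sub-cluster found — leaves the assignment unchanged; other CpGs are
    never touched.
    """
    if assignment.method != "hdbscan":
        raise ValidationError("noise re-clustering is defined for the density method only")
    X = np.asarray(scores, dtype=float)
    mask = assignment.labels == target_label
    if mask.sum() < max(min_cluster_size, 2):
        return assignment
    sub = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X[mask])
    sub = np.where(sub < 0, 0, sub + 1)
    if np.unique(sub).size <= 1:
        return assignment
    labels = assignment.labels.copy()
    labels[mask] = 10 * target_label + sub
    return ClusterAssignment(assignment.cpg_ids, labels, "hdbscan")


# --------------------------------------------------------------------------- #
# cluster summaries and merging
# --------------------------------------------------------------------------- #


def cluster_eigenvalues(
    beta: BetaMatrix,
    member_cpgs: list[str],
) -> np.ndarray:
    """Per-sample score on PC1 of the cluster's centered-and-scaled betas.

    The sign is oriented so the score correlates positively with the
    cluster's mean methylation across samples; CpGs absent from the matrix
    are dropped (cross-array intersection), needing at least one survivor.
    """
    present = [c for c in member_cpgs if c in beta.frame.index]
    if not present:
        raise ValidationError("no member CpGs present in the beta matrix")
    rows = beta.frame.loc[present].to_numpy()
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (rows - mu) / sd  # CpGs x samples
    if len(present) == 1:
        scores = Z[0].copy()
    else:
        M = Z.T  # samples x CpGs
        M = M - M.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(M, full_matrices=False)
        scores = u[:, 0] * s[0]
    mean_meth = rows.mean(axis=0)
    if np.std(mean_meth) > 0 and np.corrcoef(scores, mean_meth)[0, 1] < 0:
        scores = -scores
    return scores


def mean_cluster_trajectory(
    trajectories: SmoothedTrajectorySet,
    member_cpgs: list[str],
    standardize: bool = False,
) -> np.ndarray:
    """Pointwise mean of the (optionally per-curve z-scored) member curves."""
    sub = trajectories.subset(member_cpgs)
    curves = sub.standardized() if standardize else sub.curves
    return curves.mean(axis=0)


def build_cluster_profiles(
    assignment: ClusterAssignment,
    trajectories: SmoothedTrajectorySet,
    beta: BetaMatrix,
    standardize: bool = True,
) -> list[ClusterProfile]:
    profiles = []
    for label in sorted(np.unique(assignment.labels)):
        members = assignment.members(int(label))
        profiles.append(
            ClusterProfile(
                cluster_id=int(label),
                mean_trajectory=mean_cluster_trajectory(trajectories, members, standardize),
                eigen_sample_scores=cluster_eigenvalues(beta, members),
                n_cpgs=len(members),
                cpg_ids=members,
            )
        )
    return profiles


@dataclass
class MergeResult:
    profiles: list[ClusterProfile]
    label_map: dict[int, int]
    log: pd.DataFrame
    assignment: ClusterAssignment | None = None


def merge_correlated_clusters(
    profiles: list[ClusterProfile],
    trajectories: SmoothedTrajectorySet,
    beta: BetaMatrix,
    rho_threshold: float = 0.90,
    assignment: ClusterAssignment | None = None,
    exclude_noise: bool = True,
    standardize: bool = True,
) -> MergeResult:
    """Merge redundant clusters by single linkage on the Spearman-rho graph.

    Pairs of cluster eigen-sample scores with rho > ``rho_threshold`` are
    linked; connected components merge into one cluster (keeping the smallest
    member id) whose profile is recomputed from the union of CpGs. The noise
    cluster 0, when present, is kept out of the graph by default.
    """
    eligible = [p for p in profiles if not (exclude_noise and p.cluster_id == 0)]
    ids = [p.cluster_id for p in eligible]
    parent = {i: i for i in ids}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    records = []
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            rho = stats.spearmanr(
                eligible[i].eigen_sample_scores, eligible[j].eigen_sample_scores
            ).statistic
            merged = bool(rho > rho_threshold)
            records.append({"cluster_a": ids[i], "cluster_b": ids[j],
                            "spearman_rho": float(rho), "merged": merged})
            if merged:
                ra, rb = find(ids[i]), find(ids[j])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    label_map = {i: find(i) for i in ids}
    for p in profiles:
        if p.cluster_id not in label_map:
            label_map[p.cluster_id] = p.cluster_id

    merged_profiles = []
    for root in sorted(set(label_map.values())):
        members: list[str] = []
        for p in profiles:
            if label_map[p.cluster_id] == root:
                members.extend(p.cpg_ids)
        merged_profiles.append(
            ClusterProfile(
                cluster_id=root,
                mean_trajectory=mean_cluster_trajectory(trajectories, members, standardize),
                eigen_sample_scores=cluster_eigenvalues(beta, members),
                n_cpgs=len(members),
                cpg_ids=members,
            )
        )

    new_assignment = None
    if assignment is not None:
        new_labels = np.array([label_map.get(int(l), int(l)) for l in assignment.labels])
        new_assignment = ClusterAssignment(assignment.cpg_ids, new_labels, assignment.method)
    return MergeResult(
        profiles=merged_profiles,
        label_map=label_map,
        log=pd.DataFrame.from_records(records),
        assignment=new_assignment,
    )


def compare_cohort_trajectories(
    traj_a: np.ndarray,
    grid_a: np.ndarray,
    traj_b: np.ndarray,
    grid_b: np.ndarray,
) -> float:
    """Pearson correlation of two mean trajectories on their age overlap.

    Curves are linearly interpolated onto a common grid spanning the shared
    age support before correlating.
    """
    grid_a, grid_b = np.asarray(grid_a, float), np.asarray(grid_b, float)
    lo, hi = max(grid_a.min(), grid_b.min()), min(grid_a.max(), grid_b.max())
    if hi <= lo:
        raise ValidationError("trajectories have no overlapping age support")
    common = np.linspace(lo, hi, 200)
    a = np.interp(common, grid_a, np.asarray(traj_a, float))
    b = np.interp(common, grid_b, np.asarray(traj_b, float))
    return float(stats.pearsonr(a, b).statistic)
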