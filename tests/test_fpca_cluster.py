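import numpy as np
import pytest

from snitch.fpca_cluster import (
    ClusterProfile,
    SmoothedTrajectorySet,
    build_cluster_profiles,
    cluster_eigenvalues,
    cluster_scores,
    compare_cohort_trajectories,
    estimate_fuzzifier,
    fuzzy_cmeans,
    mean_cluster_trajectory,
    merge_correlated_clusters,
    recluster_noise,
    run_fpca,
    select_fuzzy_c,
    select_kmeans_k,
)
from snitch.io import AnalysisConfig, BetaMatrix, ValidationError

import pandas as pd


def _traj(curves, grid=None):
    curves = np.atleast_2d(curves)
    grid = np.arange(curves.shape[1], dtype=float) if grid is None else grid
    return SmoothedTrajectorySet(
        cpg_ids=[f"cg{i}" for i in range(curves.shape[0])], grid=grid, curves=curves
    )


def _blobs(rng, centers, n_per=30, sd=0.05):
    X = np.vstack([c + sd * rng.standard_normal((n_per, len(c))) for c in centers])
    truth = np.repeat(np.arange(len(centers)), n_per)
    return X, truth


class TestFPCA:
    def test_rank_one_input_yields_single_component(self, rng):
        grid = np.arange(0.0, 50.0)
        f = np.sin(grid / 8.0)
        a = rng.normal(0, 2, 50)
        curves = 0.5 + a[:, None] * f[None, :]
        fp = run_fpca(_traj(curves, grid), standardize=False)
        assert fp.eigenfunctions.shape[0] == 1
        assert fp.pve_cum[0] == pytest.approx(1.0, abs=1e-9)
        r = np.corrcoef(fp.scores[:, 0], a)[0, 1]
        assert r**2 > 0.999

    def test_rank_two_variance_split(self, rng):
        grid = np.arange(0.0, 100.0)
        h = 1.0
        f1 = np.sin(2 * np.pi * grid / 100) * np.sqrt(2 / (100 * h))
        f2 = np.cos(2 * np.pi * grid / 100) * np.sqrt(2 / (100 * h))
        a = rng.normal(0, 3, 600)
        b = rng.normal(0, 1, 600)
        curves = a[:, None] * f1 + b[:, None] * f2
        fp = run_fpca(_traj(curves, grid), standardize=False)
        assert fp.pve_cum[0] == pytest.approx(0.90, abs=0.02)

    def test_reconstruction_error_bounded_by_pve(self, rng):
        grid = np.arange(0.0, 80.0)
        basis = np.vstack(
            [np.sin(2 * np.pi * k * grid / 80) + np.cos(np.pi * k * grid / 80)
             for k in range(1, 6)]
        )
        weights = rng.normal(0, [[3], [2], [1], [0.5], [0.2]], size=(5, 120))
        curves = (weights.T @ basis) + 0.5
        fp = run_fpca(_traj(curves, grid), standardize=False)
        recon = fp.reconstruct()
        centered = curves - curves.mean(axis=0)
        rel_err = np.linalg.norm(curves - recon) ** 2 / np.linalg.norm(centered) ** 2
        assert rel_err <= 1e-4  # 1 - PVE threshold

    def test_eigenfunctions_orthonormal_under_quadrature(self, rng):
        grid = np.arange(0.0, 60.0, 2.0)
        curves = rng.normal(0.5, 0.1, (40, grid.size))
        fp = run_fpca(_traj(curves, grid), standardize=False)
        h = grid[1] - grid[0]
        gram = h * fp.eigenfunctions @ fp.eigenfunctions.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-6)
        assert (np.diff(fp.pve_cum) >= -1e-12).all()
        assert fp.pve_cum[-1] >= 0.9999

    def test_single_curve_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            run_fpca(_traj(np.ones((1, 10))))

    def test_deterministic_scores(self, rng):
        grid = np.arange(0.0, 50.0)
        curves = rng.uniform(0.2, 0.8, (30, 50))
        t = _traj(curves, grid)
        f1, f2 = run_fpca(t), run_fpca(t)
        assert np.array_equal(f1.scores, f2.scores)


class TestFuzzifier:
    @pytest.mark.parametrize("n,d", [(10, 2), (100, 5), (3000, 10), (3000, 300)])
    def test_always_above_one(self, n, d):
        assert estimate_fuzzifier(n, d) > 1.0

    def test_decreasing_in_dimension(self):
        assert estimate_fuzzifier(3000, 10) > estimate_fuzzifier(3000, 100)

    def test_matches_published_formula(self):
        n, d = 1234, 17
        expected = 1 + (1418 / n + 22.05) * d**-2 + (12.33 / n + 0.243) * d ** (
            -0.0406 * np.log(n) - 0.1134
        )
        assert estimate_fuzzifier(n, d) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValidationError):
            estimate_fuzzifier(1, 5)


class TestClustering:
    @pytest.mark.parametrize("method,kw", [
        ("hdbscan", {}),
        ("fuzzy", {"c": 3}),
        ("kmeans", {"k": 3}),
    ])
    def test_separated_blobs_recovered_exactly(self, rng, method, kw):
        from sklearn.metrics import adjusted_rand_score

        X, truth = _blobs(rng, [(0, 0), (5, 5), (-5, 5)])
        assignment = cluster_scores(X, method=method, seed=0, **kw)
        assert adjusted_rand_score(truth, assignment.labels) == 1.0

    def test_density_method_calls_uniform_noise_mostly_noise(self, rng):
        """On structureless data the density method designates the bulk of
        points as noise (label 0) rather than inventing a dominant cluster."""
        fracs = []
        for seed in range(3):
            X = np.random.default_rng(seed).uniform(0, 1, size=(300, 8))
            assignment = cluster_scores(X, method="hdbscan", min_cluster_size=5)
            noise = (assignment.labels == 0).mean()
            fracs.append(noise)
            _, counts = np.unique(assignment.labels, return_counts=True)
            assert (assignment.labels == 0).sum() == counts.max()  # noise is modal
        assert np.mean(fracs) > 0.5

    def test_fuzzy_memberships_row_stochastic(self, rng):
        X, _ = _blobs(rng, [(0, 0), (4, 4)])
        assignment = cluster_scores(X, method="fuzzy", c=2, seed=1)
        assert np.allclose(assignment.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(
            assignment.labels, assignment.memberships.argmax(axis=1) + 1
        )

    def test_select_fuzzy_c_finds_four_blobs(self, rng):
        X, _ = _blobs(rng, [(0, 0), (6, 0), (0, 6), (6, 6)], n_per=40)
        assert select_fuzzy_c(X, c_range=(2, 8), seed=0) == 4

    def test_select_fuzzy_c_returns_cmax_when_range_too_small(self, rng, caplog):
        X, _ = _blobs(rng, [(0, 0), (8, 0), (0, 8), (8, 8), (16, 8)], n_per=30)
        import logging

        with caplog.at_level(logging.WARNING):
            c = select_fuzzy_c(X, c_range=(2, 3), seed=0)
        assert c == 3

    def test_select_fuzzy_c_deterministic(self, rng):
        X, _ = _blobs(rng, [(0, 0), (6, 0), (0, 6)], n_per=25)
        assert select_fuzzy_c(X, seed=3) == select_fuzzy_c(X, seed=3)

    def test_select_kmeans_k_finds_five_blobs(self, rng):
        X, _ = _blobs(rng, [(0, 0), (8, 0), (0, 8), (8, 8), (4, 16)], n_per=40)
        assert select_kmeans_k(X, k_max=12, restarts=10) == 5

    def test_kmeans_wcss_non_increasing(self, rng):
        from sklearn.cluster import KMeans

        X, _ = _blobs(rng, [(0, 0), (5, 5)], n_per=50)
        wcss = [KMeans(n_clusters=k, n_init=10, random_state=0).fit(X).inertia_
                for k in range(1, 8)]
        assert (np.diff(wcss) <= 1e-9).all()

    def test_fuzzy_near_crisp_fuzzifier_stable(self, rng):
        # wide data drives the fuzzifier toward 1; memberships must not overflow
        X, truth = _blobs(rng, [tuple(np.zeros(200)), tuple(np.ones(200) * 3)], n_per=20)
        m = estimate_fuzzifier(*X.shape)
        assert m < 1.2
        _, u = fuzzy_cmeans(X, 2, m=m, seed=0)
        assert np.isfinite(u).all()


class TestNoiseReclustering:
    def test_two_subblobs_split_with_decimal_labels(self, rng):
        X, _ = _blobs(rng, [(0, 0), (10, 10), (10.8, 10.8)], n_per=25)
        base = cluster_scores(X, method="hdbscan", min_cluster_size=5)
        # find the label covering the two close blobs (they merge at base scale)
        labels, counts = np.unique(base.labels[base.labels > 0], return_counts=True)
        target = int(labels[np.argmax(counts)])
        refined = recluster_noise(base, X, target, min_cluster_size=5)
        new = set(refined.labels[base.labels == target])
        if len(new) > 1:  # refinement split the target
            assert all(l // 10 == target for l in new)
        untouched = base.labels != target
        assert np.array_equal(refined.labels[untouched], base.labels[untouched])

    def test_homogeneous_target_unchanged(self, rng):
        X, _ = _blobs(rng, [(0, 0), (8, 8)], n_per=30)
        base = cluster_scores(X, method="hdbscan", min_cluster_size=5)
        refined = recluster_noise(base, X, 1, min_cluster_size=5)
        assert np.array_equal(refined.labels, base.labels)


def _profile_setup(rng, eigen_scores):
    """Build profiles + matching beta/trajectories for the given per-cluster
    eigen score vectors (one CpG row per cluster replicates its score)."""
    n_samples = len(next(iter(eigen_scores.values())))
    grid = np.arange(0.0, 20.0)
    rows, ids = [], []
    for cid, score in eigen_scores.items():
        for j in range(3):
            noise = 0.001 * rng.standard_normal(n_samples)
            rows.append(0.5 + 0.1 * (np.asarray(score) + noise))
            ids.append(f"c{cid}_cg{j}")
    beta = BetaMatrix(
        pd.DataFrame(
            np.clip(np.vstack(rows), 0, 1),
            index=ids,
            columns=[f"s{i}" for i in range(n_samples)],
        )
    )
    curves = np.clip(0.5 + 0.01 * rng.standard_normal((len(ids), grid.size)), 0, 1)
    traj = SmoothedTrajectorySet(cpg_ids=ids, grid=grid, curves=curves)
    profiles = [
        ClusterProfile(
            cluster_id=cid,
            mean_trajectory=curves[:3].mean(axis=0),
            eigen_sample_scores=np.asarray(eigen_scores[cid], dtype=float),
            n_cpgs=3,
            cpg_ids=[f"c{cid}_cg{j}" for j in range(3)],
        )
        for cid in eigen_scores
    ]
    return profiles, traj, beta


class TestMerging:
    def test_identical_scores_merge(self, rng):
        s = rng.normal(size=60)
        profiles, traj, beta = _profile_setup(rng, {1: s, 2: s})
        merged = merge_correlated_clusters(profiles, traj, beta)
        assert len(merged.profiles) == 1
        assert merged.label_map == {1: 1, 2: 1}

    def test_uncorrelated_scores_not_merged(self, rng):
        profiles, traj, beta = _profile_setup(
            rng, {1: rng.normal(size=60), 2: rng.normal(size=60)}
        )
        merged = merge_correlated_clusters(profiles, traj, beta)
        assert len(merged.profiles) == 2

    def test_chain_merges_by_single_linkage(self, rng):
        """A~B and B~C above threshold merges all three even though A~C is not."""
        from scipy.stats import spearmanr

        n = 200
        for seed in range(50):
            r = np.random.default_rng(seed)
            z = r.normal(size=n)
            a = z + 0.28 * r.normal(size=n)
            b = z + 0.28 * r.normal(size=n)
            c = b + 0.45 * r.normal(size=n)
            rab = spearmanr(a, b).statistic
            rbc = spearmanr(b, c).statistic
            rac = spearmanr(a, c).statistic
            if rab > 0.9 and rbc > 0.9 and rac < 0.9:
                break
        else:
            pytest.fail("could not construct the chain configuration")
        profiles, traj, beta = _profile_setup(rng, {1: a, 2: b, 3: c})
        merged = merge_correlated_clusters(profiles, traj, beta)
        assert len(merged.profiles) == 1  # transitive closure

    def test_merge_idempotent(self, rng):
        s = rng.normal(size=60)
        profiles, traj, beta = _profile_setup(rng, {1: s, 2: s, 3: rng.normal(size=60)})
        once = merge_correlated_clusters(profiles, traj, beta)
        twice = merge_correlated_clusters(once.profiles, traj, beta)
        assert [p.cluster_id for p in twice.profiles] == [p.cluster_id for p in once.profiles]
        assert all(
            set(p.cpg_ids) == set(q.cpg_ids)
            for p, q in zip(twice.profiles, once.profiles)
        )


class TestClusterSummaries:
    def test_eigen_scores_of_identical_rows(self, rng):
        common = np.clip(0.5 + 0.2 * np.sin(np.arange(40) / 5.0), 0, 1)
        beta = BetaMatrix(
            pd.DataFrame(
                np.tile(common, (4, 1)),
                index=[f"cg{i}" for i in range(4)],
                columns=[f"s{i}" for i in range(40)],
            )
        )
        scores = cluster_eigenvalues(beta, beta.cpg_ids)
        standardized = (common - common.mean()) / common.std()
        r = np.corrcoef(scores, standardized)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_orientation_positive_against_mean_methylation(self, rng):
        rows = np.clip(rng.uniform(0.3, 0.7, (6, 50)) + 0.1 * rng.standard_normal((6, 50)), 0, 1)
        beta = BetaMatrix(
            pd.DataFrame(rows, index=[f"cg{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(50)])
        )
        scores = cluster_eigenvalues(beta, beta.cpg_ids)
        assert np.corrcoef(scores, rows.mean(axis=0))[0, 1] > 0

    def test_mean_trajectory_basics(self, rng):
        grid = np.arange(0.0, 30.0)
        c1 = 0.4 + 0.2 * np.sin(grid / 4)
        t = _traj(np.vstack([c1, c1, c1]), grid)
        assert np.allclose(mean_cluster_trajectory(t, t.cpg_ids), c1)
        assert np.allclose(mean_cluster_trajectory(t, ["cg0"]), c1)
        # mirror-image standardized curves cancel
        t2 = _traj(np.vstack([c1, 0.8 - c1]), grid)
        m = mean_cluster_trajectory(t2, t2.cpg_ids, standardize=True)
        assert np.max(np.abs(m)) < 1e-9

    def test_compare_cohort_trajectories(self, rng):
        grid_a = np.arange(10.0, 90.0)
        grid_b = np.arange(20.0, 95.0, 1.0)
        sig = lambda g: 1 / (1 + np.exp(-(g - 50) / 5))
        assert compare_cohort_trajectories(sig(grid_a), grid_a, sig(grid_b), grid_b) == (
            pytest.approx(1.0, abs=1e-9)
        )
        assert compare_cohort_trajectories(
            sig(grid_a), grid_a, -sig(grid_a), grid_a
        ) == pytest.approx(-1.0, abs=1e-9)
        noisy = sig(grid_b) + 0.01 * rng.standard_normal(grid_b.size)
        assert compare_cohort_trajectories(sig(grid_a), grid_a, noisy, grid_b) > 0.99
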