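import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import gapwave as gw


def brute_force_medoids(d, k):
    """Exhaustive search over all medoid subsets; returns (cost, medoids)."""
    n = d.shape[0]
    best = (np.inf, None)
    for combo in itertools.combinations(range(n), k):
        cost = d[list(combo)].min(axis=0).sum()
        if cost < best[0] - 1e-12:
            best = (cost, combo)
    return best


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        z = gw.zscale(np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]]))
        d = gw.correlation_distance(z)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_distance_two(self):
        x = np.array([1.0, 3, 2, 5])
        d = gw.correlation_distance(np.vstack([x, -x]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_uncorrelated_profiles_distance_one(self):
        d = gw.correlation_distance(np.array([[1.0, 2, 1, 2], [1.0, 1, 2, 2]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_symmetry_zero_diagonal_and_range(self, rng):
        v = rng.normal(size=(12, 8))
        d = gw.correlation_distance(v)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)
        assert np.all((d >= 0) & (d <= 2))

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            gw.correlation_distance(np.array([[1.0, 1, 1], [1.0, 2, 3]]))


class TestPamCluster:
    def test_k_equals_n_zero_cost(self, rng):
        v = rng.normal(size=(5, 4))
        d = gw.correlation_distance(v)
        res = gw.pam_cluster(d, 5)
        assert res.total_cost == pytest.approx(0.0)
        assert sorted(res.medoids) == list(range(5))

    def test_one_dim_hand_oracle(self):
        pts = np.array([0.0, 1.0, 10.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = gw.pam_cluster(d, 1)
        assert list(res.medoids) == [1]          # costs 11, 10, 19
        assert res.total_cost == pytest.approx(10.0)

    def test_invalid_k_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            gw.pam_cluster(d, 4)

    @pytest.mark.parametrize("n_groups,sizes", [(2, (3, 4)), (2, (4, 4)),
                                                (3, (2, 3, 3)), (3, (3, 3, 2))])
    def test_matches_brute_force_on_grouped_data(self, n_groups, sizes):
        """With k = number of planted groups, BUILD+SWAP attains the
        exhaustive-search optimum (n <= 8, k <= 3)."""
        centers = np.array([[0.0, 0], [6, 0], [0, 6]])[:n_groups]
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = np.vstack([c + rng.normal(0, 0.5, size=(s, 2))
                             for c, s in zip(centers, sizes)])
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            res = gw.pam_cluster(d, n_groups)
            best_cost, _ = brute_force_medoids(d, n_groups)
            assert res.total_cost == pytest.approx(best_cost)

    def test_result_is_single_swap_optimal(self):
        """No medoid/non-medoid exchange can lower the final cost (the
        algorithm's convergence guarantee, on arbitrary instances)."""
        for seed in range(6):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(9, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            res = gw.pam_cluster(d, 3)
            medoids = list(res.medoids)
            for j in range(3):
                for h in range(9):
                    if h in medoids:
                        continue
                    trial = medoids[:j] + medoids[j + 1:] + [h]
                    cost = d[trial].min(axis=0).sum()
                    assert cost >= res.total_cost - 1e-9

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_reference_pam_cost(self, tmp_path):
        """Independent oracle: the canonical PAM in R's cluster package
        reaches the same total cost on random dissimilarities."""
        costs_r, costs_py = [], []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n, k = int(rng.integers(8, 14)), int(rng.integers(2, 4))
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            np.savetxt(tmp_path / "d.tsv", d, delimiter="\t")
            script = tmp_path / "pam.R"
            script.write_text(
                f'd <- as.matrix(read.table("{tmp_path / "d.tsv"}"))\n'
                'suppressMessages(library(cluster))\n'
                f'p <- pam(as.dist(d), {k})\n'
                'cat(sprintf("%.12f", sum(apply(d[p$id.med,,drop=FALSE],2,min))))\n')
            out = subprocess.run(["Rscript", str(script)], check=True,
                                 capture_output=True, text=True)
            costs_r.append(float(out.stdout.strip()))
            costs_py.append(gw.pam_cluster(d, k).total_cost)
        np.testing.assert_allclose(costs_py, costs_r, rtol=1e-9)

    def test_two_planted_groups_recovered(self, rng):
        a = np.array([0.0, 1, 2, 3, 4, 5]) + rng.normal(0, 0.05, size=(10, 6))
        b = np.array([5.0, 3, 4, 1, 2, 0]) + rng.normal(0, 0.05, size=(10, 6))
        d = gw.correlation_distance(np.vstack([a, b]))
        res = gw.pam_cluster(d, 2)
        labels = res.labels
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_medoids_labelled_to_own_cluster(self, rng):
        v = rng.normal(size=(15, 6))
        d = gw.correlation_distance(v)
        res = gw.pam_cluster(d, 3)
        for pos, m in enumerate(res.medoids):
            assert res.labels[m] == pos


class TestChooseK:
    @staticmethod
    def planted(archetype_count, per, rng, noise=0.05):
        bases = [np.sin(np.linspace(0, 3, 10) + i * 2.0) for i in range(archetype_count)]
        rows = [b + rng.normal(0, noise, 10) for b in bases for _ in range(per)]
        return np.vstack(rows)

    def test_two_archetypes_give_two(self, rng):
        z = gw.zscale(self.planted(2, 12, rng))
        d = gw.correlation_distance(z)
        assert gw.choose_k(d, z, k_range=(2, 6)) == 2

    def test_five_archetypes_give_five(self, small_run):
        assert small_run["clusters"].k == 5

    def test_single_archetype_falls_back_to_two_with_warning(self, rng):
        z = gw.zscale(self.planted(1, 20, rng))
        d = gw.correlation_distance(z)
        with pytest.warns(UserWarning, match="falling back"):
            assert gw.choose_k(d, z, k_range=(2, 5)) == 2


class TestMedianZProfiles:
    def test_single_member_cluster_is_its_z_profile(self):
        m = gw.ExpressionMatrix([[1.0, 2, 3], [9.0, 1, 5]], ["a", "b"], [3, 7, 10], "log2")
        prof = gw.median_z_profiles(m, [0, 1])
        np.testing.assert_allclose(prof.loc[0], gw.zscale(m.values)[0])

    def test_mirror_members_give_zero_profile(self):
        x = np.array([1.0, 4, 2, 6])
        m = gw.ExpressionMatrix(np.vstack([x, -x]), ["a", "b"], [3, 7, 10, 14], "log2")
        prof = gw.median_z_profiles(m, [0, 0])
        np.testing.assert_allclose(prof.loc[0], 0, atol=1e-12)

    def test_noiseless_archetype_recovered_exactly(self):
        arch = gw.ArchetypeSpec("late_spermatids", 27, 0.95, 4.5, 3)
        days = np.array(gw.DEFAULT_SAMPLING_DAYS)
        prof = arch.log2_profile(days)
        m = gw.ExpressionMatrix(np.tile(prof, (3, 1)) + 8.0,
                                list("abc"), days, "log2")
        out = gw.median_z_profiles(m, [0, 0, 0])
        np.testing.assert_allclose(out.loc[0], gw.zscale(prof[None, :])[0], atol=1e-12)

    def test_empty_cluster_rejected(self):
        m = gw.ExpressionMatrix([[1.0, 2, 3]], ["a"], [3, 7, 10], "log2")
        with pytest.raises(ValueError):
            gw.median_z_profiles(m, [0, 1])


class TestClusterResult:
    def test_swap_cost_not_worse_than_build_only(self, rng):
        """Full PAM cost can never exceed the greedy initialisation's cost."""
        v = rng.normal(size=(40, 8))
        d = gw.correlation_distance(v)
        res = gw.pam_cluster(d, 4)
        # any k-subset containing the BUILD choices costs >= the final cost
        for seed in range(5):
            rng2 = np.random.default_rng(seed)
            combo = rng2.choice(40, size=4, replace=False)
            assert res.total_cost <= d[combo].min(axis=0).sum() + 1e-9

    def test_cluster_sizes_and_labels_consistent(self, small_run):
        res = small_run["clusters"]
        assert res.cluster_sizes().sum() == len(res.labels)
        assert set(res.labels.unique()) == set(range(1, res.k + 1))
        for mid in res.medoid_ids:
            assert mid in res.labels.index
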