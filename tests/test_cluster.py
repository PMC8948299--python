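"""PAM, silhouettes, k selection, ARI and the sensitivity variants."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import mmclust as m
from mmclust.cluster import pam, select_k, silhouette
from mmclust.errors import ParameterError


def exhaustive_cost(D, k):
    n = D.shape[0]
    return min(
        D[:, list(c)].min(axis=1).sum() for c in itertools.combinations(range(n), k)
    )


def random_dissimilarity(seed, n):
    rng = np.random.default_rng(seed)
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestPam:
    def test_one_dimensional_worked_example(self):
        pts = np.array([0.0, 1.0, 9.0, 10.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = pam(D, 2)
        assert res.total_cost == pytest.approx(2.0, abs=1e-12)
        assert list(res.medoids) == [1, 2]  # both BUILD ties break low
        assert list(res.assignment) == [0, 0, 1, 1]
        assert res.n_swaps == 0

    def test_zero_cost_with_duplicate_points(self):
        row = np.array([[0, 1], [0, 1], [5, 5], [5, 5]])
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(row))
        res = pam(D, 2)
        assert res.total_cost == 0.0

    def test_invariants(self):
        D = random_dissimilarity(0, 15)
        res = pam(D, 3)
        # medoids assigned to themselves, everyone to the nearest medoid
        for pos, mi in enumerate(res.medoids):
            assert res.assignment[mi] == pos
        nearest = D[:, res.medoids].argmin(axis=1)
        assert (nearest == res.assignment).all()
        recomputed = D[np.arange(15), res.medoids[res.assignment]].sum()
        assert res.total_cost == pytest.approx(recomputed, abs=1e-12)

    def test_parameter_errors(self):
        D = random_dissimilarity(1, 6)
        for k in (1, 6, 7):
            with pytest.raises(ParameterError):
                pam(D, k)
        with pytest.raises(ParameterError):
            pam(np.arange(9.0).reshape(3, 3), 2)  # not symmetric

    def test_swap_local_optimum_certificate(self):
        """No single medoid/non-medoid exchange can improve the solution."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 14))
            D = random_dissimilarity(100 + seed, n)
            for k in (2, 3):
                res = pam(D, k)
                med = set(res.medoids.tolist())

                def cost(ms):
                    return D[:, sorted(ms)].min(axis=1).sum()

                for mi in med:
                    for h in set(range(n)) - med:
                        assert cost((med - {mi}) | {h}) >= res.total_cost - 1e-12

    def test_usually_attains_exhaustive_minimum(self):
        """The swap local optimum coincides with the global optimum on a
        clear majority of random instances (it is not guaranteed to)."""
        hits = total = 0
        for seed in range(40):
            D = random_dissimilarity(seed, 10)
            for k in (2, 3):
                total += 1
                if pam(D, k).total_cost <= exhaustive_cost(D, k) + 1e-12:
                    hits += 1
        assert hits / total >= 0.75

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_reference_r_implementation(self, tmp_path):
        """Total cost agrees with R's cluster::pam on random matrices."""
        mats = {seed: random_dissimilarity(seed, 12) for seed in (0, 1, 2)}
        for seed, D in mats.items():
            np.savetxt(tmp_path / f"D_{seed}.txt", D)
        script = tmp_path / "pam.R"
        script.write_text(
            "library(cluster)\n"
            "for (s in c(0,1,2)) {\n"
            f"  D <- as.matrix(read.table(file.path('{tmp_path}', sprintf('D_%d.txt', s))))\n"
            "  for (k in c(2,3)) {\n"
            "    p <- pam(as.dist(D), k, diss=TRUE)\n"
            "    cost <- sum(apply(D[, p$id.med, drop=FALSE], 1, min))\n"
            "    cat(sprintf('%d %d %.12f\\n', s, k, cost))\n"
            "  }\n"
            "}\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        for line in out.stdout.strip().splitlines():
            s, k, cost = line.split()
            res = pam(mats[int(s)], int(k))
            assert res.total_cost == pytest.approx(float(cost), abs=1e-9)


class TestSilhouette:
    def test_three_point_worked_example(self):
        pts = np.array([0.0, 1.0, 10.0])
        D = np.abs(pts[:, None] - pts[None, :])
        s, avg = silhouette(D, [0, 0, 1])
        assert s[0] == pytest.approx(0.9, abs=1e-12)
        assert s[1] == pytest.approx(8 / 9, abs=1e-12)
        assert s[2] == 0.0  # singleton convention
        assert avg == pytest.approx((0.9 + 8 / 9) / 3, abs=1e-12)

    def test_separated_identical_clusters_score_one(self):
        D = np.zeros((4, 4))
        D[:2, 2:] = 1.0
        D[2:, :2] = 1.0
        s, avg = silhouette(D, [0, 0, 1, 1])
        assert (s == 1.0).all() and avg == 1.0

    def test_all_identical_points_score_zero(self):
        D = np.zeros((4, 4))
        s, avg = silhouette(D, [0, 0, 1, 1])
        assert (s == 0.0).all() and avg == 0.0

    def test_single_cluster_rejected(self):
        D = random_dissimilarity(0, 5)
        with pytest.raises(ParameterError):
            silhouette(D, [0, 0, 0, 0, 0])

    def test_relabelling_invariance_and_sklearn_agreement(self):
        from sklearn.metrics import silhouette_samples

        D = random_dissimilarity(7, 25)
        labels = np.random.default_rng(7).integers(0, 3, 25)
        s, avg = silhouette(D, labels)
        assert np.abs(s).max() <= 1.0
        s2, avg2 = silhouette(D, (labels + 1) % 3)
        assert avg == pytest.approx(avg2, abs=1e-12)
        ref = silhouette_samples(D, labels, metric="precomputed")
        assert np.abs(s - ref).max() < 1e-9


class TestSelectK:
    def test_recovers_three_planted_groups(self, default_demographics):
        weights, profiles = m.well_separated_profiles(n_groups=3)
        cfg = m.SimulationConfig(
            n_patients=300,
            group_weights=weights,
            condition_profiles=profiles,
            demographics={"groups": default_demographics["groups"][:3],
                          "background": default_demographics["background"]},
            multimorbid_fraction=1.0,
            missing_id_rate=0.0,
            missing_postcode_rate=0.0,
            seed=2,
        )
        _, truth = m.generate_population(cfg)
        M = truth.drop(columns=["patient_id", "group"])
        trace = select_k(m.jaccard_matrix(M), range(2, 7))
        assert trace.chosen_k == 3
        assert m.adjusted_rand(truth["group"], trace.best.assignment) > 0.9

    def test_singleton_grid(self):
        D = random_dissimilarity(3, 12)
        trace = select_k(D, [2])
        assert trace.chosen_k == 2

    def test_empty_grid_rejected(self):
        D = random_dissimilarity(3, 12)
        with pytest.raises(ParameterError):
            select_k(D, [0, 1, 40])

    def test_tie_goes_to_smallest_k(self):
        # all-identical points: every k scores average silhouette 0
        D = np.zeros((6, 6))
        trace = select_k(D, [2, 3, 4])
        assert [s for _, s in trace.entries] == [0.0, 0.0, 0.0]
        assert trace.chosen_k == 2


class TestAdjustedRand:
    def test_examples(self):
        assert m.adjusted_rand([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert m.adjusted_rand([0, 0, 1, 1], [5, 5, 2, 2]) == 1.0  # label invariance
        assert m.adjusted_rand([0, 0, 1, 1], [0, 0, 0, 0]) == 0.0
        with pytest.raises(ParameterError):
            m.adjusted_rand([0, 1], [0, 1, 2])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.integers(0, 4, 80)
            b = rng.integers(0, 3, 80)
            assert m.adjusted_rand(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestSensitivitySuite:
    def test_noop_variant_is_identity(self):
        """If no condition is rare, the drop-rare variant equals baseline."""
        rng = np.random.default_rng(4)
        M = pd.DataFrame((rng.random((60, 6)) < 0.5).astype(int))
        M = M[M.sum(axis=1) > 0]
        base = select_k(m.jaccard_matrix(M), [2, 3]).best
        rep = m.sensitivity_suite(M, base, k_grid=[2, 3],
                                  variants=("drop_rare_conditions",))
        v = rep.variants["drop_rare_conditions"]
        assert v.dropped_conditions == []
        assert v.ari_vs_baseline == 1.0
        assert v.chosen_k == base.k

    def test_variants_on_planted_data(self, planted_population, planted_baseline):
        rep = m.sensitivity_suite(
            planted_population["matrix"], planted_baseline.best, k_grid=range(2, 16)
        )
        assert rep.variants["hamming"].ari_vs_baseline >= 0.9
        assert abs(rep.variants["drop_rare_conditions"].chosen_k
                   - planted_baseline.chosen_k) <= 1
        # dropping the top condition keeps the group structure
        assert rep.variants["drop_top_condition"].ari_vs_baseline >= 0.9
        summary = rep.summary()
        assert set(summary["variant"]) == set(rep.variants)
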