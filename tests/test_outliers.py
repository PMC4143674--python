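"""Family centroids, leave-one-family-out distances, trajectories, flags."""

import numpy as np
import pandas as pd
import pytest

from pedstruct import (family_centroids, generational_trajectory,
                       loo_sd_distance, rank_and_flag, validate_pedigree)
from pedstruct.outliers import marryin_flags
from pedstruct.pca import PCAResult


def result_from_scores(scores, fids):
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    samples = [(fids[i], f"i{i + 1}") for i in range(n)]
    return PCAResult(approach="all", eigenvalues=np.ones(k),
                     variance_fraction=np.full(k, 1 / k), scores=scores,
                     loadings=np.zeros((1, k)), weights=np.full(n, 1 / n),
                     samples=samples)


class TestFamilyCentroids:
    def test_single_member_family(self):
        res = result_from_scores([[1.0, 2.0], [0, 0], [0, 0]],
                                 ["A", "B", "B"])
        cen = family_centroids(res, None, 2)
        row = cen[cen.fid == "A"].iloc[0]
        assert (row.PC1, row.PC2) == (1.0, 2.0)

    def test_symmetric_pair_at_origin(self):
        res = result_from_scores([[3.0], [-3.0], [1.0]], ["A", "A", "B"])
        cen = family_centroids(res, None, 1)
        assert cen[cen.fid == "A"].iloc[0].PC1 == 0.0

    def test_hand_averaged_three_families(self):
        scores = [[1, 0], [3, 2], [0, 4], [2, 2], [-1, -1], [-5, 1]]
        fids = ["A", "A", "B", "B", "C", "C"]
        cen = family_centroids(result_from_scores(scores, fids), None, 2)
        got = {r.fid: (r.PC1, r.PC2) for r in cen.itertuples()}
        assert got["A"] == (2.0, 1.0)
        assert got["B"] == (1.0, 3.0)
        assert got["C"] == (-3.0, 0.0)
        assert got["__global__"] == (0.0, 8 / 6)

    def test_size_weighted_centroid_identity(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(30, 3))
        fids = [f"F{i % 4}" for i in range(30)]
        cen = family_centroids(result_from_scores(scores, fids), None, 3)
        fam = cen[cen.fid != "__global__"]
        glob = cen[cen.fid == "__global__"].iloc[0]
        for pc in ("PC1", "PC2", "PC3"):
            total = (fam["n"] * fam[pc]).sum()
            assert total == pytest.approx(30 * getattr(glob, pc), abs=1e-10)


class TestLooSdDistance:
    def test_coincident_centroid_zero(self):
        res = result_from_scores([[1.0], [-1.0], [0.0], [2.0], [-2.0]],
                                 ["A", "A", "B", "B", "B"])
        rep = loo_sd_distance(res, None, 1)
        assert rep.table.set_index("fid").loc["A", "distance_sd"] == 0.0

    def test_one_pc_toy_population_sd(self):
        # remaining scores {-1, 0, 1}: population SD sqrt(2/3); family
        # centroid at 2 -> distance 2 / sqrt(2/3)
        res = result_from_scores([[2.0], [-1.0], [0.0], [1.0]],
                                 ["A", "B", "B", "C"])
        rep = loo_sd_distance(res, None, 1)
        d = rep.table.set_index("fid").loc["A", "distance_sd"]
        assert d == pytest.approx(2.0 / np.sqrt(2 / 3))

    def test_rank_is_permutation(self):
        rng = np.random.default_rng(5)
        res = result_from_scores(rng.normal(size=(40, 2)),
                                 [f"F{i % 8}" for i in range(40)])
        rep = loo_sd_distance(res, None, 2)
        assert sorted(rep.table["rank"]) == list(range(1, 9))

    def test_axis_covariant_not_rotation_invariant(self):
        # anisotropic scores: a 45-degree rotation changes the per-axis
        # standardized distance, documenting the axis-aligned convention
        rng = np.random.default_rng(6)
        scores = np.column_stack([rng.normal(0, 5, 60), rng.normal(0, 0.5, 60)])
        scores[:6, 1] += 3.0
        fids = [f"F{i % 10}" for i in range(60)]
        d0 = loo_sd_distance(result_from_scores(scores, fids), None, 2
                             ).table.distance_sd.to_numpy()
        th = np.pi / 4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d1 = loo_sd_distance(result_from_scores(scores @ R.T, fids), None, 2
                             ).table.distance_sd.to_numpy()
        assert not np.allclose(d0, d1, rtol=1e-3)

    def test_mahalanobis_rotation_invariant(self):
        rng = np.random.default_rng(7)
        scores = np.column_stack([rng.normal(0, 5, 60), rng.normal(0, 0.5, 60)])
        fids = [f"F{i % 10}" for i in range(60)]
        d0 = loo_sd_distance(result_from_scores(scores, fids), None, 2,
                             mahalanobis=True).table.distance_sd.to_numpy()
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d1 = loo_sd_distance(result_from_scores(scores @ R.T, fids), None, 2,
                             mahalanobis=True).table.distance_sd.to_numpy()
        np.testing.assert_allclose(d0, d1, rtol=1e-8)

    def test_needs_two_families(self):
        res = result_from_scores([[1.0], [2.0]], ["A", "A"])
        with pytest.raises(ValueError, match="2 families"):
            loo_sd_distance(res, None, 1)


class TestRankAndFlag:
    def test_table_one_pattern(self):
        # three clear outliers against seventeen background families
        dists = [3.0, 2.5, 2.4] + [0.8] * 17
        fids = [f"F{i}" for i in range(20)]
        table = pd.DataFrame(dict(fid=fids, n=20, distance_sd=dists))
        table["rank"] = table.distance_sd.rank(ascending=False,
                                               method="first").astype(int)
        from pedstruct.outliers import OutlierReport
        rep = OutlierReport(table=table, k=3, approach="all")
        out = rank_and_flag(rep, sd_flag=2.0)
        assert out.flagged.sum() == 3
        assert list(out.fid[:3]) == ["F0", "F1", "F2"]

    def test_no_flags_below_threshold(self):
        table = pd.DataFrame(dict(fid=["A", "B"], n=2,
                                  distance_sd=[0.5, 1.2], rank=[2, 1]))
        from pedstruct.outliers import OutlierReport
        out = rank_and_flag(OutlierReport(table, 1, "all"), sd_flag=2.0)
        assert not out.flagged.any()

    def test_zero_threshold_flags_all(self):
        table = pd.DataFrame(dict(fid=["A", "B"], n=2,
                                  distance_sd=[0.5, 1.2], rank=[2, 1]))
        from pedstruct.outliers import OutlierReport
        out = rank_and_flag(OutlierReport(table, 1, "all"), sd_flag=0.0)
        assert out.flagged.all()


class TestGenerationalTrajectory:
    def ped(self):
        recs = [dict(fid="F", iid=i, father=f, mother=m, sex=s, genotyped=True)
                for i, f, m, s in [
                    ("A", None, None, 1), ("B", None, None, 2),
                    ("C", "A", "B", 1), ("D", None, None, 2),
                    ("E", "C", "D", 1)]] + [
                dict(fid="Z", iid="z1", father=None, mother=None, sex=1,
                     genotyped=True),
                dict(fid="Z", iid="z2", father=None, mother=None, sex=2,
                     genotyped=True)]
        return validate_pedigree(recs)

    def test_marryin_flags(self):
        flags = marryin_flags(self.ped(), "F")
        assert flags == {"A": False, "B": False, "D": True}

    def test_all_members_at_centroid(self):
        ped = self.ped()
        res = result_from_scores(np.zeros((7, 2)),
                                 ["F"] * 5 + ["Z"] * 2)
        res.samples = [("F", i) for i in ["A", "B", "C", "D", "E"]] + \
            [("Z", "z1"), ("Z", "z2")]
        traj = generational_trajectory(res, ped, "F", 2)
        assert np.allclose(traj.per_generation.mean_dist, 0.0)

    def test_midparent_geometry_and_marryin_exclusion(self):
        ped = self.ped()
        # founders at +4, marry-in at 0, child C at parents' midpoint (4),
        # grandchild E at midpoint of C and D (2); background family at 0
        scores = {"A": 4.0, "B": 4.0, "C": 4.0, "D": 0.0, "E": 2.0,
                  "z1": 0.0, "z2": 0.0}
        res = result_from_scores(
            np.array([[v] for v in scores.values()]),
            ["F"] * 5 + ["Z"] * 2)
        res.samples = [("F", i) for i in ["A", "B", "C", "D", "E"]] + \
            [("Z", "z1"), ("Z", "z2")]
        traj = generational_trajectory(res, ped, "F", 1)
        per_gen = traj.per_generation.set_index("generation")
        centroid = np.mean(list(scores.values()))
        # gen 0 descendant-only mean excludes marry-in D
        assert per_gen.loc[0, "mean_dist_descendants"] == \
            pytest.approx(4.0 - centroid)
        assert per_gen.loc[0, "mean_dist"] == \
            pytest.approx(np.mean([4 - centroid, 4 - centroid,
                                   centroid - 0]))
        assert per_gen.loc[2, "mean_dist_descendants"] == \
            pytest.approx(2.0 - centroid)
        ind = traj.per_individual.set_index("iid")
        assert bool(ind.loc["D", "marryin"]) is True

    def test_unknown_family(self):
        res = result_from_scores([[0.0]], ["F"])
        with pytest.raises(KeyError):
            generational_trajectory(res, self.ped(), "nope", 1)
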