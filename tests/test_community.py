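"""Binning, consensus, transforms, ordination and permutation tests.

Independent oracles: skbio's anosim and pcoa, scipy's procrustes, and
naive in-test enumerations.
"""

from itertools import permutations as it_permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from photomat import ValidationError
from photomat.community import (
    anosim,
    bin_fragments,
    bray_curtis,
    consensus_profile,
    hellinger,
    metric_mds_physiology,
    nmds,
    procrustes_test,
    shared_otu_summary,
)


def long_table(rows):
    return pd.DataFrame(rows, columns=["sample", "replicate", "fragment_bp",
                                       "intensity"])


class TestBinning:
    def test_neighbouring_lengths_share_a_bin(self):
        t = long_table([("s", 1, 500.0, 1.0), ("s", 1, 500.9, 2.0)])
        binned = bin_fragments(t, window=2)
        assert binned.shape[1] == 1
        assert binned.iloc[0, 0] == 1.0  # relative abundance

    def test_single_fragment_has_unit_relative_abundance(self):
        binned = bin_fragments(long_table([("s", 1, 333.0, 7.7)]), window=2)
        assert binned.iloc[0].sum() == 1.0

    def test_window_below_one_bp_rejected(self):
        with pytest.raises(ValidationError):
            bin_fragments(long_table([("s", 1, 200.0, 1.0)]), window=0.5)

    def test_bins_anchor_at_100(self):
        binned = bin_fragments(long_table([("s", 1, 101.9, 1.0)]), window=2)
        assert list(binned.columns) == [100.0]


class TestConsensus:
    def table(self, rows):
        df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
            [("s", 1), ("s", 2), ("s", 3)], names=["sample", "replicate"]))
        return df

    def test_two_of_three_retained_one_removed(self):
        binned = self.table([[0.5, 0.5, 0.0],
                             [0.4, 0.0, 0.6],
                             [0.7, 0.0, 0.3]])
        cons = consensus_profile(binned)
        assert cons.loc["s"].iloc[0] > 0  # 3-of-3
        assert cons.loc["s"].iloc[1] == 0  # 1-of-3 removed
        assert cons.loc["s"].iloc[2] > 0  # 2-of-3 retained

    def test_consensus_abundance_is_mean_of_nonzero(self):
        binned = self.table([[0.1], [0.2], [0.3]])
        assert consensus_profile(binned).loc["s"].iloc[0] == pytest.approx(0.2)

    def test_wrong_replicate_count_rejected(self):
        binned = self.table([[0.1], [0.2], [0.3]]).iloc[:2]
        with pytest.raises(ValidationError):
            consensus_profile(binned)

    def test_configurable_k_of_n(self):
        binned = self.table([[0.3], [0.0], [0.0]])
        cons = consensus_profile(binned, min_presence=1)
        assert cons.loc["s"].iloc[0] == pytest.approx(0.3)


class TestTransforms:
    def test_hellinger_known_rows(self):
        t = pd.DataFrame([[4.0, 0.0, 0.0], [1.0, 1.0, 0.0]], index=["a", "b"])
        h = hellinger(t)
        np.testing.assert_allclose(h.loc["a"], [1, 0, 0])
        np.testing.assert_allclose(h.loc["b"], [0.70710678, 0.70710678, 0],
                                   atol=1e-8)

    def test_hellinger_rows_have_unit_norm(self, rng):
        t = pd.DataFrame(rng.random((5, 8)))
        h = hellinger(t)
        np.testing.assert_allclose((h ** 2).sum(axis=1), 1.0, atol=1e-12)

    def test_hellinger_zero_row_names_sample(self):
        t = pd.DataFrame([[1.0], [0.0]], index=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            hellinger(t)

    @pytest.mark.parametrize(
        "a, b, expected",
        [([1, 1, 0], [1, 1, 0], 0.0),
         ([1, 1, 0], [0, 0, 2], 1.0),
         ([1, 2, 0], [0, 2, 4], 5.0 / 9.0)],
    )
    def test_bray_curtis_values(self, a, b, expected):
        dm = bray_curtis(pd.DataFrame([a, b], dtype=float))
        assert dm.iloc[0, 1] == pytest.approx(expected)
        assert dm.iloc[1, 0] == dm.iloc[0, 1]
        assert dm.iloc[0, 0] == 0.0

    def test_bray_curtis_bounded(self, rng):
        dm = bray_curtis(pd.DataFrame(rng.random((6, 10)))).to_numpy()
        assert (dm >= 0).all() and (dm <= 1 + 1e-12).all()


class TestNMDS:
    def test_planar_distances_embed_with_negligible_stress(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1.3, 1.1]], float)
        dm = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(dm, restarts=16, seed=0)
        assert res.stress < 1e-3

    def test_duplicate_samples_land_together(self):
        pts = np.array([[0, 0], [0, 0], [3, 0], [0, 3], [3, 3]], float)
        dm = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(dm, restarts=8, seed=0)
        c = res.coordinates.to_numpy()
        d01 = np.linalg.norm(c[0] - c[1])
        others = pdist(c).mean()
        assert d01 < 0.05 * others

    def test_clustered_data_beats_random_configuration(self, rng):
        """Fitted stress below that of a random configuration, every seed."""
        from sklearn.isotonic import IsotonicRegression

        def stress1(dm, coords):
            iu = np.triu_indices(len(coords), 1)
            d = squareform(pdist(coords))[iu]
            dhat = IsotonicRegression().fit_transform(dm[iu], d)
            return np.sqrt(((d - dhat) ** 2).sum() / (d ** 2).sum())

        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = np.vstack([r.normal(0, 0.3, (5, 3)), r.normal(3, 0.3, (5, 3))])
            dm = squareform(pdist(x))
            res = nmds(pd.DataFrame(dm), restarts=4, seed=seed)
            rand = r.standard_normal((10, 2))
            if res.stress < stress1(dm, rand):
                wins += 1
        assert wins == 20


class TestMetricMDS:
    def frame(self, vals):
        return pd.DataFrame(vals, columns=["a_chl", "y_max", "i_k", "i_max"])

    def test_identical_mats_coincide(self, rng):
        v = rng.random((4, 4))
        v[1] = v[0]
        res = metric_mds_physiology(self.frame(v))
        c = res.coordinates.to_numpy()
        assert np.linalg.norm(c[0] - c[1]) < 1e-9

    def test_two_sd_offset_gives_distance_two(self):
        # three mats; first variable carries the only signal
        v = np.array([[0.0, 1, 1, 1], [0.0, 1, 1, 1], [2.0, 1, 1, 1]])
        v[:, 0] /= v[:, 0].std(ddof=1)  # unit-SD column: offset is 2 SD units
        res = metric_mds_physiology(self.frame(v))
        c = res.coordinates.to_numpy()
        assert np.linalg.norm(c[0] - c[2]) == pytest.approx(
            np.linalg.norm((v[:, 0] - v[:, 0].mean())[0]
                           - (v[:, 0] - v[:, 0].mean())[2])
            / v[:, 0].std(ddof=1), rel=1e-6)

    def test_matches_skbio_pcoa(self, rng):
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix

        v = rng.random((6, 4))
        res = metric_mds_physiology(self.frame(v))
        z = (v - v.mean(0)) / v.std(0, ddof=1)
        d = squareform(pdist(z))
        ref = pcoa(DistanceMatrix(d), number_of_dimensions=2).samples.to_numpy()
        got = res.coordinates.to_numpy()
        for k in range(2):  # axes defined up to sign
            assert (np.allclose(got[:, k], ref[:, k], atol=1e-6)
                    or np.allclose(got[:, k], -ref[:, k], atol=1e-6))

    def test_constant_variable_dropped(self, rng):
        v = rng.random((5, 4))
        v[:, 2] = 1.0
        res = metric_mds_physiology(self.frame(v))
        assert res.coordinates.attrs["dropped_constant"] == ["i_k"]


class TestANOSIM:
    def two_cluster_dm(self, rng, n_per=4, sep=3.0):
        x = np.vstack([rng.normal(0, 0.5, (n_per, 3)),
                       rng.normal(sep, 0.5, (n_per, 3))])
        return pd.DataFrame(squareform(pdist(x)))

    def test_perfect_separation_gives_r_one(self, rng):
        dm = self.two_cluster_dm(rng, sep=50.0)
        res = anosim(dm, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_random_labels_have_zero_mean_r(self):
        rs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            dm = pd.DataFrame(squareform(pdist(r.random((8, 4)))))
            labels = r.permutation(["a"] * 4 + ["b"] * 4)
            rs.append(anosim(dm, labels, n_permutations=0 + 99, seed=seed).r)
        assert abs(np.mean(rs)) < 0.05

    def test_matches_skbio_statistic(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        dm = self.two_cluster_dm(rng, sep=1.0)
        labels = ["a"] * 4 + ["b"] * 4
        mine = anosim(dm, labels, n_permutations=99, seed=0)
        ref = sk_anosim(DistanceMatrix(dm.to_numpy()), grouping=labels,
                        permutations=99)
        assert mine.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_exact_enumeration_matches_brute_force(self, rng):
        """n = 6, two groups of 3: exact p equals naive enumeration."""
        dm = self.two_cluster_dm(rng, n_per=3, sep=1.0)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = anosim(dm, labels, exact=True)
        # brute force: all distinct relabelings via permutations
        d = dm.to_numpy()
        iu = np.triu_indices(6, 1)
        from scipy.stats import rankdata

        ranks = rankdata(d[iu])

        def r_stat(lab):
            same = lab[iu[0]] == lab[iu[1]]
            m = 15.0
            return (ranks[~same].mean() - ranks[same].mean()) / (m / 2)

        seen = set()
        stats = []
        for perm in it_permutations(range(6)):
            key = tuple(labels[list(perm)])
            if key not in seen:
                seen.add(key)
                stats.append(r_stat(np.array(key)))
        assert len(seen) == 20
        expected_p = np.mean([s >= r_stat(labels) - 1e-12 for s in stats])
        assert res.p == pytest.approx(expected_p)
        assert res.n_permutations == 20

    def test_degenerate_grouping_rejected(self, rng):
        dm = self.two_cluster_dm(rng)
        with pytest.raises(ValidationError):
            anosim(dm, ["a"] * 7 + ["b"], n_permutations=99)


class TestProcrustes:
    def config(self, rng, n=10, k=2):
        return pd.DataFrame(rng.standard_normal((n, k)),
                            index=[f"m{i}" for i in range(n)])

    def test_self_concordance(self, rng):
        a = self.config(rng)
        res = procrustes_test(a, a.copy(), n_permutations=0)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-10)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_similarity_invariance(self, rng):
        a = self.config(rng)
        theta = 0.73
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        b = pd.DataFrame(3.7 * (a.to_numpy() @ rot) + np.array([5.0, -2.0]),
                         index=a.index)
        res = procrustes_test(a, b, n_permutations=0)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_disparity(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        a = self.config(rng)
        b = self.config(rng)
        res = procrustes_test(a, b, n_permutations=0)
        _, _, disparity = scipy_procrustes(a.to_numpy(), b.to_numpy())
        assert res.m12_squared == pytest.approx(disparity, abs=1e-10)

    def test_mismatched_samples_rejected_before_compute(self, rng):
        a = self.config(rng)
        b = self.config(rng)
        b.index = [f"x{i}" for i in range(len(b))]
        with pytest.raises(ValidationError):
            procrustes_test(a, b)

    def test_linked_configurations_detected(self, rng):
        a = self.config(rng, n=12)
        noise = 0.1 * rng.standard_normal(a.shape)
        b = pd.DataFrame(a.to_numpy() + noise, index=a.index)
        res = procrustes_test(a, b, n_permutations=199, seed=0)
        assert res.p < 0.05 and res.r > 0.9


class TestSharedOTUs:
    def site(self, cols):
        return pd.DataFrame([[1.0] * len(cols)], columns=cols)

    def test_identical_sites_fully_ubiquitous(self):
        tables = {s: self.site([1, 2, 3]) for s in "ABC"}
        out = shared_otu_summary(tables)
        assert out["ubiquitous_pct"] == 100.0 and out["single_site"] == 0

    def test_disjoint_sites_share_nothing(self):
        tables = {"A": self.site([1, 2]), "B": self.site([3, 4])}
        out = shared_otu_summary(tables)
        assert out["ubiquitous"] == 0 and out["single_site"] == 4
        assert out["pairwise_shared_pct"]["A-B"] == 0.0

    def test_survey_counts_give_21_point_1_percent(self):
        """84 ubiquitous of 398 total OTUs -> 21.1% everywhere-present."""
        ubiq = list(range(84))
        tables = {}
        start = 84
        for i, s in enumerate(["AD", "AU", "BR", "SP"]):
            n_spec = 79 if i < 2 else 78  # 84 + 79+79+78+78 = 398
            specific = list(range(start, start + n_spec))
            start += n_spec
            tables[s] = self.site(ubiq + specific)
        out = shared_otu_summary(tables)
        assert out["total_otus"] == 398
        assert out["ubiquitous"] == 84
        assert round(out["ubiquitous_pct"], 1) == 21.1
        assert out["single_site"] == 314
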