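"""Distance matrices and permutation tests against oracles and references."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers_oracles import bray_curtis_oracle
from trophos import (
    DegenerateDesignError,
    braycurtis_matrix,
    cap,
    euclidean_matrix,
    pairwise_permanova,
    permanova_nested,
    permanova_oneway,
    permdisp,
    simper,
)


class TestBrayCurtis:
    def test_identical_rows_give_zero(self):
        bio = pd.DataFrame([[1.0, 2.0, 3.0]] * 2)
        dm = braycurtis_matrix(bio)
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_give_one(self):
        bio = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]])
        dm = braycurtis_matrix(bio)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_two_by_two_matches_bruteforce(self):
        bio = pd.DataFrame([[1.0, 1.0], [1.0, 0.0]])
        dm = braycurtis_matrix(bio, log_transform=True)
        y = np.log1p(bio.to_numpy())
        assert dm.values[0, 1] == pytest.approx(
            bray_curtis_oracle(y[0], y[1]), abs=1e-12
        )

    def test_random_matrix_matches_bruteforce(self, rng):
        bio = pd.DataFrame(rng.gamma(1.0, 1.0, size=(8, 5)))
        dm = braycurtis_matrix(bio, log_transform=False)
        y = bio.to_numpy()
        for i in range(8):
            for j in range(8):
                assert dm.values[i, j] == pytest.approx(
                    bray_curtis_oracle(y[i], y[j]) if i != j else 0.0,
                    abs=1e-12,
                )
        assert ((dm.values >= 0) & (dm.values <= 1)).all()

    def test_all_zero_sample_dropped_with_warning(self):
        bio = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0]],
                           index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="all-zero"):
            dm = braycurtis_matrix(bio)
        assert dm.labels == ("a", "c")


class TestPermanovaOneway:
    def test_matches_classical_anova_on_univariate_euclidean(self, rng):
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        res = permanova_oneway(euclidean_matrix(y), g, n_perm=99, seed=0)
        f_classic = stats.f_oneway(y[:8], y[8:16], y[16:]).statistic
        assert res.pseudo_f("factor") == pytest.approx(f_classic, abs=1e-9)

    def test_matches_skbio_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        bio = pd.DataFrame(rng.gamma(1.0, 1.0, size=(20, 6)))
        dm = braycurtis_matrix(bio, log_transform=False)
        g = np.repeat(["a", "b"], 10)
        res = permanova_oneway(dm, g, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values), g, permutations=99
        )
        assert res.pseudo_f("factor") == pytest.approx(
            float(ref["test statistic"]), abs=1e-10
        )

    def test_duplicated_groups_show_no_effect(self, rng):
        pts = rng.normal(size=(6, 2))
        stacked = np.vstack([pts, pts])
        g = np.repeat(["a", "b"], 6)
        res = permanova_oneway(euclidean_matrix(stacked), g, n_perm=199, seed=0)
        assert res.pseudo_f("factor") == pytest.approx(0.0, abs=1e-10)
        assert res.p_value("factor") > 0.05

    def test_separated_clouds_detected(self, rng):
        pts = np.vstack([rng.normal(0, 1, size=(12, 2)),
                         rng.normal(6, 1, size=(12, 2))])
        g = np.repeat(["a", "b"], 12)
        res = permanova_oneway(euclidean_matrix(pts), g, n_perm=999, seed=0)
        assert res.p_value("factor") <= 0.001

    def test_p_value_never_zero(self, rng):
        pts = np.vstack([rng.normal(0, 1, size=(5, 2)),
                         rng.normal(50, 1, size=(5, 2))])
        res = permanova_oneway(
            euclidean_matrix(pts), np.repeat(["a", "b"], 5), n_perm=99, seed=0
        )
        assert res.p_value("factor") >= 1 / 100

    def test_statistic_invariant_to_sample_order_and_label_names(self, rng):
        pts = rng.normal(size=(12, 2))
        g = np.repeat(["a", "b"], 6)
        dm = euclidean_matrix(pts)
        f0 = permanova_oneway(dm, g, n_perm=99, seed=0).pseudo_f("factor")
        order = rng.permutation(12)
        f1 = permanova_oneway(
            euclidean_matrix(pts[order]), g[order], n_perm=99, seed=1
        ).pseudo_f("factor")
        f2 = permanova_oneway(
            dm, np.where(g == "a", "zebra", "yak"), n_perm=99, seed=2
        ).pseudo_f("factor")
        assert f1 == pytest.approx(f0, abs=1e-10)
        assert f2 == pytest.approx(f0, abs=1e-10)

    def test_group_of_size_one_rejected(self):
        dm = euclidean_matrix(np.arange(4.0))
        with pytest.raises(DegenerateDesignError):
            permanova_oneway(dm, ["a", "a", "a", "b"], n_perm=99)

    def test_monotone_power_in_effect_size(self, rng):
        rates = []
        for shift in (0.0, 1.0, 2.5):
            hits = 0
            reps = 60
            for _ in range(reps):
                pts = np.vstack([rng.normal(0, 1, size=(8, 2)),
                                 rng.normal(shift, 1, size=(8, 2))])
                res = permanova_oneway(
                    euclidean_matrix(pts), np.repeat(["a", "b"], 8),
                    n_perm=199, seed=int(rng.integers(2**31 - 1)),
                )
                hits += res.p_value("factor") <= 0.05
            rates.append(hits / reps)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9


class TestPermanovaNested:
    @staticmethod
    def balanced_design(rng, shift=0.0, n_per_cell=4):
        species, areas, data = [], [], []
        for si in range(4):
            for area in ("N", "C", "S"):
                mu = np.array([shift * (si % 2), shift * (si // 2)])
                data.append(rng.normal(mu, 1.0, size=(n_per_cell, 2)))
                species += [f"sp{si}"] * n_per_cell
                areas += [area] * n_per_cell
        return np.vstack(data), np.array(species), np.array(areas)

    def test_textbook_degrees_of_freedom(self, rng):
        pts, species, areas = self.balanced_design(rng)
        res = permanova_nested(euclidean_matrix(pts), species, areas,
                               n_perm=99, seed=0)
        df = res.table["df"]
        assert df["fixed"] == 3          # a - 1
        assert df["nested"] == 8         # a (b - 1)
        assert df["Residual"] == 36      # a b (n - 1)
        assert df["fixed"] + df["nested"] + df["Residual"] == df["Total"]

    def test_sums_of_squares_partition(self, rng):
        pts, species, areas = self.balanced_design(rng, shift=1.0)
        res = permanova_nested(euclidean_matrix(pts), species, areas,
                               n_perm=99, seed=0)
        ss = res.table["SS"]
        assert ss["fixed"] + ss["nested"] + ss["Residual"] == pytest.approx(
            ss["Total"], rel=1e-10
        )
        assert (ss.drop("Total") >= -1e-9).all()

    def test_univariate_balanced_matches_nested_anova_f(self, rng):
        """Against the closed-form nested ANOVA from explicit group means."""
        y = rng.normal(size=24)
        species = np.repeat(["s1", "s2"], 12)
        areas = np.tile(np.repeat(["a", "b", "c"], 4), 2)
        res = permanova_nested(euclidean_matrix(y), species, areas,
                               n_perm=99, seed=0)
        grand = y.mean()
        ss_sp = sum(12 * (y[species == s].mean() - grand) ** 2
                    for s in ("s1", "s2"))
        cells = [(s, a) for s in ("s1", "s2") for a in ("a", "b", "c")]
        ss_cell = sum(
            4 * (y[(species == s) & (areas == a)].mean()
                 - y[species == s].mean()) ** 2
            for s, a in cells
        )
        ss_res = sum(
            ((y[(species == s) & (areas == a)]
              - y[(species == s) & (areas == a)].mean()) ** 2).sum()
            for s, a in cells
        )
        f_fixed = (ss_sp / 1) / (ss_cell / 4)
        f_nested = (ss_cell / 4) / (ss_res / 18)
        assert res.pseudo_f("fixed") == pytest.approx(f_fixed, abs=1e-9)
        assert res.pseudo_f("nested") == pytest.approx(f_nested, abs=1e-9)

    def test_all_identical_samples(self):
        pts = np.ones((16, 2))
        species = np.repeat(["s1", "s2"], 8)
        areas = np.tile(np.repeat(["a", "b"], 4), 2)
        res = permanova_nested(euclidean_matrix(pts), species, areas,
                               n_perm=99, seed=0)
        assert np.isnan(res.pseudo_f("fixed"))
        assert res.p_value("fixed") == 1.0

    def test_species_effect_detected_area_null(self, rng):
        pts, species, areas = self.balanced_design(rng, shift=2.0, n_per_cell=5)
        res = permanova_nested(euclidean_matrix(pts), species, areas,
                               n_perm=199, seed=0)
        assert res.p_value("fixed") <= 0.05

    def test_single_fixed_level_rejected(self):
        dm = euclidean_matrix(np.arange(6.0))
        with pytest.raises(DegenerateDesignError):
            permanova_nested(dm, ["s"] * 6, ["a", "a", "b", "b", "c", "c"],
                             n_perm=99)


class TestPairwise:
    def test_pairwise_covers_all_level_pairs(self, rng):
        pts = rng.normal(size=(18, 2))
        g = np.repeat(["a", "b", "c"], 6)
        out = pairwise_permanova(euclidean_matrix(pts), g, n_perm=99, seed=0)
        assert len(out) == 3
        assert set(zip(out["group_a"], out["group_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }

    def test_holm_adjustment_monotone(self, rng):
        pts = rng.normal(size=(18, 2))
        g = np.repeat(["a", "b", "c"], 6)
        out = pairwise_permanova(euclidean_matrix(pts), g, n_perm=99, seed=0,
                                 correction="holm")
        assert (out["p_holm"] >= out["p_perm"] - 1e-12).all()
        assert (out["p_holm"] <= 1.0).all()


class TestPermdisp:
    def test_distances_match_direct_geometry(self, rng):
        pts = rng.normal(size=(30, 2))
        g = np.repeat(["a", "b"], 15)
        res = permdisp(euclidean_matrix(pts), g, n_perm=99, seed=0)
        direct = np.concatenate([
            np.linalg.norm(pts[:15] - pts[:15].mean(axis=0), axis=1),
            np.linalg.norm(pts[15:] - pts[15:].mean(axis=0), axis=1),
        ])
        np.testing.assert_allclose(res.distances.to_numpy(), direct, atol=1e-9)

    def test_matches_skbio_centroid_f(self, rng):
        # Euclidean input: no negative eigenvalues, so the corrected
        # distance formula coincides with the plain PCoA geometry skbio uses
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(20, 3))
        dm = euclidean_matrix(pts)
        g = np.repeat(["a", "b"], 10)
        res = permdisp(dm, g, n_perm=99, seed=0)
        ref = skbio.stats.distance.permdisp(
            skbio.DistanceMatrix(dm.values), g, permutations=99,
            test="centroid",
        )
        assert res.f_stat == pytest.approx(float(ref["test statistic"]),
                                           rel=1e-6)

    def test_unequal_spread_detected_and_ordered(self, rng):
        pts = np.vstack([rng.normal(0, 1, size=(20, 2)),
                         rng.normal(0, 3, size=(20, 2))])
        g = np.repeat(["tight", "wide"], 20)
        res = permdisp(euclidean_matrix(pts), g, n_perm=999, seed=0)
        assert res.group_means["wide"] > res.group_means["tight"]
        assert res.p_perm <= 0.05

    def test_coincident_points_reported_as_no_test(self):
        pts = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        res = permdisp(euclidean_matrix(pts), ["a"] * 3 + ["b"] * 3,
                       n_perm=99, seed=0)
        assert not res.tested
        assert np.isnan(res.f_stat)


class TestSimper:
    def test_single_differing_taxon_contributes_everything(self):
        bio = pd.DataFrame(
            {"shared": [1.0, 1.0, 1.0, 1.0], "only_b": [0.0, 0.0, 2.0, 2.0]}
        )
        (res,) = simper(bio, ["g1", "g1", "g2", "g2"])
        assert res.table.loc["only_b", "contribution_pct"] == pytest.approx(100.0)

    def test_contributions_sum_to_average_dissimilarity(self, rng):
        bio = pd.DataFrame(rng.gamma(1.0, 1.0, size=(12, 6)))
        for res in simper(bio, np.repeat(["a", "b", "c"], 4)):
            assert res.table["avg_contribution"].sum() == pytest.approx(
                res.average_dissimilarity, abs=1e-9
            )
            assert res.table["contribution_pct"].sum() == pytest.approx(
                100.0, abs=1e-6
            )

    def test_average_matches_mean_of_pairwise_braycurtis(self, rng):
        bio = pd.DataFrame(rng.gamma(1.0, 1.0, size=(10, 4)))
        g = np.repeat(["a", "b"], 5)
        (res,) = simper(bio, g)
        dm = braycurtis_matrix(bio, log_transform=True)
        cross = dm.values[:5, 5:]
        assert res.average_dissimilarity == pytest.approx(
            100 * cross.mean(), abs=1e-9
        )

    def test_disjoint_profiles_near_total_dissimilarity(self, rng):
        g1 = np.hstack([rng.gamma(2.0, 1.0, size=(6, 3)), np.zeros((6, 3))])
        g2 = np.hstack([np.zeros((6, 3)), rng.gamma(2.0, 1.0, size=(6, 3))])
        bio = pd.DataFrame(np.vstack([g1, g2]))
        (res,) = simper(bio, np.repeat(["a", "b"], 6))
        assert res.average_dissimilarity >= 90.0

    def test_cutoff_truncation(self, rng):
        bio = pd.DataFrame(rng.gamma(1.0, 1.0, size=(10, 8)))
        (res,) = simper(bio, np.repeat(["a", "b"], 5), cutoff=60.0)
        trunc = res.truncated
        assert trunc["cumulative_pct"].iloc[-1] >= 60.0
        if len(trunc) > 1:
            assert trunc["cumulative_pct"].iloc[-2] < 60.0

    def test_monotone_sorted_contributions(self, rng):
        bio = pd.DataFrame(rng.gamma(1.0, 1.0, size=(10, 6)))
        (res,) = simper(bio, np.repeat(["a", "b"], 5))
        contrib = res.table["contribution_pct"].to_numpy()
        assert (np.diff(contrib) <= 1e-12).all()
        assert (np.diff(res.table["cumulative_pct"].to_numpy()) >= -1e-12).all()


class TestCap:
    def test_perfect_separation_allocates_fully(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, size=(10, 2)),
                         rng.normal(8, 0.2, size=(10, 2))])
        res = cap(euclidean_matrix(pts), np.repeat(["a", "b"], 10))
        assert res.allocation_success == pytest.approx(100.0)

    def test_shuffled_labels_near_chance(self, rng):
        pts = rng.normal(size=(36, 2))
        g = rng.permutation(np.repeat(["a", "b", "c"], 12))
        res = cap(euclidean_matrix(pts), g)
        assert res.allocation_success <= 65.0  # chance is ~33%

    def test_m_respects_rank_and_sample_bounds(self, rng):
        pts = rng.normal(size=(12, 2))
        g = np.repeat(["a", "b"], 6)
        res = cap(euclidean_matrix(pts), g)
        assert 1 <= res.m <= min(12 - 2, 11)

    def test_too_few_samples_rejected(self):
        dm = euclidean_matrix(np.arange(2.0))
        with pytest.raises(DegenerateDesignError):
            cap(dm, ["a", "b"])
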