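"""Taxon aggregation, alpha/beta diversity, PCoA and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import comb
from scipy.spatial.distance import braycurtis

from pandagut.catalog import GeneCatalogEntry
from pandagut.matrix import AbundanceMatrix
from pandagut.profiles import (
    DistanceMatrix,
    TaxonProfile,
    aggregate_taxa,
    chao1,
    diversity_table,
    filter_low_abundance,
    pcoa,
    permanova,
    pielou_evenness,
    rarefaction_curve,
    shannon_index,
    whittaker_distance,
)


def _entry(gid, species="X sp", genus="X", family="F", phylum="P"):
    return GeneCatalogEntry(
        gid, 100, {"phylum": phylum, "family": family, "genus": genus, "species": species}
    )


def _matrix(values, rows, cols, units="counts"):
    return AbundanceMatrix(pd.DataFrame(values, index=rows, columns=cols), units=units)


class TestAggregation:
    def test_species_sum(self):
        m = _matrix([[0.1], [0.2]], ["g1", "g2"], ["s"], units="relative")
        catalog = [_entry("g1"), _entry("g2")]
        prof = aggregate_taxa(m, catalog, "species")
        assert prof.matrix.data.loc["X sp", "s"] == pytest.approx(0.3)

    def test_all_unclassified_pools_to_one_row(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"], ["s1", "s2"])
        catalog = [
            GeneCatalogEntry(g, 100, {r: "Unclassified" for r in
                                      ("phylum", "family", "genus", "species")})
            for g in ("g1", "g2")
        ]
        prof = aggregate_taxa(m, catalog, "species")
        assert prof.matrix.row_ids == ["Unclassified"]
        np.testing.assert_allclose(prof.matrix.values[0], [4.0, 6.0])

    def test_genus_totals_match_groupby_oracle(self, small_dataset):
        catalog, _, matrix, _ = small_dataset
        prof = aggregate_taxa(matrix, catalog, "genus")
        # independent oracle: melt + join + groupby
        genus_of = {e.gene_id: e.lineage["genus"] for e in catalog}
        melted = matrix.data.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample", value_name="x"
        )
        melted["genus"] = melted["gene"].map(genus_of)
        oracle = melted.pivot_table(
            index="genus", columns="sample", values="x", aggfunc="sum"
        )[matrix.sample_ids]
        np.testing.assert_allclose(
            prof.matrix.data.sort_index().to_numpy(), oracle.sort_index().to_numpy(),
            atol=1e-12,
        )

    def test_mass_conservation(self, small_dataset):
        catalog, _, matrix, _ = small_dataset
        for rank in ("species", "family", "phylum"):
            prof = aggregate_taxa(matrix, catalog, rank)
            np.testing.assert_allclose(
                prof.matrix.values.sum(axis=0), matrix.values.sum(axis=0), atol=1e-9
            )

    def test_unknown_gene_errors(self):
        m = _matrix([[1.0]], ["gX"], ["s"])
        with pytest.raises(ValueError, match="absent"):
            aggregate_taxa(m, [_entry("g1")], "species")


class TestLowAbundanceFilter:
    def test_below_floor_everywhere_removed(self):
        prof = TaxonProfile(
            "species", _matrix([[1e-9, 1e-9], [0.5, 0.5]], ["low", "hi"],
                               ["s1", "s2"], units="relative")
        )
        out = filter_low_abundance(prof, 1e-8)
        assert out.matrix.row_ids == ["hi"]

    def test_exactly_at_floor_kept(self):
        prof = TaxonProfile(
            "species", _matrix([[1e-8, 0.0], [0.5, 0.5]], ["edge", "hi"],
                               ["s1", "s2"], units="relative")
        )
        out = filter_low_abundance(prof, 1e-8)
        assert "edge" in out.matrix.row_ids  # strictly "below" is removed

    def test_counting_134_families_7_below_floor(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1e-6, 1e-3, size=(134, 5))
        vals[:7] = 1e-9
        prof = TaxonProfile(
            "family",
            _matrix(vals, [f"f{i}" for i in range(134)],
                    [f"s{i}" for i in range(5)], units="relative"),
        )
        assert filter_low_abundance(prof, 1e-8).matrix.data.shape[0] == 127

    def test_counts_profile_rejected(self):
        prof = TaxonProfile("species", _matrix([[1.0]], ["a"], ["s"]))
        with pytest.raises(ValueError, match="relative"):
            filter_low_abundance(prof, 1e-8)


class TestAlphaDiversity:
    def test_shannon_uniform(self):
        assert shannon_index([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_shannon_single_taxon_zero(self):
        assert shannon_index([1, 0, 0]) == 0.0

    def test_shannon_counts_532(self):
        # frozen from exact formula: -sum p ln p, p = (.5,.3,.2)
        assert shannon_index([5, 3, 2]) == pytest.approx(1.0296530, abs=1e-6)

    def test_shannon_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            shannon_index([0.0, 0.0])

    @given(st.integers(2, 30))
    def test_shannon_maximal_at_uniform(self, s):
        rng = np.random.default_rng(s)
        p = rng.dirichlet(np.ones(s))
        assert shannon_index(p) <= np.log(s) + 1e-12

    def test_pielou_uniform_is_one(self):
        for s in (2, 5, 17):
            assert pielou_evenness([1.0 / s] * s) == pytest.approx(1.0)

    def test_pielou_single_taxon_undefined(self):
        assert pielou_evenness([3, 0]) is None

    def test_pielou_counts_532(self):
        # frozen: 1.0296530 / ln 3
        assert pielou_evenness([5, 3, 2]) == pytest.approx(0.9372306, abs=1e-6)

    def test_chao1_no_singletons_equals_observed(self):
        assert chao1([3, 5, 7]) == 3.0

    def test_chao1_frozen_example(self):
        # S=4, F1=2, F2=1: 4 + 2*1/(2*2) = 4.5
        assert chao1([1, 1, 2, 3]) == pytest.approx(4.5)

    def test_chao1_non_integer_errors(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([1.5, 2.0])

    def test_diversity_table_chao1_only_for_counts(self):
        prof = TaxonProfile("species", _matrix([[0.5], [0.5]], ["a", "b"], ["s"],
                                               units="relative"))
        assert np.isnan(diversity_table(prof)["chao1"].iloc[0])


class TestRarefaction:
    COUNTS = [20, 10, 5, 2, 1, 1, 1]

    def test_full_depth_exact_sd_zero(self):
        total = sum(self.COUNTS)
        out = rarefaction_curve(self.COUNTS, [total], n_resamples=5, seed=0)
        assert out["mean_richness"].iloc[0] == 7
        assert out["sd_richness"].iloc[0] == 0.0
        assert out["mean_chao1"].iloc[0] == pytest.approx(chao1(self.COUNTS))

    def test_mean_richness_monotone_in_depth(self):
        out = rarefaction_curve(self.COUNTS, [5, 10, 20, 40], n_resamples=30, seed=1)
        assert out["mean_richness"].is_monotonic_increasing

    def test_depth_above_total_errors(self):
        with pytest.raises(ValueError, match="depth"):
            rarefaction_curve(self.COUNTS, [1000], seed=0)

    def test_mean_matches_hypergeometric_expectation(self):
        # closed form computed independently here with binomial coefficients
        counts = np.array(self.COUNTS)
        n = counts.sum()
        depth = 15
        expected = sum(
            1 - comb(n - c, depth, exact=True) / comb(n, depth, exact=True)
            for c in counts
        )
        out = rarefaction_curve(counts, [depth], n_resamples=3000, seed=2)
        se = out["sd_richness"].iloc[0] / np.sqrt(3000)
        assert out["mean_richness"].iloc[0] == pytest.approx(expected, abs=5 * se + 1e-6)


class TestWhittaker:
    def _profile(self, vals, rows, cols):
        return TaxonProfile("species", _matrix(vals, rows, cols, units="relative"))

    def test_identical_samples_distance_zero(self):
        p = self._profile([[0.5, 0.5], [0.5, 0.5]], ["a", "b"], ["s1", "s2"])
        assert whittaker_distance(p).values[0, 1] == 0.0

    def test_disjoint_samples_distance_one(self):
        p = self._profile([[1.0, 0.0], [0.0, 1.0]], ["a", "b"], ["s1", "s2"])
        assert whittaker_distance(p).values[0, 1] == pytest.approx(1.0)

    def test_three_vs_three_one_shared_absent(self):
        # A={a,b,c}, B={b,c,d}: S_union=4, mean alpha=3 -> 4/3 - 1 = 1/3
        vals = [[0.4, 0.0], [0.3, 0.3], [0.3, 0.3], [0.0, 0.4]]
        p = self._profile(vals, ["a", "b", "c", "d"], ["s1", "s2"])
        assert whittaker_distance(p).values[0, 1] == pytest.approx(1 / 3)

    def test_empty_sample_errors(self):
        p = self._profile([[0.5, 0.0]], ["a"], ["s1", "s2"])
        with pytest.raises(ValueError, match="presence"):
            whittaker_distance(p)

    def test_weighted_variant_is_braycurtis(self):
        rng = np.random.default_rng(3)
        vals = rng.dirichlet(np.ones(6), size=4).T
        p = self._profile(vals, [f"t{i}" for i in range(6)], list("abcd"))
        d = whittaker_distance(p, weighted=True)
        for i in range(4):
            for j in range(4):
                assert d.values[i, j] == pytest.approx(
                    braycurtis(vals[:, i], vals[:, j]), abs=1e-12
                )


class TestPCoA:
    def test_collinear_points_single_positive_eigenvalue(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.coordinates.shape[1] == 1
        rec = np.abs(
            res.coordinates.values[:, 0][:, None] - res.coordinates.values[:, 0][None, :]
        )
        np.testing.assert_allclose(rec, d, atol=1e-10)

    def test_equidistant_points_equal_eigenvalues(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(n)], d))
        positive = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(positive) == n - 1
        np.testing.assert_allclose(positive, positive[0], rtol=1e-9)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((10, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d))
        coords = res.coordinates.values
        rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(8)]
        mine = pcoa(DistanceMatrix(ids, d))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids))
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues[mine.eigenvalues > 1e-8])[::-1],
            np.sort(theirs.eigvals.values[theirs.eigvals.values > 1e-8])[::-1],
            rtol=1e-8,
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestPermanova:
    def _random_case(self, seed=6, n=20):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        groups = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(ids)}
        return DistanceMatrix(ids, d), groups

    def test_well_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(7)
        pts = np.vstack(
            [rng.standard_normal((8, 2)), rng.standard_normal((8, 2)) + 50]
        )
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(16)]
        groups = {s: ("A" if i < 8 else "B") for i, s in enumerate(ids)}
        res = permanova(DistanceMatrix(ids, d), groups, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.R2 > 0.9

    def test_r2_invariant_to_distance_scaling(self):
        dist, groups = self._random_case()
        r1 = permanova(dist, groups, n_permutations=49, seed=1)
        scaled = DistanceMatrix(dist.sample_ids, dist.values * 7.3)
        r2 = permanova(scaled, groups, n_permutations=49, seed=1)
        assert r1.R2 == pytest.approx(r2.R2, rel=1e-12)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-12)

    def test_statistic_invariant_to_sample_reordering(self):
        dist, groups = self._random_case()
        perm = np.random.default_rng(8).permutation(len(dist.sample_ids))
        ids2 = [dist.sample_ids[i] for i in perm]
        d2 = dist.values[np.ix_(perm, perm)]
        r1 = permanova(dist, groups, n_permutations=9, seed=0)
        r2 = permanova(DistanceMatrix(ids2, d2), groups, n_permutations=9, seed=0)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-12)
        assert r1.R2 == pytest.approx(r2.R2, rel=1e-12)

    def test_degenerate_all_zero_distances(self):
        ids = list("abcd")
        groups = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        with pytest.warns(UserWarning, match="degenerate"):
            res = permanova(DistanceMatrix(ids, np.zeros((4, 4))), groups)
        assert res.R2 == 0.0 and res.p_value == 1.0

    def test_singleton_group_errors(self):
        ids = list("abc")
        groups = {"a": "X", "b": "X", "c": "Y"}
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(DistanceMatrix(ids, np.ones((3, 3)) - np.eye(3)), groups)

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        dist, groups = self._random_case(seed=9)
        mine = permanova(dist, groups, n_permutations=9, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.values, dist.sample_ids),
            [groups[s] for s in dist.sample_ids],
            permutations=9,
        )
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)
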