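import numpy as np
import pytest

from ricedus import (
    DistanceMatrix,
    TraitTable,
    distance_correlation,
    distance_matrix,
    lower_triangle,
    metric_screen,
    subsample_curve,
    trait_correlation_matrix,
)
from ricedus.distances import TEN_METRICS


def _dm(values, ids=None, metric="m"):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"A{i+1}" for i in range(values.shape[0])]
    return DistanceMatrix(values=values, variety_ids=ids, metric=metric)


def _random_dm(rng, n, ids=None):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return _dm(v, ids)


class TestLowerTriangle:
    def test_three_by_three_order(self):
        dm = _dm([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        np.testing.assert_array_equal(lower_triangle(dm), [0.1, 0.2, 0.3])

    def test_two_by_two_length_one(self):
        assert lower_triangle(_dm([[0, 0.5], [0.5, 0]])).shape == (1,)

    def test_length_formula(self, rng):
        dm = _random_dm(rng, 9)
        assert lower_triangle(dm).size == 9 * 8 // 2


class TestDistanceCorrelation:
    def test_identical_matrices_r_one(self, rng):
        dm = _random_dm(rng, 8)
        res = distance_correlation(dm, dm, n_perm=0)
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 28

    def test_affine_transform_r_one(self, rng):
        dm = _random_dm(rng, 8)
        dm2 = _dm(2.5 * dm.values + 0.3 * (1 - np.eye(8)))
        assert distance_correlation(dm, dm2, n_perm=0).r == pytest.approx(1.0)

    def test_four_variety_hand_computation(self):
        a = _dm([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]])
        b = _dm([[0, 2, 1, 5], [2, 0, 3, 4], [1, 3, 0, 7], [5, 4, 7, 0]])
        x = np.array([1, 2, 4, 3, 5, 6], dtype=float)
        y = np.array([2, 1, 3, 5, 4, 7], dtype=float)
        expected = float(np.corrcoef(x, y)[0, 1])
        assert distance_correlation(a, b, n_perm=0).r == pytest.approx(expected)

    def test_symmetric_in_arguments(self, rng):
        a, b = _random_dm(rng, 7), _random_dm(rng, 7)
        ra = distance_correlation(a, b, n_perm=0).r
        rb = distance_correlation(b, a, n_perm=0).r
        assert ra == pytest.approx(rb)

    def test_variety_mismatch_rejected(self, rng):
        a = _random_dm(rng, 4, ids=["A", "B", "C", "D"])
        b = _random_dm(rng, 4, ids=["A", "B", "C", "E"])
        with pytest.raises(ValueError):
            distance_correlation(a, b)

    def test_permutation_p_attains_minimum_for_identical(self, rng):
        dm = _random_dm(rng, 10)
        for n_perm in (49, 199):
            res = distance_correlation(dm, dm, n_perm=n_perm, rng=0)
            assert res.p == pytest.approx(1 / (n_perm + 1))

    def test_agrees_with_skbio_mantel(self, rng):
        skbio = pytest.importorskip("skbio")
        a, b = _random_dm(rng, 12), _random_dm(rng, 12)
        res = distance_correlation(a, b, n_perm=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(a.values, ids=a.variety_ids),
            skbio.DistanceMatrix(b.values, ids=b.variety_ids),
            method="pearson",
            permutations=0,
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)


class TestMetricScreen:
    def test_positive_correlation_under_strong_coupling(self, rng):
        # phenotypic side derived directly from genotypes: every metric
        # must detect the coupling
        from ricedus import SimulationConfig, encode_phenotypes, impute_mode
        from ricedus import simulate_genotypes, simulate_traits

        cfg = SimulationConfig(
            n_varieties=40,
            n_loci=400,
            n_subpops=3,
            fst=0.3,
            n_traits=10,
            h2=0.95,
            n_causal=80,
            n_levels=5,
            seed=9,
        )
        g, _ = simulate_genotypes(cfg)
        gi = impute_mode(g)
        traits, _ = simulate_traits(gi, cfg)
        pheno = encode_phenotypes(traits)
        results = metric_screen(
            gi.values, pheno, gi.variety_ids, TEN_METRICS, n_perm=0
        )
        assert len(results) == len(TEN_METRICS)
        assert all(res.r > 0 for res in results)
        # sorted by descending r
        rs = [res.r for res in results]
        assert rs == sorted(rs, reverse=True)

    def test_single_metric_delegates(self, small_panel):
        g = small_panel["genotypes"]
        pheno = small_panel["pheno"]
        [res] = metric_screen(
            g.values, pheno, g.variety_ids, ("jaccard",), n_perm=0
        )
        dm_mol = distance_matrix(g.values, "jaccard", g.variety_ids)
        dm_phe = distance_matrix(pheno.values, "jaccard", g.variety_ids)
        assert res.r == pytest.approx(
            distance_correlation(dm_mol, dm_phe, n_perm=0).r
        )


class TestSubsampleCurve:
    def test_full_size_equals_full_data_r(self, small_panel):
        g = small_panel["genotypes"]
        pheno = small_panel["pheno"]
        curve = subsample_curve(
            g.values, pheno, g.variety_ids, "snps", [g.n_loci], 3, "jaccard", 1
        )
        dm_mol = distance_matrix(g.values, "jaccard", g.variety_ids)
        dm_phe = distance_matrix(pheno.values, "jaccard", g.variety_ids)
        full_r = distance_correlation(dm_mol, dm_phe, n_perm=0).r
        np.testing.assert_allclose(curve.r_values, full_r)

    def test_deterministic_under_seed(self, small_panel):
        g = small_panel["genotypes"]
        pheno = small_panel["pheno"]
        kw = dict(axis="snps", sizes=[20, 100], reps=2, metric="jaccard", seed=7)
        c1 = subsample_curve(g.values, pheno, g.variety_ids, **kw)
        c2 = subsample_curve(g.values, pheno, g.variety_ids, **kw)
        np.testing.assert_array_equal(c1.r_values, c2.r_values)

    def test_largest_size_not_worse_than_smallest(self, small_panel):
        g = small_panel["genotypes"]
        pheno = small_panel["pheno"]
        curve = subsample_curve(
            g.values,
            pheno,
            g.variety_ids,
            "snps",
            [10, g.n_loci],
            reps=20,
            metric="jaccard",
            seed=3,
        )
        assert curve.r_values[1].mean() >= curve.r_values[0].mean()

    def test_trait_axis_never_splits_blocks(self, small_panel):
        g = small_panel["genotypes"]
        pheno = small_panel["pheno"]
        # subsampling 2 whole traits must give indicator matrices whose
        # row sums never exceed 2 (one indicator per kept trait)
        curve = subsample_curve(
            g.values, pheno, g.variety_ids, "traits", [2], 5, "jaccard", 11
        )
        assert curve.r_values.shape == (1, 5)
        # direct block-integrity check through the subset helper
        chosen = pheno.trait_names[:2]
        block = pheno.subset_traits(chosen)
        assert set(t for t, _ in block.column_labels) == set(chosen)
        full_cols = [c for c in pheno.column_labels if c[0] in chosen]
        assert block.column_labels == full_cols

    def test_oversized_request_rejected(self, small_panel):
        g = small_panel["genotypes"]
        pheno = small_panel["pheno"]
        with pytest.raises(ValueError):
            subsample_curve(
                g.values, pheno, g.variety_ids, "snps",
                [g.n_loci + 1], 1, "jaccard", 0,
            )


class TestTraitCorrelationMatrix:
    def test_diagonal_and_identical_columns(self):
        codes = np.array([[1, 1, 5], [2, 2, 4], [3, 3, 1], [4, 4, 2]], float)
        t = TraitTable(codes, ["a", "b", "c"], ["V1", "V2", "V3", "V4"])
        corr, mask = trait_correlation_matrix(t, display_cut=0.35)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert corr[0, 1] == pytest.approx(1.0)
        assert mask[0, 1]

    def test_antimonotone_minus_one(self):
        codes = np.column_stack([np.arange(1, 6), np.arange(5, 0, -1)]).astype(float)
        t = TraitTable(codes, ["up", "down"], [f"V{i}" for i in range(5)])
        corr, _ = trait_correlation_matrix(t)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_constant_column_masked_not_propagated(self):
        codes = np.array([[1, 3], [1, 4], [1, 5]], dtype=float)
        t = TraitTable(codes, ["const", "var"], ["V1", "V2", "V3"])
        corr, mask = trait_correlation_matrix(t)
        assert np.isnan(corr[0, 1])
        assert not mask[0, 1]
        assert corr[1, 1] == 1.0

    def test_pairwise_complete_over_missing(self):
        codes = np.array(
            [[1, 1], [2, 2], [3, 3], [np.nan, 9], [4, 4]], dtype=float
        )
        t = TraitTable(codes, ["a", "b"], [f"V{i}" for i in range(5)])
        corr, _ = trait_correlation_matrix(t)
        assert corr[0, 1] == pytest.approx(1.0)  # the nan row is excluded
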