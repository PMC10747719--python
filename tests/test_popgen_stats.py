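import math

import numpy as np
import pytest

from msatforge import (
    DistanceMatrix,
    allele_freqs,
    bootstrap_support,
    evanno_delta_k,
    fst_matrix,
    gst_overall,
    hwe_exact,
    hwe_table,
    nei_distance,
    nj_tree,
    pcoa,
    pic,
    summary_stats,
    write_newick,
)
from msatforge.synth_fixtures import simulate_genotypes
from conftest import make_dataset
from oracles import random_tree_distances


class TestAlleleFreqs:
    def test_counts_typed_alleles_only(self):
        ds = make_dataset({"P1": {"L1": [(128, 128), (128, 131), (0, 0)]}})
        table = allele_freqs(ds)
        assert table.freq("P1", "L1") == {128: 0.75, 131: 0.25}
        assert table.n[("P1", "L1")] == 2

    def test_all_missing_is_flagged_undefined(self):
        ds = make_dataset({"P1": {"L1": [(0, 0), (0, 0)]}})
        table = allele_freqs(ds)
        assert not table.is_defined("P1", "L1")
        assert table.freq("P1", "L1") == {}

    def test_frequencies_sum_to_one(self):
        ds, _ = simulate_genotypes(n_pops=2, n_per_pop=15, n_loci=8, fst=0.1,
                                   seed=2, missing_rate=0.1)
        table = allele_freqs(ds)
        for key, freqs in table.freqs.items():
            if table.n[key]:
                assert math.isclose(sum(freqs.values()), 1.0, abs_tol=1e-9)


class TestSummaryStats:
    def test_monomorphic_locus(self):
        ds = make_dataset({"P1": {"L1": [(100, 100)] * 5}})
        row = summary_stats(ds).iloc[0]
        assert (row.na, row.ho, row.he) == (1, 0.0, 0.0)

    def test_balanced_biallelic_he(self):
        ds = make_dataset({"P1": {"L1": [(100, 103), (100, 103)]}})
        assert summary_stats(ds).iloc[0].he == pytest.approx(0.5)

    def test_observed_heterozygosity_is_a_direct_count(self):
        het = [(100, 103)] * 13
        hom = [(100, 100)] * 7
        ds = make_dataset({"P1": {"L1": het + hom}})
        assert summary_stats(ds).iloc[0].ho == pytest.approx(0.65)

    def test_unbiased_flag_scales_he(self):
        ds = make_dataset({"P1": {"L1": [(100, 103), (100, 103)]}})
        he = summary_stats(ds, unbiased=True).iloc[0].he
        assert he == pytest.approx(0.5 * 4 / 3)


class TestPic:
    @pytest.mark.parametrize("freqs, expected", [
        ([0.5, 0.5], 0.375),
        ([1.0], 0.0),
        ([0.25] * 4, 0.703125),
    ])
    def test_examples(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected)

    def test_pic_below_he_on_random_simplex_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(2, 9))
            p = rng.dirichlet(np.ones(k))
            he = 1.0 - float(np.sum(p ** 2))
            assert 0.0 <= pic(p) < he + 1e-12

    def test_empty_input(self):
        with pytest.raises(ValueError):
            pic([])


class TestHweExact:
    def test_three_heterozygotes(self):
        # two admissible arrays with P = 0.4 (observed) and 0.6
        assert hwe_exact({(1, 2): 3}) == pytest.approx(0.4)

    def test_hw_proportions_give_p_one(self):
        # the observed array is the distribution's mode, so every array
        # qualifies and the tail probability is 1
        assert hwe_exact({(1, 1): 25, (1, 2): 50, (2, 2): 25}) == pytest.approx(1.0)

    def test_strong_heterozygote_excess_is_significant(self):
        assert hwe_exact({(1, 2): 40}) < 0.01

    def test_monomorphic_is_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_exact({(1, 1): 30})

    def test_mc_estimate_agrees_with_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            counts = _random_table(rng, n=15, k=3)
            exact = hwe_exact(counts)
            mc = hwe_exact(counts, mc_reps=4000, seed=11, max_enumeration=0)
            se = math.sqrt(max(exact * (1 - exact), 1e-6) / 4000)
            assert abs(mc - exact) <= 3 * se + 1e-12

    def test_seed_reproducible(self):
        counts = _random_table(np.random.default_rng(9), n=30, k=4)
        a = hwe_exact(counts, mc_reps=500, seed=5, max_enumeration=0)
        b = hwe_exact(counts, mc_reps=500, seed=5, max_enumeration=0)
        assert a == b


def _random_table(rng, n, k):
    p = rng.dirichlet(np.ones(k) * 3)
    counts = {}
    for _ in range(n):
        a, b = sorted(rng.choice(k, size=2, p=p) + 1)
        counts[(a, b)] = counts.get((a, b), 0) + 1
    if len({x for pair in counts for x in pair}) < 2:
        return {(1, 2): n}
    return counts


class TestHweTable:
    def test_small_and_monomorphic_cells_excluded(self):
        ds = make_dataset({
            "P1": {"L1": [(100, 103)] * 12, "L2": [(100, 100)] * 12},
            "P2": {"L1": [(100, 103)] * 5, "L2": [(100, 103)] * 5},
        })
        table = hwe_table(ds, min_n=10, seed=0)
        by = {(r.population, r.locus): r for r in table.itertuples()}
        assert not math.isnan(by[("P1", "L1")].p)
        assert math.isnan(by[("P1", "L2")].p)  # monomorphic
        assert math.isnan(by[("P2", "L1")].p)  # n below threshold


class TestNeiDistance:
    def test_identical_tables_give_zero(self):
        f = {"L1": {100: 0.3, 103: 0.7}, "L2": {200: 1.0}}
        assert nei_distance(f, f) == 0.0

    def test_single_locus_example(self):
        fa = {"L1": {100: 1.0}}
        fb = {"L1": {100: 0.5, 103: 0.5}}
        assert nei_distance(fa, fb) == pytest.approx(0.34657, abs=1e-5)

    def test_disjoint_alleles_give_infinity(self):
        fa = {"L1": {100: 1.0}}
        fb = {"L1": {103: 1.0}}
        assert nei_distance(fa, fb) == math.inf


class TestFstMatrix:
    def test_fixed_alternative_alleles(self):
        ds = make_dataset({
            "P1": {"L1": [(100, 100)] * 5},
            "P2": {"L1": [(103, 103)] * 5},
        })
        assert fst_matrix(ds)[("P1", "P2")] == pytest.approx(1.0)

    def test_identical_populations(self):
        block = [(100, 103)] * 4 + [(100, 100)] * 2
        ds = make_dataset({"P1": {"L1": block}, "P2": {"L1": block}})
        assert fst_matrix(ds)[("P1", "P2")] == pytest.approx(0.0)
        assert gst_overall(ds) == pytest.approx(0.0)

    def test_mirrored_frequencies(self):
        a = [(100, 100)] * 3 + [(100, 103)] * 2
        b = [(103, 103)] * 3 + [(100, 103)] * 2
        ds = make_dataset({"P1": {"L1": a}, "P2": {"L1": b}})
        assert fst_matrix(ds)[("P1", "P2")] == pytest.approx(0.36)


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        result = pcoa(dm)
        assert np.allclose(result.percent_variance, [50.0, 50.0])

    def test_collinear_points_put_everything_on_axis_one(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        result = pcoa(dm)
        assert np.allclose(result.percent_variance, [100.0])

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(list("abcdef"), d)
        coords = pcoa(dm).coordinates
        back = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(back, d, atol=1e-8)

    def test_agrees_with_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix(list("abcdefg"), d))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, list("abcdefg")))
        ref_pct = np.asarray(ref.proportion_explained)[:3] * 100
        assert np.allclose(ours.percent_variance[:3], ref_pct, atol=1e-6)

    def test_nan_matrix_is_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = math.nan
        with pytest.raises(ValueError, match="NaN"):
            pcoa(DistanceMatrix(["a", "b", "c"], d))


class TestNjTree:
    def test_recovers_additive_four_taxon_tree(self):
        d = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree.bipartitions() == {frozenset("AB")}
        newick = write_newick(tree)
        assert "(A:2,B:3)" in newick or "(B:3,A:2)" in newick

    def test_three_taxa_solve_exactly(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d))
        assert write_newick(tree) == "(A:1,B:2,C:3);"

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_ultrametric_matrix_matches_single_linkage_split(self):
        # ((A,B),(C,D)) with heights 1 and 4
        d = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree.bipartitions() == {frozenset("AB")}

    def test_agrees_with_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(12)
        for _ in range(10):
            labels = list("ABCDEF")
            dist, truth = random_tree_distances(rng, labels)
            d = np.array([[dist[a][b] for b in labels] for a in labels])
            ours = nj_tree(DistanceMatrix(labels, d)).bipartitions()
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
            ref_parts = _skbio_bipartitions(ref, set(labels))
            assert ours == truth == ref_parts


def _skbio_bipartitions(tree, all_labels):
    parts = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_labels) - 1:
            other = frozenset(all_labels) - below
            parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return parts


class TestBootstrapSupport:
    @staticmethod
    def _structured_dataset(seed=0):
        ds, _ = simulate_genotypes(n_pops=4, n_per_pop=20, n_loci=12, fst=0.15,
                                   seed=seed)
        return ds

    def test_single_replicate_gives_all_or_nothing(self):
        tree = bootstrap_support(self._structured_dataset(), reps=1, seed=0)
        supports = [n.support for n in _internal(tree) if n.support is not None]
        assert supports and all(s in (0, 100) for s in supports)

    def test_identical_seeds_identical_supports(self):
        ds = self._structured_dataset()
        t1 = bootstrap_support(ds, reps=25, seed=7)
        t2 = bootstrap_support(ds, reps=25, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_single_locus_is_an_error(self):
        ds = make_dataset({
            "P1": {"L1": [(100, 103)] * 4},
            "P2": {"L1": [(100, 103)] * 4},
            "P3": {"L1": [(100, 103)] * 4},
        })
        with pytest.raises(ValueError, match="2 loci"):
            bootstrap_support(ds, reps=10, seed=0)


def _internal(node):
    out = [] if node.is_leaf else [node]
    for c in node.children:
        out.extend(_internal(c))
    return out


class TestEvannoDeltaK:
    @staticmethod
    def _reps(means, sd=10.0):
        return {k + 1: [m - sd, m, m + sd] for k, m in enumerate(means)}

    def test_second_difference_example(self):
        result = evanno_delta_k(self._reps([-5000, -4000, -3900, -3890]))
        table = result.table.set_index("k")
        assert table.loc[2, "delta_k"] == pytest.approx(90.0)
        assert table.loc[3, "delta_k"] == pytest.approx(9.0)
        assert result.optimal_k == 2

    def test_linear_likelihoods_have_zero_delta_k(self):
        result = evanno_delta_k(self._reps([-500, -400, -300, -200]))
        assert np.allclose(result.table["delta_k"].dropna(), 0.0)

    def test_shift_invariance(self):
        base = self._reps([-5000, -4000, -3900, -3890])
        shifted = {k: [x + 1234.5 for x in v] for k, v in base.items()}
        a = evanno_delta_k(base).table["delta_k"].dropna().to_numpy()
        b = evanno_delta_k(shifted).table["delta_k"].dropna().to_numpy()
        assert np.allclose(a, b)

    def test_zero_variance_gives_infinity_with_warning(self):
        reps = {1: [-500.0, -500.0], 2: [-400.0, -400.0], 3: [-390.0, -390.0]}
        with pytest.warns(UserWarning, match="zero variance"):
            result = evanno_delta_k(reps)
        assert math.isinf(result.table.set_index("k").loc[2, "delta_k"])

    def test_nonconsecutive_k_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [1, 2], 3: [1, 2], 4: [1, 2]})
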