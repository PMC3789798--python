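import math

import numpy as np
import pytest
from scipy import stats

from linkmap.linkage import (
    LinkageMatrix,
    MaskRule,
    apply_masks,
    assign_bin,
    bin_pairs_by_distance,
    build_linkage_matrix,
    chromosome_genetic_length,
    consolidate,
    read_mask_rules,
    write_mask_rules,
)
from linkmap.pipeline import estimate_pair_distances
from linkmap.simulate import SimConfig, Simulation


class TestAssignBin:
    @pytest.mark.parametrize(
        "pos, expected", [(1, 0), (5000, 0), (5001, 1), (12300, 2)]
    )
    def test_boundaries(self, pos, expected):
        assert assign_bin(pos, 5000) == expected

    def test_position_below_one(self):
        with pytest.raises(ValueError):
            assign_bin(0, 5000)

    def test_beyond_chromosome(self):
        with pytest.raises(ValueError):
            assign_bin(300_001, 5000, chromosome_length=300_000)

    def test_partition(self):
        # every position maps to exactly one bin and bin < n
        length, bs = 23_750, 5000
        n = math.ceil(length / bs)
        bins = [assign_bin(p, bs, length) for p in range(1, length + 1)]
        assert min(bins) == 0 and max(bins) == n - 1
        assert sorted(set(bins)) == list(range(n))


def _mk(annotation, pairs, chrom="chrA", bin_size=5000):
    return build_linkage_matrix(pairs, annotation, chrom, bin_size)


class TestBuildMatrix:
    def test_cell_mean_and_counts(self, toy_annotation, pair_factory):
        # gA1 mid 100 kb -> bin 19; gA2 mid 140 kb -> bin 27
        pairs = [pair_factory("gA1", "gA2", 20.0), pair_factory("gA1", "gA2", 30.0)]
        lm = _mk(toy_annotation, pairs)
        assert lm.G[19, 27] == 25.0
        assert lm.counts[19, 27] == 2

    def test_empty_cell_is_missing_not_zero(self, toy_annotation, pair_factory):
        lm = _mk(toy_annotation, [pair_factory("gA1", "gA2", 20.0)])
        assert math.isnan(lm.G[0, 0])
        assert lm.counts[0, 0] == 0

    def test_single_pair_cell_equals_value(self, toy_annotation, pair_factory):
        lm = _mk(toy_annotation, [pair_factory("gA1", "gA3", 12.5)])
        assert lm.G[19, 31] == 12.5

    def test_unknown_gene_named(self, toy_annotation, pair_factory):
        with pytest.raises(KeyError, match="gNOPE"):
            _mk(toy_annotation, [pair_factory("gA1", "gNOPE", 5.0)])

    def test_wrong_chromosome_rejected(self, toy_annotation, pair_factory):
        with pytest.raises(ValueError, match="gB1"):
            _mk(toy_annotation, [pair_factory("gA1", "gB1", 5.0)])

    def test_order_invariance(self, toy_annotation, pair_factory):
        rng = np.random.default_rng(0)
        pairs = [
            pair_factory(q, a, v)
            for q, a, v in [
                ("gA1", "gA2", 10), ("gA2", "gA1", 40), ("gA1", "gA3", 5),
                ("gA1", "gA2", 30), ("gA3", "gA4", 50),
            ]
        ]
        lm1 = _mk(toy_annotation, pairs)
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        lm2 = _mk(toy_annotation, shuffled)
        np.testing.assert_array_equal(lm1.G, lm2.G)
        np.testing.assert_array_equal(lm1.counts, lm2.counts)


class TestConsolidate:
    def _matrix(self, G, chrom="chrA"):
        n = G.shape[0]
        return LinkageMatrix(
            chromosome=chrom, bin_size=5000, n=n, G=G,
            counts=np.ones((n, n), dtype=int), mask=np.zeros((n, n), dtype=bool),
        )

    def test_elementwise_average(self):
        lm = consolidate(self._matrix(np.array([[0.0, 10.0], [20.0, 0.0]])))
        np.testing.assert_array_equal(lm.G_prime, [[0.0, 15.0], [15.0, 0.0]])

    def test_single_direction_kept(self):
        G = np.array([[np.nan, 10.0], [np.nan, np.nan]])
        lm = consolidate(self._matrix(G))
        assert lm.G_prime[0, 1] == 10.0
        assert lm.G_prime[1, 0] == 10.0

    def test_excluded_chromosome_untouched(self):
        G = np.array([[0.0, 10.0], [20.0, 0.0]])
        lm = consolidate(self._matrix(G, chrom="chrIII"))
        np.testing.assert_array_equal(lm.G_prime, G)

    def test_symmetry_exact_on_random(self):
        rng = np.random.default_rng(5)
        G = rng.uniform(0, 50, (40, 40))
        G[rng.random((40, 40)) < 0.3] = np.nan
        lm = consolidate(self._matrix(G))
        Gp = lm.G_prime
        both = np.isfinite(Gp) & np.isfinite(Gp.T)
        assert np.max(np.abs(Gp[both] - Gp.T[both])) == 0.0


class TestMasks:
    def test_interval_masks_rows_and_columns(self, toy_annotation, pair_factory):
        lm = _mk(toy_annotation, [pair_factory("gA1", "gA2", 20.0)])
        lm = apply_masks(lm, [MaskRule("chrA", 1, 15_000, "marker")])
        assert lm.mask[:3, :].all() and lm.mask[:, :3].all()
        assert not lm.mask[3:, 3:].any()

    def test_empty_rules_no_change(self, toy_annotation, pair_factory):
        lm = _mk(toy_annotation, [pair_factory("gA1", "gA2", 20.0)])
        assert not apply_masks(lm, []).mask.any()

    def test_overlapping_rules_union(self, toy_annotation, pair_factory):
        lm = _mk(toy_annotation, [pair_factory("gA1", "gA2", 20.0)])
        rules = [MaskRule("chrA", 1, 10_000), MaskRule("chrA", 5_001, 15_000)]
        once = apply_masks(lm, rules)
        twice = apply_masks(once, rules)
        np.testing.assert_array_equal(once.mask, twice.mask)
        assert once.mask[:3, :].all()

    def test_other_chromosome_rule_ignored(self, toy_annotation, pair_factory):
        lm = _mk(toy_annotation, [pair_factory("gA1", "gA2", 20.0)])
        assert not apply_masks(lm, [MaskRule("chrB", 1, 15_000)]).mask.any()

    def test_rules_file_round_trip(self, tmp_path):
        rules = [MaskRule("chrV", 1, 40_000, "CAN1 marker"), MaskRule("chrXIV", 1, 80_000, "LYP1")]
        path = tmp_path / "masks.tsv"
        write_mask_rules(rules, path)
        assert read_mask_rules(path) == rules


class TestBinPairsByDistance:
    def test_bin_centers_and_means(self):
        d = np.array([1.0, 4.0, 7.0])
        v = np.array([10.0, 20.0, 30.0])
        centers, means, counts = bin_pairs_by_distance(d, v, 5.0)
        np.testing.assert_array_equal(centers, [2.5, 7.5])
        np.testing.assert_array_equal(means, [15.0, 30.0])
        np.testing.assert_array_equal(counts, [2, 1])

    def test_nan_skipped(self):
        centers, means, _ = bin_pairs_by_distance([1.0, 2.0], [np.nan, 4.0], 5.0)
        np.testing.assert_array_equal(means, [4.0])


class TestSyntheticMonotonicity:
    def test_mean_distance_increases_with_bin_separation(self):
        cfg = SimConfig(
            seed=11, genome=[(400_000, 200_000)], n_genes_per_chromosome=120,
            noise_sd=0.0, base_rate=1.0,
        )
        sim = Simulation(cfg)
        pairs = estimate_pair_distances(sim.screens())
        lm = consolidate(
            build_linkage_matrix(pairs["chr01"], sim.annotation, "chr01"), exclude=set()
        )
        i, j = np.indices(lm.G_prime.shape)
        sep = np.abs(i - j)
        seps, means = [], []
        # cap (50) reached at 50 kb = 10 bins at rate 1 cM/kb
        for d in range(1, 10):
            vals = lm.G_prime[(sep == d) & np.isfinite(lm.G_prime)]
            if len(vals):
                seps.append(d)
                means.append(vals.mean())
        rho = stats.spearmanr(seps, means).statistic
        assert rho >= 0.95


class TestChromosomeGeneticLength:
    def _uniform_maps(self, rate=1.0, lengths=(300_000, 500_000, 800_000, 1_200_000)):
        cfg = SimConfig(
            seed=2, genome=[(L, L // 2) for L in lengths], gene_spacing_bp=8000,
            noise_sd=0.0, base_rate=rate,
        )
        sim = Simulation(cfg)
        pairs = estimate_pair_distances(sim.screens())
        maps = {
            c: consolidate(build_linkage_matrix(p, sim.annotation, c), exclude=set())
            for c, p in pairs.items()
        }
        return maps, sim.annotation

    def test_recovers_planted_uniform_rate(self):
        rate = 1.0
        maps, ann = self._uniform_maps(rate)
        fit = chromosome_genetic_length(maps, ann)
        assert fit.a == pytest.approx(rate, rel=0.1)
        assert abs(fit.b) < 0.1 * max(t for _, t, _ in fit.per_chromosome.values())
        for name, (L, total, r) in fit.per_chromosome.items():
            assert total == pytest.approx(r * L, rel=1e-12)

    def test_fewer_than_three_chromosomes_refused(self, toy_annotation, pair_factory):
        lm = consolidate(
            build_linkage_matrix([pair_factory("gA1", "gA2", 20.0)], toy_annotation, "chrA"),
            exclude=set(),
        )
        with pytest.raises(ValueError):
            chromosome_genetic_length({"chrA": lm}, toy_annotation)

    def test_equal_rates_perfect_fit(self):
        # analytic matrices with exactly equal per-cell rates
        from linkmap.io_formats import Chromosome, GenomeAnnotation

        rate, bs = 0.8, 5000
        lengths = (300_000, 500_000, 800_000, 1_200_000)
        ann = GenomeAnnotation(
            [Chromosome(f"chr{i:02d}", L, L // 2) for i, L in enumerate(lengths)]
        )
        maps = {}
        for i, L in enumerate(lengths):
            n = math.ceil(L / bs)
            ii, jj = np.indices((n, n))
            G = rate * np.abs(ii - jj) * bs / 1000.0
            G[G >= 50.0] = np.nan  # keep only the linear range
            lm = LinkageMatrix(
                f"chr{i:02d}", bs, n, G, np.ones((n, n), dtype=int),
                np.zeros((n, n), dtype=bool), G_prime=G,
            )
            maps[f"chr{i:02d}"] = lm
        fit = chromosome_genetic_length(maps, ann)
        L_arr = np.array([v[0] for v in fit.per_chromosome.values()])
        total = np.array([v[1] for v in fit.per_chromosome.values()])
        resid = total - (fit.a * L_arr + fit.b)
        assert np.max(np.abs(resid)) < 1e-6 * total.max()
        assert fit.a == pytest.approx(rate, rel=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-6)
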