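"""Gamete sampling, crossing, diallel combinatorics, doubled haploids."""

import itertools

import numpy as np
import pytest
from scipy import stats

from breedsim import (
    CrossPlan,
    GeneticMap,
    Population,
    cross,
    diallel,
    diallel_plan,
    double_haploid,
    flatten_dh,
    positions_to_recomb,
    random_crosses,
    sample_gamete,
    sample_masks,
)

from conftest import random_population


def two_marker_map(delta_cM):
    pos = np.array([0.0, delta_cM])
    chrom = np.array(["1", "1"])
    return GeneticMap(
        chromosome=chrom,
        recomb_prob=positions_to_recomb(pos, chrom),
        effects=np.ones((1, 2)),
        trait_names=["T"],
        position_cM=pos,
    )


class TestGamete:
    def test_homozygous_parent_gives_its_haplotype(self, small_map, rng):
        hap = (rng.random(small_map.n_markers) < 0.5).astype(np.int8)
        parent = np.stack([hap, hap], axis=-1)
        gamete = sample_gamete(parent, small_map, rng)
        np.testing.assert_array_equal(gamete, hap)

    def test_zero_recombination_keeps_chromosomes_intact(self, small_map, rng):
        gmap = GeneticMap(
            chromosome=small_map.chromosome,
            recomb_prob=np.where(small_map.chrom_end, np.nan, 0.0),
            effects=small_map.effects,
            trait_names=small_map.trait_names,
        )
        parent = np.stack(
            [np.zeros(gmap.n_markers, np.int8), np.ones(gmap.n_markers, np.int8)],
            axis=-1,
        )
        for _ in range(20):
            gamete = sample_gamete(parent, gmap, rng)
            for sl in gmap.chromosome_slices():
                piece = gamete[sl]
                assert (piece == piece[0]).all()  # one intact haplotype per chromosome

    def test_recombinant_fraction_matches_haldane(self, rng):
        """Two markers 10 cM apart: recombinant gametes at the Haldane rate."""
        gmap = two_marker_map(10.0)
        r = gmap.recomb_prob[0]
        n = 20_000
        masks = sample_masks(gmap, n, rng)
        frac = (masks[:, 0] != masks[:, 1]).mean()
        sd = np.sqrt(r * (1 - r) / n)
        assert abs(frac - r) < 4 * sd

    def test_uniform_start_per_chromosome(self, rng):
        gmap = two_marker_map(10.0)
        masks = sample_masks(gmap, 20_000, rng)
        start = masks[:, 0].mean()
        assert abs(start - 0.5) < 4 * np.sqrt(0.25 / 20_000)

    def test_chromosome_independence(self, rng):
        """Mask states on different chromosomes are independent."""
        chrom = np.array(["1", "1", "2", "2"])
        pos = np.array([0.0, 5.0, 0.0, 5.0])
        gmap = GeneticMap(
            chromosome=chrom,
            recomb_prob=positions_to_recomb(pos, chrom),
            effects=np.ones((1, 4)),
            trait_names=["T"],
            position_cM=pos,
        )
        masks = sample_masks(gmap, 4000, rng)
        table = np.zeros((2, 2))
        for a in (0, 1):
            for b in (0, 1):
                table[a, b] = ((masks[:, 0] == a) & (masks[:, 2] == b)).sum()
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 1e-3


class TestCross:
    def test_output_shape(self, small_map, founders, rng):
        plan = CrossPlan([[0, 1], [2, 3], [4, 5]])
        off = cross(founders, plan, small_map, rng)
        assert off.genome.shape == (3, small_map.n_markers, 2)

    def test_allele_provenance(self, small_map, rng):
        """Every offspring allele occurs in the corresponding parent."""
        pop = random_population(10, small_map, rng)
        pairs = np.column_stack(
            [rng.integers(0, 10, 25), rng.integers(0, 10, 25)]
        )
        off = cross(pop, CrossPlan(pairs), small_map, rng)
        for i, (p0, p1) in enumerate(pairs):
            assert all(
                off.genome[i, j, 0] in pop.genome[p0, j] for j in range(pop.m)
            )
            assert all(
                off.genome[i, j, 1] in pop.genome[p1, j] for j in range(pop.m)
            )

    def test_homozygous_reference_parents_give_zeros(self, small_map, rng):
        pop = Population(np.zeros((2, small_map.n_markers, 2), np.int8))
        off = cross(pop, CrossPlan([[0, 1]]), small_map, rng)
        assert not off.genome.any()

    def test_selfing_segregates_1_2_1(self, rng):
        """Selfing a fully heterozygous parent: genotypes 0/1/2 at 1:2:1."""
        gmap = two_marker_map(50.0)
        parent = Population(
            np.array([[[0, 1], [0, 1]]], dtype=np.int8)
        )
        n = 4000
        plan = CrossPlan(np.zeros((n, 2), dtype=int))
        off = cross(parent, plan, gmap, rng)
        dosage = off.genome.sum(axis=2)
        for j in range(2):
            counts = np.bincount(dosage[:, j], minlength=3)
            for c, p in zip(counts, (0.25, 0.5, 0.25)):
                sd = np.sqrt(n * p * (1 - p))
                assert abs(c - n * p) < 4 * sd

    def test_out_of_range_pair_named(self, small_map, founders, rng):
        with pytest.raises(IndexError, match="pair 1"):
            cross(founders, CrossPlan([[0, 1], [0, 99]]), small_map, rng)

    def test_determinism(self, small_map, founders):
        plan = CrossPlan([[0, 1], [2, 3]])
        a = cross(founders, plan, small_map, np.random.default_rng(5))
        b = cross(founders, plan, small_map, np.random.default_rng(5))
        np.testing.assert_array_equal(a.genome, b.genome)


class TestRandomCrosses:
    def test_shape_and_determinism(self, small_map, founders):
        a = random_crosses(founders, 200, small_map, np.random.default_rng(3))
        b = random_crosses(founders, 200, small_map, np.random.default_rng(3))
        assert a.genome.shape == (200, small_map.n_markers, 2)
        np.testing.assert_array_equal(a.genome, b.genome)

    def test_zero_crosses(self, small_map, founders, rng):
        assert random_crosses(founders, 0, small_map, rng).n == 0

    def test_needs_two_parents(self, small_map, founders, rng):
        solo = founders.subset([0])
        with pytest.raises(ValueError, match="at least 2"):
            random_crosses(solo, 5, small_map, rng)


class TestDiallel:
    @pytest.mark.parametrize("n,per,expected", [(10, 10, 450), (20, 10, 1900), (2, 1, 1)])
    def test_offspring_counts(self, small_map, rng, n, per, expected):
        pop = random_population(n, small_map, rng)
        off = diallel(pop, per, small_map, rng)
        assert off.n == expected

    @pytest.mark.parametrize("n", [2, 5, 13, 30])
    def test_plan_matches_pair_enumeration(self, n):
        """Diallel plan equals brute-force enumeration of unordered pairs."""
        plan = diallel_plan(n, 1)
        expected = sorted(itertools.combinations(range(n), 2))
        got = sorted(map(tuple, plan.pairs))
        assert got == expected
        assert plan.k == n * (n - 1) // 2

    def test_needs_two_parents(self):
        with pytest.raises(ValueError):
            diallel_plan(1, 1)


class TestDoubledHaploid:
    def test_shape_contract(self, small_map, founders, rng):
        out = double_haploid(founders, 4, small_map, rng)
        assert out.shape == (founders.n, 4, small_map.n_markers, 2)

    def test_every_line_homozygous(self, small_map, rng):
        pop = random_population(6, small_map, rng)
        out = double_haploid(pop, 5, small_map, rng)
        np.testing.assert_array_equal(out[..., 0], out[..., 1])

    def test_homozygous_parent_reproduced_exactly(self, small_map, rng):
        hap = (rng.random(small_map.n_markers) < 0.5).astype(np.int8)
        pop = Population(np.stack([hap, hap], axis=-1)[None])
        out = double_haploid(pop, 3, small_map, rng)
        for i in range(3):
            np.testing.assert_array_equal(out[0, i], pop.genome[0])

    def test_flatten(self, small_map, founders, rng):
        out = double_haploid(founders, 4, small_map, rng)
        flat = flatten_dh(out)
        assert flat.n == founders.n * 4
        np.testing.assert_array_equal(flat.genome[:4], out[0])

    def test_dh_must_be_positive(self, small_map, founders, rng):
        with pytest.raises(ValueError):
            double_haploid(founders, 0, small_map, rng)
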