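"""Meiotic recombination: gametes, crosses, cross batches, doubled haploids.

The gamete sampler realizes the Poisson crossover model at marker resolution
as a first-order Markov chain over the contributing-haplotype indicator: the
haplotype contributing the allele at the first marker of each chromosome is
chosen uniformly, and at every subsequent marker it switches with the
recombination probability of the preceding interval. This is the exact
marginal of a Poisson crossover process observed at the marker positions, and
it samples a gamete in O(m).

All randomness flows through an explicit ``numpy.random.Generator``; there is
no global RNG state. Identical generator state gives identical output arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .linkage_map import GeneticMap
from .population import PLOIDY, Population


@dataclass
class CrossPlan:
    """An ordered batch of ``k`` biparental crosses, as parent-index pairs."""

    pairs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=int)
        if p.size == 0:
            p = p.reshape(0, 2)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValidationError(f"pairs must have shape (k, 2); got {p.shape}")
        self.pairs = p

    @property
    def k(self) -> int:
        return self.pairs.shape[0]

    def check(self, n: int) -> None:
        if self.k and (self.pairs.min() < 0 or self.pairs.max() >= n):
            bad = int(
                np.flatnonzero((self.pairs < 0).any(1) | (self.pairs >= n).any(1))[0]
            )
            raise IndexError(
                f"cross pair {bad} = {tuple(self.pairs[bad])} is out of range "
                f"for a population of {n}"
            )


def sample_masks(gmap: GeneticMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``(n_gametes, m)`` recombination masks.

    Each mask is a 0/1 vector selecting, at every marker, which of the two
    parental haplotypes contributes the allele. Within a chromosome the mask
    follows the Markov switching process defined by the map's recombination
    probabilities; the start of each chromosome is uniform. Masks for
    different gametes are independent.

    Implementation: per-marker toggle indicators (probability 0.5 at a
    chromosome start, the interval recombination probability elsewhere),
    cumulated with XOR along the genome. A 0.5-toggle at a chromosome start
    makes the state there uniform and independent of the previous chromosome.
    """
    toggles = rng.random((n_gametes, gmap.n_markers)) < gmap.toggle_prob
    return np.cumsum(toggles, axis=1).astype(np.int8) % 2


def gametes_from_masks(genomes: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Apply recombination masks to parental genomes.

    ``genomes`` has shape ``(..., m, 2)`` and ``masks`` shape ``(..., m)``
    with matching leading axes; returns the ``(..., m)`` gametes. Works for
    real-valued ("soft") parents as well as binary ones.
    """
    sel = np.asarray(masks)[..., None]
    return np.take_along_axis(np.asarray(genomes), sel, axis=-1)[..., 0]


def sample_gamete(
    individual: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombined gamete (length ``m``) from one ``(m, 2)`` genome."""
    genome = np.asarray(individual)
    if genome.shape != (gmap.n_markers, PLOIDY):
        raise ValidationError(
            f"individual genome must have shape ({gmap.n_markers}, {PLOIDY}); "
            f"got {genome.shape}"
        )
    mask = sample_masks(gmap, 1, rng)[0]
    return gametes_from_masks(genome, mask)


def cross(
    pop: Population,
    plan: CrossPlan,
    gmap: GeneticMap,
    rng: np.random.Generator,
    masks: np.ndarray | None = None,
) -> Population:
    """Perform the ``k`` biparental crosses of a plan.

    Offspring ``i`` receives two independent gametes: haplotype 0 from
    ``plan.pairs[i, 0]`` and haplotype 1 from ``plan.pairs[i, 1]``. Output
    shape is ``(k, m, 2)``.

    ``masks`` (shape ``(k, 2, m)``) may be supplied to fix the recombination
    outcomes, e.g. for paired comparisons with the continuous relaxation.
    """
    pop.check_map(gmap)
    plan = plan if isinstance(plan, CrossPlan) else CrossPlan(plan)
    plan.check(pop.n)
    k, m = plan.k, pop.m
    if masks is None:
        masks = sample_masks(gmap, 2 * k, rng).reshape(k, 2, m)
    else:
        masks = np.asarray(masks, dtype=np.int8).reshape(k, 2, m)
    parents = pop.genome[plan.pairs]          # (k, 2, m, 2)
    gametes = gametes_from_masks(parents, masks)  # (k, 2, m)
    return Population(np.moveaxis(gametes, 1, 2))


def random_crosses(
    pop: Population, k: int, gmap: GeneticMap, rng: np.random.Generator
) -> Population:
    """``k`` crosses between uniformly sampled distinct-parent pairs.

    Pairs are drawn with replacement across crosses; the two parents within
    a pair are always distinct (biparental).
    """
    if pop.n < 2:
        raise ValueError("random crosses need at least 2 parents")
    first = rng.integers(0, pop.n, size=k)
    second = rng.integers(0, pop.n - 1, size=k)
    second = second + (second >= first)
    return cross(pop, CrossPlan(np.column_stack([first, second])), gmap, rng)


def diallel_plan(n: int, offspring_per_cross: int = 1) -> CrossPlan:
    """Full-diallel plan: every unordered distinct pair, no selfs.

    ``n (n - 1) / 2`` pairs, each repeated ``offspring_per_cross`` times.
    """
    if n < 2:
        raise ValueError("a diallel needs at least 2 parents")
    i, j = np.triu_indices(n, k=1)
    pairs = np.repeat(np.column_stack([i, j]), offspring_per_cross, axis=0)
    return CrossPlan(pairs)


def diallel(
    pop: Population,
    offspring_per_cross: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Population:
    """Cross every unordered pair of distinct parents.

    Yields ``n (n - 1) / 2 * offspring_per_cross`` offspring: a full diallel
    of 10 parents with 10 offspring per cross gives 450 individuals, and of
    20 parents, 1900.
    """
    return cross(pop, diallel_plan(pop.n, offspring_per_cross), gmap, rng)


def double_haploid(
    pop: Population, dh: int, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Doubled-haploid induction: ``dh`` fully homozygous lines per individual.

    Each line is one recombined gamete duplicated onto both haplotypes, so
    every output individual is homozygous at every marker. The output keeps
    the per-parent grouping: shape ``(n, dh, m, d)``. Use
    :func:`flatten_dh` to obtain a Population of ``n * dh`` individuals.
    """
    if dh < 1:
        raise ValueError("dh (lines per individual) must be >= 1")
    pop.check_map(gmap)
    n, m = pop.n, pop.m
    masks = sample_masks(gmap, n * dh, rng).reshape(n, dh, m)
    parents = pop.genome[:, None, :, :]           # (n, 1, m, 2) broadcast over dh
    gametes = gametes_from_masks(np.broadcast_to(parents, (n, dh, m, 2)), masks)
    return np.stack([gametes, gametes], axis=-1).astype(np.int8)


def flatten_dh(dh_array: np.ndarray) -> Population:
    """Flatten a ``(n, dh, m, d)`` doubled-haploid block to a Population."""
    n, dh, m, d = dh_array.shape
    return Population(dh_array.reshape(n * dh, m, d))
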