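"""Synthetic linkage maps and founder populations.

Everything the simulator consumes can be generated here, seeded and
self-validating, so the whole package is testable and runnable without any
external data. Founders are drawn site-independently (no linkage
disequilibrium); an inbred mode sets both haplotypes equal at every marker,
matching the fully homozygous founders of an inbred breeding program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .linkage_map import GeneticMap, positions_to_recomb
from .population import Population


@dataclass
class FixtureSpec:
    """Geometry and sampling parameters for synthetic maps and founders."""

    chromosomes: int = 10
    markers_per_chromosome: int = 100
    chromosome_length_cM: float = 100.0
    founders: int = 50
    allele_freq: float = 0.5
    traits: int = 1
    effect_std: float = 1.0
    heritability: tuple[float, ...] = (0.4,)
    inbred: bool = False
    random_positions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chromosomes, self.markers_per_chromosome, self.founders) < 0:
            raise ValidationError("fixture counts must be non-negative")
        if self.chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValidationError("need at least one chromosome and one marker")
        if self.traits < 1:
            raise ValidationError("need at least one trait")
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValidationError("allele_freq must lie in [0, 1]")
        if len(self.heritability) not in (1, self.traits):
            raise ValidationError(
                "heritability must have one value or one per trait"
            )


def make_map(spec: FixtureSpec) -> GeneticMap:
    """Synthetic map: evenly spaced (or sorted-uniform) positions per
    chromosome over ``chromosome_length_cM``, standard-normal effects scaled
    by ``effect_std``. Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    c, per = spec.chromosomes, spec.markers_per_chromosome
    m = c * per
    chromosome = np.repeat([f"chr{i + 1}" for i in range(c)], per)
    if spec.random_positions:
        pos = np.concatenate(
            [np.sort(rng.uniform(0, spec.chromosome_length_cM, per)) for _ in range(c)]
        )
    else:
        pos = np.tile(np.linspace(0.0, spec.chromosome_length_cM, per), c)
    effects = rng.standard_normal((spec.traits, m)) * spec.effect_std
    h2 = np.broadcast_to(np.asarray(spec.heritability, float), (spec.traits,))
    return GeneticMap(
        chromosome=chromosome,
        recomb_prob=positions_to_recomb(pos, chromosome),
        effects=effects,
        trait_names=[f"trait{i + 1}" for i in range(spec.traits)],
        position_cM=pos,
        heritability=h2.copy(),
    )


def make_founders(spec: FixtureSpec, gmap: GeneticMap) -> Population:
    """Synthetic founders: phased binary genomes, sites independent, allele 1
    at frequency ``spec.allele_freq``. In inbred mode one haplotype is drawn
    and duplicated, so every founder is homozygous at every marker."""
    rng = np.random.default_rng(spec.seed + 1)
    n, m = spec.founders, gmap.n_markers
    if spec.inbred:
        hap = (rng.random((n, m)) < spec.allele_freq).astype(np.int8)
        genome = np.stack([hap, hap], axis=-1)
    else:
        genome = (rng.random((n, m, 2)) < spec.allele_freq).astype(np.int8)
    return Population(genome, ids=[f"F{i:04d}" for i in range(n)])
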