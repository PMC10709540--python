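"""Truncation selection and the standard score functions.

A score function maps a population to one finite real score per individual;
:func:`select` keeps the top ``k``. Three scores ship with the package:

* genomic estimated breeding value (``score_gebv``) — genomic selection;
* optimal haploid value (``score_ohv``) — the merit of the best doubled
  haploid derivable from an individual: twice the sum, over genome segments,
  of the better haplotype's summed effect contribution;
* simulated phenotype (``score_phenotype``) — with low heritability this is
  visual selection, with high heritability a well-replicated yield trial.

Multi-trait populations are aggregated into a scalar by a linear index with
user weights (equal by default).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .linkage_map import GeneticMap
from .population import Population
from .traits import PhenotypeSimulator, gebv, phenotype as _phenotype, phenotype_mean

ScoreFunction = Callable[[Population], np.ndarray]


def _trait_index(values: np.ndarray, trait_weights) -> np.ndarray:
    """Collapse (n, t) trait values to length-n scores by a linear index."""
    t = values.shape[1]
    w = np.ones(t) if trait_weights is None else np.asarray(trait_weights, float)
    if w.shape != (t,):
        raise ValidationError(f"trait_weights must have length {t}")
    return values @ w


def select(
    pop: Population, k: int, score: ScoreFunction | np.ndarray
) -> tuple[Population, np.ndarray]:
    """Keep the ``k`` highest-scoring individuals.

    ``score`` is either a callable ``Population -> (n,) scores`` or a
    precomputed score vector. Ties break toward the lower original index,
    deterministically. The selected individuals are returned in original
    index order together with their indices, so selections are subsets with
    provenance.
    """
    scores = score(pop) if callable(score) else np.asarray(score, dtype=float)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if scores.shape != (pop.n,):
        raise ValidationError(
            f"score returned {scores.shape[0]} values for {pop.n} individuals"
        )
    if not np.isfinite(scores).all():
        bad = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise ValidationError(f"non-finite score for individual {bad}")
    if not 1 <= k <= pop.n:
        raise ValueError(f"k must satisfy 1 <= k <= n = {pop.n}; got {k}")
    # stable sort on -scores: equal scores keep ascending original index
    order = np.argsort(-scores, kind="stable")[:k]
    idx = np.sort(order)
    return pop.subset(idx), idx


def score_gebv(
    pop: Population, gmap: GeneticMap, trait_weights: Sequence[float] | None = None
) -> np.ndarray:
    """Linear-index-weighted GEBV scores (equal trait weights by default)."""
    return _trait_index(gebv(pop, gmap).values, trait_weights)


def ohv(
    pop: Population,
    gmap: GeneticMap,
    segments: Sequence[slice] | None = None,
    block_size: int | None = None,
) -> np.ndarray:
    """Optimal haploid values per trait, shape ``(n, t)``.

    ``OHV(i, tau) = 2 * sum_seg max_h sum_{j in seg} effects[tau, j] *
    genome[i, j, h]`` — the GEBV of the best doubled haploid obtainable from
    individual ``i`` if each segment could be inherited intact. Segments
    default to whole chromosomes; ``block_size`` instead cuts each chromosome
    into fixed-size marker blocks.
    """
    pop.check_map(gmap)
    if segments is None:
        segments = []
        for sl in gmap.chromosome_slices():
            if block_size is None:
                segments.append(sl)
            else:
                segments.extend(
                    slice(a, min(a + block_size, sl.stop))
                    for a in range(sl.start, sl.stop, block_size)
                )
    out = np.zeros((pop.n, gmap.n_traits))
    genome = pop.genome.astype(float)
    for sl in segments:
        hap_vals = np.einsum("tm,nmh->nth", gmap.effects[:, sl], genome[:, sl])
        out += hap_vals.max(axis=2)
    return 2.0 * out


def score_ohv(
    pop: Population,
    gmap: GeneticMap,
    segments: Sequence[slice] | None = None,
    block_size: int | None = None,
    trait_weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Linear-index-weighted optimal haploid value scores."""
    return _trait_index(ohv(pop, gmap, segments, block_size), trait_weights)


def score_phenotype(
    pop: Population,
    gmap: GeneticMap,
    n_envs: int,
    rng: np.random.Generator,
    trait_weights: Sequence[float] | None = None,
    heritability=None,
    simulator: PhenotypeSimulator | None = None,
) -> np.ndarray:
    """Mean simulated phenotype across ``n_envs`` environments.

    ``heritability`` overrides the map's value (e.g. per breeding-program
    stage); a prebuilt ``simulator`` may be passed to reuse fixed G×E
    effects across calls. Otherwise a simulator is calibrated on ``pop``.
    """
    if simulator is not None:
        values = simulator.phenotype(pop, n_envs, rng)
    else:
        m = gmap if heritability is None else gmap.with_heritability(heritability)
        values = _phenotype(pop, m, n_envs, rng)
    return _trait_index(phenotype_mean(values), trait_weights)
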