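"""Continuous relaxation of biparental crossing.

A hard cross picks two concrete parents; the relaxation replaces each parent
slot by a point on the simplex over the whole population. For a batch of
``k`` crosses on a population of size ``n``, the weights form a
``(k, n, 2)`` array whose ``(cross, slot)`` rows are non-negative and sum to
one. Each "soft parent" is the weighted average of all genomes, a
recombination mask is sampled once per gamete exactly as in the hard cross,
and the mask is applied to the soft parent.

Holding the masks fixed, the output is a *linear* function of the weights.
That is the differentiability contract: the gradient with respect to the
weights exists pathwise (masks are treated as fixed samples), so any
automatic-differentiation backend — or the hand-coded linear adjoint — yields
it. At a simplex vertex (one-hot weights) the relaxation reproduces the hard
cross exactly under the same masks, so gradient-based optimizers can move
continuously between discrete crossing plans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .linkage_map import GeneticMap
from .meiosis import gametes_from_masks, sample_masks
from .population import Population

#: Per-slot weight rows must sum to 1 within this tolerance; anything further
#: off is rejected rather than silently renormalized, which would corrupt
#: optimizer steps.
WEIGHT_TOL = 1e-8


@dataclass
class CrossWeights:
    """``(k, n, 2)`` simplex weights: one row per (cross, parent slot)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3 or w.shape[2] != 2:
            raise ValidationError(
                f"weights must have shape (k, n, 2); got {w.shape}"
            )
        if (w < 0).any():
            raise ValidationError("cross weights must be non-negative")
        sums = w.sum(axis=1)
        if not np.allclose(sums, 1.0, rtol=0, atol=WEIGHT_TOL):
            worst = float(np.abs(sums - 1.0).max())
            raise ValidationError(
                "each (cross, parent-slot) weight row must sum to 1 "
                f"(max deviation {worst:.3g} > {WEIGHT_TOL:g})"
            )
        self.weights = w

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_pairs(cls, pairs, n: int) -> "CrossWeights":
        """One-hot weights reproducing a hard cross plan on ``n`` parents."""
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        w = np.zeros((pairs.shape[0], n, 2))
        for s in (0, 1):
            w[np.arange(pairs.shape[0]), pairs[:, s], s] = 1.0
        return cls(w)


def soft_parents(pop: Population, w: CrossWeights) -> np.ndarray:
    """Weighted-average parents, shape ``(k, 2, m, 2)``.

    ``soft[c, s]`` is the (m, 2) real genome of slot ``s`` of cross ``c``:
    the weights-weighted average of every population member's genome.
    """
    if w.weights.shape[1] != pop.n:
        raise ValidationError(
            f"weights are over {w.weights.shape[1]} parents but the "
            f"population has {pop.n}"
        )
    return np.einsum("kns,nmh->ksmh", w.weights, pop.genome.astype(float))


def soft_cross(
    pop: Population,
    w: CrossWeights | np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator | None = None,
    masks: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-parent crossing: ``k`` real-valued offspring ``(k, m, 2)``.

    One recombination mask is sampled per gamete (two per cross) and applied
    to the soft parent of its slot. For binary populations and simplex
    weights the output lies in [0, 1]. With the masks held fixed the map
    ``weights -> offspring`` is linear.

    Either ``rng`` (to sample masks) or explicit ``masks`` of shape
    ``(k, 2, m)`` must be given.
    """
    if not isinstance(w, CrossWeights):
        w = CrossWeights(w)
    pop.check_map(gmap)
    if masks is None:
        if rng is None:
            raise ValueError("either rng or masks must be provided")
        masks = sample_masks(gmap, 2 * w.k, rng).reshape(w.k, 2, gmap.n_markers)
    else:
        masks = np.asarray(masks, dtype=np.int8).reshape(w.k, 2, gmap.n_markers)
    parents = soft_parents(pop, w)                # (k, 2, m, 2)
    gametes = gametes_from_masks(parents, masks)  # (k, 2, m)
    return np.moveaxis(gametes, 1, 2)             # (k, m, 2)
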