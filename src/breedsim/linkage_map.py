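"""Genetic linkage maps.

A linkage map is the simulator's static parameterization: one row per marker
with a chromosome identifier, a genetic position in centimorgans (or,
alternatively, a pre-computed per-interval recombination probability), and one
column of additive effects per trait.

Genetic distances are converted to recombination probabilities with the
Haldane mapping function ``r = (1 - exp(-2 d)) / 2`` (``d`` in Morgans), the
exact inverse map of a Poisson crossover process without interference: the
probability of an odd number of crossovers in an interval of ``d`` Morgans
under a Poisson(``d``) count is exactly that expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MapSchemaError, TraitLookupError, ValidationError

#: Accepted names for the chromosome-identifier column, in priority order.
CHROM_COLUMNS = ("CHR.PHYS", "chromosome", "chrom", "CHR")
#: Column holding marker positions in centimorgans.
POSITION_COLUMN = "cM"
#: Column holding per-interval recombination probabilities.
RECOMB_COLUMN = "RecombRate"

_RESERVED = set(CHROM_COLUMNS) | {POSITION_COLUMN, RECOMB_COLUMN}


@dataclass
class GeneticMap:
    """Validated per-marker map with per-trait additive effects.

    Parameters
    ----------
    chromosome
        Length-``m`` array of chromosome labels. Markers of one chromosome
        must be contiguous.
    recomb_prob
        Length-``m`` array; entry ``j`` is the probability of a recombination
        between marker ``j`` and marker ``j+1`` of the same chromosome.
        The entry at the last marker of each chromosome is undefined and
        ignored (NaN when derived from positions).
    effects
        ``(t, m)`` matrix of additive marker effects, one row per trait.
    trait_names
        ``t`` trait labels matching the effect rows.
    position_cM
        Optional length-``m`` genetic positions, non-decreasing within each
        chromosome.
    heritability
        Optional length-``t`` narrow-sense heritabilities, each in (0, 1].
    """

    chromosome: np.ndarray
    recomb_prob: np.ndarray
    effects: np.ndarray
    trait_names: list[str]
    position_cM: np.ndarray | None = None
    heritability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome)
        self.recomb_prob = np.asarray(self.recomb_prob, dtype=float)
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        self.trait_names = list(self.trait_names)
        if self.position_cM is not None:
            self.position_cM = np.asarray(self.position_cM, dtype=float)
        if self.heritability is not None:
            self.heritability = np.atleast_1d(
                np.asarray(self.heritability, dtype=float)
            )
        self._validate()

    # -- derived geometry ---------------------------------------------------

    @property
    def n_markers(self) -> int:
        return self.chromosome.shape[0]

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def chrom_start(self) -> np.ndarray:
        """Boolean mask: True at the first marker of each chromosome."""
        start = np.ones(self.n_markers, dtype=bool)
        start[1:] = self.chromosome[1:] != self.chromosome[:-1]
        return start

    @property
    def chrom_end(self) -> np.ndarray:
        """Boolean mask: True at the last marker of each chromosome."""
        end = np.ones(self.n_markers, dtype=bool)
        end[:-1] = self.chromosome[:-1] != self.chromosome[1:]
        return end

    @property
    def chromosomes(self) -> np.ndarray:
        """Chromosome labels in order of first appearance."""
        return self.chromosome[self.chrom_start]

    def chromosome_slices(self) -> list[slice]:
        """Marker-index slice of each chromosome, in map order."""
        starts = np.flatnonzero(self.chrom_start)
        stops = np.append(starts[1:], self.n_markers)
        return [slice(a, b) for a, b in zip(starts, stops)]

    @property
    def toggle_prob(self) -> np.ndarray:
        """Per-marker haplotype-switch probability for the gamete sampler.

        0.5 at the first marker of each chromosome (uniform start of the
        Markov chain), the preceding interval's recombination probability
        elsewhere.
        """
        p = np.empty(self.n_markers, dtype=float)
        start = self.chrom_start
        p[start] = 0.5
        p[~start] = self.recomb_prob[:-1][~start[1:]]
        return p

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        m = self.n_markers
        if self.recomb_prob.shape != (m,):
            raise ValidationError(
                f"recomb_prob has shape {self.recomb_prob.shape}, expected ({m},)"
            )
        if self.effects.shape[1] != m:
            raise ValidationError(
                f"effects has {self.effects.shape[1]} marker columns, map has {m}"
            )
        if self.effects.shape[0] != self.n_traits:
            raise ValidationError(
                f"{self.effects.shape[0]} effect rows but "
                f"{self.n_traits} trait names"
            )
        # chromosomes must be contiguous runs so marker indices are stable
        n_runs = int(self.chrom_start.sum())
        if n_runs != len(np.unique(self.chromosome)):
            raise ValidationError(
                "chromosome labels must be contiguous (a chromosome id "
                "reappears after a different one)"
            )
        if self.position_cM is not None:
            if self.position_cM.shape != (m,):
                raise ValidationError("position_cM length does not match marker count")
            delta = np.diff(self.position_cM)
            bad = (delta < 0) & ~self.chrom_start[1:]
            if bad.any():
                j = int(np.flatnonzero(bad)[0]) + 1
                raise ValidationError(
                    f"marker positions decrease within chromosome "
                    f"{self.chromosome[j]!r} at marker index {j}; "
                    "markers must be sorted by position (no silent re-sorting)"
                )
        # probabilities checked on within-chromosome intervals only
        interval = ~self.chrom_end
        r = self.recomb_prob[interval]
        if np.isnan(r).any() or (r < 0).any() or (r > 0.5).any():
            raise ValidationError(
                "recombination probabilities must lie in [0, 0.5] for every "
                "within-chromosome interval"
            )
        if self.heritability is not None:
            if self.heritability.shape != (self.n_traits,):
                raise ValidationError(
                    "heritability length does not match trait count"
                )
            if (self.heritability <= 0).any() or (self.heritability > 1).any():
                raise ValidationError("heritability values must lie in (0, 1]")

    def with_heritability(self, heritability) -> "GeneticMap":
        """Copy of the map with the heritability vector replaced."""
        h = np.broadcast_to(
            np.asarray(heritability, dtype=float), (self.n_traits,)
        ).copy()
        return GeneticMap(
            chromosome=self.chromosome,
            recomb_prob=self.recomb_prob,
            effects=self.effects,
            trait_names=self.trait_names,
            position_cM=self.position_cM,
            heritability=h,
        )


def positions_to_recomb(position_cM, chromosome) -> np.ndarray:
    """Convert genetic positions to per-interval recombination probabilities.

    For adjacent markers on the same chromosome separated by ``delta``
    centimorgans, the Haldane mapping function gives
    ``r = (1 - exp(-2 delta / 100)) / 2``.  The returned vector has length
    ``m``; entries at the last marker of each chromosome are NaN (no interval
    exists across a chromosome boundary).

    Raises
    ------
    ValidationError
        If positions decrease within a chromosome.
    """
    pos = np.asarray(position_cM, dtype=float)
    chrom = np.asarray(chromosome)
    if pos.shape != chrom.shape:
        raise ValidationError("position and chromosome vectors differ in length")
    m = pos.shape[0]
    r = np.full(m, np.nan)
    if m == 0:
        return r
    same = chrom[:-1] == chrom[1:]
    delta = np.diff(pos)
    if (delta[same] < 0).any():
        raise ValidationError(
            "negative centimorgan distance: positions must be sorted within "
            "each chromosome"
        )
    r[:-1][same] = 0.5 * (1.0 - np.exp(-2.0 * delta[same] / 100.0))
    return r


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    path = Path(source)
    with open(path, "r") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def load_map(
    source,
    trait_names: Sequence[str] | None = None,
    heritability=None,
    random_effects: bool = False,
    seed: int | None = None,
) -> GeneticMap:
    """Load and validate a linkage map from a delimited table.

    Parameters
    ----------
    source
        Path to a CSV/TSV file, or a DataFrame. The table needs a chromosome
        column (one of ``CHR.PHYS``, ``chromosome``, ``chrom``, ``CHR``) and
        either a ``cM`` position column or a ``RecombRate`` probability
        column; every other column is a candidate trait column. Column
        matching is exact and case-sensitive.
    trait_names
        Traits to use, each naming a column. Default: all non-reserved
        columns, in table order.
    heritability
        Optional per-trait heritabilities in (0, 1].
    random_effects, seed
        If a requested trait has no column, its effects may be drawn from a
        standard normal distribution — only when ``random_effects=True`` and
        a ``seed`` is given, so the draw is explicit and reproducible.
    """
    table = _read_table(source)

    chrom_col = next((c for c in CHROM_COLUMNS if c in table.columns), None)
    if chrom_col is None:
        raise MapSchemaError(
            f"no chromosome column found; expected one of {CHROM_COLUMNS}"
        )
    chromosome = table[chrom_col].to_numpy()
    m = len(table)

    position = None
    if POSITION_COLUMN in table.columns:
        position = table[POSITION_COLUMN].to_numpy(dtype=float)
        recomb = positions_to_recomb(position, chromosome)
    elif RECOMB_COLUMN in table.columns:
        recomb = table[RECOMB_COLUMN].to_numpy(dtype=float)
    else:
        raise MapSchemaError(
            f"map needs a {POSITION_COLUMN!r} position column or a "
            f"{RECOMB_COLUMN!r} probability column"
        )

    if trait_names is None:
        trait_names = [c for c in table.columns if c not in _RESERVED]
    trait_names = list(trait_names)

    rng = None
    effects = np.empty((len(trait_names), m))
    for i, name in enumerate(trait_names):
        if name in table.columns:
            effects[i] = table[name].to_numpy(dtype=float)
        elif random_effects and seed is not None:
            if rng is None:
                rng = np.random.default_rng(seed)
            effects[i] = rng.standard_normal(m)
        else:
            raise TraitLookupError(
                f"trait {name!r} is not a column of the linkage map "
                "(pass random_effects=True with a seed to draw effects)"
            )

    return GeneticMap(
        chromosome=chromosome,
        recomb_prob=recomb,
        effects=effects,
        trait_names=trait_names,
        position_cM=position,
        heritability=heritability,
    )


def save_map(gmap: GeneticMap, dest) -> None:
    """Write a map back to CSV (positions if available, else probabilities)."""
    data: dict = {"chromosome": gmap.chromosome}
    if gmap.position_cM is not None:
        data[POSITION_COLUMN] = gmap.position_cM
    else:
        data[RECOMB_COLUMN] = gmap.recomb_prob
    for i, name in enumerate(gmap.trait_names):
        data[name] = gmap.effects[i]
    pd.DataFrame(data).to_csv(dest, index=False)
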