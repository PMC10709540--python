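"""Genomic estimated breeding values and G×E phenotype simulation.

GEBV
----
For additive traits the genomic estimated breeding value is a tensor
contraction of the ``(t, m)`` marker-effect matrix with the ``(n, m, d)``
population array: multiply along the marker axis and sum-reduce over markers
and ploidy, giving an ``(n, t)`` matrix.

Phenotypes
----------
Phenotypes add a genotype-by-environment interaction and residual noise:

    P(i, tau, e) = G(i, tau) + env_e * X(i, tau) + eps(i, tau, e)

where ``env_e ~ N(0, 1)`` is one scalar per simulated environment, ``X`` is
the contraction of a *fixed* per-trait G×E marker-effect vector (drawn from a
standard normal once, at simulator construction) with the genome, and ``eps``
is i.i.d. Gaussian residual noise. The environment scalar multiplies the G×E
trait value only; it does not rescale the residual.

The non-genetic variance is calibrated on the population passed at simulator
construction so that Var(G)/Var(P) equals each trait's heritability there,
and is split between G×E and residual by ``gxe_fraction`` (default: evenly).
This makes h² an operational, testable quantity: regressing it back out of a
large simulated population recovers the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .linkage_map import GeneticMap
from .population import Population


@dataclass
class TraitValues:
    """``(n, t)`` matrix of per-individual, per-trait values."""

    values: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.size and not np.isfinite(v).all():
            raise ValidationError("trait values must be finite")
        if v.shape[1] != len(self.trait_names):
            raise ValidationError(
                f"{v.shape[1]} value columns for {len(self.trait_names)} traits"
            )
        self.values = v

    def to_dataframe(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        if ids is not None:
            df.insert(0, "id", list(ids))
        return df


def gebv(pop: Population, gmap: GeneticMap) -> TraitValues:
    """Genomic estimated breeding values, shape ``(n, t)``.

    ``values[i, tau] = sum_j sum_p effects[tau, j] * genome[i, j, p]``.
    """
    pop.check_map(gmap)
    values = np.einsum("tm,nmd->nt", gmap.effects, pop.genome.astype(float))
    return TraitValues(values.reshape(pop.n, gmap.n_traits), gmap.trait_names)


class PhenotypeSimulator:
    """Phenotype generator with fixed G×E effects and calibrated variances.

    Parameters
    ----------
    gmap
        Map with heritability set for every trait.
    calibration_pop
        Population on which genetic and non-genetic variances are calibrated;
        typically the founders. The fixed G×E marker-effect vectors are drawn
        here and never redrawn for the simulator's lifetime.
    gxe_fraction
        Share of the non-genetic variance carried by the G×E term (the rest
        is residual). Default 0.5.
    rng
        Source of the one-time G×E effect draw. Must be independent of the
        stream that generated the map's trait effects: replaying the same
        deviates would make the G×E trait collinear with the genetic trait
        instead of an independent random trait.
    """

    def __init__(
        self,
        gmap: GeneticMap,
        calibration_pop: Population,
        rng: np.random.Generator,
        gxe_fraction: float = 0.5,
    ) -> None:
        if gmap.heritability is None:
            raise ConfigurationError(
                "phenotype simulation needs heritability in the map"
            )
        if not 0.0 <= gxe_fraction <= 1.0:
            raise ValidationError("gxe_fraction must lie in [0, 1]")
        self.gmap = gmap
        t, m = gmap.n_traits, gmap.n_markers

        g = gebv(calibration_pop, gmap).values
        var_g = g.var(axis=0, ddof=1) if calibration_pop.n > 1 else np.zeros(t)
        h2 = gmap.heritability
        var_ng = var_g * (1.0 - h2) / h2
        self.var_resid = (1.0 - gxe_fraction) * var_ng
        var_gxe = gxe_fraction * var_ng

        # fixed G×E effects: standard-normal draw, rescaled so the G×E trait
        # value has the calibrated variance on the calibration population
        raw = rng.standard_normal((t, m))
        raw_vals = np.einsum(
            "tm,nmd->nt", raw, calibration_pop.genome.astype(float)
        )
        raw_var = raw_vals.var(axis=0, ddof=1) if calibration_pop.n > 1 else np.zeros(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(raw_var > 0, np.sqrt(var_gxe / np.where(raw_var > 0, raw_var, 1.0)), 0.0)
        self.gxe_effects = raw * scale[:, None]

    def gxe_values(self, pop: Population) -> np.ndarray:
        """``(n, t)`` G×E trait values (contraction with the fixed effects)."""
        return np.einsum("tm,nmd->nt", self.gxe_effects, pop.genome.astype(float))

    def phenotype(
        self, pop: Population, n_envs: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Simulate phenotypes, shape ``(n, t, n_envs)``."""
        if n_envs < 1:
            raise ValueError("n_envs must be >= 1")
        pop.check_map(self.gmap)
        g = gebv(pop, self.gmap).values
        env = rng.standard_normal(n_envs)
        x = self.gxe_values(pop)
        eps = rng.standard_normal((pop.n, self.gmap.n_traits, n_envs)) * np.sqrt(
            self.var_resid
        )[None, :, None]
        return g[:, :, None] + x[:, :, None] * env[None, None, :] + eps


def phenotype(
    pop: Population,
    gmap: GeneticMap,
    n_envs: int,
    rng: np.random.Generator,
    gxe_fraction: float = 0.5,
) -> np.ndarray:
    """One-shot phenotype simulation, calibrated on ``pop`` itself.

    Builds a :class:`PhenotypeSimulator` on the given population (its fixed
    G×E effects are drawn from ``rng``) and simulates ``n_envs``
    environments. Returns ``(n, t, n_envs)``.
    """
    sim = PhenotypeSimulator(gmap, pop, rng, gxe_fraction=gxe_fraction)
    return sim.phenotype(pop, n_envs, rng)


def phenotype_mean(values: np.ndarray) -> np.ndarray:
    """Average an ``(n, t, n_envs)`` phenotype array over environments."""
    return np.asarray(values).mean(axis=2)
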