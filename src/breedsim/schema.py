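"""Multi-stage inbred breeding-program runner.

The reference program: an F0 founder set is crossed at random to create F1;
each F1 line is fixed by doubled-haploid induction; the resulting lines then
pass through head rows (HDRW) under low-accuracy visual selection and
preliminary, advanced, and elite yield trials (PYT, AYT, EYT), each stage
evaluated with increasing accuracy while the population shrinks.

Stage "accuracy" is operationalized as the heritability used by the phenotype
score at that stage, together with the number of simulated environments
(replication). Defaults: HDRW keeps 500 lines at h² = 0.1 in one
environment; PYT 50 at 0.3 in two; AYT 10 at 0.5 in four; EYT 5 at 0.7 in
eight. A scaling factor multiplies every population size (founders, crosses,
stage sizes) for throughput experiments; the DH count per line is a per-line
property and is not scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .fixtures import FixtureSpec, make_map
from .linkage_map import GeneticMap
from .meiosis import diallel, double_haploid, flatten_dh, random_crosses
from .population import Population
from .selection import score_phenotype, select
from .traits import gebv


@dataclass
class Stage:
    """One evaluation stage: keep ``size`` lines by phenotype score."""

    name: str
    size: int
    heritability: float
    n_envs: int = 1


DEFAULT_STAGES = (
    Stage("HDRW", 500, 0.1, 1),
    Stage("PYT", 50, 0.3, 2),
    Stage("AYT", 10, 0.5, 4),
    Stage("EYT", 5, 0.7, 8),
)


@dataclass
class SchemaConfig:
    """Sizes and selection rules of the breeding program."""

    founders: int = 50
    n_crosses: int = 200
    dh_per_line: int = 100
    stages: tuple[Stage, ...] = DEFAULT_STAGES
    scale: int = 1
    diallel_prestep: int = 0  # offspring per cross of an optional F0 diallel

    def __post_init__(self) -> None:
        self.stages = tuple(
            s if isinstance(s, Stage) else Stage(**s) for s in self.stages
        )
        if min(self.founders, self.n_crosses, self.dh_per_line) < 1:
            raise ConfigurationError("founders, n_crosses, dh_per_line must be >= 1")
        if self.scale < 1:
            raise ConfigurationError("scaling factor must be >= 1")
        sizes = [s.size for s in self.stages]
        if any(x < 1 for x in sizes):
            raise ConfigurationError("stage sizes must be strictly positive")
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ConfigurationError(
                "stage sizes must be non-increasing across the trial stages"
            )
        for s in self.stages:
            if not 0.0 < s.heritability <= 1.0:
                raise ConfigurationError(
                    f"stage {s.name}: heritability must lie in (0, 1]"
                )
            if s.n_envs < 1:
                raise ConfigurationError(f"stage {s.name}: n_envs must be >= 1")
        if self.stages and self.stages[0].size * self.scale > (
            self.n_crosses * self.scale * self.dh_per_line
        ):
            raise ConfigurationError(
                "first stage keeps more lines than DH induction produces"
            )

    @classmethod
    def from_yaml(cls, path) -> "SchemaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["stages"] = [dict(s) for s in raw["stages"]]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class StageReport:
    """Genetic-value summary of the population emitted at one stage."""

    stage: str
    size: int
    mean: np.ndarray  # per-trait mean GEBV
    std: np.ndarray
    max: np.ndarray


def _report(stage: str, pop: Population, gmap: GeneticMap) -> StageReport:
    v = gebv(pop, gmap).values
    return StageReport(
        stage=stage,
        size=pop.n,
        mean=v.mean(axis=0),
        std=v.std(axis=0, ddof=1) if pop.n > 1 else np.zeros(v.shape[1]),
        max=v.max(axis=0),
    )


def reports_to_frame(reports, trait_names) -> pd.DataFrame:
    """Long-format table: one row per (stage, trait)."""
    rows = []
    for r in reports:
        for i, t in enumerate(trait_names):
            rows.append(
                {
                    "stage": r.stage,
                    "size": r.size,
                    "trait": t,
                    "mean": r.mean[i],
                    "std": r.std[i],
                    "max": r.max[i],
                }
            )
    return pd.DataFrame(rows)


def run_schema(
    config: SchemaConfig,
    gmap: GeneticMap,
    founders: Population,
    rng: np.random.Generator,
) -> tuple[list[StageReport], Population]:
    """Execute the program and report the genetic-value trajectory.

    F0 (founders) -> [optional diallel] -> random F1 crosses -> DH induction
    -> one truncation-selection pass per configured stage, scored by mean
    simulated phenotype at the stage's heritability and replication. Returns
    one :class:`StageReport` per stage (including F0, F1, DH) and the final
    population. Deterministic under the generator's state.
    """
    if gmap.n_traits < 1:
        raise ConfigurationError("schema needs a map with at least one trait")
    expected = config.founders * config.scale
    if founders.n != expected:
        raise ConfigurationError(
            f"config expects {expected} founders (founders x scale); "
            f"got {founders.n}"
        )
    founders.check_map(gmap)

    reports = [_report("F0", founders, gmap)]
    pop = founders
    if config.diallel_prestep:
        pop = diallel(pop, config.diallel_prestep, gmap, rng)
        reports.append(_report("F0_diallel", pop, gmap))

    pop = random_crosses(pop, config.n_crosses * config.scale, gmap, rng)
    reports.append(_report("F1", pop, gmap))

    pop = flatten_dh(double_haploid(pop, config.dh_per_line, gmap, rng))
    reports.append(_report("DH", pop, gmap))

    for stage in config.stages:
        scores = score_phenotype(
            pop, gmap, stage.n_envs, rng, heritability=stage.heritability
        )
        pop, _ = select(pop, stage.size * config.scale, scores)
        reports.append(_report(stage.name, pop, gmap))
    return reports, pop


def default_map_for_schema(
    chromosomes: int = 21,
    qtl_per_chromosome: int = 100,
    seed: int = 0,
    chromosome_length_cM: float = 100.0,
    heritability: float = 0.4,
) -> GeneticMap:
    """Map with the reference geometry: 21 chromosomes x 100 QTL by default,
    uniformly spaced positions, standard-normal effects. Seeded."""
    return make_map(
        FixtureSpec(
            chromosomes=chromosomes,
            markers_per_chromosome=qtl_per_chromosome,
            chromosome_length_cM=chromosome_length_cM,
            heritability=(heritability,),
            seed=seed,
        )
    )


def plot_trajectory(reports, trait: int = 0, ax=None):
    """Strip/point chart of mean +/- sd genetic value per stage (cosmetic)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stages = [r.stage for r in reports]
    means = [r.mean[trait] for r in reports]
    stds = [r.std[trait] for r in reports]
    ax.errorbar(range(len(stages)), means, yerr=stds, fmt="o-")
    ax.set_xticks(range(len(stages)), stages)
    ax.set_ylabel("genetic value (GEBV)")
    ax.set_xlabel("stage")
    return ax
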