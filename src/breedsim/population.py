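"""Phased populations in the (n, m, d) encoding.

A population of ``n`` diploid individuals genotyped at ``m`` markers is a
rank-3 binary array of shape ``(n, m, d)`` with ``d = 2``: entry
``genome[i, j, p]`` is the allele (0 or 1) carried by individual ``i`` on
haplotype ``p`` at marker ``j``. The encoding requires phased input; phasing
itself is delegated to external software.

Two interchange formats are supported: a native NumPy ``.npz`` container
(bit-exact round trips, O(1) shape validation) and phased VCF. In VCF the
REF allele maps to 0 and the single ALT allele to 1; ``GT`` ``a|b`` fills the
haplotype axis as ``(a, b)``; multi-allelic sites and unphased genotypes are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, PhasingError, ValidationError
from .linkage_map import GeneticMap

PLOIDY = 2


@dataclass
class Population:
    """Phased genomes plus optional individual labels and VCF site metadata."""

    genome: np.ndarray
    ids: list[str] | None = None
    sites: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genome)
        if g.ndim != 3 or g.shape[2] != PLOIDY:
            raise DimensionError(
                f"genome must have shape (n, m, {PLOIDY}); got {g.shape}"
            )
        if g.size and not np.isin(g, (0, 1)).all():
            raise ValidationError("genome entries must be 0 or 1")
        self.genome = g.astype(np.int8, copy=False)
        if self.ids is not None:
            self.ids = [str(x) for x in self.ids]
            if len(self.ids) != g.shape[0]:
                raise DimensionError(
                    f"{len(self.ids)} ids for {g.shape[0]} individuals"
                )

    @property
    def n(self) -> int:
        return self.genome.shape[0]

    @property
    def m(self) -> int:
        return self.genome.shape[1]

    def __len__(self) -> int:
        return self.n

    def subset(self, indices) -> "Population":
        """New population holding ``indices`` in the given order."""
        idx = np.asarray(indices, dtype=int)
        ids = [self.ids[i] for i in idx] if self.ids is not None else None
        return Population(self.genome[idx], ids=ids, sites=self.sites)

    def check_map(self, gmap: GeneticMap) -> None:
        if self.m != gmap.n_markers:
            raise DimensionError(
                f"population has {self.m} markers but the map has "
                f"{gmap.n_markers}"
            )


def concat(populations: Sequence[Population]) -> Population:
    """Row-concatenate populations over the individual axis."""
    pops = list(populations)
    genome = np.concatenate([p.genome for p in pops], axis=0)
    ids = None
    if all(p.ids is not None for p in pops):
        ids = [i for p in pops for i in p.ids]
    return Population(genome, ids=ids)


# -- native container ---------------------------------------------------------


def save_population(pop: Population, dest) -> None:
    """Save to the native ``.npz`` container (bit-exact round trip)."""
    arrays: dict = {"genome": pop.genome}
    if pop.ids is not None:
        arrays["ids"] = np.asarray(pop.ids, dtype=str)
    if pop.sites is not None:
        arrays["site_pos"] = pop.sites["pos"].to_numpy(dtype=np.int64)
        for col in ("chrom", "ref", "alt"):
            # fixed-width unicode, not object: keeps the file pickle-free
            arrays[f"site_{col}"] = pop.sites[col].to_numpy(dtype=str)
    try:
        with open(dest, "wb") as fh:
            np.savez(fh, **arrays)
    except OSError as exc:
        raise OSError(f"cannot write population to {dest}: {exc}") from exc


def load_population(source, gmap: GeneticMap | None = None) -> Population:
    """Load from the native container, optionally validating against a map."""
    try:
        with np.load(source, allow_pickle=False) as data:
            genome = data["genome"]
            ids = list(data["ids"]) if "ids" in data else None
            sites = None
            if "site_chrom" in data:
                sites = pd.DataFrame(
                    {c: data[f"site_{c}"] for c in ("chrom", "pos", "ref", "alt")}
                )
    except OSError as exc:
        raise OSError(f"cannot read population from {source}: {exc}") from exc
    pop = Population(genome, ids=ids, sites=sites)
    if gmap is not None:
        pop.check_map(gmap)
    return pop


# -- phased VCF ---------------------------------------------------------------


def import_vcf(path, gmap: GeneticMap | None = None) -> Population:
    """Import a phased VCF as a Population.

    REF -> 0, ALT -> 1; ``GT a|b`` fills the haplotype axis as ``(a, b)``.
    Multi-allelic sites, missing genotypes, and unphased records (``/``
    separator) are rejected: the (n, m, d) encoding requires phased data.
    """
    from cyvcf2 import VCF  # deferred: htslib init is not free

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    chroms, poss, refs, alts = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multi-allelic site at {var.CHROM}:{var.POS} is not supported"
            )
        site = np.empty((len(samples), PLOIDY), dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise PhasingError(
                    f"unphased genotype for sample {samples[s]!r} at "
                    f"{var.CHROM}:{var.POS}: input genetic data must be "
                    "phased (GT with '|'); phase with external software first"
                )
            if a not in (0, 1) or b not in (0, 1):
                raise ValidationError(
                    f"non-binary or missing allele at {var.CHROM}:{var.POS}"
                )
            site[s] = (a, b)
        rows.append(site)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()

    genome = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0, PLOIDY), dtype=np.int8)
    )
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    pop = Population(genome, ids=samples, sites=sites)
    if gmap is not None:
        pop.check_map(gmap)
        vcf_chrom = np.asarray(chroms, dtype=str)
        map_chrom = gmap.chromosome.astype(str)
        if not np.array_equal(vcf_chrom, map_chrom):
            raise ValidationError(
                "VCF marker order does not match the linkage map: per-marker "
                "chromosome labels differ"
            )
    return pop


def export_vcf(pop: Population, dest, gmap: GeneticMap | None = None) -> None:
    """Write a population as an uncompressed phased VCF.

    Site coordinates come from ``pop.sites`` when the population was imported
    from VCF; otherwise chromosome labels come from the map (or "1") with
    sequential 1-based positions and placeholder A/T alleles.
    """
    if pop.sites is not None and len(pop.sites) == pop.m:
        sites = pop.sites
    else:
        if gmap is not None:
            chrom = gmap.chromosome.astype(str)
        else:
            chrom = np.full(pop.m, "1")
        pos = np.ones(pop.m, dtype=int)
        for c in np.unique(chrom):
            mask = chrom == c
            pos[mask] = np.arange(1, mask.sum() + 1)
        sites = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"}
        )

    ids = pop.ids or [f"IND{i:04d}" for i in range(pop.n)]
    with open(dest, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsim\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for j in range(pop.m):
            row = sites.iloc[j]
            gts = "\t".join(
                f"{pop.genome[i, j, 0]}|{pop.genome[i, j, 1]}"
                for i in range(pop.n)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
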