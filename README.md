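# breedsim

Stochastic simulation of plant breeding programs for quantitative
geneticists and breeding-scheme designers: meiotic recombination, doubled
haploid (DH) induction, genomic estimated breeding values (GEBV),
genotype-by-environment (G×E) phenotypes, truncation selection, a
differentiable relaxation of crossing, and a configurable multi-stage inbred
breeding schema.

## The model

A population of *n* diploid individuals genotyped at *m* biallelic markers is
a phased binary array of shape *(n, m, d)* with *d* = 2. The simulator is
parameterized by a genetic linkage map: per-marker chromosome, position in
centimorgans (cM), and one column of additive effects per trait.

**Recombination.** Crossovers follow the Poisson (no-interference) model.
Genetic distance δ cM converts to a recombination probability via the
Haldane mapping function, r = (1 − e^(−2δ/100))/2, which is exactly the
probability of an odd Poisson crossover count over δ/100 Morgans. A gamete
is sampled as a first-order Markov chain over the contributing-haplotype
indicator: uniform start at each chromosome, switch with probability r
between adjacent markers — the exact marginal of the Poisson process at
marker resolution, in O(m).

**Crossing.** A cross plan is a k×2 array of parent indices; each of the k
offspring receives two independent recombined gametes. Convenience builders
cover random biparental crosses and the full diallel (all unordered distinct
pairs: 10 parents × 10 offspring/cross → 450 offspring; 20 parents → 1900).
DH induction duplicates one gamete per line, giving a fully homozygous
*(n, dh, m, d)* block.

**Traits.** GEBV is the tensor contraction of the *(t, m)* effect matrix
with the genome array (sum over markers and ploidy → *(n, t)*). Phenotypes
add G×E and noise: P = G + env·X + ε, where env ~ N(0,1) per environment and
X is the contraction of a fixed, independently drawn G×E marker-effect
vector; variances are calibrated so Var(G)/Var(P) equals the trait's
heritability h² on the calibration population.

**Selection.** Truncation selection by any score: GEBV, optimal haploid
value (OHV = 2 Σ_segments max over the two haplotypes of the segment effect
sum — the best DH derivable from an individual), or simulated phenotype
(low h² ≈ visual selection).

**Relaxation.** `soft_cross` generalizes crossing to weighted-average
parents: weights of shape *(k, n, 2)* on the simplex per parent slot. With
recombination masks held fixed the output is linear in the weights, so
gradients for cross-plan optimization are exact and backend-agnostic;
one-hot weights reproduce the hard cross bit-for-bit.

## Worked example

```python
import numpy as np
import breedsim as bs

spec = bs.FixtureSpec(chromosomes=10, markers_per_chromosome=100,
                      founders=50, heritability=(0.4,), seed=23)
gmap = bs.make_map(spec)              # 1000 markers across ten chromosomes
founders = bs.make_founders(spec, gmap)

cfg = bs.SchemaConfig(founders=50, n_crosses=200, dh_per_line=100)
reports, elite = bs.run_schema(cfg, gmap, founders, np.random.default_rng(0))
for r in reports:
    print(f"{r.stage:>5} n={r.size:<6} mean GEBV = {r.mean[0]:8.2f}")
```

```
   F0 n=50     mean GEBV =   -41.67
   F1 n=200    mean GEBV =   -43.51
   DH n=20000  mean GEBV =   -43.61
 HDRW n=500    mean GEBV =   -25.75
  PYT n=50     mean GEBV =    21.50
  AYT n=10     mean GEBV =    51.58
  EYT n=5      mean GEBV =    62.76
```

Founders are crossed at random (F1), each F1 line is fixed as 100 doubled
haploids (20 000 lines), and four trial stages — head rows (HDRW) and
preliminary/advanced/elite yield trials (PYT/AYT/EYT) — select on simulated
phenotypes of increasing accuracy while shrinking the population. Mean GEBV
rises by ~104 units from founders to elite lines: the genetic gain of the
program. (Crossing and DH leave the mean essentially unchanged — they only
reshuffle and fix alleles; selection is what moves it.)

The same operations are available from a shell:

```bash
breedsim fixtures make --chromosomes 10 --markers 100 --founders 50 \
    --seed 1 --out-map map.csv --out-pop founders.npz
breedsim cross --pop founders.npz --map map.csv --random -k 200 \
    --seed 1 --out f1.npz
breedsim dh --pop f1.npz --map map.csv --per-individual 100 --out dh.npz
breedsim select --pop dh.npz --map map.csv --score gebv -k 50 --out top.npz
breedsim schema run --map map.csv --pop founders.npz --seed 1 --out report.csv
```

Phased VCF import/export (`breedsim pop import-vcf / export-vcf`) maps REF→0,
ALT→1 and `GT a|b` to the haplotype axis; unphased or multi-allelic records
are rejected.

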