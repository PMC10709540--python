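# Methods

This note records the model assumptions, the numerical and design choices,
and what the synthetic-data generators do and do not emulate.

## Recombination model

Meiosis is simulated for diploids under the Poisson crossover model — no
chiasma interference. The cM→probability conversion is the Haldane mapping
function r(δ) = (1 − e^(−2δ/100))/2, the unique mapping consistent with a
Poisson crossover count: r(δ) equals the probability of an odd number of
crossovers in δ/100 Morgans. The test suite verifies this identity against
an independently computed truncated Poisson series to 1e−12. Kosambi and
other interference-aware mappings are out of scope, as are autopolyploid
meiosis, sex-specific maps, and mutation.

Gametes are sampled at marker resolution as a first-order Markov chain over
the contributing-haplotype indicator: uniform start at each chromosome,
switch between adjacent markers with the interval's recombination
probability. This is the exact marginal of the Poisson process at the marker
positions and costs O(m) per gamete. Implementation detail: per-marker
Bernoulli "toggles" (probability 0.5 at chromosome starts, r otherwise)
cumulated with XOR along the genome; a 0.5-toggle makes each chromosome's
start state uniform and independent of the previous chromosome. The
chromosome-start haplotype is drawn independently per chromosome per gamete.
Empirical recombinant fractions, uniform starts, and inter-chromosome
independence are all tested statistically (4-SD binomial bands, chi-square).

A map supplied with a `RecombRate` column is used verbatim (values validated
in [0, 0.5] on within-chromosome intervals; the last marker of each
chromosome carries no interval). Positions must be sorted within each
chromosome; the loader rejects unsorted input rather than silently
reordering, so marker indices stay aligned with population arrays.

## Crossing and doubled haploids

The two gametes of one offspring use independent randomness. The diallel
crosses every *unordered distinct* pair (no selfs): C(n,2) pairs ×
offspring per cross, fixed by the combinatorics of the full-diallel design
(450 offspring for 10 parents × 10; 1900 for 20 × 10). `random_crosses`
samples pairs with replacement across crosses but requires the two parents
within a pair to be distinct (biparental). Selfing is available through an
explicit plan (i, i).

DH induction samples one gamete per line and duplicates it onto both
haplotypes; the output keeps the (n, dh, m, d) grouping, with `flatten_dh`
as the documented path to an (n·dh, m, d) population.

## Differentiable crossing

`soft_cross` replaces each parent slot of a cross with a simplex-weighted
average of the whole population, then applies a recombination mask sampled
exactly as in the hard cross. Masks are treated as fixed samples (a pathwise
estimator): conditional on the masks the map weights → offspring is linear,
so the gradient with respect to the weights is exact and can be delivered by
any autodiff backend or a hand-coded linear adjoint. The package itself is
pure NumPy and ships no autodiff dependency. Weight rows must sum to 1
within 1e−8 and are rejected otherwise — silent renormalization would
corrupt optimizer steps. One-hot weights under shared masks reproduce the
hard cross bit-for-bit (tested on 100 random instances). Soft offspring are
real-valued in [0, 1]; feeding them back into hard crossing is permitted but
population validation flags non-binary genomes.

## Traits and phenotypes

GEBV is the (t, m) × (n, m, d) tensor contraction (sum over markers and
ploidy), checked against a scalar double-loop oracle to 1e−12. Only additive
architectures are modeled; dominance and epistasis are out of scope.

Phenotypes follow P(i, τ, e) = G(i, τ) + env_e · X(i, τ) + ε(i, τ, e):

- env_e ~ N(0, 1), one scalar per environment;
- X is the contraction of a per-trait G×E marker-effect vector drawn from a
  standard normal once at simulator construction and fixed for the
  simulator's lifetime. The draw must come from an RNG stream independent of
  whatever stream produced the map's trait effects — replaying the same
  deviates would make X collinear with G instead of an independent trait;
- ε is i.i.d. Gaussian residual noise. The environment scalar multiplies the
  G×E value only; it does not rescale the residual.

Variance calibration: on the calibration population (the one passed at
construction, typically the founders), non-genetic variance is set to
Var(G)·(1 − h²)/h² per trait and split between G×E and residual by
`gxe_fraction` (default 0.5, i.e. evenly). This makes h² operational:
regressing Var(G)/Var(P) out of a 2000-individual simulated population
recovers the target within ±0.05 (tested at h² ∈ {0.1, 0.4, 0.9}). The
recovery estimate uses the mean of per-environment variances over 400
environments: with a single environment the G×E variance enters through one
squared normal draw — a chi²₁ fluctuation no estimator can average away.
Monomorphic calibration populations (zero genetic variance) degrade
gracefully to zero non-genetic variance. h² = 1 gives P ≡ G exactly.

## Selection

Truncation selection keeps the top k by score; ties break toward the lower
original index (deterministic, seed-independent), and the selected
individuals return in original order with their indices for provenance.
OHV segments default to whole chromosomes, with an optional fixed-size
marker-block segmentation; OHV ≥ GEBV pointwise with equality exactly on
fully homozygous individuals (max ≥ mean, doubled). Multi-trait scores are a
linear index with user weights, equal by default. The phenotype score
averages over an explicit number of environments rather than using a single
draw; its ranking accuracy against true GEBV rises monotonically with h²
(tested over {0.1, 0.4, 0.9}).

## Breeding schema

The reference inbred program: 50 founders, 200 random biparental crosses,
100 DH per F1 line (20 000 candidate lines), then HDRW → PYT → AYT → EYT
phenotype-selection stages. Stage sizes and accuracies are not fixed by the
reference description, so they are configuration with these defaults, chosen
once as the standard "large nursery shrinking to a handful of elite lines,
evaluated with increasing accuracy" shape:

| stage | kept | h²  | environments |
|-------|------|-----|--------------|
| HDRW  | 500  | 0.1 | 1            |
| PYT   | 50   | 0.3 | 2            |
| AYT   | 10   | 0.5 | 4            |
| EYT   | 5    | 0.7 | 8            |

HDRW's h² = 0.1 in a single environment operationalizes low-accuracy visual
selection. A scaling factor multiplies all population sizes (founders,
crosses, stage keeps); the DH count per line is a per-line property and is
not scaled. Whether the founder set is itself the product of a diallel is
left open in the reference description; the runner takes founders as given
and offers an optional diallel pre-step. Each stage builds its phenotype
simulator on the current population with the stage's heritability — stages
are independent trials, not repeated measurements of one environment set.

The tested property is the qualitative trajectory, not numeric parity with
any other simulator (different RNGs make trajectories stochastic): with the
reference configuration on a 1000-marker fixture map, final-stage mean GEBV
exceeds the founder mean in ≥19 of 20 seeded runs, and selection erodes
genetic variance from the DH stage to the elite stage in the median over
seeds.

## Synthetic data

`make_map` places markers uniformly (or sorted-uniform at random) over a
configurable chromosome length, default 100 cM, with standard-normal
effects. `make_founders` draws sites independently at a configurable allele
frequency (default 0.5), optionally in fully inbred mode. What this does
*not* emulate: linkage disequilibrium, realistic allele-frequency spectra,
population structure, or coalescent ancestry. Passing tests therefore
demonstrate correctness of the simulation machinery under the stated model,
not calibration against any real germplasm panel.

Problem sizes used in tests and in `scripts/acceptance.py` — 1e5 gametes for
recombination-rate recovery, 1e4 selfed offspring for Mendelian ratios,
n = 2000 for heritability recovery, 20 seeded runs of the full reference
schema on a 1000-marker map — were chosen to make the statistical bands
(4 binomial SDs, ±0.05 on h²) decisive at desk scale.

## File formats and conventions

- Linkage maps: CSV canonical, TSV accepted; exact, case-sensitive column
  names (`cM`, `RecombRate`; chromosome column one of `CHR.PHYS`,
  `chromosome`, `chrom`, `CHR`).
- Populations: native `.npz` container (bit-exact round trips) and phased
  VCF. REF↦0, first ALT↦1, `GT a|b` ↦ (a, b) on the haplotype axis;
  multi-allelic sites, missing calls, and unphased records are rejected.
  VCF marker order is checked against the map by marker count and per-marker
  chromosome labels; genetic (cM) and physical (bp) positions are
  incommensurable, so positions are not compared.
- RNG: every stochastic operation takes an explicit `numpy.random.Generator`;
  no global state; identical generator state ⇒ identical outputs.
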