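# Methods

## Alignment curation

Alignments are rectangular matrices over `{A, C, G, T, -, N}` with a
per-column map to 1-based reference coordinates (rCRS for real mtDNA data).
`?` and lower-case input are normalized on reading; IUPAC ambiguity codes
are rejected explicitly rather than silently coerced to missing, since they
encode information the downstream statistics cannot use.

**Masking.** Reference ranges (defaults: the poly-C stretches 303–315 and
16183–16194) are dropped by coordinate, and optionally every column that
contains an indel in at least one sequence.  Masking is idempotent and
commutes with imputation whenever the masked columns carry no missing data.

**Imputation.** A missing base in sample *s* at column *c* is filled only
when at least two other samples (i) agree with *s* at every column where
*s* is non-missing and (ii) carry the same non-missing base at *c*.  The
rule is applied in a single synchronous pass computed from the
pre-imputation state: results are order-independent and never chain through
freshly imputed bases.  When qualifying donors disagree the site stays
missing — the unanimity reading of "the nucleotide present in at least two
otherwise identical haplotypes".  Donors are counted as individuals, not as
distinct haplotype classes; with the unanimity requirement the two readings
differ only in the support count recorded in the report.

**Distances.** Pairwise difference counts use pairwise deletion: a column
is skipped for a pair when either base is missing.  This matches common
practice when a few sites remain missing after imputation; it can in
principle break the triangle inequality, which therefore is only asserted
on complete data.

## Diversity statistics

Haplotype (gene) diversity from counts (n₁, …, n_k), n = Σnᵢ, pᵢ = nᵢ/n:

    H  = n/(n−1) · (1 − Σ pᵢ²)
    V(H) = 2/(n(n−1)) · [ 2(n−2)(Σpᵢ³ − (Σpᵢ²)²) + Σpᵢ² − (Σpᵢ²)² ]

Nucleotide diversity is the mean pairwise difference divided by a
comparable length *L* (default: the post-masking column count; the choice
of denominator is configurable because it is a convention, not an
estimate).  Its standard deviation is the square root of the total
sampling variance in the no-recombination case appropriate for mtDNA:

    V(π) = (n+1)/(3(n−1)L) · π + 2(n²+n+3)/(9n(n−1)) · π²

Haplogroup frequency intervals are exact Clopper–Pearson bounds from beta
quantiles, with the conventions lower = 0 at k = 0 and upper = 1 at k = n.
Where only a published frequency and sample size are available, the count
is reconstructed as round(freq·n); the reconstruction is validated by
round-tripping the printed intervals.

Haplotype sharing between groups of populations has two selectable
readings: a haplotype is shared *within* a group if present in ≥2 of its
populations (default), or if carried by ≥2 individuals regardless of
population; shared *between* groups means present in at least one
population of each.

## AMOVA, Φ_ST, Mantel

AMOVA decomposes squared inter-individual distances (pairwise difference
counts by default, so Φ- rather than F-statistics).  For sets of
individuals, SSD = Σ_{i<j} d²ᵢⱼ / n.  The one-level design uses

    σ²_w = SSD(within)/ (N−P)
    σ²_a = (SSD(among)/(P−1) − σ²_w) / n_c,   n_c = (N − Σn_p²/N)/(P−1)
    Φ_ST = σ²_a / (σ²_a + σ²_w)

and the two-level design the standard nested mean-square equations with
unequal-sample-size coefficients n, n′, n″.  Negative components are
reported as computed (they are legitimate estimator outcomes, and published
tables print them); percentages always sum to 100.

Permutation schemes follow the statistic being tested: Φ_ST permutes
individuals among populations, Φ_SC individuals among populations within
their group, Φ_CT whole populations among groups (sizes preserved).
P-values use the (b+1)/(m+1) estimator so they are never exactly zero;
default 1,000 permutations.  These p-values are discrete and slightly
conservative, which the calibration tests account for.

Pairwise Φ_ST is the one-level AMOVA restricted to each population pair —
the equality is asserted in the tests against an independent brute-force
sums-of-squares oracle.

Geographic distances are great-circle (haversine, R = 6371 km), averaged
over all sample pairs of two populations; samples without GPS are dropped
from the geographic averaging only.  The Mantel statistic is the Pearson
correlation of upper-triangle entries with a joint row/column permutation
test; the default is one-tailed ("greater", distance matrices correlate
positively) with 999 permutations, both configurable, since the choice is a
convention.  At least three labels are required (one pair has no degrees of
freedom).

## The drift-resampling test

The test asks: if two populations descend from a common ancestor that
carried a focal haplogroup (or single haplotype) at frequency *p*, how
probable are the frequencies observed today?

Model and defaults:

* ancestral population of Nₑ = 2000 individuals, marked count
  round(p·2000);
* random partition into two daughters of Nₑ = 1000 each (hypergeometric
  marked counts, sampling without replacement);
* G = split_years / 25 generations of constant-size Wright–Fisher
  resampling per daughter.  The update is a binomial draw on the marked
  count — identical in distribution to resampling 1000 parents with
  replacement, but O(1) per generation.  A literal per-individual mode is
  kept as a validation oracle and cross-checked in the tests (mean and
  variance of the final frequency within 3 MC standard errors at Nₑ = 100);
* split times must be whole numbers of generations (500/1000/2000 y → 20/40/80);
* after the final generation, 100 inner samples of the study sizes are
  drawn from each daughter without replacement (a binomial mode is
  available; at n ≈ 50 of 1000 the difference is negligible), and the inner
  score is the fraction of draws with both sample frequencies inside the
  two target intervals, endpoints inclusive on the k/n scale;
* the outer loop repeats the whole history 10,000 times; the reported
  probability is the grand mean, with its Monte-Carlo standard error.

**Mutation of a focal haplotype.**  When the tracked class is a single
haplotype rather than a haplogroup, it can mutate away at a whole-molecule
rate of one mutation per 3533 years.  Two operationalizations are exposed:

* `event` (default): each generation, each daughter loses one marked
  carrier with probability 25/3533 ≈ 0.0071 — a single mutation event at
  the stated rate.  Aggregate effect on a class of hundreds of carriers is
  negligible (expected loss < 1 carrier over 80 generations).
* `lineage`: every marked lineage independently loses the mark each
  generation with probability 25/3533, i.e. exponential decay of the class
  (factor 0.57 over 80 generations).

The event reading is the default because only a weak-decay process is
consistent with the published probability surface this test was built to
reproduce: under lineage decay the long-split cells collapse at moderate
initial frequencies and inflate at high ones, qualitatively unlike the
published grid, whereas the event reading matches it across all rows.  The
lineage model remains available and is exercised by the decay-curve
property test.

**Presets.**  Four named presets encode the published comparisons
(Himba/Herero n = 51 vs Damara n = 38 or Kuvale n = 53), with the target
intervals set to the printed (percent-rounded) CI bounds, since those are
the stated inputs of the original test.  Full-precision Clopper–Pearson
bounds can be recomputed with `clopper_pearson_ci` and passed instead; the
two differ only at one bound of one preset (one sample count at the
interval edge).

**Known discrepancy.**  One published anchor cell (retained-in-one /
low-in-other scenario, split 1000 y, initial frequency 0.17, printed 0.27)
is not reproduced: the model gives ≈ 0.19 under every defensible flag
combination.  The printed value also exceeds both of its own row
neighbours (0.17 at 500 y, 0.16 at 2000 y) by more than any
time-homogeneous drift process allows given the published Monte-Carlo
effort, so we report the computed value and flag the cell rather than fit
to it.  All other anchor cells reproduce within ±0.05.

## rho dating

ρ is the mean number of differences (pairwise deletion) between a cluster's
sequences and a designated founder haplotype; under the star-genealogy
approximation σ = √(ρ/n), and the age is ρ × clock with a symmetric
1.96σ range clipped at zero.  The star approximation is appropriate for the
star-like haplogroup radiations this package targets; tree-based rho would
require phylogeny reconstruction, which is out of scope.  The founder is
user-specified (e.g. the modal haplotype); no root inference is attempted.
The default clock is 3533 years/mutation for a complete mtDNA genome; a
clock can also be derived from the per-site rate 1.665×10⁻⁸/y and the
alignment length.  No purifying-selection correction is applied, so ages on
real data will differ from calculators that apply one.

## Synthetic data

The generator emulates exactly the structure the analyses assume:
a uniform-random reference sequence; haplogroup founders at fixed
divergences from it; per-lineage private mutations drawn Poisson(λ) —
star-like radiation, so the expected pairwise difference within a
haplogroup is 2λ; optional haplotypes forced identical across populations
at target frequencies; missing bases injected uniformly at a configured
rate.  Mutation placement is infinite-sites (every mutation consumes a
fresh column), keeping distance expectations analytic for property tests;
requesting more mutations than columns is an error.  Substitutions only —
indels, recurrent hits, rate heterogeneity, and realistic mutational
spectra are not simulated, so passing tests validate the statistical
machinery, not robustness to those features of real data.  Output is
deterministic given the seed (byte-identical FASTA/TSV).

Default scales used in tests keep the suite fast while leaving Monte-Carlo
error well below the asserted tolerances: populations of 10–30 samples,
alignments of 500–2000 columns, drift checks at 2,000–10,000 replicates.

## Pipeline

`mitopop run` executes curate → diversity → structure → driftsim → rho from
one YAML config, validated eagerly with explicit error messages.  A single
seed feeds every stochastic stage; the manifest records the package
version, seed, per-stage status, and a SHA-256 checksum of every emitted
file, so identical config + seed reproduces the bundle bit-for-bit.

## Numerical and design notes

* Permutation statistics use a 1e-12 slack when comparing against the
  observed value to make ties deterministic across platforms.
* Φ ratios with zero denominators (completely monomorphic data) are
  reported as 0 rather than NaN.
* Variance estimates are floored at 0 before taking square roots.
* The drift simulator's grid spawns one child RNG stream per cell from the
  scenario seed, so cells are independent and the grid is reproducible
  regardless of evaluation order.
* Coordinates are 1-based inclusive throughout (rCRS dialect); synthetic
  alignments use the same masking machinery via their default 1..L map.

## Limitations

* The drift model has no migration, selection, or multi-allele dynamics;
  one focal mark only, matching the hypothesis test it implements.
* Study-scale published quantities (diversity tables, AMOVA percentages,
  Mantel correlations, sharing counts, rho age ranges) require the original
  sequence data, which the pipeline accepts as external FASTA/TSV input;
  the test suite validates the machinery on synthetic data instead.
* Haplogroup assignment, network construction, ordination, and Bayesian
  dating are out of scope; haplogroup labels are consumed as metadata.
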