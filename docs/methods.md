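# Methods

This note documents the statistical methods implemented in `ystrdiff`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Input model and QC

A haplotype table holds one row per male sample: a sample id, a population
id, and one allele call per Y-STR locus. Allele calls at single-copy loci
are integer repeat counts ≥ 1; genotyping output additionally contains
null calls (amplification failure), intermediate microvariants (e.g. 13.2),
and duplicated/triplicated calls at nominally single-copy loci. QC removes
any haplotype carrying one of those states at a panel locus — removal is
whole-haplotype, never per-locus, so every downstream statistic sees a
complete rectangular integer matrix.

A haplotype removable for several reasons is counted once, under the first
applicable reason in the fixed order **null → intermediate → multi-allele**.
The order is a reporting convention only (it does not change what is
removed); fixing it makes QC reports reproducible. Counts are reported
both globally and per population. Multi-copy loci (DYS385a/b, DYF387S1a/b)
are carried through I/O but skipped by QC (a two-value call is their
expected state) and excluded from all frequency-based analyses.

DYS389II amplicons physically contain DYS389I, so the independent
component of DYS389II is the difference; `adjust_dys389` replaces the
DYS389II column by DYS389II − DYS389I and refuses non-positive results.
The decomposition runs **after** QC (microvariants must not be
subtracted) and exactly once, tracked by a table-level flag — applying the
subtraction twice would silently corrupt the column, so a second call is
an error rather than a no-op.

## AFD and mAFD

For one locus and two populations, AFD = ½ Σ |f<sub>i1</sub> − f<sub>i2</sub>|
with the sum over the **union** of alleles observed in either population;
alleles absent from one side contribute frequency 0. The union is the only
dataset-complete choice of summation index: any fixed global allele
registry would change nothing (absent alleles contribute |0 − 0|), while a
per-population index would miss private alleles. AFD is half the L1
distance between frequency vectors, hence symmetric, bounded in [0, 1]
(0 = identical spectra, 1 = disjoint allele sets), and satisfies the
triangle inequality.

mAFD is the **unweighted** arithmetic mean of AFD over all C(P, 2)
unordered population pairs. Weighting by sample size was deliberately not
used: the statistic characterizes a locus across a set of populations, and
letting large cohorts dominate would re-introduce exactly the sampling
imbalance the mean over pairs avoids. Consequently mAFD is invariant
under population relabeling and locus column order.

Loci are ranked by descending mAFD; ties (possible on small synthetic
tables) break by locus name, lexicographically, so rankings are
deterministic. Sliding a window of 15 markers down the ranking with step 1
gives N − 15 + 1 panels; for the 23 single-copy loci of the extended kit
that is 9 panels, from the top-15 to the minimum-15 set.

The packaged reference ranking (`ystrdiff/data/reference_mafd.tsv`) stores
the published 23-locus mAFD values and per-locus per-generation mutation
rates (with binomial 95% CIs) from a 41-population compilation; it is a
versioned data file, loaded at run time and never hard-coded in logic.

## AMOVA Φst and permutation testing

Pairwise genetic distance between populations is the two-level AMOVA
fixation index computed from inter-haplotype distances d<sub>ij</sub>:

    SS_total  = (1/N) Σ_{i<j} d_ij
    SS_within = Σ_groups (1/n_g) Σ_{i<j ∈ g} d_ij
    σ²_w = SS_within / (N − 2)
    σ²_a = (SS_among/(P−1) − σ²_w) / n0,   n0 = (N − Σ n_g²/N)/(P−1)
    Φst  = σ²_a / (σ²_a + σ²_w)

With d = sum of squared repeat-count differences (the default) this is the
Rst-type index appropriate for STRs under stepwise mutation; with a
Hamming metric it is the Fst analogue. Both are exposed because the
literature uses either for Y-STR haplotypes; results are always labeled
with the metric used. Variance-component estimates can be slightly
negative for undifferentiated populations; negatives are reported as
computed and clamped only where a true dissimilarity is required (MDS
input, by default).

Significance: haplotypes are reshuffled between the two populations
keeping sample sizes, and p = (#{Φ\* ≥ Φ<sub>obs</sub>} + 1)/(n<sub>perm</sub> + 1),
which can never be exactly 0 and is valid (slightly conservative) at any
n<sub>perm</sub>. The comparison uses a 10⁻¹² tolerance so that a permutation
reproducing the observed partition counts as ≥ despite float-ordering
differences between the vectorized permutation path and the direct
computation. Default n<sub>perm</sub> = 10,000 and α = 0.05; tests and the
acceptance experiments use 200–500 permutations, which changes only the
granularity of p, not its validity. Each population pair gets its own RNG
stream derived from (global seed, CRC32 of the sorted pair ids), so a
distance matrix is reproducible regardless of the order pairs are
computed in, and Φst(A,B) = Φst(B,A) exactly.

Matrix comparison sorts pairs ascending by the reference matrix's distance
(the line-chart convention for panel comparisons) and classifies each pair
as increased / decreased / tied in the alternative matrix, with a
configurable tie tolerance (default 10⁻¹²).

## Multidimensional scaling

Classical (Torgerson) scaling is the default: double-center the squared
dissimilarity matrix, B = −½ J D² J, take the top-k eigenpairs, and scale
eigenvectors by √λ. It is exact on Euclidean input (planar point sets are
recovered to numerical precision) and deterministic: axes are ordered by
eigenvalue, the embedding is centered, and each axis is sign-fixed so that
its first nonzero coordinate is positive, making output bit-for-bit
reproducible. Negative eigenvalues (non-Euclidean input, common for Φst
matrices) contribute zero coordinates.

An optional SMACOF pass (iterative majorization via the Guttman transform,
uniform weights) refines the configuration toward a local minimum of raw
stress; its stress sequence is non-increasing by construction and it stops
on a relative decrease below `tol` (default 10⁻⁹) or `max_iter` (300).
Misfit is reported as Kruskal stress-1 = √(Σ(d̂ − d)²/Σd²), defined as 0
for an all-zero matrix.

Raw (clamped) Φst values are embedded directly, without any monotone or
standardizing transformation of the dissimilarities; `--keep-negative`
disables clamping for callers who prefer to shift the matrix themselves.
Two dimensions are the default, matching standard practice for population
scatter plots; the dimension is configurable.

## Synthetic data generator

The simulator is a forward Wright–Fisher model of haploid haplotypes:

- **Ancestral pool** (default 1,000 haplotypes): each locus gets a modal
  repeat count drawn uniformly from 10–24, and each haplotype carries
  small symmetric offsets (−2…+2) around the modal value with total
  non-modal mass `ancestral_diversity` · 1.5 (default 0.5). This is a
  stand-in for mutation–drift equilibrium standing variation, chosen so
  that typical per-locus heterozygosity is in the range real Y-STR panels
  show, without the cost of a long burn-in. Setting `ancestral_diversity=0`
  yields a monomorphic ancestor. The DYS389II modal value is anchored at
  DYS389I + 14…18 repeats so the nested-amplicon invariant
  (DYS389II > DYS389I) holds in simulated tables.
- **Split**: star topology by default — every population is founded
  independently from the ancestral pool by `founder_size` haplotypes
  (default 50), expands to `pop_size` in the first post-split generation,
  and then drifts for `generations_since_split` generations (default 300)
  of multinomial resampling. A split age of 0 bypasses the bottleneck:
  the population is a plain resample of the ancestral pool, so expected
  Φst ≈ 0. An optional balanced binary topology divides the root-to-leaf
  split age equally over the levels, giving nested structure (sister
  populations closer than distant ones).
- **Mutation**: strict single-step model — each locus mutates with its
  per-generation rate, ±1 repeat with probability ½ each, reflecting at
  the lower bound of one repeat so counts stay physical. Multi-step and
  length-dependent mutation are deliberately out of scope; the minimal
  model is sufficient to exercise every statistic. Default rates are the
  packaged per-locus values (5×10⁻⁴ … 1.5×10⁻²), so synthetic runs use
  the reference 23-locus panel by default.
- **QC noise**: optionally, each record is hit by each artifact class
  (null / intermediate / duplicated) independently with a per-class rate,
  at one random single-copy locus, so expected artifact counts are
  rate × n per class.
- **Scale defaults** mirror the compiled study data: 41 populations of
  510 haplotypes. Tests and the acceptance experiments run smaller
  configurations (2–10 populations, 30–500 haplotypes, 0–250 generations),
  which probe the same code paths at a fraction of the cost.

Everything derives from one integer seed through a fixed
`SeedSequence.spawn` order, so identical configurations produce
byte-identical tables.

What the generator does **not** emulate: migration and admixture between
populations, population growth/decline after the founding expansion,
haplotype-correlated mutation, locus dropout correlated with primer
binding, or the particular biogeographic clustering of the real
41-population compilation. Passing tests therefore demonstrate that the
statistics and their implementations behave correctly under a clean
drift–founder–mutation model — not that real populations will show any
particular mAFD ordering. The published reference ranking is shipped as
data precisely because it cannot be recomputed from synthetic inputs.

## Numerical and degenerate-input choices

- Frequencies must sum to 1 within 10⁻⁹ at spectrum construction;
  sampling renormalizes defensively before drawing.
- Φst denominator of 0 (all haplotypes identical in both populations) is
  reported as 0 rather than NaN.
- Correlation of mAFD with mutation rate uses Pearson and Spearman
  (scipy); zero-variance input is flagged `degenerate` with NaN
  coefficients instead of raising.
- An all-zero distance matrix embeds to all-origin coordinates with
  stress 0.
- mAFD ranking ties break lexicographically by locus name.
- The provenance hash covers all scientific settings but not the output
  directory, so identical analyses written to different paths produce
  identical artifacts including the hash.

## Known limitations

- AMOVA is two-level only (within/among two populations per pair);
  hierarchical designs and >2-group AMOVA are out of scope.
- The permutation test permutes whole haplotypes between exactly two
  populations; no global (all-populations) test is provided.
- Classical MDS on strongly non-Euclidean Φst matrices discards the
  negative-eigenvalue subspace; residual stress is reported so users can
  judge the 2-D summary, and SMACOF is available when a lower-stress
  configuration matters.
- The simulator's ancestral pool is a parametric stand-in, not a
  coalescent sample; absolute Φst and mAFD magnitudes depend strongly on
  the free parameters (founder size, split age, diversity) and are not
  calibrated to any particular real dataset.
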