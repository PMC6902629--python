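# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the known limitations of `allokin`.

## Study system and scope

The package targets allopolyploid complexes: a set of tetraploid taxa,
each formed by hybridization between two diploid (or autotetraploid)
species drawn from two diverged parental clades, carrying one
subgenome from each parent under disomic inheritance.  Inference uses
biallelic nuclear SNPs with per-genotype read depths (typical of
RADseq), separately called haploid plastid SNPs, a ploidy map and a
group map (individual → taxon; taxon → candidate-parent clade or
allotetraploid role).  The clade partition of the candidates is user
input — it normally comes from an upstream phylogenetic analysis that
this package deliberately does not re-implement.

## Variant filtering

Rules are applied in a fixed order so the completeness rule sees
depth-masked missingness:

1. genotypes with depth < `min_dp` (default 5) are set missing;
2. non-biallelic sites are dropped;
3. sites with QUAL < `min_qual` (default 100) are dropped (missing
   QUAL fails — conservative);
4. sites with non-missing fraction < `min_call_rate` (default 0.5)
   are dropped.

All thresholds are inclusive ("minimum" taken literally).  The
completeness fraction is computed over all individuals of the table;
diploid and tetraploid call sets are filtered separately and then
intersected on (contig, pos, ref, alt); same-position sites with
mismatched alleles are excluded from both.

## Dosage model

Genotypes are derived-allele dosages g ∈ {0..m}.  The read model is
binomial: each read supports the derived allele with probability
p_g = (g/m)(1−ε) + (1−g/m)ε, with ε the per-site error (mean of
10^(−Q/10) over covering base qualities, capped just below 0.5).  The
flat-prior posterior over at most five states is computed by exact
log-space enumeration — with ≤ 5 analytic likelihoods there is nothing
to sample, so the posterior carries no Monte-Carlo noise.  Numerical
conventions: log-likelihoods are floored at −745 (the smallest normal
double) so that impossible data under every dosage (only possible at
ε = 0 with both alleles observed) degrade gracefully to the flat
prior; MAP ties break toward the smaller dosage; cells with N = 0 are
missing with a uniform posterior.  The model deliberately uses no
allele-frequency or Hardy–Weinberg prior (parentage is unknown a
priori) and ignores the two-subgenome structure of allopolyploid
genotypes; at the ~200× depths the pipeline assumes, MAP error is well
below 1% (measured in the acceptance suite at 100×: ≈0.4%).

## Relatedness

One product-moment estimator serves all ploidies:

θ̂_XY = Σ_l (x_l/u − p_l)(y_l/v − p_l) / Σ_l p_l(1−p_l),  r̂ = 2 θ̂,

summed over loci co-typed in both individuals and polymorphic in the
reference panel.  The factor 2 is the ploidy-scale conversion fixed by
pedigree calibration: expected r̂ is 0 for unrelated pairs, 0.5 for
diploid parent–offspring and full sibs, 1 for a non-inbred self-pair
(verified in the tests against an explicit identity-by-descent
oracle).  Choices:

* **Frequency panel** — all candidate-parent individuals pooled,
  ploidy-weighted, fixed for every pair, so values are comparable
  across allotetraploid groups (configurable).
* **Fixed loci** (panel p̂ ∈ {0,1}) are excluded: uninformative
  numerator, vanishing denominator term.
* **L_min** — pairs sharing fewer than 100 usable loci (plastid: 1)
  are reported missing.
* Plastid data use the same estimator with u = v = 1 plus a raw
  allele-sharing fraction, which is what the maternal call ranks.

Only the ranking of candidates enters downstream decisions, so any
estimator with monotone-in-kinship expectation would give the same
assignments; the product-moment form was chosen because its pedigree
expectations are analyzable and testable.

Per-individual inbreeding for diploids is
F = (O_hom − E_hom)/(L − E_hom) with
E_hom = Σ_l [1 − 2 p_l (1−p_l) A_l/(A_l−1)], A_l the observed allele
copies at locus l.  It is a relative measure over the variable loci of
the call set (range −1..1), not a population-level F_IS.

## Parentage and direction

For each allotetraploid group, the relatedness values of all its
individuals to all individuals of each candidate taxon form that
candidate's affiliation distribution.  Per clade, the chosen parent is
the candidate with the highest mean (median also reported; both
configurable).  A two-sided Mann–Whitney–Wilcoxon test compares the
top candidate with the runner-up — exact by enumeration when the
smaller sample has ≤ 8 untied observations, else normal approximation
with tie and continuity corrections.  A non-significant difference
(α = 0.05, no multiple-testing correction by default; Benjamini–
Hochberg available) does not change the choice, it raises an
"indistinguishable" flag: external evidence (sympatry, plastid types)
may then be weighed by the analyst, which no algorithm here encodes.
The pairwise values share individuals, so the test is
pseudo-replicated; the report carries that caveat and a subsampling
option (one mean per allotetraploid individual) is provided.

The maternal parent is the chosen parent with the higher mean plastid
similarity to the group, consistent with maternal plastid inheritance;
the margin is reported, and a missing-plastid parent leaves the
direction undetermined rather than guessed.

## Private-allele chronology

Within a sibling family (allotetraploids sharing the inferred parent
pair — never the parents themselves), an allele is *observed* in a
taxon when at least one non-missing individual carries ≥ 1 copy
(missing genotypes contribute no observation, so missing data cannot
create privacy), and *private* when observed in that taxon and in no
sibling.  Both allele states of a biallelic site are counted.  Raw
counts are corrected by (n+1)/n, n the group's sample size, and the
corrected counts rank the family by relative age.  Pearson and
Spearman correlations with mean relatedness to each parent are
reported when the family has ≥ 3 taxa (older lineages drift away from
their parents, so the correlation with relatedness is expected
negative).  Node ages in years come from
`age = b (S/L) / μ · t_gen`, linear in branch length and generation
time; `--no-rescale` accepts an already per-site branch length.

## The synthetic complex

The generator produces the statistical structure the inference
assumes, with truth labels:

* **Candidate frequencies** — ancestral frequencies Uniform(0.05,
  0.95) (polymorphism-ascertained catalogs contain no near-invariant
  sites), drifted down a two-clade species tree by Balding–Nichols
  draws: child p ~ Beta with mean parent p and variance c·p(1−p);
  defaults c = 0.2 on clade branches, 0.1 on taxon branches.
* **Diploid genotypes** — per-taxon inbreeding F_is mixes one
  duplicated Bernoulli draw (probability F_is) with two independent
  draws, giving heterozygosity 2p(1−p)(1−F_is).
* **Allotetraploids** — founded as one Binomial(2, p) draw per parent
  taxon per locus; the two subgenomes never exchange alleles
  (disomic default; a flag enables tetrasomic resampling of the
  combined pool).  Post-origin drift applies per subgenome as the
  Balding–Nichols endpoint with c = 1 − exp(−age/2Nₑ) (Nₑ default
  50,000) — the diffusion limit of per-generation Wright–Fisher
  resampling, which is also implemented exactly (`drift_mode="wf"`)
  and used in the tests to confirm moment agreement; the endpoint form
  removes an O(age) loop that would dominate runtime at age 2×10⁴.
* **New mutations** — modelled as lineage substitutions in the
  weak-mutation limit: each of `invariant_sites` monomorphic positions
  (default 20,000, standing in for the invariant bulk of the RAD
  tags) becomes fixed for a new derived allele in one subgenome with
  probability μ_sim per generation.  μ_sim defaults to 10⁻⁵, chosen
  so the default family's corrected private-allele counts
  (≈20/200/10³/4×10³ at ages 100–20,000 generations) span the range
  such studies report; the simulator's per-site probability is a
  substitution rate, not a per-copy mutation rate.  Because mutations
  arise only at sites monomorphic complex-wide, private-allele truth
  labels are exact.
* **Plastids** — one haploid haplotype per taxon, generated by
  flipping each of 200 sites with probability 0.05 per tree branch;
  an allotetraploid's haplotype copies its maternal taxon's with
  Poisson(divergence × sites) substitutions (divergence 10⁻³).
* **Reads** — N ~ Poisson(λ), D ~ Binomial(N, p_g); defaults λ = 200
  (the coverage regime the pipeline targets), Phred 30, constant site
  QUAL 200 so synthetic data pass the filters unless lowered
  deliberately.

The default study: six candidate taxa in two clades, sixteen
allotetraploids of five individuals each over 5,000 standing loci,
with one four-sibling family spanning ages 100–20,000 generations and
maternal parents alternating between clades.  One seed fans out to all
stages through `numpy.random.SeedSequence` spawning in a fixed order,
so identical config + seed gives bit-identical outputs.

**What the generator does not emulate** — and hence what passing tests
do not certify for real data: RAD locus dropout and allele dropout,
linkage between sites, indels, selection, gene flow after origin,
inter-allotetraploid hybridization, population structure within taxa,
and coalescent gene-tree heterogeneity.  Effective population sizes
and bottlenecks are conventions, not estimates; the spec-level numbers
(sample sizes, depth, locus counts) emulate a desk-scale version of a
RADseq study, not any particular data set.

## Problem sizes and determinism

The acceptance suite and `scripts/acceptance.py` use: 1,000 random
cells for posterior exactness (tolerance 10⁻¹²), 10⁵ calls at 100× for
MAP error, 30 pairs × 10,000 loci per pedigree relationship, a 20-seed
ensemble of the full default complex for parentage/maternal/age-rank
recovery, all ~2,000 untied rank splits of pooled size ≤ 10 for
Wilcoxon exactness plus 1,000 null replicates at n = 30, and two
byte-compared pipeline runs.  All randomness derives from the single
`--seed` via `SeedSequence` spawning.

## Known limitations

* Relatedness values are on the estimator's own calibrated scale;
  other software's "multiplication of ploidy" conventions can differ
  by a constant factor — rankings, and therefore parentage calls, are
  unaffected.
* The dosage model ignores subgenome structure; at low coverage
  (< ~20×) its flat prior inflates heterozygous-dosage uncertainty.
* Maximum affiliation assumes the true parent taxon (or its closest
  extant relative) is among the candidates; an extinct parent shows up
  only as a uniformly distant best match, not as an explicit signal.
* Private-allele counts depend on sample size through observation
  sampling even after the (n+1)/n correction; between-family
  comparisons of counts are not meaningful, only within-family ranks.
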