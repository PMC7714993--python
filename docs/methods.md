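# Methods

This note records the models behind `panelkit`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate about real bison data.

## Genotype model and conventions

All computations run on a samples × loci matrix of alternate-allele
dosages in {0, 1, 2} with −1 as the missing sentinel. Coordinates are
1-based as in VCF; PLINK MAP positions are treated identically. Dosage
always counts the ALT allele, so ref/alt orientation is fixed at read time
and minor-allele frequency is derived downstream (`maf = min(f, 1−f)`)
rather than stored — orientation can never flip silently between modules.
Half-calls and non-diploid calls become missing with a warning; sex
chromosomes and mitochondria are skipped. PED/MAP files do not store
allele orientation, so the PLINK reader accepts locus records to pin
ref/alt, and otherwise calls the minor allele ALT (ties broken
lexicographically) — documented behaviour, not a guess made per file.

## Panel design filters

Two named presets capture the two selection stages of each tool:

* **stage 1** (sequencing-derived candidates): QUAL > 1,000 base filter
  with missing rate < 20% for composition candidates (plus MAF > 0.1 and
  allelic-differentiation p < 1e−4 between subspecies); parentage
  candidates additionally require MAF > 0.45, missing < 5%, HWE p > 1e−4,
  QUAL > 10,000 and a single probe per strand, followed by 1-Mbp thinning.
* **stage 2** (array-genotyped validation): overall call rate > 95%, per
  subspecies > 90%; for parentage additionally MAF > 0.4 overall, > 0.3
  per subspecies, HWE p > 0.05, and exclusion of the array conversion
  types `NoMinorHom`, `OTV`, `MonoHighResolution`; then LD pruning.

Thresholds are strict inequalities in the stated direction ("MAF > 0.4"
keeps 0.401, rejects 0.400). Probe-chemistry and caller-QC criteria are
platform metadata and are modelled as optional boolean locus flags; when a
locus lacks the annotation a criterion needs, that criterion is skipped for
that locus with a warning rather than silently rejecting.

**HWE test.** The exact conditional test on the heterozygote count given
the sample size and minor-allele count, two-sided by probability mass —
the standard genotype-QC choice. Up to n = 200 genotypes the conditional
distribution is evaluated in exact integer arithmetic, so ties between
equally probable outcomes are decided exactly; beyond that a normalized
ratio recurrence is used (relative error far below any QC threshold). A
1-df chi-square variant is available. Whether the original validation QC
used an exact or chi-square HWE test is not knowable from the outside;
the exact test is the default because it is well-behaved at the small
per-subspecies counts involved.

**Allelic differentiation.** 1-df chi-square on the 2×2 allele-count
table, `χ² = N(ad−bc)²/(r₁r₂c₁c₂)`, matching an allele-frequency GWAS;
Fisher's exact test is offered for small counts. A zero margin returns
(0, 1).

**Flanking-polymorphism filter.** A locus is removed when any other
variant lies within 36 bp (inclusive) on the same chromosome; both members
of a close pair go, since either one contaminates the other's probe
context.

**Distance thinning** is a greedy left-to-right scan per chromosome (the
first locus of a run wins), dropping any locus closer than 1 Mbp to the
last kept one; the comparison is half-open (a gap of exactly 1 Mbp is
kept). Removed loci are returned as "alternative" SNPs. An optional
ranked mode admits loci in descending-MAF order instead.

**LD pruning.** Composite LD: squared Pearson correlation of dosage
columns over pairwise-complete samples (phase unknown; zero variance ⇒ r²
reported as 0 with a warning). Within a sliding window (defaults: 50 loci,
step 5, r² ceiling 0.2 — conventional pruning practice; all three
configurable), while any pair exceeds the ceiling the lower-MAF member is
dropped, ties dropping the later locus; passes repeat until stable, which
guarantees no surviving within-window pair above the ceiling.

## Parentage exclusion

For a biallelic locus with allele frequencies p and q = 1 − p under
Hardy–Weinberg equilibrium and random mating:

* Q1 (other parent known): `PE₁ = pq(1 − pq)`
* Q2 (duo): `PE₂ = 2p²q²`
* Q3 (offspring vs parent pair):
  `PE₃ = p⁴(1−p²) + q⁴(1−q²) + 8p³q³ + 2p²q²(p²+q²)`

The closed forms were derived by summing over the finite genotype space,
and `pe_enumerate` keeps that enumeration in the codebase as the normative
definition; the test suite asserts agreement to 1e−12 across the MAF grid,
guarding against transcription errors. All three are maximised at
MAF 0.5 (0.1875, 0.125, 0.28125), so a panel of k loci at MAF 0.5 gives
the theoretical floor `PN = (1−PE)^k` that no real k-SNP panel can beat.
Multi-locus PN is accumulated in log space to avoid underflow at
panel sizes in the hundreds.

Verification is deterministic Mendelian counting. Duo: a mismatch is a
pair of opposite homozygotes, the only impossibility for biallelic
markers. Trio: at loci where offspring, known parent and candidate are all
called and the offspring is compatible with the known parent, the
candidate mismatches when no allele pair (one from each adult) produces
the offspring genotype; offspring–known-parent conflicts are reported
separately and never held against the candidate. The default mismatch
tolerance is 0 (genotyping-error-free panels achieve perfect concordance);
it is configurable for noisy data. Loci with any missing member leave the
comparison's denominator.

## Composition estimation

The PlainsScore regresses an animal's per-locus allele frequencies
(`dosage/2`) on the two reference frequency vectors with the mixing
coefficient bounded in [0, 1]. With a single coefficient, bounded least
squares reduces to clipping the unconstrained estimate — an implementation
theorem the tests assert against both a general BVLS solver and a dense
grid search of the residual (which is exactly quadratic in b). The closed
form is the default path (and is vectorised across animals); the BVLS
route remains for future models with three or more reference populations.
Reference frequencies are plug-in point estimates from labelled animals at
the requested confidence level (default: level 1 only); no shrinkage is
applied. Missing genotypes drop the locus for that animal only, with the
per-animal locus count reported. Loci on which the two references agree
contribute nothing to numerator or denominator and are permitted; only a
panel on which the references are *entirely* indistinguishable is an
error. Scores are reported in percent with two decimals.

## Synthetic data

The generator emulates the study conditions rather than real genomes.
Defaults: 17,018 composition loci; Balding–Nichols divergence at
Fst = 0.15 around ancestral frequencies Uniform(0.05, 0.95); rejection
until |f_P − f_W| ≥ 0.2 (emulating the allelic-differentiation screen);
reference groups of 203 plains and 57 wood animals; 500 animals per
simulated population. Fst = 0.15 was chosen once as a realistic
between-subspecies differentiation for a panel pre-selected for
informative loci; together with the |Δf| floor it yields reference
populations that clustering separates completely, as observed for the
real confidence-labelled animals.

Cross types are sampled per locus from allele pools — pure: Binomial(2, f);
F1: Bernoulli(f_P) + Bernoulli(f_W); F2 gametes and the backcross hybrid
gamete: Bernoulli((f_P+f_W)/2). For unlinked loci these match the marginal
distributions of individual-based crossing, which is sufficient because
every downstream statistic here (exclusion power, the regression, k-means)
uses per-locus marginals; linkage, inbreeding, mutation and multi-
generation pedigrees are deliberately absent. Trios draw parents from the
population and transmit one uniform allele each; an optional error rate
replaces reported genotypes with population draws.

The full-scenario pipeline (`simulate_study`) mirrors the validation
analysis's two-step structure: populations are simulated from the
*estimated* reference frequencies (the 203/57 animals' sample
frequencies), and composition is estimated against those same estimates.
This is what makes the pure-plains median sit a hair under 100% — roughly
half the unconstrained estimates exceed 1 and are clipped, so the sample
median of 500 falls just below the boundary — while pure wood pins at
exactly 0.00%.

What passing tests therefore show: the estimator recovers known admixture
fractions to well under a percentage point under HWE-with-divergence
sampling, and exclusion rates match closed-form theory. What they do not
show: robustness to real-data features such as within-subspecies
substructure (the real plains animals form two sub-clusters), relatedness
inside reference groups, genotyping batch effects, or cattle
introgression, none of which the generator produces.

## Clustering validation

Distances are Euclidean on dosage vectors. With missing data the default
policy computes squared distance over co-called loci and rescales by
m/m_co before the square root (unbiased under missing-at-random); mean
imputation is available as an alternative. Classical (Torgerson) MDS
double-centres −D²/2 and eigendecomposes; coordinates are scaled by
√eigenvalue, the first nonzero loading of each axis is forced positive for
reproducible output, and the embedding truncates with a warning when fewer
than k eigenvalues are positive. K-means minimises within-cluster sums of
squares with 25 seeded starts by default, keeping the best run; on
well-separated dosage clouds (the regime the concordance check targets)
the optimiser's local-search flavour is immaterial. Concordance
cross-tabulates clusters against subspecies labels restricted to
confidence levels 1–2 by default, mirroring how reliably labelled animals
are used as the yardstick.

## Problem sizes and determinism

The shipped analyses run at the study's own scale (17,018 loci, 203 + 57
reference animals, 500 per simulated population, 1,000 trios and 1,000
candidate comparisons for parentage, 100 + 100 samples for clustering);
the vectorised samplers make this a seconds-scale computation. Every
stochastic routine takes an explicit seed and routes all randomness
through one `numpy.random.Generator`; identical seeds give bit-identical
outputs, and derived sub-seeds stay below 2³¹.

## Known limitations

* Biallelic autosomal SNPs only; no BCF/binary PLINK, phasing, indels or
  sex chromosomes.
* Exclusion theory assumes HWE, random mating, independent loci and no
  genotyping error; the mismatch tolerance is the only error knob.
* The composition model has exactly two reference populations and treats
  their frequencies as known; uncertainty in the references propagates
  into scores unshrunk.
* Likelihood-based parentage assignment, kinship matrices, model-based
  admixture (STRUCTURE/ADMIXTURE-style) and cattle-introgression scoring
  are out of scope.
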