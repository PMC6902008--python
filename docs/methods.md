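# Methods

## The depletion statistic

For a haplotype with estimated frequency *f* among the 2*N* phased
haplotypes of *N* genotyped animals, Hardy–Weinberg predicts *N·f²*
homozygotes.  The scan tests each window haplotype with the lower-tail
exact binomial probability P(X ≤ observed), X ~ Binomial(N, f²).  The
tail is summed from binomial log-pmf terms with `logsumexp`, so values
of order 10⁻³⁰ carry full relative precision; P(X ≤ 0) equals the
closed form (1 − f²)^N to 10 decimal digits and the general tail matches
exact-rational summation on every small instance we test.  The test is
one-sided by construction: only a *deficit* of homozygotes is evidence
of a recessive lethal.

Windows default to 20 markers, step 1 — the window size a mapped lethal
region of ~19 markers suggests — and both are configurable.  Haplotypes
are only tested when their expected homozygote count is at least 10
(`min_expected_hom`); rarer haplotypes have essentially no power and
would only inflate the test count.  Significance uses a fixed threshold
P < 5×10⁻³ with no multiplicity adjustment, matching how such scans are
run in practice; a Bonferroni-adjusted column is emitted alongside for
transparency.  Overlapping significant windows are merged into one
region when their haplotypes agree on every shared marker (the same
lineage seen through shifted windows); the region is reported by its
outermost marker positions.

The per-window sample size N counts animals whose two haplotypes are
fully observed in the window; after phasing/imputation this is the
panel size.

## Genotype QC

Samples with more than 15% missing genotypes are removed first, then
markers in a fixed order so the report is deterministic: unknown map
position → call rate < 0.85 → MAF ≤ 0.01 (the inclusion criterion is
strictly "greater than") → Hardy–Weinberg exact P < 10⁻¹². Each marker
is counted once, in the first filter that removes it.  The HWE test is
the two-sided conditional exact test: conditioning on allele counts, it
sums the probabilities of all heterozygote counts (of matching parity)
whose conditional probability does not exceed the observed one —
probability-mass ordering, no mid-p — the convention of standard
genotype-QC tools.  Weights are computed with log-gamma terms so the
test is stable at biobank-scale counts.

## Litter contrasts

Mating classes are labelled sire-first (CxN = carrier sire, NxC =
carrier dam); the class tables keep the reciprocal classes separate,
and the Welch contrast defaults to CxC vs the literal CxN class with an
option to pool CxN+NxC.  Class-level survival percentages pool counts
across litters (ratio of sums) — robust to litter-size variation —
while Welch's t-test operates on per-litter survival values, which are
the replicates.  Farrowing survival is live-born / total-born;
lactation survival is weaned / live-born (weaning ≈ 21 days).

Under a fully penetrant lethal, one quarter of CxC live-born piglets
are homozygous and die before weaning, so CxC lactation survival
converges to 0.75× the carrier-by-non-carrier baseline (~25% relative
drop) while farrowing survival is unaffected.

## Gene-drop simulator

Discrete generations; random mating with a 1:10 sire:dam ratio
(boar-line-like); litter sizes Poisson around a mean of 10; baseline
farrowing and lactation survival 91% and 90%; one recessive lethal at
4.5% founder allele frequency.  Founder marker alleles are drawn
independently with frequencies uniform on (0.05, 0.95); every founder
haplotype carrying the lethal also carries one shared ancestral marker
haplotype over ±12.5 cM around the locus, emulating the long
identity-by-descent segment a recent mutation rides on in a small-Ne
line (the half-width is configurable; it must exceed the scan window
for the emulation to be faithful, and recombination erodes it each
generation).  Founders are survivors by construction, so no founder is
homozygous for the lethal.

Meiosis follows Haldane's no-interference model, realized at marker
resolution: recombination between adjacent markers is an independent
Bernoulli event with probability (1 − e^(−2d))/2 for map distance d
Morgan — exactly the marginal a Poisson crossover process induces on
the marker grid — which vectorizes over tens of thousands of gametes.

Homozygote fate: stillborn at the baseline stillbirth rate (default
1 − 0.91), otherwise dead within 48 h (truncated-exponential age, scale
8 h, so most deaths fall inside 24 h).  This default keeps CxC
farrowing survival at baseline and produces the ~25% lactation deficit;
both probabilities are configurable, including partially penetrant
settings.  Other piglets are stillborn or die pre-weaning at the
baseline rates with uniform death ages.  Only piglets surviving to
weaning are genotyped (founders included); a configurable number of
final-generation CxC "validation litters" is fully genotyped including
dead piglets, feeding the segregation stage.

The sequenced subset (default 71 animals including 5 carriers) carries
a variant neighborhood within ±1.5 Mb of the locus: the causal 16-bp
deletion in perfect LD with the lethal haplotype, a block of variants
copied from the carrier haplotype exactly (perfect LD), a block with
graded haplotype concordance (0.90–0.995, which with few carriers often
still realizes r² = 1 — the reason perfect-LD variant counts are large
in such studies), and unlinked background variants.  Consequence
annotations mark the causal deletion as frameshift, one graded variant
as splice-acceptor and three as tolerated missense (scores 0.19–0.45).

Trait records emulate deregressed breeding values: DEBV = carrier
effect × dosage + polygenic value + residual, with the polygenic value
gene-dropped (founders N(0, h²), offspring midparent plus Mendelian
noise of variance h²/2 — inbreeding shrinkage of the Mendelian term is
ignored), residual variance (1 − h²)/w per record, weights uniform on
(0.5, 2) and reliabilities uniform on (0.15, 0.95) so the >0.20 filter
has something to remove.  Default carrier effect −0.39 (the
lactation-survival effect size the simulator targets) and h² = 0.10, a
typical heritability for piglet-survival traits.  The single config
seed drives one generator; identical seeds give byte-identical
datasets.

What the simulator does **not** emulate: selection on breeding values,
balancing selection, mutation, the X chromosome, linkage disequilibrium
among background markers (founder alleles are drawn independently, so
only the lethal region has haplotype structure), overlapping
generations, and frequency trajectories over time.  Passing tests
therefore show the statistics behave correctly under the assumed
population model, not that they are robust to, e.g., strong background
LD or family stratification beyond what the pedigree captures.

## Frameshift consequence prediction

A coding model is the spliced CDS (start codon through stop codon) plus
genomic exon intervals and strand; genomic deletions map strand-aware
into CDS coordinates and must fall inside one exon (the supported case;
splice-spanning deletions are rejected, not guessed).  In-frame
deletions (length ≡ 0 mod 3) report zero novel residues.  Frameshifts
translate the shifted sequence — extended by the trailing transcript
sequence in case the original stop is lost — to the first stop, and
report the shared prefix with the wild-type protein, the novel residue
count, and the lost wild-type residues.  An HGVS-style
`chrom:g.<pos>del<SEQ>` identifier round-trips and its deleted sequence
is validated against the reference.

The package ships a deterministic **synthetic** transcript model
(`synthetic_sptbn4_like_model`) mirroring the geometry of the pig
SPTBN4 case — a 2563-residue protein in which deleting
`GACGGTGTACGCCGGT` at the codon-1902 boundary yields a 30-residue novel
tail, a premature stop, and loss of the final 662 residues.  It is a
constructed stand-in, not the Ensembl transcript; it exercises the full
translation path at realistic scale.

## Variant prioritization

LD is the squared Pearson correlation between variant genotype dosage
and haplotype dosage over sequenced animals (the haplotype treated as a
pseudo-marker); zero-variance vectors give a missing r², never 0.
Candidates need r² > 0.8.  Ranking: high-impact consequences first
(within the tier, protein-truncating frameshift/stop-gained before
splice predictions, which are the less certain annotation), then
missense not predicted tolerated, tolerated missense (score above 0.05,
the cited predictor's conventional cutoff), then everything else; ties
break by descending r², then position.  r² = 1 within 10⁻⁹ is flagged
as perfect LD.

## Segregation and penetrance

Carrier-by-carrier litters are tested against 1:2:1 at birth, or 1:2
among survivors when homozygotes die before genotyping age (the
complete-lethality expectation; partial-lethality ratios are out of
scope).  Chi-squared is the textbook Σ(O−E)²/E; whenever the total is
≤ 100 an exact multinomial p is reported as well, with the same
probability-mass ordering as the HWE test.  Penetrance is the fraction
of homozygotes dead within the window (default 48 h); stillborn
piglets count as dead at age 0.  Counts are sufficient: pooling litters
equals testing summed counts.

## The carrier association model

DEBV_ij·w = μ + R_i + a_j + e_ij: response is the deregressed breeding
value, R the fixed regression on carrier dosage (0/1/2 — homozygotes
are absent from survivor data but the code path supports 2), a_j the
additive genetic effect with covariance A·σ²ₐ under the pedigree
numerator relationship matrix, and e heteroscedastic with variance
σ²ₑ/w per record.  Records are filtered to weight > 0 and DEBV
reliability > 0.20.

Variance components are supplied as the ratio σ²ₐ/σ²ₑ (from each
trait's routine-evaluation heritability, ratio = h²/(1−h²)); REML
estimation is out of scope.  σ²ₑ is profiled from the generalized
residual sum of squares, (y'Dy − θ̂'W'Dy)/(n − p).  The mixed-model
equations are assembled sparsely: A⁻¹ comes directly from Henderson's
rules with inbreeding coefficients from the Meuwissen–Luo recursion, so
a 15,000-record fit takes seconds without ever forming A.  The fixed
effect's sampling variance is σ̂²ₑ times the corresponding block of the
inverse coefficient matrix, which equals (X'V⁻¹X)⁻¹; the dense tabular
A and direct GLS inversion serve as the cross-check in tests (equal to
1e-8 relative).  The dosage effect is tested with a Wald z against the
standard normal — standard at these sample sizes — with the p-value
computed in log space so −log₁₀(P) ≈ 50 is representable; effects with
−log₁₀(P) > 5 are flagged significant.  A ratio of 0 collapses the
model to weighted least squares (used as a degenerate-case check).

## Problem sizes and numerical choices

The test suite and acceptance script verify scan localization on a
simulated population of ~25,000 genotyped animals × 2,000 markers
(5,000 founders, one generation), effect recovery on 15,000 trait
records, and the litter contrast on a litter-heavy simulation
(~10,000 litters, ~100 CxC) — sizes chosen to match the study
population while keeping a full run in minutes on one CPU.  Exact-test
oracles use exhaustive rational arithmetic on all small instances.
Probability-mass orderings use a 10⁻¹⁰ relative slack when comparing
log-probabilities so float ties (e.g. symmetric configurations) are
counted as ties.  Pipeline outputs are sorted deterministically and a
manifest (parameters, seed, input checksums) makes a run re-executable.

## Known limitations

- The scan assumes phased, imputation-complete panels; phasing itself
  is out of scope and phase errors are not modelled.
- Window-haplotype frequency slightly underestimates the lethal allele
  frequency (within-window recombinants of the carrier haplotype are
  not counted); the effect is bounded by the window's map length.
- The exact binomial treats the haplotype frequency as known; at very
  small expected counts the test is conservative.
- Carrier status from a marker haplotype is a proxy: with sparse maps
  the focal window can mis-call recombinant carriers, which attenuates
  downstream LD (visible in the pipeline when marker spacing is coarse).
- The animal model fixes variance ratios rather than estimating them,
  and tests a single variant at a time.
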