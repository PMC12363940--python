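# Methods

## The measurement being modelled

PAS-seq reads run 5′→3′ through a genomic insert whose last base is the
cleavage/polyadenylation position, then the poly(A) tail, then a 6-nt
ligated linker. Counting reads per poly(A) site (PAS) therefore measures
isoform-level 3′-end usage. Acute depletion of a nuclear retention/decay
factor is modelled as multiplicative effects on the expected counts of
the misprocessed RNA classes: IPA sites (inside introns) and PROMPT sites
(antisense, upstream of a TSS) gain abundance in depleted cells, with an
extra "leakage" multiplier in the depleted cytoplasm representing escape
from nuclear retention; terminal sites are unaffected. Intron retention
is modelled separately at the junction-count level.

## Synthetic-data generator

The generator is first-class, tested code: every downstream stage is
scored against the truth records it emits.

**Genome and annotation.** Genes are placed left-to-right on one contig
with alternating strands and 3.5-kb intergenic gaps (so a 3-kb PROMPT
window never overlaps a neighbouring gene). Exons are 150–300 nt, introns
250–450 nt, 1–4 introns per gene. Each gene has one terminal PAS at its
3′-most base; an exact fraction of genes (default 0.2) gets one intronic
PAS at an intron midpoint, and an exact fraction (default 0.2) one PROMPT
PAS 300–1,500 nt upstream of the TSS on the antisense strand. Coordinates
are 0-based half-open, strand "+"/"−", and a site's position is the last
transcribed base, so BED interchange is direct.

**Sequence-level hygiene.** Three deterministic edits make filter and
trimmer performance measurable rather than luck: (i) the base at every
true PAS is non-A in transcribed sense, so poly(A) trimming stops exactly
at the 3′ end; (ii) the 10-nt downstream window of every true PAS is
resampled until it fails the A-rich rule, so no true read is
filter-eligible; (iii) decoy A-tracts (6–8 As in transcribed sense,
planted in half of introns, ≥30 nt from any PAS) create unambiguous
internal-priming targets. Real genomes are not sanitized this way — on
real data a small fraction of genuine 3′ ends downstream of A-rich
sequence is lost, which these simulations deliberately do not show.

**Counts.** Per-site baselines are lognormal (σ = 0.5) around
`base_mean` = 100, scaled per class: IPA 0.15×, PROMPT 0.05× of terminal.
The class factors encode that IPA isoforms are minor and PROMPTs
near-undetectable at steady state; they also keep the affected site
fraction and library mass small enough that TMM's
majority-non-differential assumption holds — with equal abundances and
~50% affected sites the normalization itself becomes biased, a regime no
real transcriptome presents. Counts are NB with var = μ + φμ²
(φ default 0.05; φ = 0 falls back to Poisson). The design is 2 conditions
(DMSO control / dTAG depleted) × 2 compartments × 3 replicates.

**Reads.** Each counted tag becomes one read:
`[insert][A-tail (8–30 nt)][linker CTGTAG]`, padded to a fixed 75-nt
pre-trim length (so insert length = 75 − 6 − tail ≥ 20 always holds for
the default tail range; inserts below 20 nt, or running off the contig,
are skipped and logged). A fraction `internal_priming_rate` of reads is
re-anchored to a random decoy instead of its true PAS. The real protocol's
layout details (linker identity, orientation) are not published; the
simulated layout is a self-consistent stand-in, and the trimmer/aligner
are tested against it, not against real chemistry. No sequencing errors,
quality realism or paired ends are simulated.

**Junction counts.** Per intron and sample, `depth` = 100 molecules are
observed: retained molecules (binomial with the intron's true PSI,
default 0.1) support both boundaries (I1 = I2), spliced ones the
exon–exon junction. 20% of introns — 80% of them drawn from last
introns — get PSI + 0.3 in the depleted cytoplasm. Setting I1 = I2 per
molecule reflects that one retained pre-mRNA spans both boundaries; the
PSI estimator is then exactly a binomial proportion.

## Read processing

Trimming removes the terminal linker (≤1 mismatch, mirroring standard
adapter-trimmer tolerance) and then the **maximal** terminal A-run.
Reads with an A-run shorter than `min_tail` = 3 failed trimming and are
rejected, as are inserts shorter than 20 nt. A consequence of the
maximal-run rule: an insert whose own last base is A is indistinguishable
from tail, so the generator never ends inserts in A; on real data this
costs single-base 3′-end precision at A-ending sites.

Alignment is exact full-length string search of the insert and its
reverse complement over all contigs, requiring a unique hit;
multi-mappers and no-hits are reported with reasons. This is a toy-genome
device — real data enter the pipeline as pre-aligned BED tags.

## Internal-priming filter

A tag is an artifact iff the 10 bases immediately downstream of its 3′
end, read in transcribed sense ("+": genomic [p+1, p+11); "−": reverse
complement of [p−10, p)), contain a run of ≥6 A or ≥7 A total. N bases
never count as A and break runs (conservative: truncated windows at
contig edges are padded with N and so tend to be kept). The window is
strictly downstream of the read — the read's own terminal bases are not
examined — because the artifact arises from oligo-dT annealing to
template downstream of the apparent 3′ end. The rule is evaluated in
transcribed sense so it is strand-symmetric (genomic T tracts upstream of
a "−" tag are As on the transcript).

## PAS assignment and classification

A filtered tag is assigned to the same-strand PAS within ±24 nt of its 3′
end (typical 3′-cluster width; exposed as `--flank`), nearest first, ties
to the upstream site. Classification is positional with precedence
IPA > terminal > PROMPT on overlap: intronic positions of a same-strand
gene are IPA; terminal-exon positions terminal; positions ≤3,000 nt
upstream of a TSS on the antisense strand and outside any same-strand
gene are PROMPT; everything else `other`. The 3-kb PROMPT window is
standard usage, not a published constant of the assay.

## Differential testing

**Normalization** follows the published TMM definition: M-values (log2
CPM ratio vs a reference sample) trimmed 30% per side, A-values 5% per
side, surviving M-values averaged with binomial precision weights;
reference = sample whose upper-quartile CPM is closest to the mean;
factors anchored to geometric mean 1. Effective library size =
raw total × factor.

**Dispersion** is a pooled method of moments: within each replicated
group, per-site sample mean m and variance v of effective-library-scaled
counts satisfy E[v] ≈ m + φm²; φ̂ = max(0, Σ(v−m)/Σm²) pooled over sites
and groups. No tagwise shrinkage or GLM machinery — a deliberate
simplification that is accurate when a common dispersion truly applies,
as in the generator.

**Exact test.** For one site, the two group sums are compared
conditionally on their total t: P(Y₁ = x | t) ∝ f₁(x)·f₂(t−x), where f_g
is the NB mass of the group-g sum (r_g = n_g/φ, mean λ̂N_g with
λ̂ = t / (N₁+N₂) and N_g the summed effective library sizes). The
two-sided p-value sums the probability of every split at most as likely
as the observed one. At φ = 0 the conditional law is exactly binomial
with success probability N₂/(N₁+N₂) — the property the binomial-oracle
test checks to 10⁻¹⁰. This conditions after effective-library
equalization rather than via quantile pseudo-data; the simplification is
testable and documented, not hidden. log2FC uses per-group means of
factor-scaled counts with a 0.5 pseudocount so zero counts stay finite.

**Multiple testing** is Benjamini–Hochberg (via statsmodels); calls
require FDR ≤ 0.05 and |log2FC| > 1.

## Compartment and retention statistics

Class-level log2FCs are computed within each compartment (normalizing
within the compartment, matching how paired nucleus/cytoplasm panels are
constructed), then the per-site cytoplasmic and nuclear responses of each
class are compared by Mann-Whitney. The test enumerates the exact
permutation distribution of U over pooled mid-ranks when n+m ≤ 16 (at
most C(16,8) = 12,870 splits; ties handled exactly) and otherwise uses
the normal approximation with tie and continuity corrections.

Retention replicates are pooled per compartment before Fisher's exact
test on [[I_cyto, S_cyto], [I_nuc, S_nuc]] (inclusion = mean of the two
boundary counts, rounded) — exact at toy depths, at the cost of ignoring
replicate-level variability; per-replicate PSI values are also reported.
"Significant" for positional enrichment means ΔPSI > 0.1 and BH-FDR
≤ 0.05 (both exposed as flags); enrichment of last introns among the
significant set is a two-sided exact binomial test against the background
last-intron fraction. The single-intron convention is `last`, since the
leakage phenomenon concerns the 3′-most intron.

ΔΔCt follows the standard rule 2^−ΔΔCt with ΔΔCt =
(Ct_target − Ct_ref)_b − (Ct_target − Ct_ref)_a.

## Screen / mass-spec overlap

Top-n hit selection sorts by FDR with deterministic tie-breaks
(enrichment score, then symbol; boundary ties warn). Coverage fold
enrichment is (num + pc)/(den + pc) with a 1-percentage-point pseudocount
for zero denominators, per replicate when replicate columns are given;
the ≥ threshold filter is inclusive and supports `any` /
`all-replicates` modes, since published hit lists use both conventions.
Symbols match exactly after uppercasing — alias/ortholog mapping is out
of scope and mismatches surface in the Venn report rather than being
guessed.

## Numerical choices and degenerate inputs

- Conditional pmfs are computed in log space and normalized with
  logsumexp; the "at most as likely" comparison uses a 10⁻¹² log-space
  tolerance so symmetric ties are counted once each.
- Both group sums zero → p = 1, log2FC = 0. All-zero junction rows →
  PSI missing. Zero-total compartments → missing ΔPSI. Degenerate
  backgrounds (all introns `last`) → enrichment p = 1.
- All randomness flows through `numpy.random.default_rng` seeded from
  `(seed, stage)` pairs, so the annotation, counts, reads and junction
  stages are independently reproducible and byte-identical across runs.

## Problem sizes

Default analyses run at desk scale: null calibration uses ~5,000 PAS
(3,600 genes) at 3v3; power uses ~300 spiked IPA sites; the depletion
signature uses 250 genes with full read-level processing reserved for
smaller (~20-gene, ~10⁴-read) simulations. These sizes give the
acceptance checks sampling error well inside their margins while keeping
the whole suite in minutes.

## Known limitations

Exact alignment cannot represent mismatches, splicing or multi-mapping
structure of real genomes; the priming filter's real-data false-positive
rate (true 3′ ends above genomic A tracts) is invisible here by
construction; the common-dispersion exact test understates uncertainty
when dispersions vary per site; pooled Fisher retention tests treat
replicates as exchangeable; and the compartment contrasts assume
within-compartment normalization is meaningful (no spike-ins, no
absolute cross-compartment scale).
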