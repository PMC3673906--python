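# Methods

This note records the statistical models, the synthetic study conditions,
and the design choices behind `conifersnp`, in enough detail to judge what
passing tests do and do not demonstrate.

## The pooled site-calling model

Pooled libraries expose allele frequencies, not genotypes: each read at a
site is, to a good approximation, an independent draw from the pool's
allele-frequency distribution, perturbed by sequencing error. The caller
tests the composite null hypothesis that the pool's minor-allele frequency
is at most θ, given a per-base error rate e. At the null boundary, an
alternative read arrives with probability

    p0 = θ(1 − e) + (1 − θ)e

(a true minor allele read survives error, or a major-allele read is
miscalled). The reported probability is the one-sided binomial upper tail
P(X ≥ a) for a alternative reads out of the effective (non-N) depth. This
boundary form is the conservative frequentist reading of pooled-sample SNP
testing: any true frequency below θ gives a smaller tail probability, so
the test's size is controlled at the boundary. The pool's chromosome count
is not modelled; with pools of tens of genotypes the binomial read-sampling
term dominates and the boundary test is the defensible choice.

Defaults: θ = 0.01, e = 0.01, minimum depth 5, minimum 2 alternative reads,
base/mapping-quality floors 20, and a 20 000-read cap above which a site is
skipped with a warning. The alternative allele is the highest-count
non-reference base; ties break deterministically in A<C<G<T order.
Tri-allelic sites are scored on the best alternative but retain the full
allele set so the bi-allelic rule can act downstream. A site whose reads
carry one allele that differs from the reference ("fixed difference") is
never emitted as a SNP — without within-pool polymorphism the discrepancy
is indistinguishable from a reference or sequencing artifact. Indels are
the exception: an indel relative to the reference is recorded even without
within-pool polymorphism, scored by the same binomial tail on its
supporting-read count. Indels from the long-read pool are dropped at
merging (homopolymer artifacts make them untrustworthy).

N-channel handling: bases below the quality floor (including quality-2
runs, which the pipeline converts to N before counting) contribute to depth
but never to allele counts; p-values use the effective depth excluding N.

## Fisher combination and flank masking

Per-pool probabilities for the same site are combined with Fisher's method:
X² = −2 Σ ln pᵢ is χ²-distributed with 2k degrees of freedom under the
joint null. The survival function is evaluated with the even-df closed form
exp(−x/2) Σ_{i<k} (x/2)^i / i!, which is exact and oracle-checkable against
numerical quadrature of the χ² density. When a pool has no retained call at
a site, only the pools present contribute and df = 2 × (pools present);
using a fixed df = 10 with absent pools would deflate significance
artificially. This is a deliberate deviation from a literal fixed-df
reading and is flagged here. p-values of exactly 0 are clamped at 1e-300
(logged) so ln is defined while preserving ordering.

A variant is retained for masking iff its minimum per-pool p or its pooled
p falls below the flanking threshold P_F (default 0.10 — deliberately
permissive, since a missed flanking variant silently breaks an assay
probe). Masked SNP positions are rewritten as the IUPAC code of the full
allele set (reference plus all alternatives); the combined reference takes
the union of per-pool allele sets. Indels have no IUPAC symbol and are
carried as a 0-based half-open BED track instead of sequence edits, keeping
masked sequences length-identical to the input.

## Target and array cascades

Target SNPs must (a) lie on the longest isotig of their isogroup (one
marker locus per gene model), (b) be bi-allelic, (c) not sit within ±10 nt
(configurable) of a masked indel position — this window is a reproducible
stand-in for an upstream aligner's opaque "near high-quality indel"
annotation, (d) reach mapping quality > 40 in at least one pool, and
(e) have min per-pool p below P_S (10⁻², 10⁻³ or 10⁻⁴). Relaxing P_S can
only grow the set (superset property, tested).

The array cascade then: (1) drops isotigs in low-confidence classes C5/C6;
(2) keeps up to two SNPs per priority (differentially-expressed or
annotation-selected) isotig with pairwise spacing ≥ 50 nt, chosen greedily
by ascending mean p; (3) requires non-priority SNPs to replicate in ≥ 2
pools and keeps the single lowest-mean-p SNP per isotig; (4) applies
assay-design filters to non-priority rows only: two-probe chemistries (A/T
and C/G pairs) are dropped, as are design scores < 0.60 (or absent — an
unscorable assay cannot be ordered), mean reads < 10, and mean frequency
< 0.05. Mean reads and frequency are averaged over the pools that detected
the SNP; averaging over all pools would impute zeros and bias the filter
against rare but real variants. Every rejected row carries the first rule
it failed, so |input| = |selected| + |ledger| everywhere. "Most probable"
ties break by position then allele order, making selection invariant to
input row order.

## Assembly QC

C1–C7 classification uses three criteria per isotig against a related
species' unigene set: number of distinct subjects among *countable* matches
(those within 5 identity points of the isotig's best hit), whether other
isotigs' countable matches share a subject, and whether shared-subject
alignments overlap. Overlap is evaluated on subject-side coordinates
(closed intervals, ≥ 1 shared base): the subject sequence is the common
ruler two isotigs can actually collide on. No match at all is C7.

Strand orientation uses the exact two-tailed binomial test on
reverse-complement (C) versus direct (D) unique alignment locations at null
0.5 (the "small p-values" two-sided method). With dUTP-style stranded
libraries, reads map as reverse complements of the transcript, so C
significantly above D means forward orientation. Ties (C = D) and p ≥ 0.05
are ambiguous.

N50 follows the standard convention: the smallest length L such that
sequences ≥ L sum to at least half the total. (Prose descriptions of N50
sometimes invert the inequality; the standard form is implemented and has
the weighted-median property N50 ≥ median, which is property-tested.)

Contaminant screening removes a sequence iff its best hit has bitscore > 50
and E-value < 1e-10 and the hit's genus (first token of the organism
field) appears in the bacterial/fungal name lists; an absent hit keeps the
sequence.

## Genotyping-array QC

Per locus: call frequency (called / samples), genotype counts, minor-allele
frequency among called genotypes, observed heterozygosity n_AB/n, expected
heterozygosity 2p(1−p) (plain, not the n/(n−1)-corrected estimator — the
attainable maximum of 0.5 matches reported ranges), and the exact
conditional Hardy-Weinberg test. The HWE test conditions on the observed
allele counts, computes the probability of every attainable heterozygote
count (same parity as the rare-allele count) by the standard recurrence
from the distribution's mode, and sums the probabilities of configurations
no more probable than the observed one — the cumulative, not mid-p,
variant. It matches an exact-integer enumeration oracle for every
configuration with ≤ 10 individuals.

A locus is *successful* when call frequency ≥ 0.85 (after optionally
no-calling genotypes with per-call quality < 0.15) and MAF > 0; loci that
pass the call-rate gate but are monomorphic form a distinct "called, not
polymorphic" category. Array-level summaries report the full percentage
grid (assayed/attempted, called, successful on each base, 1 decimal,
round-half-away-from-zero) and flag HWE deviants at the per-test threshold
family_alpha / n_successful, counted over successful loci only.

## Synthetic study conditions

The generator's defaults define the conditions under which the test suite
and acceptance measurements run; they were chosen once to be realistic for
a pooled conifer transcriptome study and are not tuned per test:

- **Pools**: five datasets — one combined Sanger/454 long-read pool
  (indel-untrusted) and four short-read pools.
- **Coverage**: negative binomial per site, mean 100, dispersion 10.
  RNA-seq-derived pileups are overdispersed relative to Poisson; dispersion
  10 gives a coefficient of variation ≈ 0.33.
- **Errors**: uniform substitution, probability e/3 to each of the three
  other bases, e = 0.01 — the single error-rate parameter the caller also
  uses. At a SNP site with pool frequency f the expected alternative-read
  fraction is f(1−e) + (1−f)e/3, and the generator-consistency tests check
  exactly this closed form.
- **Variants**: ~2 per kb; 60% planted in ≥ 2 pools; planted frequencies
  uniform on [0.05, 0.5]; 10% indels (1–3 nt insertions).
- **Genotypes**: inbreeding-adjusted HWE model, P(AB) = 2pq(1−f), with
  independent no-calls; 260 samples in pipeline runs.
- **Seeding**: one global seed fans out to fixed per-component child
  streams (numpy `SeedSequence` spawn keys), so components are independent
  yet the whole run is byte-reproducible.

What the generator does *not* emulate: read-level artifacts (alignment
error, strand bias, indel realignment ambiguity), library-size differences
between pools, linkage between nearby variants, and cluster-intensity
noise in genotyping. Passing tests therefore demonstrate the statistical
machinery is correct under its stated model, not that real-data error modes
are handled; on real data the caller's false-positive rate depends on
alignment quality far more than on the binomial model.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: caller power is measured on 1 000 planted sites (frequency 0.20,
depths drawn from the default coverage model conditioned on ≥ 50), the
false-positive rate on 5 000 null sites, orientation recovery on 300
references at 1 000 reads each, HWE calibration on 10 000 loci of 260
samples, and full pipeline runs on 3–12 transcripts. Stochastic assertions
use 3-standard-error bands at fixed seeds. Numerical tolerances: binomial
tail vs. enumeration 1e-12; χ² closed form vs. quadrature 1e-10; HWE vs.
enumeration 1e-12. Degenerate inputs (empty pileups, zero called
genotypes, monomorphic loci, empty masks, zero-length assemblies) return
well-defined empty/None results rather than raising, except where the input
is structurally inconsistent (negative counts, off-reference positions,
conflicting reference bases), which raises a validation error.

## Known limitations

- The flanking-indel adjacency window (±10 nt) is a configurable surrogate
  for an external tool's annotation; no claim is made that it reproduces
  that tool's flag exactly.
- The Fisher df policy for partially covered sites (df = 2 × pools present)
  is a modelling choice; see above.
- Indel probabilities reuse the SNP binomial tail on supporting reads; no
  indel-specific error model is fitted.
- The per-pool chromosome count is not part of the likelihood (boundary
  binomial test only).
- Design scores are inputs (or simulated Beta(5,2) draws in synthetic
  runs); the vendor's scoring algorithm is proprietary and out of scope.
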