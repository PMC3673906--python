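# conifersnp

A toolkit for building and validating a SNP genotyping resource from
**pooled transcriptome sequencing**, aimed at tree breeders and population
geneticists working on non-model conifers. When cDNA from many genotypes is
sequenced as a pool, individual genotypes are invisible — only allele
frequencies can be read out of the aligned read counts. `conifersnp`
implements the full path from per-site read counts to a validated marker
panel:

1. **Pooled site calling** — at each reference position, the evidence for a
   SNP is the count of alternative-allele reads `a` out of depth `n`. The
   caller tests the composite null "pool minor-allele frequency ≤ θ given
   per-base error rate e" at its boundary: under the null, alternative reads
   arrive with probability `p₀ = θ(1−e) + (1−θ)e`, and

   `p_snp = P(X ≥ a)`, `X ~ Binomial(n, p₀)`, with θ = e = 0.01 by default.

   Sites with depth < 5 or < 2 alternative reads are filtered, and a site
   whose reads carry a single allele differing from the reference is treated
   as reference/sequencing error, never as a SNP.
2. **Across-pool combination** — Fisher's method pools the per-dataset
   probabilities: `X² = −2·Σ ln pᵢ` on `2k` degrees of freedom (10 for five
   pools), evaluated with the even-df closed form
   `exp(−x/2)·Σ_{i<k}(x/2)^i/i!`. Variants below a permissive flanking
   threshold `P_F = 0.10` (in any single pool or pooled) are rewritten in the
   reference as **IUPAC ambiguity codes** ({A,G}→R, {A,C,G}→V, …) so assay
   primers avoid them; indel positions go to a BED interval track.
3. **Target and array selection** — bi-allelic, indel-free, well-mapped
   (MQ > 40), confident (`min p < P_S`, default 10⁻⁴) SNPs on the longest
   isotig per gene model; then an Infinium-array cascade (≤ 2 spaced SNPs per
   priority gene, single best replicated SNP elsewhere, one-probe chemistry,
   design score ≥ 0.6, ≥ 10 reads, frequency ≥ 0.05), with a complete
   rejection ledger.
4. **Assembly QC** — C1–C7 structural confidence classes against a related
   species' unigene set, exact-binomial strand orientation from stranded
   libraries, contaminant screening, and assembly statistics (N50 etc.).
5. **Genotyping-array QC** — call frequency, MAF, observed/expected
   heterozygosity, and the exact conditional Hardy–Weinberg test with a
   Bonferroni-corrected deviation flag; conversion-rate accounting and
   resource extrapolation.

A first-class **synthetic data generator** plants variants with known pool
frequencies, known strand orientations, known homology-class structures and
known genotype distributions, so every stage is testable end-to-end with no
sequencing data.

## Worked example

```python
from conifersnp import report, run_pipeline

result = run_pipeline({
    "seed": 42,
    "simulate": {"n_isotigs": 12, "isotig_length_range": (500, 1200)},
    "orientation": {"n_refs": 20, "reads_per_ref": 200},
})
print(report(result.manifest))
```

prints (abridged):

```
stage counts:
  reference_sequences          12
  planted_variants             21
  combined_variants            5064
  masked_snp_positions         28
  masked_indel_positions       1
  target_snps                  14
  target_rejected              5049
  array_candidates             7
  array_successful             7

array summary:
  attempted 7  assayed 7  called 7  successful 7
  successful_of_assayed        100.0
```

Reading this: five simulated pools over 12 transcripts yield 5064 merged
variant records (most are error-driven sites with p near 1); 28 positions
meet the flanking threshold and are IUPAC-masked; 14 variants survive the
target cascade, 7 become array candidates, and all 7 convert into successful
markers in the simulated 260-tree genotyping run. Counts are conserved at
every filter (input = retained + rejected), and re-running with the same
config and seed reproduces every SHA-256 digest in the manifest.

The `examples/` directory holds one short script per capability
(simulation, pooled calling, Fisher combination and masking, target/array
selection, assembly QC, array QC, full pipeline). A thin CLI mirrors the
stages: `conifersnp simulate | call | combine | select-targets | classify |
orient | stats | array-qc | pipeline run`.

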