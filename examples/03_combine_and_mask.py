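"""Merge pools with Fisher's method and mask flanking variants as IUPAC codes.

A variant seen weakly in several pools can still be real: Fisher's method
pools the per-dataset probabilities into X^2 = -2*sum(ln p_i) on 2k degrees
of freedom. Variants passing the permissive flanking threshold (P_F = 0.10,
single-dataset or pooled) are rewritten in the reference as ambiguity codes
so assay design avoids them.
"""

from conifersnp import (SimConfig, build_masked_reference, fisher_combine,
                        merge_datasets, select_flanking_variants,
                        simulate_pileups, simulate_reference)
from conifersnp.site_calling import call_dataset
from conifersnp.simulate import DEFAULT_INDEL_UNTRUSTED

chi_sq, df, pooled = fisher_combine([0.2] * 5)
print(f"five pools each at p=0.2: X^2={chi_sq:.3f}, df={df}, pooled p={pooled:.4f}")
print("  -> none significant alone, but jointly below P_F = 0.10\n")

cfg = SimConfig(n_isotigs=3, seed=3)
reference, truth = simulate_reference(cfg)
pileups = simulate_pileups(reference, truth, cfg)
snp_tables, indel_tables = {}, {}
for ds in cfg.dataset_ids:
    snp_tables[ds], indel_tables[ds] = call_dataset(
        pileups, dataset_id=ds, indel_trusted=ds not in DEFAULT_INDEL_UNTRUSTED)

combined = merge_datasets(snp_tables, indel_tables,
                          indel_untrusted=DEFAULT_INDEL_UNTRUSTED)
mask = select_flanking_variants(combined, p_f=0.10)
masked, _, indel_track = build_masked_reference(reference, mask)

print(f"combined variants: {len(combined)}; "
      f"masked SNP positions: {mask.n_masked_snps()}; "
      f"masked indel positions: {mask.n_masked_indels()}")
for isotig, positions in list(mask.snps.items())[:1]:
    for pos, alleles in sorted(positions.items())[:3]:
        print(f"  {isotig}:{pos} alleles {sorted(alleles)} -> "
              f"'{masked[isotig][pos - 1]}' in the masked reference")
print("masked sequences keep their length; indels go to a BED-style track")
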