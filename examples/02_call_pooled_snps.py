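"""Per-pool SNP calling with the composite-null binomial test.

In a pooled library, reads sample allele frequencies. The caller asks: could
this many alternative reads arise if the pool's minor-allele frequency were
at most theta = 0.01 with per-base error e = 0.01? The reported p_snp is the
binomial upper tail at the null boundary p0 = theta(1-e) + (1-theta)e.
"""

from conifersnp import (CallerParams, SimConfig, simulate_pileups,
                        simulate_reference)
from conifersnp.site_calling import call_dataset

cfg = SimConfig(n_isotigs=3, seed=7)
reference, truth = simulate_reference(cfg)
pileups = simulate_pileups(reference, truth, cfg)

params = CallerParams()  # theta=0.01, e=0.01, depth>=5, >=2 alt reads
print(f"null boundary p0 = {params.null_alt_probability:.4f}")

ds = cfg.dataset_ids[0]
calls, indels = call_dataset(pileups, dataset_id=ds, params=params)
print(f"dataset {ds}: {len(calls)} retained SNP calls, {len(indels)} indels")
print(calls.nsmallest(5, "p_snp")[["isotig", "pos", "ref", "alt",
                                   "alt_count", "depth", "p_snp"]]
      .to_string(index=False))
print("small p_snp = alternative reads far exceed what error alone explains;"
      " p near 1 = consistent with sequencing error")
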