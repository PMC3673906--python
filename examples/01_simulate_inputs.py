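"""Generate synthetic pipeline inputs with planted ground truth.

Draws a small transcript reference, plants SNPs/indels with known pool
frequencies, and emits per-dataset pileup count tables — the raw material
every later stage consumes.
"""

from conifersnp import SimConfig, simulate_pileups, simulate_reference

cfg = SimConfig(n_isotigs=5, isotig_length_range=(500, 1000), seed=42)
reference, truth = simulate_reference(cfg)
pileups = simulate_pileups(reference, truth, cfg)

print(f"reference: {len(reference)} isotigs, "
      f"{sum(len(s) for s in reference.values())} nt total")
print(f"planted variants: {len(truth)} "
      f"({sum(t.is_indel for t in truth)} indels)")
for tv in truth[:3]:
    freqs = ", ".join(f"{d}={f:.2f}" for d, f in sorted(tv.per_pool_freq.items()))
    kind = f"indel +{tv.indel_seq}" if tv.is_indel else f"{tv.ref_allele}>{tv.alt_allele}"
    print(f"  {tv.isotig_id}:{tv.position} {kind}  pool frequencies: {freqs}")
print(f"pileup table: {len(pileups)} rows "
      f"({cfg.n_datasets} datasets x every reference position)")
print("each row carries A/C/G/T/N counts whose sum equals the recorded depth")
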