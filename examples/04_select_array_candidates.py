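"""Target-SNP filtering and Infinium array candidate selection.

Targets must be bi-allelic, indel-free, well mapped (MQ > 40 somewhere),
confident (min p < P_S), and on the longest isotig of their gene model.
The array cascade then keeps up to two spaced SNPs per priority gene, the
single best replicated SNP per other isotig, and applies assay-design
filters (one-probe chemistry, design score >= 0.6, >= 10 reads, freq >= 0.05).
"""

from conifersnp import (SelectionConfig, extrapolate_resource,
                        filter_target_snps, run_pipeline,
                        select_array_candidates)
from conifersnp.simulate import simulate_design_scores

result = run_pipeline({"seed": 5,
                       "simulate": {"n_isotigs": 8,
                                    "isotig_length_range": (600, 1200)},
                       "orientation": {"n_refs": 10, "reads_per_ref": 100}})
combined = result.tables["combined"]
isogroups = result.tables["isogroup_map"]

cfg = SelectionConfig(ps_threshold=1e-4)
targets, rejected = filter_target_snps(combined, isogroups, config=cfg)
print(f"{len(combined)} combined variants -> {len(targets)} target SNPs "
      f"({len(rejected)} rejected; first-failed-rule ledger kept)")
print(rejected["reason"].value_counts().to_string())

scores = simulate_design_scores([(r.isotig, r.pos) for r in targets.itertuples()],
                                seed=5)
selected, ledger = select_array_candidates(targets, design_scores=scores,
                                           config=cfg)
print(f"\narray candidates: {len(selected)} selected, {len(ledger)} rejected")

est = extrapolate_resource(len(targets), 0.725)
print(f"at a 72.5% conversion rate, {len(targets)} targets extrapolate to "
      f"~{est} genotypable markers")
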