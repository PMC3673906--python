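"""Assembly evaluation: confidence classes, orientation, stats, contaminants.

Isotigs with clean one-to-one homology to a related species' unigenes (C1)
inspire the most confidence that reads assembled into a single true locus;
overlapping shared matches (C5/C6) suggest collapsed paralogs or fragmented
assembly. Strand orientation comes from stranded-library mapping counts.
"""

from conifersnp import (assembly_stats, classify_isotigs, orient_sequence,
                        screen_contaminant, simulate_match_table,
                        simulate_stranded_counts, orient_table)

plan = {"C1": 4, "C2": 2, "C3": 2, "C5": 2, "C7": 3}
matches, expected = simulate_match_table(plan, seed=9)
classes = classify_isotigs(matches, isotig_ids=list(expected))
print("confidence classes (classifier vs plan):")
print(classes["confidence_class"].value_counts().sort_index().to_string())

counts = simulate_stranded_counts(8, 500, 0.1, seed=9)
calls = orient_table(counts[["ref_id", "D", "C"]])
ok = (calls["orientation"] == counts["true_orientation"]).mean()
print(f"\norientation: {ok:.0%} of {len(counts)} references recovered "
      f"(misorientation rate 0.1, exact binomial test at 0.05)")
print(orient_sequence(2, 48, ref_id="demo"))

verdict = screen_contaminant(
    {"bitscore": 240.0, "evalue": 1e-35, "genus": "Pseudomonas"},
    genus_names={"Pseudomonas", "Fusarium"})
print(f"\nstrong Pseudomonas best-hit -> {verdict}")

st = assembly_stats([1390, 980, 2141, 356, 1883, 520, 760])
print(f"\nassembly: n={st.n_sequences} mean={st.mean:.0f} "
      f"median={st.median:.0f} N50={st.n50} total={st.total}")
print("N50: smallest length such that sequences at least that long hold "
      "half the assembled nucleotides")
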