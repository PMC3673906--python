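"""Generator correctness: determinism, conservation, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from conifersnp import (SimConfig, TruthVariant, simulate_genotypes,
                        simulate_match_table, simulate_pileups,
                        simulate_reference, simulate_stranded_counts)


class TestReference:
    def test_zero_density_plants_no_variants(self):
        ref, truth = simulate_reference(SimConfig(n_isotigs=1, variant_density=0.0))
        assert truth == []
        assert len(ref) == 1

    def test_same_seed_reproduces_outputs_exactly(self):
        cfg = SimConfig(n_isotigs=3, seed=7)
        ref1, truth1 = simulate_reference(cfg)
        ref2, truth2 = simulate_reference(SimConfig(n_isotigs=3, seed=7))
        assert ref1 == ref2
        assert truth1 == truth2
        p1 = simulate_pileups(ref1, truth1, cfg)
        p2 = simulate_pileups(ref2, truth2, cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_variant_count_in_poisson_band_of_its_own_lengths(self):
        cfg = SimConfig(n_isotigs=10, isotig_length_range=(500, 1000),
                        variant_density=2.0, seed=1)
        ref, truth = simulate_reference(cfg)
        lam = sum(len(s) for s in ref.values()) / 1000.0 * 2.0
        lo, hi = poisson.interval(0.99, lam)
        assert lo <= len(truth) <= hi

    def test_truth_positions_lie_on_reference(self):
        ref, truth = simulate_reference(SimConfig(n_isotigs=5, seed=3))
        for tv in truth:
            assert 1 <= tv.position <= len(ref[tv.isotig_id])
            assert ref[tv.isotig_id][tv.position - 1] == tv.ref_allele

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(isotig_length_range=(0, 100))

    def test_truth_variant_validates_fields(self):
        with pytest.raises(ValueError):
            TruthVariant("iso", 1, "A", "A", {"ds": 0.2})
        with pytest.raises(ValueError):
            TruthVariant("iso", 1, "A", "G", {"ds": 1.5})


class TestPileups:
    def test_no_error_no_variants_gives_pure_reference(self):
        cfg = SimConfig(n_isotigs=1, isotig_length_range=(200, 200),
                        error_rate=0.0, variant_density=0.0, n_datasets=1, seed=5)
        ref, truth = simulate_reference(cfg)
        pile = simulate_pileups(ref, truth, cfg)
        for row in pile.itertuples():
            assert getattr(row, f"count{row.ref}") == row.depth

    def test_fixed_allele_with_zero_error_reaches_full_depth(self):
        cfg = SimConfig(n_isotigs=1, isotig_length_range=(50, 50),
                        error_rate=0.0, variant_density=0.0, n_datasets=1, seed=5)
        ref, _ = simulate_reference(cfg)
        name, seq = next(iter(ref.items()))
        alt = "G" if seq[9] != "G" else "T"
        truth = [TruthVariant(name, 10, seq[9], alt, {cfg.dataset_ids[0]: 1.0})]
        pile = simulate_pileups(ref, truth, cfg)
        site = pile[pile["pos"] == 10].iloc[0]
        assert site[f"count{alt}"] == site["depth"]

    def test_depth_conservation_invariant(self):
        cfg = SimConfig(n_isotigs=2, n_fraction=0.05, seed=9)
        ref, truth = simulate_reference(cfg)
        pile = simulate_pileups(ref, truth, cfg)
        total = (pile[["countA", "countC", "countG", "countT"]].sum(axis=1)
                 + pile["countN"])
        assert (total == pile["depth"]).all()

    def test_mean_alt_fraction_matches_generator_closed_form(self):
        # 1000 replicate sites at planted frequency 0.2
        cfg = SimConfig(n_isotigs=1, isotig_length_range=(1000, 1000),
                        variant_density=0.0, n_datasets=1, seed=21)
        ref, _ = simulate_reference(cfg)
        name, seq = next(iter(ref.items()))
        ds = cfg.dataset_ids[0]
        truth = []
        for pos in range(1, 1001):
            rb = seq[pos - 1]
            alt = "A" if rb != "A" else "C"
            truth.append(TruthVariant(name, pos, rb, alt, {ds: 0.2}))
        pile = simulate_pileups(ref, truth, cfg)
        alt_counts = np.array([
            row[f"count{tv.alt_allele}"]
            for tv, (_, row) in zip(truth, pile.iterrows())
        ])
        fracs = alt_counts / pile["depth"].to_numpy()
        e = cfg.error_rate
        expected = 0.2 * (1 - e) + 0.8 * e / 3.0
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se

    def test_unknown_isotig_in_truth_rejected(self):
        cfg = SimConfig(n_isotigs=1, seed=1)
        ref, _ = simulate_reference(cfg)
        bad = [TruthVariant("nope", 1, "A", "G", {cfg.dataset_ids[0]: 0.2})]
        with pytest.raises(ValueError):
            simulate_pileups(ref, bad, cfg)


class TestStrandedCounts:
    def test_perfect_library_maps_all_reverse_complement(self):
        tbl = simulate_stranded_counts(1, 50, 0.0, seed=2, orientations=["+"])
        assert tuple(tbl.loc[0, ["D", "C"]]) == (0, 50)

    def test_zero_reads_degenerate(self):
        tbl = simulate_stranded_counts(3, 0, 0.1, seed=2)
        assert (tbl[["D", "C"]] == 0).all().all()

    def test_misorientation_rate_recovered(self):
        tbl = simulate_stranded_counts(1, 10000, 0.1, seed=2, orientations=["+"])
        c, d = int(tbl.loc[0, "C"]), int(tbl.loc[0, "D"])
        se = np.sqrt(0.9 * 0.1 / 10000)
        assert abs(c / (c + d) - 0.9) < 3 * se

    def test_rate_domain_enforced(self):
        with pytest.raises(ValueError):
            simulate_stranded_counts(1, 10, 0.5)


class TestGenotypes:
    def test_monomorphic_locus_is_all_reference_homozygote(self):
        calls, _ = simulate_genotypes(1, 200, 0.0, seed=4)
        assert set(calls.ravel()) == {"AA"}

    def test_heterozygosity_recovered_at_maf_half(self):
        calls, _ = simulate_genotypes(1, 10000, 0.5, seed=4)
        het = float((calls == "AB").mean())
        se = np.sqrt(0.5 * 0.5 / 10000)
        assert abs(het - 0.5) < 3 * se

    def test_call_rate_recovered(self):
        calls, _ = simulate_genotypes(1, 10000, 0.3, no_call_rate=0.2, seed=4)
        called = float((calls != "NC").mean())
        se = np.sqrt(0.8 * 0.2 / 10000)
        assert abs(called - 0.8) < 3 * se

    def test_impossible_inbreeding_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(1, 10, 0.5, inbreeding_f=-1.5)
        with pytest.raises(ValueError):
            simulate_genotypes(1, 10, 0.6)


class TestMatchTable:
    def test_no_match_class_yields_no_rows(self):
        matches, expected = simulate_match_table({"C7": 5}, seed=6)
        assert matches.empty
        assert list(expected.values()) == ["C7"] * 5

    def test_one_to_one_class_uses_distinct_subjects(self):
        matches, expected = simulate_match_table({"C1": 3}, seed=6)
        # the best hit per isotig points at a subject no other isotig's
        # countable hits touch
        best = matches.loc[matches.groupby("qseqid")["pident"].idxmax()]
        assert best["sseqid"].nunique() == 3

    def test_partner_classes_require_at_least_two(self):
        with pytest.raises(ValueError):
            simulate_match_table({"C5": 1})
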