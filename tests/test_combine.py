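"""Fisher combination, dataset merging, and IUPAC masking."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from conifersnp import (FlankingMaskSet, build_masked_reference,
                        chi_sq_upper_tail_even_df, code_for_bases,
                        fisher_combine, merge_datasets,
                        select_flanking_variants)
from conifersnp.combine import apply_snp_mask


def chi2_sf_quadrature(x, df):
    """Independent oracle: numerical integration of the chi-square density."""
    k = df / 2.0
    def density(t):
        return t ** (k - 1) * math.exp(-t / 2.0) / (2 ** k * math.gamma(k))
    val, err = quad(density, x, np.inf, epsabs=1e-13, limit=300)
    return val


class TestFisherCombine:
    def test_all_uninformative_pvalues_combine_to_one(self):
        chi_sq, df, pooled = fisher_combine([1.0] * 5)
        assert chi_sq == 0.0
        assert pooled == 1.0

    def test_five_datasets_give_ten_degrees_of_freedom(self):
        _, df, _ = fisher_combine([0.5] * 5)
        assert df == 10

    def test_halves_match_quadrature_oracle(self):
        chi_sq, df, pooled = fisher_combine([0.5] * 5)
        assert chi_sq == pytest.approx(-2 * 5 * math.log(0.5), abs=1e-12)
        assert pooled == pytest.approx(chi2_sf_quadrature(chi_sq, df), abs=1e-10)

    def test_single_pvalue_identity(self):
        for p in (0.9, 0.3, 0.01, 1e-6):
            _, _, pooled = fisher_combine([p])
            assert pooled == pytest.approx(p, abs=1e-12)

    def test_zero_pvalue_clamped_not_fatal(self):
        chi_sq, _, pooled = fisher_combine([0.0, 0.5])
        assert math.isfinite(chi_sq) and 0.0 <= pooled <= 1.0

    def test_pvalue_above_one_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([1.2])

    def test_odd_df_rejected(self):
        with pytest.raises(ValueError):
            chi_sq_upper_tail_even_df(5.0, 3)


class TestMergeDatasets:
    def test_single_dataset_variant_kept_with_its_own_p(self, snp_row_factory,
                                                        snp_table_factory):
        tables = {"ds1": snp_table_factory([snp_row_factory(p_snp=0.07)])}
        combined = merge_datasets(tables)
        assert len(combined) == 1
        row = combined.iloc[0]
        assert row["n_datasets"] == 1
        assert row["pooled_p"] == pytest.approx(0.07, abs=1e-12)

    def test_three_dataset_site_pools_by_fisher(self, snp_row_factory,
                                                snp_table_factory):
        ps = [0.02, 0.3, 0.11]
        tables = {
            f"ds{i + 1}": snp_table_factory(
                [snp_row_factory(dataset_id=f"ds{i + 1}", p_snp=p)])
            for i, p in enumerate(ps)
        }
        combined = merge_datasets(tables)
        row = combined.iloc[0]
        chi_sq = -2 * sum(math.log(p) for p in ps)
        assert row["df"] == 6
        assert row["chi_sq"] == pytest.approx(chi_sq, abs=1e-12)
        assert row["pooled_p"] == pytest.approx(
            chi2_sf_quadrature(chi_sq, 6), abs=1e-10)
        assert row["allele_union"] == "A,G"

    def test_untrusted_indels_dropped_entirely(self, snp_table_factory):
        import pandas as pd
        indels = pd.DataFrame([{
            "isotig": "iso1", "pos": 5, "dataset_id": "sang454",
            "event": "+CT", "count": 4, "depth": 30, "p_indel": 0.01,
        }])
        combined = merge_datasets({}, {"sang454": indels},
                                  indel_untrusted={"sang454"})
        assert combined.empty

    def test_conflicting_reference_bases_rejected(self, snp_row_factory,
                                                  snp_table_factory):
        t1 = snp_table_factory([snp_row_factory(ref="A")])
        t2 = snp_table_factory([snp_row_factory(ref="C", dataset_id="ds2")])
        with pytest.raises(ValueError):
            merge_datasets({"ds1": t1, "ds2": t2})


class TestFlankingSelection:
    def _combined(self, ps, snp_row_factory, snp_table_factory):
        tables = {
            f"ds{i + 1}": snp_table_factory(
                [snp_row_factory(dataset_id=f"ds{i + 1}", p_snp=p)])
            for i, p in enumerate(ps)
        }
        return merge_datasets(tables)

    def test_single_dataset_route(self, snp_row_factory, snp_table_factory):
        combined = self._combined([0.05, 0.9, 0.9, 0.9, 0.9],
                                  snp_row_factory, snp_table_factory)
        mask = select_flanking_variants(combined, p_f=0.10)
        assert mask.n_masked_snps() == 1

    def test_uniform_half_pvalues_excluded(self, snp_row_factory, snp_table_factory):
        combined = self._combined([0.5] * 5, snp_row_factory, snp_table_factory)
        assert combined.iloc[0]["pooled_p"] > 0.10
        mask = select_flanking_variants(combined, p_f=0.10)
        assert mask.n_masked_snps() == 0

    def test_pooled_route_rescues_weak_replication(self, snp_row_factory,
                                                   snp_table_factory):
        # each p_i = 0.2 exceeds P_F alone, but Fisher pooling crosses it
        combined = self._combined([0.2] * 5, snp_row_factory, snp_table_factory)
        row = combined.iloc[0]
        assert row["min_p"] > 0.10
        assert row["chi_sq"] == pytest.approx(16.094, abs=1e-3)
        assert row["pooled_p"] == pytest.approx(
            chi2_sf_quadrature(row["chi_sq"], 10), abs=1e-10)
        assert row["pooled_p"] < 0.10
        mask = select_flanking_variants(combined, p_f=0.10)
        assert mask.n_masked_snps() == 1


class TestMasking:
    def test_two_allele_code(self):
        masked = apply_snp_mask({"iso1": "ACGTACGTAC"}, {"iso1": {10: {"A", "G"}}})
        assert masked["iso1"][9] == "R"
        assert len(masked["iso1"]) == 10

    def test_empty_mask_identity(self):
        ref = {"iso1": "ACGT"}
        mask = FlankingMaskSet()
        combined, per_ds, track = build_masked_reference(ref, mask)
        assert combined == ref and track == []

    def test_union_of_dataset_allele_sets(self):
        mask = FlankingMaskSet()
        mask.add_snp("iso1", 3, {"A", "C"})
        mask.add_snp("iso1", 3, {"A", "G"})
        combined, _, _ = build_masked_reference({"iso1": "TTATT"}, mask)
        assert combined["iso1"][2] == code_for_bases({"A", "C", "G"})
        assert combined["iso1"][2] == "V"

    def test_masking_conservation_and_roundtrip(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        positions = {int(p) + 1: {"A", "G"} for p in
                     rng.choice(200, size=17, replace=False)}
        masked = apply_snp_mask({"iso1": seq}, {"iso1": positions})["iso1"]
        non_acgt = sum(1 for ch in masked if ch not in "ACGT")
        assert non_acgt == len(positions)
        # replace codes by a member allele, re-mask: reproduces the masked seq
        unmasked = "".join(
            "A" if ch not in "ACGT" else ch for ch in masked)
        remasked = apply_snp_mask({"iso1": unmasked}, {"iso1": positions})["iso1"]
        assert remasked == masked

    def test_off_reference_mask_position_rejected(self):
        with pytest.raises(ValueError):
            apply_snp_mask({"iso1": "ACGT"}, {"iso1": {9: {"A", "G"}}})
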