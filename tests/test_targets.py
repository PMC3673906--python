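"""Target-SNP cascade and array candidate selection."""

import pandas as pd
import pytest

from conifersnp import (SelectionConfig, extrapolate_resource, extract_flanks,
                        filter_target_snps, marker_density,
                        select_array_candidates)
from conifersnp.combine import COMBINED_COLUMNS


def combined_row(isotig="t1", pos=100, alleles=("A", "G"), min_p=5e-5,
                 mean_p=None, n_datasets=3, mean_reads=40.0, mean_freq=0.2,
                 max_mapq=60.0):
    union = sorted(set(alleles))
    return {
        "isotig": isotig, "pos": pos, "ref": union[0], "variant_type": "SNP",
        "allele_union": ",".join(union), "alt_alleles": ",".join(union[1:]),
        "n_datasets": n_datasets, "chi_sq": 10.0, "df": 2 * n_datasets,
        "pooled_p": min_p, "min_p": min_p,
        "mean_p": mean_p if mean_p is not None else min_p,
        "mean_reads": mean_reads, "mean_freq": mean_freq,
        "max_mapq": max_mapq, "per_dataset_p": "",
    }


def combined_table(rows):
    return pd.DataFrame(rows, columns=COMBINED_COLUMNS)


ISOGROUPS = pd.DataFrame({
    "isotig": ["t1", "t2", "t3"],
    "isogroup": ["g1", "g1", "g2"],
    "length": [1000, 500, 800],
})


class TestFilterTargets:
    def test_hand_enumerated_fixture(self):
        rows = [
            combined_row(pos=100),                              # keep
            combined_row(isotig="t2", pos=50),                  # not longest
            combined_row(pos=200, alleles=("A", "C", "G")),     # tri-allelic
            combined_row(pos=300),                              # near indel @305
            combined_row(pos=400, max_mapq=35.0),               # low mapq
            combined_row(pos=500, min_p=5e-3),                  # above P_S
            combined_row(pos=600),                              # keep
            combined_row(isotig="t3", pos=10),                  # keep
            combined_row(isotig="t3", pos=20, alleles=("C", "T")),  # keep
            combined_row(isotig="t2", pos=60, min_p=1e-9),      # not longest
            combined_row(pos=700, max_mapq=40.0),               # mapq not > 40
            combined_row(pos=800, min_p=1e-4),                  # not < threshold
        ]
        targets, ledger = filter_target_snps(
            combined_table(rows), ISOGROUPS,
            indel_positions={"t1": [305]},
            config=SelectionConfig(ps_threshold=1e-4))
        kept = set(zip(targets["isotig"], targets["pos"]))
        assert kept == {("t1", 100), ("t1", 600), ("t3", 10), ("t3", 20)}
        assert len(ledger) + len(targets) == 12
        reasons = dict(zip(zip(ledger["isotig"], ledger["pos"]), ledger["reason"]))
        assert reasons[("t2", 50)] == "NOT_LONGEST_ISOTIG"
        assert reasons[("t1", 200)] == "NOT_BIALLELIC"
        assert reasons[("t1", 300)] == "NEAR_INDEL"
        assert reasons[("t1", 400)] == "LOW_MAPQ"
        assert reasons[("t1", 500)] == "ABOVE_PS"

    def test_missing_isogroup_mapping_rejected(self):
        with pytest.raises(ValueError):
            filter_target_snps(combined_table([combined_row(isotig="zzz")]),
                               ISOGROUPS)

    def test_superset_across_thresholds(self):
        rows = [combined_row(pos=p, min_p=mp) for p, mp in
                zip(range(10, 200, 10), [10 ** -(1 + i % 5) for i in range(19)])]
        tbl = combined_table(rows)
        kept = {}
        for ps in (1e-4, 1e-3, 1e-2):
            targets, _ = filter_target_snps(
                tbl, ISOGROUPS, config=SelectionConfig(ps_threshold=ps))
            kept[ps] = set(zip(targets["isotig"], targets["pos"]))
        assert kept[1e-4] <= kept[1e-3] <= kept[1e-2]

    def test_assay_type_assignment(self):
        rows = [combined_row(pos=100, alleles=("A", "T")),
                combined_row(pos=200, alleles=("C", "G")),
                combined_row(pos=300, alleles=("A", "G"))]
        targets, _ = filter_target_snps(combined_table(rows), ISOGROUPS)
        types = dict(zip(targets["pos"], targets["assay_type"]))
        assert types == {100: "InfiniumI", 200: "InfiniumI", 300: "InfiniumII"}


def target_row(isotig="t1", pos=100, allele_pair="A/G", mean_p=1e-5,
               n_datasets=3, mean_reads=40.0, mean_freq=0.2,
               confidence_class="C1"):
    from conifersnp.targets import assay_type
    return {
        "isotig": isotig, "isogroup": f"g_{isotig}", "pos": pos,
        "ref": allele_pair[0], "allele_pair": allele_pair, "iupac": "R",
        "min_p": mean_p, "mean_p": mean_p, "n_datasets": n_datasets,
        "mean_reads": mean_reads, "mean_freq": mean_freq, "max_mapq": 60.0,
        "near_indel": False, "confidence_class": confidence_class,
        "assay_type": assay_type(allele_pair.split("/")),
    }


class TestArraySelection:
    def test_two_probe_chemistry_dropped_for_nonpriority(self):
        targets = pd.DataFrame([target_row(allele_pair="A/T")])
        sel, ledger = select_array_candidates(
            targets, design_scores={("t1", 100): 0.9})
        assert sel.empty
        assert ledger.iloc[0]["reason"] == "TWO_PROBE_ASSAY"

    def test_two_probe_chemistry_kept_for_priority(self):
        targets = pd.DataFrame([target_row(allele_pair="A/T")])
        sel, _ = select_array_candidates(targets, priority_isotigs={"t1"})
        assert len(sel) == 1 and bool(sel.iloc[0]["de_priority"])

    def test_priority_spacing_never_picks_close_pair(self):
        rows = [target_row(pos=100, mean_p=1e-6),
                target_row(pos=130, mean_p=2e-6),
                target_row(pos=200, mean_p=3e-6)]
        sel, ledger = select_array_candidates(
            pd.DataFrame(rows), priority_isotigs={"t1"})
        picked = sorted(sel["pos"])
        assert picked == [100, 200]  # 100/130 violates 50-nt spacing
        assert len(sel) + len(ledger) == 3

    def test_low_confidence_classes_dropped_first(self):
        rows = [target_row(pos=100, confidence_class="C5"),
                target_row(pos=200, confidence_class="C6"),
                target_row(pos=300, confidence_class="C1")]
        sel, ledger = select_array_candidates(
            pd.DataFrame(rows), design_scores={("t1", 300): 0.9})
        assert list(sel["pos"]) == [300]
        assert set(ledger["reason"]) >= {"LOW_CONFIDENCE_CLASS"}

    def test_nonpriority_requires_replication_and_best_per_isotig(self):
        rows = [target_row(pos=100, mean_p=1e-6, n_datasets=1),
                target_row(pos=200, mean_p=1e-5),
                target_row(pos=300, mean_p=1e-7)]
        scores = {("t1", 200): 0.9, ("t1", 300): 0.9}
        sel, ledger = select_array_candidates(pd.DataFrame(rows),
                                              design_scores=scores)
        assert list(sel["pos"]) == [300]  # lowest mean_p among replicated
        reasons = dict(zip(ledger["pos"], ledger["reason"]))
        assert reasons[100] == "TOO_FEW_DATASETS"
        assert reasons[200] == "NOT_MOST_PROBABLE_IN_ISOTIG"

    @pytest.mark.parametrize("field,value,reason", [
        ("design", 0.5, "LOW_DESIGN_SCORE"),
        ("reads", 5.0, "LOW_READ_SUPPORT"),
        ("freq", 0.01, "LOW_FREQUENCY"),
    ])
    def test_final_assay_filters(self, field, value, reason):
        row = target_row()
        score = 0.9
        if field == "design":
            score = value
        elif field == "reads":
            row["mean_reads"] = value
        else:
            row["mean_freq"] = value
        sel, ledger = select_array_candidates(
            pd.DataFrame([row]), design_scores={("t1", 100): score})
        assert sel.empty and ledger.iloc[0]["reason"] == reason

    def test_missing_design_score_fails_nonpriority(self):
        sel, ledger = select_array_candidates(pd.DataFrame([target_row()]))
        assert sel.empty and ledger.iloc[0]["reason"] == "LOW_DESIGN_SCORE"

    def test_order_invariance(self):
        rows = [target_row(isotig=f"t{i}", pos=100 + i, mean_p=10 ** -(3 + i % 4))
                for i in range(8)]
        scores = {(r["isotig"], r["pos"]): 0.9 for r in rows}
        fwd, _ = select_array_candidates(pd.DataFrame(rows), design_scores=scores)
        rev, _ = select_array_candidates(pd.DataFrame(rows[::-1]),
                                         design_scores=scores)
        pd.testing.assert_frame_equal(fwd, rev)


class TestResourceArithmetic:
    def test_extrapolation_rounds_to_nearest(self):
        assert extrapolate_resource(278979, 0.725) == 202260
        assert extrapolate_resource(150025, 0.725) == 108768
        assert extrapolate_resource(12345, 0.0) == 0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_resource(-1, 0.5)

    def test_marker_density(self):
        assert marker_density(5000, 2000) == pytest.approx(2.5)

    def test_flank_extraction_brackets_target(self):
        masked = {"iso1": "AAAARAAAAA"}
        s = extract_flanks(masked, "iso1", 7, "A/G", flank=3)
        assert s == "ARA[A/G]AAA"
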