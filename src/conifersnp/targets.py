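"""Target-SNP filtering and genotyping-array candidate selection.

From the combined variant table, target SNPs are the bi-allelic, well-mapped,
indel-free variants confident at a stated probability threshold P_S, taken
only from the longest isotig of each gene model (isogroup) to avoid redundant
markers. A second cascade then picks array candidates: priority SNPs (in
differentially expressed or annotation-selected genes) are kept up to two per
isotig with a minimum spacing, while the rest must replicate across pools and
survive assay-design constraints (single-probe chemistry, design score,
coverage, frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .iupac import code_for_bases


@dataclass
class SelectionConfig:
    """Thresholds of the target and array cascades (defaults as published)."""

    ps_threshold: float = 1e-4
    min_mapq: float = 40.0
    min_snp_spacing: int = 50
    max_snps_per_isotig_priority: int = 2
    min_datasets_nonpriority: int = 2
    min_design_score: float = 0.60
    min_mean_reads: float = 10.0
    min_mean_freq: float = 0.05
    excluded_classes: frozenset = frozenset({"C5", "C6"})
    indel_adjacency_window: int = 10

    def __post_init__(self):
        if self.ps_threshold <= 0:
            raise ValueError("ps_threshold must be positive")
        if self.min_snp_spacing < 1:
            raise ValueError("min_snp_spacing must be >= 1")


TARGET_COLUMNS = [
    "isotig", "isogroup", "pos", "ref", "allele_pair", "iupac",
    "min_p", "mean_p", "n_datasets", "mean_reads", "mean_freq", "max_mapq",
    "near_indel", "confidence_class", "assay_type",
]


def assay_type(allele_pair) -> str:
    """Infinium chemistry for an allele pair: A/T and C/G need two probes."""
    pair = frozenset(allele_pair)
    return "InfiniumI" if pair in (frozenset("AT"), frozenset("CG")) else "InfiniumII"


def filter_target_snps(combined: pd.DataFrame, isogroup_map: pd.DataFrame,
                       confidence: dict | None = None,
                       indel_positions: dict | None = None,
                       config: SelectionConfig | None = None):
    """First cascade: combined variants -> target-SNP table.

    Retains SNPs that (a) lie on the longest isotig of their isogroup,
    (b) are bi-allelic, (c) are not within ``indel_adjacency_window`` nt of a
    masked indel, (d) reached mapping quality > ``min_mapq`` in some dataset,
    and (e) have min per-dataset probability < ``ps_threshold``. Returns
    ``(targets, ledger)``; the ledger records the first failed rule per
    rejected row, so |input SNP rows| = |targets| + |ledger|.
    """
    config = config or SelectionConfig()
    confidence = confidence or {}
    indel_positions = indel_positions or {}

    info = isogroup_map.set_index("isotig")
    longest = set(
        isogroup_map.sort_values(["length", "isotig"], ascending=[False, True])
        .drop_duplicates("isogroup")["isotig"]
    )

    snps = combined[combined["variant_type"] == "SNP"]
    kept, rejected = [], []
    for row in snps.sort_values(["isotig", "pos"]).to_dict("records"):
        isotig = row["isotig"]
        if isotig not in info.index:
            raise ValueError(f"isotig {isotig} absent from isogroup map")
        alleles = sorted(row["allele_union"].split(","))
        near = any(
            abs(int(row["pos"]) - ip) <= config.indel_adjacency_window
            for ip in indel_positions.get(isotig, [])
        )
        reason = None
        if isotig not in longest:
            reason = "NOT_LONGEST_ISOTIG"
        elif len(alleles) != 2:
            reason = "NOT_BIALLELIC"
        elif near:
            reason = "NEAR_INDEL"
        elif not row["max_mapq"] > config.min_mapq:
            reason = "LOW_MAPQ"
        elif not row["min_p"] < config.ps_threshold:
            reason = "ABOVE_PS"
        if reason is not None:
            rejected.append({"isotig": isotig, "pos": row["pos"], "reason": reason})
            continue
        kept.append({
            "isotig": isotig,
            "isogroup": info.loc[isotig, "isogroup"],
            "pos": int(row["pos"]),
            "ref": row["ref"],
            "allele_pair": "/".join(alleles),
            "iupac": code_for_bases(alleles),
            "min_p": row["min_p"],
            "mean_p": row["mean_p"],
            "n_datasets": int(row["n_datasets"]),
            "mean_reads": row["mean_reads"],
            "mean_freq": row["mean_freq"],
            "max_mapq": row["max_mapq"],
            "near_indel": near,
            "confidence_class": confidence.get(isotig, "C7"),
            "assay_type": assay_type(alleles),
        })
    return (pd.DataFrame(kept, columns=TARGET_COLUMNS),
            pd.DataFrame(rejected, columns=["isotig", "pos", "reason"]))


def _pick_spaced(rows, max_n: int, spacing: int):
    """Greedy pick by ascending mean_p honoring pairwise spacing."""
    chosen = []
    for row in rows:
        if len(chosen) >= max_n:
            break
        if all(abs(row["pos"] - c["pos"]) >= spacing for c in chosen):
            chosen.append(row)
    return chosen


def select_array_candidates(targets: pd.DataFrame, priority_isotigs=frozenset(),
                            design_scores: dict | None = None,
                            config: SelectionConfig | None = None):
    """Second cascade: target SNPs -> array candidates + rejection ledger.

    Order of operations: (1) drop low-confidence classes; (2) priority SNPs
    (differentially expressed / annotation-selected isotigs): up to two per
    isotig, pairwise spacing >= ``min_snp_spacing``, best (lowest mean_p)
    first; (3) non-priority SNPs must replicate in >= 2 datasets, then the
    single most probable SNP per isotig is retained; (4) assay-design filters
    (two-probe chemistry, design score, read support, frequency) apply to
    non-priority rows only. Deterministic under input row permutation: ties
    break by position then allele order.
    """
    config = config or SelectionConfig()
    design_scores = design_scores or {}
    priority_isotigs = set(priority_isotigs)

    rows = targets.sort_values(
        ["mean_p", "isotig", "pos", "allele_pair"], kind="mergesort"
    ).to_dict("records")

    selected, ledger = [], []

    def reject(row, reason):
        ledger.append({"isotig": row["isotig"], "pos": row["pos"], "reason": reason})

    survivors = []
    for row in rows:
        if row["confidence_class"] in config.excluded_classes:
            reject(row, "LOW_CONFIDENCE_CLASS")
        else:
            survivors.append(row)

    prio = [r for r in survivors if r["isotig"] in priority_isotigs]
    nonprio = [r for r in survivors if r["isotig"] not in priority_isotigs]

    by_isotig: dict = {}
    for r in prio:
        by_isotig.setdefault(r["isotig"], []).append(r)
    for isotig, group in sorted(by_isotig.items()):
        chosen = _pick_spaced(group, config.max_snps_per_isotig_priority,
                              config.min_snp_spacing)
        chosen_keys = {(c["isotig"], c["pos"]) for c in chosen}
        for r in group:
            if (r["isotig"], r["pos"]) in chosen_keys:
                selected.append({**r, "de_priority": True,
                                 "design_score": design_scores.get((r["isotig"], r["pos"]))})
            else:
                reject(r, "PRIORITY_SPACING_OR_CAP")

    by_isotig = {}
    for r in nonprio:
        if r["n_datasets"] < config.min_datasets_nonpriority:
            reject(r, "TOO_FEW_DATASETS")
            continue
        by_isotig.setdefault(r["isotig"], []).append(r)
    for isotig, group in sorted(by_isotig.items()):
        best, rest = group[0], group[1:]
        for r in rest:
            reject(r, "NOT_MOST_PROBABLE_IN_ISOTIG")
        score = design_scores.get((best["isotig"], best["pos"]))
        if best["assay_type"] == "InfiniumI":
            reject(best, "TWO_PROBE_ASSAY")
        elif score is None or score < config.min_design_score:
            reject(best, "LOW_DESIGN_SCORE")
        elif best["mean_reads"] < config.min_mean_reads:
            reject(best, "LOW_READ_SUPPORT")
        elif best["mean_freq"] < config.min_mean_freq:
            reject(best, "LOW_FREQUENCY")
        else:
            selected.append({**best, "de_priority": False, "design_score": score})

    sel_cols = TARGET_COLUMNS + ["de_priority", "design_score"]
    sel = pd.DataFrame(selected, columns=sel_cols)
    if not sel.empty:
        sel = sel.sort_values(["isotig", "pos"]).reset_index(drop=True)
    led = pd.DataFrame(ledger, columns=["isotig", "pos", "reason"])
    if not led.empty:
        led = led.sort_values(["isotig", "pos"]).reset_index(drop=True)
    return sel, led


def extrapolate_resource(n_candidates: int, conversion_rate: float) -> int:
    """Estimated count of true (or genotypable) SNPs: round(n * rate)."""
    if n_candidates < 0 or conversion_rate < 0:
        raise ValueError("inputs must be non-negative")
    if conversion_rate > 1:
        raise ValueError("conversion_rate must be in [0,1]")
    import math
    return int(math.floor(n_candidates * conversion_rate + 0.5))


def marker_density(n_markers: float, genome_length_cm: float) -> float:
    """Markers per centiMorgan — the sufficiency yardstick for genomic selection."""
    if genome_length_cm <= 0:
        raise ValueError("genome length must be positive")
    return n_markers / genome_length_cm


def extract_flanks(masked_reference: dict, isotig: str, pos: int,
                   allele_pair: str, flank: int = 60) -> str:
    """Assay-submission string: IUPAC-masked flanks around [X/Y] at the target."""
    seq = masked_reference[isotig]
    left = seq[max(0, pos - 1 - flank): pos - 1]
    right = seq[pos: pos + flank]
    a, b = allele_pair.split("/")
    return f"{left}[{a}/{b}]{right}"
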