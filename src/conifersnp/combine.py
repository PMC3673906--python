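"""Across-dataset merging, Fisher-combined probabilities, and IUPAC masking.

Independent pools give independent per-site variant probabilities p_i.
Fisher's combined probability method pools them: X^2 = -2 * sum(ln p_i) is
chi-square distributed with 2k degrees of freedom under the joint null, so a
variant weakly supported in several pools can still reach significance. A
permissive flanking threshold P_F then selects every variant that could
disrupt assay-probe hybridization, and those positions are rewritten in the
reference as IUPAC ambiguity codes (SNPs) or interval-track entries (indels,
which have no IUPAC symbol).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import code_for_bases

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # underflow guard for ln(p); preserves ordering

COMBINED_COLUMNS = [
    "isotig", "pos", "ref", "variant_type", "allele_union", "alt_alleles",
    "n_datasets", "chi_sq", "df", "pooled_p", "min_p", "mean_p",
    "mean_reads", "mean_freq", "max_mapq", "per_dataset_p",
]


def chi_sq_upper_tail_even_df(chi_sq: float, df: int) -> float:
    """Chi-square upper-tail probability via the even-df closed form.

    For df = 2k the survival function is exp(-x/2) * sum_{i<k} (x/2)^i / i!.
    Accumulated with a running term to stay accurate for large x.
    """
    if df <= 0 or df % 2 != 0:
        raise ValueError("df must be a positive even integer")
    if chi_sq < 0:
        raise ValueError("chi_sq must be >= 0")
    k = df // 2
    half = chi_sq / 2.0
    term = 1.0
    total = 1.0
    for i in range(1, k):
        term *= half / i
        total += term
    return min(1.0, math.exp(-half) * total)


def fisher_combine(p_values, n_datasets: int | None = None):
    """Fisher's method: returns ``(chi_sq, df, pooled_p)``.

    ``df = 2 * n_datasets`` with ``n_datasets`` defaulting to the number of
    supplied p-values (datasets with no coverage at a site contribute nothing
    and do not inflate df). Zero p-values are clamped at a logged floor.
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("need at least one p-value")
    if n_datasets is None:
        n_datasets = len(p_values)
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    clean = []
    for p in p_values:
        if p > 1.0:
            raise ValueError(f"p-value above 1: {p}")
        if p <= 0.0:
            logger.warning("p-value %g clamped to floor %g", p, P_FLOOR)
            p = P_FLOOR
        clean.append(p)
    chi_sq = -2.0 * sum(math.log(p) for p in clean)
    df = 2 * n_datasets
    return chi_sq, df, chi_sq_upper_tail_even_df(chi_sq, df)


@dataclass
class FlankingMaskSet:
    """Positions to be hidden from assay design, per isotig.

    ``snps`` maps isotig -> {position -> set of alleles (ref + alts)};
    ``indels`` maps isotig -> sorted list of masked indel positions.
    """

    p_f: float = 0.10
    snps: dict = field(default_factory=dict)
    indels: dict = field(default_factory=dict)

    def add_snp(self, isotig: str, pos: int, alleles):
        self.snps.setdefault(isotig, {}).setdefault(pos, set()).update(alleles)

    def add_indel(self, isotig: str, pos: int):
        lst = self.indels.setdefault(isotig, [])
        if pos not in lst:
            lst.append(pos)
            lst.sort()

    def n_masked_snps(self) -> int:
        return sum(len(d) for d in self.snps.values())

    def n_masked_indels(self) -> int:
        return sum(len(v) for v in self.indels.values())


def merge_datasets(snp_tables: dict, indel_tables: dict | None = None,
                   indel_untrusted=frozenset()) -> pd.DataFrame:
    """Merge per-dataset call tables into one combined-variant table.

    ``snp_tables``/``indel_tables`` map dataset id -> the caller's output
    DataFrames. One output row per (isotig, position, type); datasets without
    a retained call at the position are simply absent from that row's
    per-dataset map. Indels from untrusted datasets are dropped before
    merging. Raises on conflicting reference bases across datasets.
    """
    indel_tables = indel_tables or {}
    sites: dict = {}

    for ds, table in snp_tables.items():
        for row in table.to_dict("records"):
            key = (row["isotig"], int(row["pos"]), "SNP")
            rec = sites.setdefault(key, {"ref": row["ref"], "per_dataset": {}})
            if rec["ref"] != row["ref"]:
                raise ValueError(
                    f"conflicting reference base at {key[0]}:{key[1]}: "
                    f"{rec['ref']} vs {row['ref']} (dataset {ds})"
                )
            rec["per_dataset"][ds] = row

    for ds, table in indel_tables.items():
        if ds in indel_untrusted:
            continue
        for row in table.to_dict("records"):
            key = (row["isotig"], int(row["pos"]), "indel")
            rec = sites.setdefault(key, {"ref": None, "per_dataset": {}})
            rec["per_dataset"][ds] = row

    rows = []
    for (isotig, pos, vtype), rec in sorted(sites.items()):
        per = rec["per_dataset"]
        if vtype == "SNP":
            pvals = {ds: r["p_snp"] for ds, r in per.items()}
            alts = sorted({r["alt"] for r in per.values()})
            union = sorted(set(alts) | {rec["ref"]})
            mean_reads = float(np.mean([r["depth"] for r in per.values()]))
            mean_freq = float(np.mean([r["freq"] for r in per.values()]))
            max_mapq = float(max(r["mapq"] for r in per.values()))
        else:
            pvals = {ds: r["p_indel"] for ds, r in per.items()}
            alts = sorted({r["event"] for r in per.values()})
            union = alts
            mean_reads = float(np.mean([r["depth"] for r in per.values()]))
            mean_freq = float(np.mean([r["count"] / r["depth"] for r in per.values()]))
            max_mapq = float("nan")
        chi_sq, df, pooled_p = fisher_combine(list(pvals.values()))
        rows.append({
            "isotig": isotig,
            "pos": pos,
            "ref": rec["ref"],
            "variant_type": vtype,
            "allele_union": ",".join(union),
            "alt_alleles": ",".join(alts),
            "n_datasets": len(per),
            "chi_sq": chi_sq,
            "df": df,
            "pooled_p": pooled_p,
            "min_p": min(pvals.values()),
            "mean_p": float(np.mean(list(pvals.values()))),
            "mean_reads": mean_reads,
            "mean_freq": mean_freq,
            "max_mapq": max_mapq,
            "per_dataset_p": ";".join(f"{ds}:{p:.6g}" for ds, p in sorted(pvals.items())),
        })
    return pd.DataFrame(rows, columns=COMBINED_COLUMNS)


def select_flanking_variants(combined: pd.DataFrame, p_f: float = 0.10) -> FlankingMaskSet:
    """Retain variants meeting the flanking threshold in any single dataset
    or pooled across datasets; everything retained is masked downstream."""
    mask = FlankingMaskSet(p_f=p_f)
    if combined.empty:
        return mask
    keep = (combined["min_p"] < p_f) | (combined["pooled_p"] < p_f)
    for row in combined[keep].to_dict("records"):
        if row["variant_type"] == "SNP":
            alleles = set(row["allele_union"].split(","))
            mask.add_snp(row["isotig"], int(row["pos"]), alleles)
        else:
            mask.add_indel(row["isotig"], int(row["pos"]))
    return mask


def apply_snp_mask(reference: dict, snp_mask: dict) -> dict:
    """Rewrite masked SNP positions as IUPAC codes; everything else unchanged.

    ``snp_mask`` maps isotig -> {pos -> allele set}. Sequence lengths are
    preserved. An allele set of {N} masks to N with a warning.
    """
    out = {}
    for isotig, seq in reference.items():
        positions = snp_mask.get(isotig, {})
        if not positions:
            out[isotig] = seq
            continue
        chars = list(seq)
        for pos, alleles in positions.items():
            if not 1 <= pos <= len(chars):
                raise ValueError(f"mask position {pos} off reference {isotig}")
            if set(a.upper() for a in alleles) == {"N"}:
                logger.warning("allele set at %s:%d is {N}; masking as N", isotig, pos)
            chars[pos - 1] = code_for_bases(alleles)
        out[isotig] = "".join(chars)
    return out


def build_masked_reference(reference: dict, mask: FlankingMaskSet,
                           per_dataset_alleles: dict | None = None):
    """Build the combined masked reference, and per-dataset ones if given.

    The combined sequence masks each SNP position with the union of allele
    sets across datasets. ``per_dataset_alleles`` optionally maps dataset ->
    {isotig -> {pos -> allele set}} to also emit a masked reference per
    dataset. Returns ``(combined_seqs, per_dataset_seqs, indel_track)`` where
    ``indel_track`` is a list of 0-based half-open BED intervals.
    """
    combined_seqs = apply_snp_mask(reference, mask.snps)
    per_dataset_seqs = {}
    if per_dataset_alleles:
        for ds, ds_mask in per_dataset_alleles.items():
            per_dataset_seqs[ds] = apply_snp_mask(reference, ds_mask)
    indel_track = [
        (isotig, pos - 1, pos, "indel")
        for isotig, positions in sorted(mask.indels.items())
        for pos in positions
    ]
    return combined_seqs, per_dataset_seqs, indel_track


def per_dataset_allele_sets(snp_tables: dict, p_f: float = 0.10) -> dict:
    """Allele sets {ref, alt} per dataset for positions that dataset retains
    at the flanking threshold — input for per-dataset masked references."""
    out: dict = {}
    for ds, table in snp_tables.items():
        ds_mask: dict = {}
        for row in table.to_dict("records"):
            if row["p_snp"] < p_f:
                ds_mask.setdefault(row["isotig"], {}).setdefault(
                    int(row["pos"]), set()
                ).update({row["ref"], row["alt"]})
        out[ds] = ds_mask
    return out
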