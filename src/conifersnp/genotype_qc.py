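"""Genotyping-array locus QC: call rates, MAF, heterozygosity, HWE.

A locus "converts" into a usable marker when it is reliably called in most
samples and actually polymorphic. Per locus this module computes the call
frequency, genotype counts, minor-allele frequency, observed (n_AB/n) and
expected (2pq) heterozygosities, and an exact Hardy-Weinberg test. Departures
from HWE at a Bonferroni-corrected threshold flag genotyping artifacts,
paralog collapse, or population structure.

The HWE test is the exact conditional test: given the observed allele
counts, the probability of each attainable heterozygote count (same parity
as the observed rare-allele count) follows a closed recurrence, and the
p-value sums the probabilities of all configurations no more probable than
the observed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("AA", "AB", "BB")
NO_CALL = "NC"


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def apply_call_threshold(calls: np.ndarray, qualities: np.ndarray,
                         threshold: float = 0.15) -> np.ndarray:
    """Replace calls whose per-call quality score falls below ``threshold``
    (GenCall-style, in [0,1]) with no-calls; everything else unchanged."""
    calls = np.asarray(calls)
    qualities = np.asarray(qualities, dtype=float)
    if calls.shape != qualities.shape:
        raise ValueError("calls and qualities must have the same shape")
    return np.where(qualities < threshold, NO_CALL, calls)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test probability for one bi-allelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one (the cumulative, not mid-p, form). Monomorphic loci have a
    single attainable configuration and return 1.0.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one called genotype")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # attainable heterozygote counts share the parity of the rare-allele count
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (c-h+2)/2 * 4)
    h = mid
    val = 1.0
    while h >= 2:
        hom_r = (n_rare - h) // 2
        hom_c = (2 * n - n_rare - h) // 2
        val *= h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        probs[h] = val
    h = mid
    val = 1.0
    while h + 2 <= n_rare and (2 * n - n_rare - h) >= 2:
        hom_r = (n_rare - h) // 2
        hom_c = (2 * n - n_rare - h) // 2
        val *= 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
        probs[h] = val
    total = sum(probs.values())
    obs = probs[n_ab if n_ab in probs else min(probs, key=lambda k: abs(k - n_ab))]
    if n_ab not in probs:
        raise ValueError(
            f"heterozygote count {n_ab} unattainable for allele counts "
            f"({n_rare}, {2 * n - n_rare})"
        )
    p = sum(v for v in probs.values() if v <= obs * (1.0 + 1e-12)) / total
    return min(1.0, p)


@dataclass
class LocusQC:
    """Per-locus summary of a genotyping-array locus report row."""

    locus_id: str
    n_samples: int
    n_called: int
    call_frequency: float
    n_aa: int
    n_ab: int
    n_bb: int
    maf: float | None
    ho: float | None
    he: float | None
    hwe_p: float | None
    pass_call_rate: bool
    polymorphic: bool
    successful: bool


def locus_qc(calls, locus_id: str = "", min_call_rate: float = 0.85) -> LocusQC:
    """QC metrics for one locus from its per-sample calls.

    ``calls`` is an iterable over {AA, AB, BB, NC}. The minor allele is the
    rarer of the two among called genotypes; he = 2p(1-p) (plain, not
    sample-size corrected). A locus is successful when it passes the call-rate
    threshold *and* is polymorphic. With zero called samples, frequency-based
    metrics are None.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one sample")
    n_samples = len(calls)
    n_aa = sum(1 for c in calls if c == "AA")
    n_ab = sum(1 for c in calls if c == "AB")
    n_bb = sum(1 for c in calls if c == "BB")
    n_called = n_aa + n_ab + n_bb
    call_frequency = n_called / n_samples
    if n_called == 0:
        return LocusQC(locus_id, n_samples, 0, 0.0, 0, 0, 0,
                       None, None, None, None, False, False, False)
    q = (2 * n_bb + n_ab) / (2 * n_called)
    maf = min(q, 1.0 - q)
    ho = n_ab / n_called
    he = 2.0 * maf * (1.0 - maf)
    hwe_p = hwe_exact_test(n_aa, n_ab, n_bb)
    pass_call_rate = call_frequency >= min_call_rate
    polymorphic = maf > 0.0
    return LocusQC(
        locus_id=locus_id, n_samples=n_samples, n_called=n_called,
        call_frequency=call_frequency, n_aa=n_aa, n_ab=n_ab, n_bb=n_bb,
        maf=maf, ho=ho, he=he, hwe_p=hwe_p,
        pass_call_rate=pass_call_rate, polymorphic=polymorphic,
        successful=pass_call_rate and polymorphic,
    )


def qc_matrix(calls: np.ndarray, locus_ids=None,
              min_call_rate: float = 0.85) -> pd.DataFrame:
    """Run :func:`locus_qc` over a loci-by-samples call matrix."""
    calls = np.asarray(calls)
    n_loci = calls.shape[0]
    if locus_ids is None:
        locus_ids = [f"locus{i + 1:05d}" for i in range(n_loci)]
    rows = []
    for i in range(n_loci):
        qc = locus_qc(calls[i], locus_id=locus_ids[i], min_call_rate=min_call_rate)
        rows.append(vars(qc))
    return pd.DataFrame(rows)


@dataclass
class QCSummary:
    """Array-level accounting in the style of a SNP-validation summary table."""

    n_attempted: int
    n_assayed: int
    n_called: int
    n_successful: int
    n_hwe_deviant: int | None
    family_alpha: float
    bonferroni_alpha: float | None
    percentages: dict

    @property
    def conversion_rate_attempted(self) -> float:
        return self.percentages["successful_of_attempted"]

    @property
    def conversion_rate_assayed(self) -> float:
        return self.percentages["successful_of_assayed"]


def summarize_counts(n_attempted: int, n_assayed: int, n_called: int,
                     n_successful: int, n_hwe_deviant: int | None = None,
                     family_alpha: float = 0.05) -> QCSummary:
    """Build the summary percentage grid from array-stage counts.

    Counts must be nested (successful <= called <= assayed <= attempted).
    The per-test Bonferroni threshold is family_alpha / n_successful.
    """
    if not (0 <= n_successful <= n_called <= n_assayed <= n_attempted):
        raise ValueError("counts must satisfy successful<=called<=assayed<=attempted")
    if n_attempted == 0:
        logger.warning("empty array: no percentages computable")
        return QCSummary(0, 0, 0, 0, n_hwe_deviant, family_alpha, None, {})
    bonferroni = family_alpha / n_successful if n_successful > 0 else None
    if bonferroni is None:
        logger.warning("no successful loci: Bonferroni threshold undefined")
    pct = {
        "assayed_of_attempted": percent(n_assayed, n_attempted),
        "called_of_attempted": percent(n_called, n_attempted),
        "called_of_assayed": percent(n_called, n_assayed),
        "successful_of_attempted": percent(n_successful, n_attempted),
        "successful_of_assayed": percent(n_successful, n_assayed),
        "successful_of_called": percent(n_successful, n_called) if n_called else None,
    }
    if n_hwe_deviant is not None and n_successful:
        pct["hwe_deviant_of_successful"] = percent(n_hwe_deviant, n_successful)
    return QCSummary(
        n_attempted=n_attempted, n_assayed=n_assayed, n_called=n_called,
        n_successful=n_successful, n_hwe_deviant=n_hwe_deviant,
        family_alpha=family_alpha, bonferroni_alpha=bonferroni,
        percentages=pct,
    )


def summarize_array(per_locus: pd.DataFrame, n_attempted: int, n_assayed: int,
                    family_alpha: float = 0.05) -> QCSummary:
    """Summarize a per-locus QC table (one row per assayed locus).

    HWE deviants are counted over successful loci at the Bonferroni threshold
    computed from the number of successful loci.
    """
    n_called = int(per_locus["pass_call_rate"].sum())
    succ = per_locus[per_locus["successful"]]
    n_successful = len(succ)
    bonferroni = family_alpha / n_successful if n_successful else None
    n_dev = (int((succ["hwe_p"] < bonferroni).sum())
             if bonferroni is not None else None)
    return summarize_counts(n_attempted, n_assayed, n_called, n_successful,
                            n_hwe_deviant=n_dev, family_alpha=family_alpha)


def histogram_table(values, bin_edges) -> pd.DataFrame:
    """Binned counts for MAF / heterozygosity distribution figures."""
    values = np.asarray([v for v in values if v is not None and not np.isnan(v)])
    counts, edges = np.histogram(values, bins=np.asarray(bin_edges))
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })
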