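"""Per-dataset pooled-sample SNP and indel probability calling.

In pooled sequencing, each read is (approximately) an independent draw from
the pool's allele frequency distribution, so a site's evidence for a SNP is
the count of alternative-allele reads out of its depth. The caller tests the
composite null "population minor-allele frequency <= theta given per-base
error rate e" at its boundary: under the null, alternative reads arrive with
probability at most p0 = theta*(1-e) + (1-theta)*e, and the reported
probability is the one-sided binomial upper tail P(X >= alt_count) at p0.
Small values mean the observed alternative-read count is unlikely unless the
pool truly segregates above theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)

FLAG_LOW_DEPTH = "LOW_DEPTH"
FLAG_LOW_ALT = "LOW_ALT"
FLAG_LOW_MAPQ = "LOW_MAPQ"
FLAG_FIXED_DIFFERENCE = "FIXED_DIFFERENCE"

_BASE_ORDER = "ACGT"  # fixed tie-break order for equal alt counts


@dataclass
class CallerParams:
    """Thresholds of the pooled caller.

    maf_threshold (theta) and error_rate (e) parameterize the composite null;
    min_depth / min_alt are the first-stage variant filters; min_baseq,
    min_mapq and max_reads mirror standard pileup ingestion limits.
    """

    maf_threshold: float = 0.01
    error_rate: float = 0.01
    min_depth: int = 5
    min_alt: int = 2
    min_baseq: int = 20
    min_mapq: int = 20
    max_reads: int = 20000

    def __post_init__(self):
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError("maf_threshold must be in (0,1)")
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must be in (0,1)")
        for name in ("min_depth", "min_alt", "min_baseq", "min_mapq", "max_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def null_alt_probability(self) -> float:
        """Boundary null per-read alternative probability p0 = θ(1−e)+(1−θ)e."""
        t, e = self.maf_threshold, self.error_rate
        return t * (1.0 - e) + (1.0 - t) * e


@dataclass
class PileupSite:
    """Nucleotide/indel counts for one dataset at one reference position."""

    isotig_id: str
    position: int
    ref_base: str
    dataset_id: str
    base_counts: dict
    n_count: int = 0
    indel_events: list = field(default_factory=list)
    depth: int = -1  # -1: derive from counts
    mapq: float = 60.0

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.ref_base not in _BASE_ORDER:
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        if any(c < 0 for c in self.base_counts.values()) or self.n_count < 0:
            raise ValueError("counts must be non-negative")
        total = sum(self.base_counts.get(b, 0) for b in _BASE_ORDER) + self.n_count
        if self.depth < 0:
            self.depth = total
        elif self.depth != total:
            raise ValueError(
                f"depth {self.depth} != sum of base counts + N ({total}) "
                f"at {self.isotig_id}:{self.position}"
            )


@dataclass
class SiteCall:
    """The caller's verdict at one site in one dataset."""

    isotig_id: str
    position: int
    dataset_id: str
    ref_base: str
    alleles_observed: list  # (base, count) sorted by descending count
    alt_allele: str | None
    alt_count: int
    depth: int
    allele_freq: float
    p_snp: float
    within_dataset_polymorphic: bool
    filter_flags: set
    p_indel: float | None = None
    indel_event: str | None = None
    indel_count: int = 0
    mapq: float = 60.0

    @property
    def is_snp(self) -> bool:
        """True when the site is a reportable SNP candidate (no filter flags)."""
        return self.alt_allele is not None and not self.filter_flags


def pooled_variant_pvalue(alt_count: int, depth: int, params: CallerParams) -> float:
    """One-sided binomial upper-tail probability P(X >= alt_count).

    X ~ Binomial(depth, p0) at the composite-null boundary p0. Returns 1.0 for
    alt_count == 0 (the upper tail includes everything).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count {alt_count} outside [0, depth={depth}]")
    if alt_count == 0:
        return 1.0
    # sf(k-1) == P(X >= k)
    return float(binom.sf(alt_count - 1, depth, params.null_alt_probability))


def mask_low_quality_bases(bases: str, qualities, params: CallerParams | None = None):
    """Move low-quality base observations into the N channel.

    ``bases`` is a string of read base calls at one site, ``qualities`` the
    matching phred scores. Bases below ``min_baseq`` (the quality-2 'B' run
    rule is the extreme case) contribute only to the N count, never to allele
    counts. Returns ``(base_counts, n_count)``; depth is preserved.
    """
    params = params or CallerParams()
    if len(bases) != len(qualities):
        raise ValueError("bases and qualities must have equal length")
    counts = {b: 0 for b in _BASE_ORDER}
    n_count = 0
    for b, q in zip(bases.upper(), qualities):
        if q < params.min_baseq or b not in counts:
            n_count += 1
        else:
            counts[b] += 1
    return counts, n_count


def call_site(site: PileupSite, params: CallerParams | None = None) -> SiteCall:
    """Score one pileup site: best alternative allele, p_snp, filter flags.

    The alternative allele is the highest-count non-reference base (ties by
    A<C<G<T). A site whose reads carry a single allele differing from the
    reference is flagged FIXED_DIFFERENCE and never reported as a SNP — with
    no within-pool polymorphism the difference is treated as reference or
    sequencing error, not a segregating variant. N counts never contribute.
    """
    params = params or CallerParams()
    if site.depth > params.max_reads:
        logger.warning(
            "site %s:%d exceeds max_reads (%d > %d); skipping",
            site.isotig_id, site.position, site.depth, params.max_reads,
        )
        return None
    counts = {b: site.base_counts.get(b, 0) for b in _BASE_ORDER}
    observed = sorted(
        ((b, c) for b, c in counts.items() if c > 0),
        key=lambda bc: (-bc[1], _BASE_ORDER.index(bc[0])),
    )
    non_ref = [(b, c) for b, c in observed if b != site.ref_base]
    if non_ref:
        alt_allele, alt_count = non_ref[0]
    else:
        alt_allele, alt_count = None, 0

    flags = set()
    if site.depth < params.min_depth:
        flags.add(FLAG_LOW_DEPTH)
    if alt_count < params.min_alt:
        flags.add(FLAG_LOW_ALT)
    if site.mapq < params.min_mapq:
        flags.add(FLAG_LOW_MAPQ)
    segregating = [b for b, c in counts.items() if c > 0]
    if len(segregating) == 1 and segregating[0] != site.ref_base:
        flags.add(FLAG_FIXED_DIFFERENCE)

    effective_depth = max(site.depth - site.n_count, 1)
    p_snp = pooled_variant_pvalue(alt_count, effective_depth, params) if site.depth else 1.0
    return SiteCall(
        isotig_id=site.isotig_id,
        position=site.position,
        dataset_id=site.dataset_id,
        ref_base=site.ref_base,
        alleles_observed=observed,
        alt_allele=alt_allele,
        alt_count=alt_count,
        depth=site.depth,
        allele_freq=alt_count / site.depth if site.depth else 0.0,
        p_snp=p_snp,
        within_dataset_polymorphic=len(segregating) >= 2,
        filter_flags=flags,
        mapq=site.mapq,
    )


def call_indel(site: PileupSite, params: CallerParams | None = None,
               indel_trusted: bool = True):
    """Score the most frequent indel event at a site, or return None.

    Unlike SNPs, an indel relative to the reference is recorded even without
    within-pool polymorphism. The same binomial tail scores its supporting
    read count; depth/alt-count filters apply analogously. Indels from
    untrusted datasets (e.g. homopolymer-prone long-read pools) are dropped.
    """
    params = params or CallerParams()
    if not site.indel_events or not indel_trusted:
        return None
    event, count = max(site.indel_events, key=lambda ec: (ec[1], ec[0]))
    if site.depth < params.min_depth or count < params.min_alt:
        return None
    effective_depth = max(site.depth - site.n_count, 1)
    p_indel = pooled_variant_pvalue(min(count, effective_depth), effective_depth, params)
    return {
        "isotig": site.isotig_id,
        "pos": site.position,
        "dataset_id": site.dataset_id,
        "event": event,
        "count": count,
        "depth": site.depth,
        "p_indel": p_indel,
    }


def _site_from_row(row) -> PileupSite:
    events = []
    raw = row.get("indel_events", "")
    if isinstance(raw, str) and raw:
        for part in raw.split(";"):
            seq, _, cnt = part.rpartition(":")
            events.append((seq, int(cnt)))
    return PileupSite(
        isotig_id=row["isotig"],
        position=int(row["pos"]),
        ref_base=row["ref"],
        dataset_id=row["dataset_id"],
        base_counts={b: int(row[f"count{b}"]) for b in _BASE_ORDER},
        n_count=int(row.get("countN", 0)),
        indel_events=events,
        depth=int(row["depth"]),
        mapq=float(row.get("mapq_rms", 60.0)),
    )


def call_dataset(pileup: pd.DataFrame, dataset_id: str | None = None,
                 params: CallerParams | None = None,
                 indel_trusted: bool = True):
    """Run the caller over a pileup table for one dataset.

    Returns ``(snp_calls, indel_calls)`` DataFrames. ``snp_calls`` holds one
    row per retained variant (sites passing all first-stage filters);
    ``indel_calls`` one row per retained indel event.
    """
    params = params or CallerParams()
    if dataset_id is not None:
        pileup = pileup[pileup["dataset_id"] == dataset_id]
    snp_rows, indel_rows = [], []
    for row in pileup.to_dict("records"):
        site = _site_from_row(row)
        call = call_site(site, params)
        if call is not None and call.is_snp:
            snp_rows.append({
                "isotig": call.isotig_id,
                "pos": call.position,
                "ref": call.ref_base,
                "dataset_id": call.dataset_id,
                "alt": call.alt_allele,
                "alt_count": call.alt_count,
                "depth": call.depth,
                "freq": call.allele_freq,
                "p_snp": call.p_snp,
                "mapq": call.mapq,
            })
        ind = call_indel(site, params, indel_trusted=indel_trusted)
        if ind is not None:
            indel_rows.append(ind)
    snp_cols = ["isotig", "pos", "ref", "dataset_id", "alt", "alt_count",
                "depth", "freq", "p_snp", "mapq"]
    indel_cols = ["isotig", "pos", "dataset_id", "event", "count", "depth", "p_indel"]
    return (pd.DataFrame(snp_rows, columns=snp_cols),
            pd.DataFrame(indel_rows, columns=indel_cols))


def parse_mpileup_line(line: str, dataset_id: str = "mpileup",
                       params: CallerParams | None = None) -> PileupSite:
    """Parse one line of samtools-mpileup text into a PileupSite.

    Subset dialect: chrom, 1-based pos, ref, depth, read bases, base quals.
    Handles '.'/',' reference matches, explicit base calls, read start (^X)
    and end ($) markers, and +N/-N indel insertions following a base. Base
    qualities below ``min_baseq`` are masked into the N channel.
    """
    params = params or CallerParams()
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError("mpileup line needs >= 6 columns")
    chrom, pos, ref, depth, bases, quals = fields[:6]
    ref = ref.upper()
    calls: list = []
    indels: dict = {}
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            i += 2  # mapping-quality char follows
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            n = int(bases[i + 1:j])
            seq = bases[j:j + n].upper()
            key = ("+" if ch == "+" else "-") + seq
            indels[key] = indels.get(key, 0) + 1
            i = j + n
            continue
        if ch in ".,":
            calls.append(ref)
        elif ch == "*":
            calls.append("N")  # deletion placeholder keeps depth
        else:
            calls.append(ch.upper())
        i += 1
    phred = [ord(q) - 33 for q in quals]
    if len(phred) != len(calls):
        # be forgiving about trailing markers; pad with high quality
        phred = (phred + [40] * len(calls))[: len(calls)]
    counts = {b: 0 for b in _BASE_ORDER}
    n_count = 0
    for b, q in zip(calls, phred):
        if q < params.min_baseq or b not in counts:
            n_count += 1
        else:
            counts[b] += 1
    return PileupSite(
        isotig_id=chrom,
        position=int(pos),
        ref_base=ref,
        dataset_id=dataset_id,
        base_counts=counts,
        n_count=n_count,
        indel_events=sorted(indels.items()),
        depth=sum(counts.values()) + n_count,
    )
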