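"""Transcriptome-assembly evaluation.

Four independent checks on an assembled reference: (1) structural confidence
classes C1-C7 from homology of each isotig to a related species' unigene set
— simple one-to-one relationships inspire the most confidence that reads
were assembled into a single true locus; (2) strand orientation inferred
from stranded-library alignment counts via an exact binomial test;
(3) contaminant screening of best BLAST hits against bacterial/fungal genus
name lists; (4) standard assembly statistics (mean, median, N50, total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

logger = logging.getLogger(__name__)

CONFIDENCE_LABELS = {
    "C1": "Highest", "C2": "Higher", "C3": "Higher", "C4": "Medium",
    "C5": "Lower", "C6": "Lowest", "C7": "Unknown",
}


def classify_isotigs(matches: pd.DataFrame, isotig_ids=None,
                     identity_window: float = 5.0) -> pd.DataFrame:
    """Assign each isotig a C1-C7 confidence class from its match table.

    Per isotig, *countable* matches are hits with percent identity within
    ``identity_window`` of its best hit. The class follows three criteria:
    number of distinct subjects among countable matches (1 vs 2+), whether
    any other isotig's countable matches share a subject (partners), and
    whether the focal subject-side intervals overlap a partner's on a shared
    subject. Mapping: no match -> C7; (1, no partners) -> C1; (2+, no
    partners) -> C2; (1, partners, no overlap) -> C3; (2+, partners, no
    overlap) -> C4; (1, partners, overlap) -> C5; (2+, partners, overlap) ->
    C6. ``isotig_ids`` extends the universe so matchless isotigs surface as C7.
    """
    if matches.empty:
        matches = pd.DataFrame(columns=["qseqid", "sseqid", "pident",
                                        "qstart", "qend", "sstart", "send"])
    if (matches["qstart"] > matches["qend"]).any():
        raise ValueError("qstart > qend; normalize strand before classifying")

    countable: dict = {}
    for q, grp in matches.groupby("qseqid"):
        best = grp["pident"].max()
        cnt = grp[grp["pident"] >= best - identity_window]
        # subject -> list of subject-side closed intervals
        ivals: dict = {}
        for r in cnt.itertuples():
            lo, hi = sorted((int(r.sstart), int(r.send)))
            ivals.setdefault(r.sseqid, []).append((lo, hi))
        countable[q] = ivals

    subject_users: dict = {}
    for q, ivals in countable.items():
        for s in ivals:
            subject_users.setdefault(s, set()).add(q)

    universe = set(countable)
    if isotig_ids is not None:
        universe |= set(isotig_ids)

    rows = []
    for q in sorted(universe):
        ivals = countable.get(q, {})
        if not ivals:
            rows.append((q, 0, False, False, "C7", CONFIDENCE_LABELS["C7"]))
            continue
        n_subjects = len(ivals)
        partners = set()
        for s in ivals:
            partners |= subject_users[s] - {q}
        has_partners = bool(partners)
        overlap = False
        for s, own in ivals.items():
            for other in subject_users[s] - {q}:
                for lo1, hi1 in own:
                    for lo2, hi2 in countable[other].get(s, []):
                        if lo1 <= hi2 and lo2 <= hi1:
                            overlap = True
        if not has_partners:
            cls = "C1" if n_subjects == 1 else "C2"
        elif not overlap:
            cls = "C3" if n_subjects == 1 else "C4"
        else:
            cls = "C5" if n_subjects == 1 else "C6"
        rows.append((q, n_subjects, has_partners, overlap, cls,
                     CONFIDENCE_LABELS[cls]))
    return pd.DataFrame(rows, columns=[
        "isotig", "n_subject_matches", "has_partners", "partners_overlap",
        "confidence_class", "confidence_label",
    ])


@dataclass(frozen=True)
class OrientationCall:
    ref_id: str
    D: int
    C: int
    p_value: float
    orientation: str  # '+', '-', or 'ambiguous'


def orient_sequence(D: int, C: int, alpha: float = 0.05,
                    ref_id: str = "") -> OrientationCall:
    """Infer strand orientation from direct (D) vs reverse-complement (C)
    unique alignment-location counts of a stranded library.

    Exact two-tailed binomial test of C successes in D + C trials at null
    0.5. With dUTP-style libraries reads map as reverse complements of the
    transcript, so significantly more C than D marks a forward (+) sequence
    and the converse a reverse (-) one; otherwise orientation is ambiguous.
    """
    if D < 0 or C < 0:
        raise ValueError("counts must be non-negative")
    n = D + C
    if n == 0:
        return OrientationCall(ref_id, D, C, 1.0, "ambiguous")
    p = float(binomtest(C, n, 0.5, alternative="two-sided").pvalue)
    if p < alpha:
        orientation = "+" if C > D else "-"
    else:
        orientation = "ambiguous"
    return OrientationCall(ref_id, D, C, p, orientation)


def orient_table(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vector version of :func:`orient_sequence` over a (ref_id, D, C) table."""
    rows = []
    for r in counts.itertuples():
        call = orient_sequence(int(r.D), int(r.C), alpha=alpha, ref_id=r.ref_id)
        rows.append((call.ref_id, call.D, call.C, call.p_value, call.orientation))
    return pd.DataFrame(rows, columns=["ref_id", "D", "C", "p_value", "orientation"])


def screen_contaminant(best_hit, genus_names, min_bitscore: float = 50.0,
                       max_evalue: float = 1e-10) -> str:
    """'remove' iff the best hit is strong (bitscore > 50, E-value < 1e-10)
    and its genus is in the contaminant name sets; otherwise 'keep'.

    ``best_hit`` is a mapping with ``bitscore``, ``evalue`` and either a
    ``genus`` field or a ``subject_desc`` whose first token is the genus.
    An absent hit keeps the sequence (nothing to implicate it).
    """
    if best_hit is None:
        return "keep"
    genus = best_hit.get("genus")
    if genus is None:
        desc = best_hit.get("subject_desc", "")
        genus = desc.split()[0] if desc.strip() else ""
    if (best_hit["bitscore"] > min_bitscore
            and best_hit["evalue"] < max_evalue
            and genus in genus_names):
        return "remove"
    return "keep"


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    mean: float
    median: float
    n50: int
    total: int


def assembly_stats(lengths) -> AssemblyStats:
    """Mean, median, N50 and total length of a sequence set.

    N50 is the smallest length L such that sequences of length >= L together
    cover at least half the total assembled nucleotides.
    """
    lengths = [int(x) for x in lengths]
    if any(x <= 0 for x in lengths):
        raise ValueError("sequence lengths must be positive")
    if not lengths:
        logger.warning("empty length list; returning zeros")
        return AssemblyStats(0, 0.0, 0.0, 0, 0)
    total = sum(lengths)
    desc = sorted(lengths, reverse=True)
    acc = 0
    n50 = desc[-1]
    for L in desc:
        acc += L
        if 2 * acc >= total:
            n50 = L
            break
    return AssemblyStats(
        n_sequences=len(lengths),
        mean=float(np.mean(lengths)),
        median=float(np.median(lengths)),
        n50=n50,
        total=total,
    )
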