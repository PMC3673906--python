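"""Synthetic inputs with planted ground truth.

Every file the pipeline consumes — reference FASTA, per-dataset pileup tables,
stranded alignment-location counts, cross-species match tables, and
genotyping-array call matrices — can be generated here with known truth, so
each downstream stage is testable end-to-end without any sequencing data.

The generators emulate a pooled-transcriptome SNP study: several cDNA pools
(datasets) sequenced over a shared transcript reference, where only allele
*frequencies*, not individual genotypes, are observable in the read counts.
A single global seed fans out deterministically to per-component child
streams, so identical (config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Pool names mirror a five-dataset design: one combined Sanger/454 long-read
# pool plus four short-read pools. The long-read pool is marked untrusted for
# indel calls (homopolymer artifacts), and its indels are dropped at merging.
DEFAULT_DATASETS = ("sang454", "mg2_il", "cb_il", "yk_il", "int_il")
DEFAULT_INDEL_UNTRUSTED = frozenset({"sang454"})

_BASES = np.array(list("ACGT"))

PILEUP_COLUMNS = [
    "isotig", "pos", "ref", "dataset_id",
    "countA", "countC", "countG", "countT", "countN",
    "indel_events", "depth", "mapq_rms",
]


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant: where it is, what it is, and its frequency per pool."""

    isotig_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    per_pool_freq: dict
    is_indel: bool = False
    indel_seq: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not self.is_indel and self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for ds, f in self.per_pool_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency for {ds} outside [0,1]: {f}")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale version of a pooled transcriptome study:
    five pools, per-base error 0.01 (matching the caller's error parameter),
    negative-binomial coverage (mean 100, dispersion 10 — overdispersed, as is
    typical of RNA-seq-derived pileups), ~2 variants per kb with planted pool
    frequencies drawn uniformly on [0.05, 0.5].
    """

    n_isotigs: int = 10
    isotig_length_range: tuple = (500, 1500)
    n_datasets: int = 5
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.01
    variant_density: float = 2.0  # variants per kb
    shared_fraction: float = 0.6  # fraction of variants planted in >= 2 pools
    indel_fraction: float = 0.1  # fraction of planted variants that are indels
    n_fraction: float = 0.0  # fraction of bases emitted as N (quality-2 rule)
    freq_range: tuple = (0.05, 0.5)
    seed: int = 0
    dataset_ids: tuple = DEFAULT_DATASETS

    def __post_init__(self):
        if self.n_isotigs < 1 or self.n_datasets < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.isotig_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid isotig_length_range")
        for name in ("error_rate", "shared_fraction", "indel_fraction", "n_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.variant_density < 0:
            raise ValueError("variant_density must be >= 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters must be positive")
        if len(self.dataset_ids) < self.n_datasets:
            self.dataset_ids = tuple(
                f"ds{i + 1}" for i in range(self.n_datasets)
            )
        else:
            self.dataset_ids = tuple(self.dataset_ids[: self.n_datasets])


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-component child generator from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# stream indices for the child generators
_STREAM_REFERENCE = 0
_STREAM_PILEUP = 1
_STREAM_STRANDED = 2
_STREAM_GENOTYPE = 3
_STREAM_MATCH = 4
_STREAM_SCORES = 5


def simulate_reference(config: SimConfig):
    """Draw reference sequences and plant variants on them.

    Returns ``(reference, truth)`` where ``reference`` maps isotig id to an
    A/C/G/T sequence string and ``truth`` is a list of :class:`TruthVariant`.
    Variant counts per isotig are Poisson with mean ``length/1000 * density``;
    a ``shared_fraction`` of variants is planted in two or more pools.
    """
    rng = child_rng(config.seed, _STREAM_REFERENCE)
    lo, hi = config.isotig_length_range
    reference: dict = {}
    truth: list = []
    ds_ids = list(config.dataset_ids)
    f_lo, f_hi = config.freq_range
    for i in range(config.n_isotigs):
        name = f"isotig{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length)
        reference[name] = "".join(seq)
        n_var = rng.poisson(length / 1000.0 * config.variant_density)
        n_var = min(n_var, length)
        if n_var == 0:
            continue
        positions = rng.choice(length, size=n_var, replace=False) + 1
        for pos in sorted(int(p) for p in positions):
            ref_base = reference[name][pos - 1]
            is_indel = bool(rng.random() < config.indel_fraction)
            if rng.random() < config.shared_fraction and config.n_datasets >= 2:
                k = int(rng.integers(2, config.n_datasets + 1))
            else:
                k = 1
            carriers = rng.choice(config.n_datasets, size=k, replace=False)
            freqs = {
                ds_ids[c]: float(rng.uniform(f_lo, f_hi)) for c in carriers
            }
            if is_indel:
                ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
                truth.append(
                    TruthVariant(name, pos, ref_base, ref_base,
                                 per_pool_freq=freqs, is_indel=True, indel_seq=ins)
                )
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                truth.append(
                    TruthVariant(name, pos, ref_base, alt, per_pool_freq=freqs)
                )
    return reference, truth


def _sequential_multinomial(rng, n, probs):
    """Exact multinomial draw vectorized over varying n at fixed probs.

    Decomposes the multinomial into conditional binomials, which numpy can
    vectorize over an array of trial counts.
    """
    n = np.asarray(n)
    remaining = n.copy()
    remaining_p = 1.0
    out = np.zeros((len(probs),) + n.shape, dtype=np.int64)
    for j, pj in enumerate(probs[:-1]):
        cond = 0.0 if remaining_p <= 0 else min(pj / remaining_p, 1.0)
        out[j] = rng.binomial(remaining, cond)
        remaining = remaining - out[j]
        remaining_p -= pj
    out[-1] = remaining
    return out


def simulate_pileups(reference: dict, truth, config: SimConfig) -> pd.DataFrame:
    """Per-dataset, per-site nucleotide count tables over the reference.

    At non-variant sites, non-reference counts arise only from the error
    model (each read miscalled with probability ``error_rate``, uniformly to
    one of the three other bases). At SNP sites in a carrying pool, the alt
    base competes at the planted frequency before errors are applied, so the
    expected alt fraction is ``f(1-e) + (1-f)e/3``. Indel-carrying reads keep
    the reference base at the anchor position and contribute an indel event.
    """
    rng = child_rng(config.seed, _STREAM_PILEUP)
    for tv in truth:
        if tv.isotig_id not in reference:
            raise ValueError(f"truth references unknown isotig {tv.isotig_id}")
        if tv.position > len(reference[tv.isotig_id]):
            raise ValueError(
                f"truth position {tv.position} beyond end of {tv.isotig_id}"
            )

    base_index = {b: i for i, b in enumerate("ACGT")}
    e = config.error_rate
    disp = config.depth_dispersion
    p_nb = disp / (disp + config.depth_mean)

    # flatten reference into site arrays
    isotigs, positions, refs = [], [], []
    for name, seq in reference.items():
        isotigs.extend([name] * len(seq))
        positions.extend(range(1, len(seq) + 1))
        refs.extend(seq)
    n_sites = len(positions)
    ref_codes = np.array([base_index[b] for b in refs])
    site_key = {(isotigs[i], positions[i]): i for i in range(n_sites)}

    snp_by_ds = {ds: {} for ds in config.dataset_ids}
    indel_by_ds = {ds: {} for ds in config.dataset_ids}
    for tv in truth:
        idx = site_key[(tv.isotig_id, tv.position)]
        for ds, f in tv.per_pool_freq.items():
            if ds not in snp_by_ds:
                continue
            if tv.is_indel:
                indel_by_ds[ds][idx] = (f"+{tv.indel_seq}", f)
            else:
                snp_by_ds[ds][idx] = (base_index[tv.alt_allele], f)

    frames = []
    for ds in config.dataset_ids:
        depth = rng.negative_binomial(disp, p_nb, size=n_sites)
        if config.n_fraction > 0:
            n_count = rng.binomial(depth, config.n_fraction)
        else:
            n_count = np.zeros(n_sites, dtype=np.int64)
        eff = depth - n_count
        counts = np.zeros((n_sites, 4), dtype=np.int64)

        snp_sites = snp_by_ds[ds]
        variant_mask = np.zeros(n_sites, dtype=bool)
        if snp_sites:
            variant_mask[list(snp_sites)] = True

        # non-variant sites, grouped by reference base so probs are constant
        for rb in range(4):
            mask = (ref_codes == rb) & ~variant_mask
            if not mask.any():
                continue
            order = [rb] + [b for b in range(4) if b != rb]
            probs = [1.0 - e, e / 3.0, e / 3.0, e / 3.0]
            drawn = _sequential_multinomial(rng, eff[mask], probs)
            for slot, b in enumerate(order):
                counts[mask, b] = drawn[slot]

        # SNP sites individually (per-site frequency)
        for idx, (alt_b, f) in snp_sites.items():
            rb = ref_codes[idx]
            others = [b for b in range(4) if b not in (rb, alt_b)]
            p_ref = (1 - f) * (1 - e) + f * (e / 3.0)
            p_alt = f * (1 - e) + (1 - f) * (e / 3.0)
            order = [rb, alt_b] + others
            probs = [p_ref, p_alt] + [e / 3.0] * len(others)
            drawn = rng.multinomial(eff[idx], np.array(probs) / sum(probs))
            for slot, b in enumerate(order):
                counts[idx, b] = drawn[slot]

        events = [""] * n_sites
        for idx, (event, f) in indel_by_ds[ds].items():
            k = rng.binomial(eff[idx], f)
            if k > 0:
                events[idx] = f"{event}:{k}"

        mapq = np.clip(rng.normal(50.0, 4.0, size=n_sites), 20.0, 60.0).round(1)
        frames.append(pd.DataFrame({
            "isotig": isotigs,
            "pos": positions,
            "ref": refs,
            "dataset_id": ds,
            "countA": counts[:, 0],
            "countC": counts[:, 1],
            "countG": counts[:, 2],
            "countT": counts[:, 3],
            "countN": n_count,
            "indel_events": events,
            "depth": depth,
            "mapq_rms": mapq,
        }))
    return pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]


def simulate_stranded_counts(n_refs: int, reads_per_ref: int,
                             misorientation_rate: float, seed: int = 0,
                             orientations=None) -> pd.DataFrame:
    """Stranded alignment-location counts with known true orientation.

    Emulates counting unique alignment locations of strand-oriented reads
    mapped as direct output (D) and as reverse complements (C). For a '+'
    reference C ~ Binomial(reads, 1 - misorientation_rate); roles swap for '-'.
    """
    if not 0.0 <= misorientation_rate < 0.5:
        raise ValueError("misorientation_rate must be in [0, 0.5)")
    if reads_per_ref < 0 or n_refs < 0:
        raise ValueError("counts must be non-negative")
    rng = child_rng(seed, _STREAM_STRANDED)
    if orientations is None:
        orientations = rng.choice(["+", "-"], size=n_refs)
    orientations = list(orientations)
    if len(orientations) != n_refs:
        raise ValueError("orientations length must equal n_refs")
    rows = []
    for i, orient in enumerate(orientations):
        c_like = int(rng.binomial(reads_per_ref, 1.0 - misorientation_rate))
        d_like = reads_per_ref - c_like
        if orient == "+":
            d, c = d_like, c_like
        else:
            d, c = c_like, d_like
        rows.append((f"ref{i + 1:05d}", d, c, orient))
    return pd.DataFrame(rows, columns=["ref_id", "D", "C", "true_orientation"])


def simulate_genotypes(n_loci: int, n_samples: int, maf, inbreeding_f: float = 0.0,
                       no_call_rate: float = 0.0, seed: int = 0):
    """Genotype call matrix under an inbreeding-adjusted HWE model.

    Genotype probabilities at minor-allele frequency q (major p = 1 - q):
    P(AA) = p^2 + pq*f, P(AB) = 2pq(1 - f), P(BB) = q^2 + pq*f. No-calls are
    assigned independently at ``no_call_rate``.

    Returns ``(calls, truth)``: ``calls`` is an (n_loci, n_samples) array of
    strings in {AA, AB, BB, NC}; ``truth`` is a per-locus DataFrame.
    """
    if not 0.0 <= no_call_rate < 1.0:
        raise ValueError("no_call_rate must be in [0, 1)")
    if not -1.0 <= inbreeding_f <= 1.0:
        raise ValueError("inbreeding_f must be in [-1, 1]")
    q = np.broadcast_to(np.asarray(maf, dtype=float), (n_loci,)).copy()
    if np.any((q < 0) | (q > 0.5)):
        raise ValueError("maf must be in [0, 0.5]")
    p = 1.0 - q
    pq = p * q
    p_ab = 2.0 * pq * (1.0 - inbreeding_f)
    p_aa = p * p + pq * inbreeding_f
    p_bb = q * q + pq * inbreeding_f
    if np.any(p_ab < -1e-12) or np.any(p_aa < -1e-12) or np.any(p_bb < -1e-12):
        raise ValueError("inbreeding_f yields negative genotype probability")

    rng = child_rng(seed, _STREAM_GENOTYPE)
    u = rng.random((n_loci, n_samples))
    c_aa = p_aa[:, None]
    c_ab = (p_aa + p_ab)[:, None]
    codes = np.where(u < c_aa, 0, np.where(u < c_ab, 1, 2))
    calls = np.array(["AA", "AB", "BB"])[codes]
    if no_call_rate > 0:
        nc = rng.random((n_loci, n_samples)) < no_call_rate
        calls = np.where(nc, "NC", calls)
    truth = pd.DataFrame({
        "locus_id": [f"locus{i + 1:05d}" for i in range(n_loci)],
        "maf": q,
        "inbreeding_f": inbreeding_f,
        "no_call_rate": no_call_rate,
    })
    return calls, truth


_MATCH_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def simulate_match_table(class_plan: dict, seed: int = 0):
    """Build a homology match table realizing a requested confidence-class plan.

    ``class_plan`` maps class labels C1..C7 to isotig counts. Classes C3-C6
    require partner isotigs and therefore counts >= 2 (a group of n isotigs
    realizes n assignments of the same class). Returns ``(matches, expected)``
    where ``matches`` is an outfmt-6-style DataFrame and ``expected`` maps each
    generated isotig id to its designed class.
    """
    for cls in class_plan:
        if cls not in {"C1", "C2", "C3", "C4", "C5", "C6", "C7"}:
            raise ValueError(f"unknown class {cls!r}")
        if class_plan[cls] < 0:
            raise ValueError("class counts must be >= 0")
    for cls in ("C3", "C4", "C5", "C6"):
        if class_plan.get(cls, 0) == 1:
            raise ValueError(f"{cls} requires at least 2 isotigs (partners)")

    rng = child_rng(seed, _STREAM_MATCH)
    rows, expected = [], {}
    iso_counter, subj_counter = [0], [0]

    def new_iso(cls):
        iso_counter[0] += 1
        name = f"dfir{iso_counter[0]:05d}"
        expected[name] = cls
        return name

    def new_subj():
        subj_counter[0] += 1
        return f"unigene{subj_counter[0]:05d}"

    def hit(q, s, pident, qstart, qend, sstart, send):
        length = qend - qstart + 1
        rows.append((q, s, round(pident, 2), length,
                     int(length * (100 - pident) / 100), 0,
                     qstart, qend, sstart, send,
                     float(f"{rng.uniform(1e-40, 1e-20):.2e}"),
                     round(rng.uniform(200, 900), 1)))

    for _ in range(class_plan.get("C7", 0)):
        new_iso("C7")  # zero match rows

    for _ in range(class_plan.get("C1", 0)):
        q, s = new_iso("C1"), new_subj()
        best = rng.uniform(90, 98)
        hit(q, s, best, 1, 400, 101, 500)
        # decoy below the 5%-of-best identity window: must not count
        hit(q, new_subj(), best - 6.0, 1, 300, 1, 300)

    for _ in range(class_plan.get("C2", 0)):
        q = new_iso("C2")
        best = rng.uniform(90, 98)
        hit(q, new_subj(), best, 1, 400, 101, 500)
        hit(q, new_subj(), best - 2.0, 1, 380, 51, 430)

    def group(cls, n_subjects, overlap):
        n = class_plan.get(cls, 0)
        if n == 0:
            return
        subjects = [new_subj() for _ in range(n_subjects)]
        for j in range(n):
            q = new_iso(cls)
            for s in subjects:
                if overlap:
                    sstart, send = 100, 600  # all partners share this window
                else:
                    sstart, send = 1 + 500 * j, 400 + 500 * j
                hit(q, s, rng.uniform(92, 97), 1, 400, sstart, send)

    group("C3", 1, overlap=False)
    group("C4", 2, overlap=False)
    group("C5", 1, overlap=True)
    group("C6", 2, overlap=True)

    matches = pd.DataFrame(rows, columns=_MATCH_COLUMNS)
    return matches, expected


def simulate_design_scores(keys, seed: int = 0) -> dict:
    """Assay design scores in [0,1] for (isotig, position) keys, Beta(5,2)."""
    rng = child_rng(seed, _STREAM_SCORES)
    return {k: float(rng.beta(5.0, 2.0)) for k in keys}
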