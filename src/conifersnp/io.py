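"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: FASTA (Biopython), tab-separated pileup/call/match
tables (pandas), BED interval tracks, genotype CSV matrices, and a minimal
site-only VCF 4.2 export carrying per-dataset and pooled probabilities in
INFO.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: dict, path):
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path, sep: str = "\t"):
    df.to_csv(path, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


MATCH_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_match_table(path) -> pd.DataFrame:
    """BLAST tabular (outfmt 6) reader: headerless, fixed column order."""
    return pd.read_csv(path, sep="\t", names=MATCH_COLUMNS, comment="#")


def write_match_table(df: pd.DataFrame, path):
    df[MATCH_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def write_bed(intervals, path):
    """0-based half-open intervals: (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_genotype_matrix(calls, locus_ids, sample_ids, path):
    df = pd.DataFrame(calls, index=locus_ids, columns=sample_ids)
    df.index.name = "locus_id"
    df.to_csv(path)


def read_genotype_matrix(path):
    df = pd.read_csv(path, index_col="locus_id")
    return df.to_numpy(dtype=str), list(df.index), list(df.columns)


def write_vcf(combined: pd.DataFrame, path, source: str = "conifersnp"):
    """Site-only VCF 4.2 with pooled and per-dataset probabilities in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=PP,Number=1,Type=Float,Description='
                 '"Fisher-combined across-dataset probability">\n')
        fh.write('##INFO=<ID=DSP,Number=.,Type=String,Description='
                 '"Per-dataset variant probabilities">\n')
        fh.write('##INFO=<ID=ND,Number=1,Type=Integer,Description='
                 '"Number of datasets detecting the variant">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in combined.to_dict("records"):
            if row["variant_type"] != "SNP":
                continue
            alt = row["alt_alleles"].replace(" ", "")
            dsp = row["per_dataset_p"].replace(";", ",")
            info = f'PP={row["pooled_p"]:.6g};ND={row["n_datasets"]};DSP={dsp}'
            fh.write(f'{row["isotig"]}\t{row["pos"]}\t.\t{row["ref"]}\t{alt}'
                     f'\t.\tPASS\t{info}\n')


def read_vcf_sites(path) -> pd.DataFrame:
    """Read back the site-only VCF written by :func:`write_vcf`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";"))
            rows.append({
                "isotig": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                "pooled_p": float(fields["PP"]), "n_datasets": int(fields["ND"]),
            })
    return pd.DataFrame(rows)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
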