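"""IUPAC nucleotide ambiguity codes.

A masked reference encodes the set of alleles segregating at a position as a
single ambiguity character (e.g. {A,G} -> R), so that downstream assay-design
tools see every flanking polymorphism without changing sequence length.
"""

from __future__ import annotations

# canonical base-set -> code table (sets of 2, 3 or 4 bases)
_SET_TO_CODE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
}

CODE_TO_BASES = {code: set(bases) for bases, code in _SET_TO_CODE.items()}
CODE_TO_BASES["N"] = set("ACGT")

VALID_BASES = frozenset("ACGT")


def code_for_bases(bases) -> str:
    """Return the IUPAC code for a set of bases.

    A set containing only the placeholder ``N`` (no informative allele) maps to
    ``N``. Raises ``ValueError`` for empty sets or non-nucleotide characters.
    """
    s = frozenset(b.upper() for b in bases)
    if not s:
        raise ValueError("empty allele set has no IUPAC code")
    if s == frozenset("N"):
        return "N"
    s = frozenset(b for b in s if b != "N") if "N" in s else s
    if "N" in bases and s:
        # any explicit N widens the set to fully ambiguous
        return "N"
    unknown = s - VALID_BASES
    if unknown:
        raise ValueError(f"non-nucleotide characters in allele set: {sorted(unknown)}")
    return _SET_TO_CODE[s]


def bases_for_code(code: str) -> set:
    """Return the set of bases an IUPAC code stands for."""
    try:
        return set(CODE_TO_BASES[code.upper()])
    except KeyError:
        raise ValueError(f"unknown IUPAC code: {code!r}") from None
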