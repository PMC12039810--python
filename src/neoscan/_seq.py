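"""Small sequence utilities shared across modules.

Everything here works on plain upper-case DNA strings. Translation goes
through Biopython's standard table so the genetic code is never re-typed.
"""

from __future__ import annotations

import itertools
import re

from Bio.Seq import Seq

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = ("TAA", "TAG", "TGA")

#: The 61 sense codons of the standard genetic code, lexicographic order.
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)

# IUPAC nucleotide codes -> regex character classes
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError(f"{what} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def translate(seq: str) -> str:
    """Translate a DNA string (truncated to a codon multiple), stops as '*'."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC nucleotide pattern into a lookahead regex.

    The lookahead lets overlapping occurrences be found, which matters for
    dense recognition sites.
    """
    try:
        body = "".join(_IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValidationError(f"not an IUPAC nucleotide code: {exc}") from exc
    return re.compile(f"(?=({body}))")


def find_motif(seq: str, motif: str, max_mismatch: int = 0) -> list[int]:
    """1-based start positions of ``motif`` in ``seq`` with <= max_mismatch
    substitutions (overlaps allowed)."""
    m = len(motif)
    if max_mismatch == 0:
        return [match.start() + 1 for match in re.finditer(f"(?={re.escape(motif)})", seq)]
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        mism = sum(a != b for a, b in zip(window, motif))
        if mism <= max_mismatch:
            hits.append(i + 1)
    return hits
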