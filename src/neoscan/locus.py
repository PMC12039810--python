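"""The DRT2-type ncRNA locus and template extraction.

A DRT2 system pairs a reverse transcriptase with a ~280-nt non-coding RNA.
Upon phage infection the RT reverse-transcribes a central ~120-nt "template
region" of the ncRNA over and over, producing concatemeric cDNA (ccDNA).
The template is flanked by two conserved "ACA" trinucleotides, the first of
which is part of the template itself, and ends in a primer-binding site
(PBS) that is annealed to a short DNA primer covalently attached to the
ncRNA 3' end.

Coordinates on every public surface are 1-based inclusive; the ncRNA is
stored as its coding-strand DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp, validate_dna
from .errors import BracketNotFoundError, ValidationError

#: Reference geometry of the K. pneumoniae-like locus emulated throughout.
REF_TEMPLATE_START = 29
REF_TEMPLATE_END = 148
REF_PBS_INTERVAL = (142, 146)
REF_PRIMER = "GATAT"
REF_NCRNA_LENGTH = 280


@dataclass
class NcrnaLocus:
    """A ncRNA sequence with its annotated template interval and primer.

    Parameters
    ----------
    id : str
        Label for reports and FASTA headers.
    sequence : str
        The ncRNA as coding-strand DNA.
    template_start, template_end : int
        1-based inclusive template interval (reference: 29–148, length 120).
    aca_positions : list[int]
        1-based start positions of the bracketing "ACA" motifs. The first
        bracket coincides with ``template_start``.
    pbs_interval : tuple[int, int]
        1-based inclusive primer-binding site (reference: 142–146).
    primer : str
        DNA primer covalently appended 3' of the ncRNA; the reverse
        complement of the PBS (reference: "GATAT").
    """

    id: str
    sequence: str
    template_start: int = REF_TEMPLATE_START
    template_end: int = REF_TEMPLATE_END
    aca_positions: list[int] = field(default_factory=list)
    pbs_interval: tuple[int, int] = REF_PBS_INTERVAL
    primer: str = REF_PRIMER

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence, what=f"ncRNA {self.id!r}")
        n = len(self.sequence)
        if not (1 <= self.template_start <= self.template_end <= n):
            raise ValidationError(
                f"template interval {self.template_start}-{self.template_end} "
                f"outside 1-{n}"
            )
        lo, hi = self.pbs_interval
        if not (self.template_start <= lo <= hi <= self.template_end):
            raise ValidationError("PBS interval must lie within the template")
        if not self.aca_positions:
            self.aca_positions = [self.template_start, self.template_end + 1]

    @property
    def template_length(self) -> int:
        return self.template_end - self.template_start + 1

    @property
    def template(self) -> str:
        """The template region, ncRNA (plus) sense."""
        return self.sequence[self.template_start - 1 : self.template_end]

    @property
    def repeat_unit(self) -> str:
        """One ccDNA repeat: the reverse complement of the template."""
        return revcomp(self.template)

    @property
    def pbs(self) -> str:
        lo, hi = self.pbs_interval
        return self.sequence[lo - 1 : hi]


def extract_template(
    locus: NcrnaLocus,
    mode: str = "coordinates",
    *,
    approx_start: int | None = None,
    length_band: tuple[int, int] = (90, 150),
) -> tuple[str, tuple[int, int]]:
    """Extract the template region of a ncRNA.

    ``coordinates`` mode slices the annotated interval. ``aca_motif`` mode
    re-derives the interval from the bracketing "ACA" motifs: the template
    begins at the first bracket (inclusive) and ends at the base immediately
    before the second bracket.

    In ``aca_motif`` mode, if ``approx_start`` is given (e.g. from alignment
    to the reference locus) the first bracket is the nearest ACA at/left of
    it, and the second bracket is the nearest downstream ACA whose implied
    template length falls within ``length_band``. Without ``approx_start``
    the first ACA occurrence and the next occurrence are used.

    Returns
    -------
    (template, (start, end)) with 1-based inclusive coordinates.
    """
    seq = locus.sequence
    if mode == "coordinates":
        return locus.template, (locus.template_start, locus.template_end)
    if mode != "aca_motif":
        raise ValidationError(f"unknown extraction mode {mode!r}")

    acas = [i + 1 for i in range(len(seq) - 2) if seq[i : i + 3] == "ACA"]
    if not acas:
        raise BracketNotFoundError(f"{locus.id}: no ACA motif found")

    if approx_start is None:
        first = acas[0]
        downstream = [p for p in acas if p > first]
    else:
        left = [p for p in acas if p <= approx_start]
        if not left:
            raise BracketNotFoundError(
                f"{locus.id}: no ACA at or left of position {approx_start}"
            )
        first = max(left)
        lo, hi = length_band
        downstream = [p for p in acas if p > first and lo <= p - first <= hi]
    if not downstream:
        raise BracketNotFoundError(
            f"{locus.id}: no second ACA bracket downstream of {first}"
        )
    second = min(downstream)
    template = seq[first - 1 : second - 1]
    return template, (first, second - 1)
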