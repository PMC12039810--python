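"""Theoretical ccDNA construction and reconstitution detection.

Concatemerizing the reverse complement of the ncRNA template produces the
theoretical ccDNA. Within one repeat the sigma-70 -10 (TATAAT) and -35
(TTGACA) hexamers sit out of order with a 91-bp gap, but across a repeat
junction the -35 of one repeat and the -10 of the next are juxtaposed with
a 17-bp spacer — a perfect match to a strong promoter. The concatemer also
carries a single junction-spanning reading frame (the nearly-endless ORF,
"neo") that is stop-free precisely because the repeat length is divisible
by three. This module detects those reconstitutions and the supporting
signals: ribosome-binding site/start placement, alignment-column
conservation, restriction-digest products, hydropathy of the encoded
protein, and a fixed-element-preserving randomized-repeat null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ._seq import (
    SENSE_CODONS,
    find_motif,
    iupac_regex,
    revcomp,
    translate,
    validate_dna,
)
from .errors import LayoutError, ValidationError

HYDROPHOBIC_RESIDUES = frozenset("AILMFWV")
_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# concatemer construction


@dataclass
class CcdnaConstruct:
    """A theoretical or simulated concatemer of a ccDNA repeat unit.

    ``junction_positions`` holds the 1-based position of the first base of
    every repeat after the first, i.e. n_repeats - 1 boundaries.
    """

    repeat_unit: str
    n_repeats: int
    sequence: str = ""
    junction_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.repeat_unit = validate_dna(self.repeat_unit, what="repeat unit")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if not self.sequence:
            self.sequence = self.repeat_unit * self.n_repeats
        if len(self.sequence) != self.n_repeats * len(self.repeat_unit):
            raise ValidationError("sequence length != n_repeats * repeat length")
        if not self.junction_positions:
            L = len(self.repeat_unit)
            self.junction_positions = [i * L + 1 for i in range(1, self.n_repeats)]

    @classmethod
    def from_repeat(cls, repeat_unit: str, n_repeats: int) -> "CcdnaConstruct":
        return cls(repeat_unit=repeat_unit, n_repeats=n_repeats)


def concatemerize(template: str, n: int) -> CcdnaConstruct:
    """Reverse-complement a template and concatenate it ``n`` times.

    This is the in-silico equivalent of rolling reverse transcription: the
    ccDNA repeat unit is the reverse complement of the ncRNA template.
    """
    template = validate_dna(template, what="template")
    if n < 1:
        raise ValidationError("n must be a positive integer")
    return CcdnaConstruct.from_repeat(revcomp(template), n)


# ---------------------------------------------------------------------------
# promoter scanning


@dataclass
class PromoterCall:
    """A detected (or diagnosed) sigma-70 promoter arrangement.

    ``arrangement`` is "canonical" (-35 upstream of -10, spacer within the
    allowed range) or "out_of_order" (-10 upstream of -35, as found within
    a single repeat; ``spacer_bp`` then reports the observed gap).
    """

    minus35_interval: tuple[int, int]
    minus10_interval: tuple[int, int]
    spacer_bp: int
    spans_junction: bool
    arrangement: str


def scan_promoters(
    ccdna: CcdnaConstruct,
    minus10_motif: str = "TATAAT",
    minus35_motif: str = "TTGACA",
    spacer_range: tuple[int, int] = (15, 19),
    max_mismatch: int = 0,
) -> list[PromoterCall]:
    """Scan a concatemer for canonical sigma-70 promoters.

    Returns all canonical calls (-35 then -10 with a spacer inside
    ``spacer_range``). When none exists, returns out-of-order diagnostics:
    each -10 occurrence paired with the nearest downstream -35, reporting
    the observed gap (91 bp for the reference repeat).
    """
    seq = ccdna.sequence
    m10 = find_motif(seq, minus10_motif.upper(), max_mismatch)
    m35 = find_motif(seq, minus35_motif.upper(), max_mismatch)
    lo, hi = spacer_range
    w10, w35 = len(minus10_motif), len(minus35_motif)

    def _spans(a: int, b: int) -> bool:
        return any(a <= j <= b for j in ccdna.junction_positions)

    calls: list[PromoterCall] = []
    for s35 in m35:
        e35 = s35 + w35 - 1
        for s10 in m10:
            spacer = s10 - e35 - 1
            if lo <= spacer <= hi:
                calls.append(
                    PromoterCall(
                        minus35_interval=(s35, e35),
                        minus10_interval=(s10, s10 + w10 - 1),
                        spacer_bp=spacer,
                        spans_junction=_spans(s35, s10 + w10 - 1),
                        arrangement="canonical",
                    )
                )
    if calls:
        return calls

    # no canonical promoter: diagnose the observed (out-of-order) layout
    diagnostics: list[PromoterCall] = []
    for s10 in m10:
        e10 = s10 + w10 - 1
        later = [s for s in m35 if s > e10]
        if not later:
            continue
        s35 = min(later)
        diagnostics.append(
            PromoterCall(
                minus35_interval=(s35, s35 + w35 - 1),
                minus10_interval=(s10, e10),
                spacer_bp=s35 - e10 - 1,
                spans_junction=_spans(s10, s35 + w35 - 1),
                arrangement="out_of_order",
            )
        )
    return diagnostics


# ---------------------------------------------------------------------------
# ORF scanning


@dataclass
class OrfCall:
    """Stop-codon content of one reading frame of a concatemer."""

    frame: int
    start_position: int | None
    stop_positions: list[int]
    spans_junction: bool
    frame_preserving: bool
    translation: str


def scan_orfs(ccdna: CcdnaConstruct) -> list[OrfCall]:
    """Report stop content for each of the three frames of the concatemer.

    ``frame_preserving`` is a property of the repeat (length divisible by
    three: the same frame continues across every junction). A frame
    ``spans_junction`` when its longest stop-free stretch contains a repeat
    boundary; a fully stop-free frame on a >= 2-repeat concatemer always
    does.
    """
    seq = ccdna.sequence
    if len(seq) < 3:
        raise ValidationError("sequence shorter than one codon")
    frame_preserving = len(ccdna.repeat_unit) % 3 == 0
    calls = []
    for f in range(3):
        aa = translate(seq[f:])
        stops = [f + 3 * i + 1 for i, c in enumerate(aa) if c == "*"]
        # longest stop-free codon stretch, as a 1-based nucleotide interval
        best = (0, -1, -1)  # (#codons, start_nt, end_nt)
        prev_stop_codon = -1
        stop_codons = [i for i, c in enumerate(aa) if c == "*"] + [len(aa)]
        for s in stop_codons:
            n_codons = s - prev_stop_codon - 1
            if n_codons > best[0]:
                start_nt = f + 3 * (prev_stop_codon + 1) + 1
                best = (n_codons, start_nt, f + 3 * s)
            prev_stop_codon = s
        spans = (
            ccdna.n_repeats >= 2
            and best[0] > 0
            and any(best[1] <= j <= best[2] for j in ccdna.junction_positions)
        )
        atg = seq.find("ATG", f)
        while atg != -1 and (atg - f) % 3 != 0:
            atg = seq.find("ATG", atg + 1)
        calls.append(
            OrfCall(
                frame=f,
                start_position=atg + 1 if atg != -1 else None,
                stop_positions=stops,
                spans_junction=spans,
                frame_preserving=frame_preserving,
                translation=aa,
            )
        )
    return calls


def stop_free_frames(calls: list[OrfCall]) -> list[OrfCall]:
    """Convenience filter: frames without any stop codon."""
    return [c for c in calls if not c.stop_positions]


# ---------------------------------------------------------------------------
# RBS / start codon


@dataclass
class RbsReport:
    """Start-codon and ribosome-binding-site context downstream of a -10."""

    window_interval: tuple[int, int]
    start_codon_position: int | None
    rbs_position: int | None
    truncated: bool


def locate_rbs(
    ccdna: CcdnaConstruct,
    promoter: PromoterCall,
    offset: int = 13,
    window: int = 15,
    rbs_motif: str = "GAG",
) -> RbsReport:
    """Locate the start codon ~``offset`` nt downstream of a canonical -10.

    The search window begins after an ``offset``-nt gap following the -10
    motif end. The first ATG in the window is reported, along with any
    ``rbs_motif`` occurrence between the -10 end and that ATG.
    """
    if promoter.arrangement != "canonical":
        raise ValidationError("locate_rbs requires a canonical promoter call")
    seq = ccdna.sequence
    e10 = promoter.minus10_interval[1]
    win_start = e10 + offset + 1
    win_end = win_start + window - 1
    truncated = win_end > len(seq)
    if truncated:
        warnings.warn("RBS window extends past the sequence end; partial report")
        win_end = len(seq)
    window_seq = seq[win_start - 1 : win_end]
    atg = window_seq.find("ATG")
    start_pos = win_start + atg if atg != -1 else None
    rbs_pos = None
    if start_pos is not None:
        upstream = seq[e10 : start_pos - 1]
        hit = upstream.rfind(rbs_motif)
        if hit != -1:
            rbs_pos = e10 + hit + 1
    return RbsReport((win_start, win_end), start_pos, rbs_pos, truncated)


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationProfile:
    """Per-column conservation of a nucleotide alignment, in bits.

    Conservation is the difference from maximum entropy: 2 - H(column),
    with H over A/C/G/T frequencies (gaps excluded). Columns with > 50%
    gaps are reported as missing (NaN) and listed in ``missing_columns``.
    """

    per_position: np.ndarray
    window: int
    smoothed: np.ndarray
    missing_columns: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.per_position) + 1),
                "conservation_bits": self.per_position,
                "smoothed": self.smoothed,
            }
        )


def conservation_profile(
    alignment: list[str], window: int = 10
) -> ConservationProfile:
    """Column-entropy conservation profile of an aligned set of sequences."""
    if len(alignment) < 2:
        raise ValidationError("need at least two aligned sequences")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValidationError("ragged alignment: unequal sequence lengths")
    rows = np.array([list(s.upper()) for s in alignment])
    n_cols = rows.shape[1]
    values = np.full(n_cols, np.nan)
    missing: list[int] = []
    for j in range(n_cols):
        col = rows[:, j]
        counts = np.array([(col == b).sum() for b in "ACGT"], dtype=float)
        n_gap = len(col) - counts.sum()
        if n_gap > 0.5 * len(col) or counts.sum() == 0:
            missing.append(j + 1)
            continue
        p = counts[counts > 0] / counts.sum()
        values[j] = 2.0 + float(np.sum(p * np.log2(p)))
    smoothed = (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return ConservationProfile(values, window, smoothed, missing)


# ---------------------------------------------------------------------------
# restriction digest


def digest(
    sequence: str, site: str = "GANTC", cut_offset: int = 1
) -> list[int]:
    """In-silico restriction digest; returns ordered fragment lengths.

    Default is the HinfI site G^ANTC (cut after the first base of every
    occurrence). Fragment lengths always sum to the input length.
    """
    sequence = validate_dna(sequence, what="digest input")
    pattern = iupac_regex(site)
    cuts = sorted(
        {m.start() + cut_offset for m in pattern.finditer(sequence)
         if 0 < m.start() + cut_offset < len(sequence)}
    )
    bounds = [0] + cuts + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# randomized-repeat null


#: Fixed elements of the reference repeat retained by the null generator:
#: -10 and -35 hexamers, the TGTTA junction (TGT repeat tail + TA repeat
#: head) and the GAG ribosome-binding site.
DEFAULT_FIXED_ELEMENTS = {
    "junction_head": ("TA", 1),
    "minus10": ("TATAAT", 13),
    "rbs": ("GAG", 23),
    "minus35": ("TTGACA", 110),
    "junction_tail": ("TGT", 118),
}


@dataclass
class RandomRepeatSpec:
    """Parameters of the randomized-repeat null model.

    Gap positions between the fixed elements are filled with codons drawn
    uniformly from the 61 sense codons of the standard code; the repeat is
    then concatemerized (default 20 copies) and translated.
    """

    repeat_length: int = 120
    fixed_elements: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_ELEMENTS)
    )
    codon_alphabet: tuple[str, ...] = SENSE_CODONS
    n_concat: int = 20
    seed: int = 0


@dataclass
class RandomRepeatResult:
    repeat: str
    construct: CcdnaConstruct
    translation: str
    frame: int


def random_repeat(spec: RandomRepeatSpec) -> RandomRepeatResult:
    """Generate one randomized repeat, its concatemer, and a translation.

    Deterministic given ``spec.seed``. The translation reported is of the
    frame with the fewest stop codons (lowest frame on ties), mirroring how
    the reading frame of interest is the one an ORF scan would keep.
    """
    L = spec.repeat_length
    occupied = np.zeros(L, dtype=bool)
    slots: list[str | None] = [None] * L
    for name, (elem, start) in spec.fixed_elements.items():
        end = start + len(elem) - 1
        if not (1 <= start <= end <= L):
            raise LayoutError(f"fixed element {name!r} outside the repeat")
        if occupied[start - 1 : end].any():
            raise LayoutError(f"fixed element {name!r} overlaps another element")
        occupied[start - 1 : end] = True
        for i, base in enumerate(elem):
            slots[start - 1 + i] = base

    rng = np.random.default_rng(spec.seed)
    i = 0
    while i < L:
        if slots[i] is not None:
            i += 1
            continue
        j = i
        while j < L and slots[j] is None:
            j += 1
        gap_len = j - i
        n_codons = -(-gap_len // 3)
        picks = rng.integers(0, len(spec.codon_alphabet), size=n_codons)
        fill = "".join(spec.codon_alphabet[idx] for idx in picks)
        for offset in range(gap_len):
            slots[i + offset] = fill[offset]
        i = j
    repeat = "".join(slots)  # type: ignore[arg-type]
    construct = CcdnaConstruct.from_repeat(repeat, spec.n_concat)
    frames = [translate(construct.sequence[f:]) for f in range(3)]
    frame = int(np.argmin([aa.count("*") for aa in frames]))
    return RandomRepeatResult(repeat, construct, frames[frame], frame)


# ---------------------------------------------------------------------------
# protein properties


def protein_properties(aa_sequence: str) -> dict[str, float]:
    """GRAVY (mean Kyte–Doolittle hydropathy), hydrophobic fraction, length."""
    if not aa_sequence:
        raise ValidationError("empty amino-acid sequence")
    aa_sequence = aa_sequence.upper()
    bad = set(aa_sequence) - _AA20
    if bad:
        raise ValidationError(f"unknown residues: {sorted(bad)}")
    analysis = ProteinAnalysis(aa_sequence)
    hydrophobic = sum(aa_sequence.count(r) for r in HYDROPHOBIC_RESIDUES)
    return {
        "gravy": analysis.gravy(),
        "hydrophobic_fraction": hydrophobic / len(aa_sequence),
        "length": len(aa_sequence),
    }
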