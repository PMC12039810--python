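"""Mechanistic simulation of rolling reverse transcription.

The generator produces ncRNA loci with the reference architecture (a
280-nt ncRNA whose central 120-nt template is bracketed by ACA motifs,
carries the promoter/ORF geometry on its reverse complement and ends in a
PBS annealed to the covalent "GATAT" primer), ortholog families for
conservation analysis, and ccDNA molecules with a full ground-truth event
log:

* minus-strand synthesis starts at the primer (first emitted bases
  "GATAT", the complement of the PBS) and runs down the template;
* at each completed repeat the RT jumps from template base 29 back to 148
  (Category 1), building tandem minus-strand repeats;
* stochastically, at a junction, synthesis reverses onto the nascent
  strand (Category 2; the final minus repeat stops two bases short and
  the plus block starts a few bases in, so detected reversals read
  31- -> 34+), producing y <= x plus-strand repeats (Category 3 jumps at
  their junctions) — an elongated DNA hairpin;
* when the plus block copies all the way back to the primer (y == x) the
  RT may read through into the ncRNA 3' domain (Category 4).

Sequencing is emulated with per-base substitution/insertion/deletion
errors and fixed adapters (long reads), random fragmentation with strand
labels and spike-in counts (short reads), or 3'-anchored RNP reads for
primer-extension logos.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import SENSE_CODONS, revcomp, translate
from .errors import LayoutError, ValidationError
from .jumpmap import MINUS, PLUS, build_index
from .locus import NcrnaLocus

# fixed 20-nt sequencing adapters used by the long-read emulation
DEFAULT_ADAPTER_5 = "CCTGTACTTCGTTCAGTTAC"
DEFAULT_ADAPTER_3 = "GCAATACGTAACTGAACGAA"

# hairpin-loop geometry relative to the template start: the final minus
# repeat stops LOOP_TRUNC bases into the template and the plus block
# resumes LOOP_SKIP bases in, so reversal jumps are (start+2)- -> (start+5)+
LOOP_TRUNC = 2
LOOP_SKIP = 5

_HEAD_FIXED = {  # repeat-unit coordinates (1-based) of the head elements
    1: "TA",  # junction head: with the TGT tail reads TGTTA across junctions
    3: "GATAT",  # complement of the PBS; minus-strand synthesis starts here
    13: "TATAAT",  # -10 promoter hexamer
    23: "GAG",  # ribosome-binding site
    32: "ATG",  # neo start codon, 13 nt downstream of the -10 end
    50: "GACTC",  # the single HinfI (GANTC) site of the repeat
}
_HEAD_LEN = 55  # head block incl. the free single base at position 55
_TAIL_FIXED = ("TTGACA", 2, "TGT")  # -35, two free bases, TGT junction tail
_BASE_VAR_CODONS = 18  # variable codons of the 120-nt reference repeat
_FREE_HEAD_CODON_STARTS = (8, 20, 26, 29, 35, 38, 41, 44, 47)
_FREE_HEAD_BASES = (11, 12, 19, 55)


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: str = ""


@dataclass
class TruthJump:
    from_position: int
    from_strand: str
    to_position: int
    to_strand: str
    category: int


@dataclass
class SimTruth:
    """Ground-truth construction trace of one simulated molecule."""

    read_id: str
    jumps: list[TruthJump]
    x: int
    y: int
    start_position: int
    has_primer: bool
    readthrough: bool
    minus_length: int
    error_positions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return self.x + self.y


@dataclass
class ErrorModel:
    substitution: float = 0.02
    insertion: float = 0.01
    deletion: float = 0.01

    def __post_init__(self) -> None:
        for rate in (self.substitution, self.insertion, self.deletion):
            if not 0 <= rate < 1:
                raise ValidationError("error rates must be in [0, 1)")


@dataclass
class SimConfig:
    """Study conditions for the rolling-RT simulation."""

    locus: NcrnaLocus
    n_reads: int = 10_000
    mean_repeats: float = 5.0  # zero-truncated geometric repeat-count law
    p_reversal: float = 0.5  # per-molecule probability of a Category-2 switch
    p_readthrough: float = 0.5  # Category-4 probability given y == x
    error_model: ErrorModel = field(default_factory=ErrorModel)
    adapter_5: str = DEFAULT_ADAPTER_5
    adapter_3: str = DEFAULT_ADAPTER_3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_reversal, self.p_readthrough):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.mean_repeats < 1:
            raise ValidationError("mean_repeats must be >= 1")


# ---------------------------------------------------------------------------
# locus generation


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]


def _assemble_repeat(
    rng: np.random.Generator, n_var_codons: int, trim: int = 0
) -> str:
    """One repeat unit from the fixed layout plus random sense-codon fill.

    ``trim`` bases are removed from the end of the variable block to build
    frame-breaking (length not divisible by 3) repeats.
    """
    head = [""] * _HEAD_LEN
    for start, elem in _HEAD_FIXED.items():
        for i, b in enumerate(elem):
            head[start - 1 + i] = b
    for s in _FREE_HEAD_CODON_STARTS:
        codon = _random_codons(rng, 1)[0]
        head[s - 1 : s + 2] = list(codon)
    for p in _FREE_HEAD_BASES:
        head[p - 1] = _random_bases(rng, 1)
    var = "".join(_random_codons(rng, n_var_codons))
    if trim:
        var = var[: len(var) - trim]
    m35, n_free, tgt = _TAIL_FIXED
    tail = m35 + _random_bases(rng, n_free) + tgt
    return "".join(head) + var + tail


def _count(sub_regex, s: str) -> int:
    import re

    return len(re.findall(f"(?=({sub_regex}))", s))


def _boundary_unmapped(index, a_tail: str, b_head: str) -> bool:
    """No chimeric k-mer spanning the A|B boundary maps to the ncRNA."""
    s = a_tail + b_head
    k = index.k
    return all(s[i : i + k] not in index.map for i in range(len(s) - k + 1))


def _locus_ok(locus: NcrnaLocus, adapter_5: str, adapter_3: str) -> bool:
    seq = locus.sequence
    ts, te = locus.template_start, locus.template_end
    repeat = locus.repeat_unit
    doubled = repeat + repeat
    L = len(repeat)
    if _count("TATAAT", doubled) != 2 or _count("TTGACA", doubled) != 2:
        return False
    if _count("GA[ACGT]TC", doubled) != 2:
        return False
    # no decoy ACA that the bracket-selection band could pick up
    for p in list(range(ts - 3, ts)) + list(range(ts + 90, te + 1)):
        if seq[p - 1 : p + 2] == "ACA":
            return False
    if L % 3 == 0 and "*" in translate(doubled[1:]):
        return False
    index = build_index(seq, 11, template_interval=(ts, te))
    if index.ambiguous:
        return False
    pbs_hi = locus.pbs_interval[1]
    k = index.k
    w = k - 1
    rc = revcomp
    boundaries = [
        (repeat[-w:], repeat[:w]),  # Category-1 junction
        (rc(seq[ts + LOOP_TRUNC - 1 : ts + LOOP_TRUNC - 1 + w]),
         seq[ts + LOOP_SKIP - 1 : ts + LOOP_SKIP - 1 + w]),  # reversal turn
        (seq[te - w : te], seq[ts - 1 : ts - 1 + w]),  # Category-3 junction
        # Category-4 read-through: the first chimeric window always maps
        # (the extension starts with comp(A280) = T = the base after the
        # PBS), extending the plus diagonal to the 3' base after the PBS;
        # only deeper chimeric windows must stay unmapped.
        (seq[pbs_hi - w + 1 : pbs_hi], rc(seq[-w:])),
        (rc(seq[te : te + w]), adapter_3[:w]),  # read-through end | adapter
        (adapter_5[-w:], rc(seq[pbs_hi - w : pbs_hi])),  # adapter | primer start
        (repeat[-w:], adapter_3[:w]),
        (seq[te - w : te], adapter_3[:w]),
        (seq[pbs_hi - w : pbs_hi], adapter_3[:w]),
    ]
    if not all(_boundary_unmapped(index, a, b) for a, b in boundaries):
        return False
    # adapter-internal windows must not map either
    for adapter in (adapter_5, adapter_3):
        if any(
            adapter[i : i + k] in index.map for i in range(len(adapter) - k + 1)
        ):
            return False
    return True


def make_locus(
    seed: int,
    template_length: int = 120,
    ncrna_length: int = 280,
    max_attempts: int = 500,
) -> NcrnaLocus:
    """Generate a reference-architecture ncRNA locus.

    The template (ncRNA positions 29 .. 28+L) is the reverse complement of
    a repeat unit carrying the canonical fixed elements; its reverse
    complement therefore starts with the leading ACA bracket, the second
    bracket follows immediately after the template, and the PBS reverse
    complement is the "GATAT" primer. Free positions are filled with sense
    codons in the neo frame. Rejection sampling guarantees unique 11-mer
    hashing of the whole ncRNA (both strands), single promoter/HinfI
    motifs per repeat, and that every boundary-spanning chimeric 11-mer
    the simulator can produce is unmappable — so jump detection can be
    exact at zero sequencing error.
    """
    if template_length >= ncrna_length - 40:
        raise LayoutError("template_length too large for ncrna_length")
    base_len = template_length + (-template_length) % 3
    n_var = (base_len - 66) // 3
    if n_var < 0:
        raise LayoutError("template_length too short for the fixed layout")
    trim = base_len - template_length
    rng = np.random.default_rng(seed)
    tail3_len = ncrna_length - 28 - template_length - 3
    if tail3_len < 15:
        raise LayoutError("ncrna_length leaves no room for the 3' domain")
    for _ in range(max_attempts):
        repeat = _assemble_repeat(rng, n_var, trim)
        template = revcomp(repeat)
        # base 28 must not complement the repeat head or the 3' adapter
        # start, which would let molecule-end chimeras map near the
        # template 5' boundary
        forbidden_28 = {revcomp(repeat[0]), revcomp(DEFAULT_ADAPTER_3[0])}
        allowed_28 = [b for b in "ACGT" if b not in forbidden_28]
        handle = _random_bases(rng, 27) + allowed_28[int(rng.integers(0, len(allowed_28)))]
        # the ncRNA ends at A280; the penultimate base must differ from T
        # so read-through chimeras cannot extend past the first duplicated
        # window
        penult = "ACG"[int(rng.integers(0, 3))]
        tail3 = _random_bases(rng, tail3_len - 2) + penult + "A"
        seq = handle + template + "ACA" + tail3
        te = 28 + template_length
        locus = NcrnaLocus(
            id=f"synthetic-locus-s{seed}",
            sequence=seq,
            template_start=29,
            template_end=te,
            aca_positions=[29, te + 1],
            pbs_interval=(te - 6, te - 2),
        )
        if _locus_ok(locus, DEFAULT_ADAPTER_5, DEFAULT_ADAPTER_3):
            return locus
    raise LayoutError(f"could not satisfy locus constraints in {max_attempts} tries")


# ---------------------------------------------------------------------------
# ortholog families


@dataclass
class Family:
    """A set of ortholog loci plus their gapped alignment."""

    loci: list[NcrnaLocus]
    alignment: list[tuple[str, str]]  # (id, aligned sequence)


#: Template lengths seen across the ortholog family, weighted to mirror a
#: distribution where 117 nt dominates, the reference is 120 nt and a few
#: members are 111 or 129 nt. All are divisible by three.
FAMILY_LENGTHS = (111, 117, 120, 129)
FAMILY_LENGTH_WEIGHTS = (0.10, 0.55, 0.25, 0.10)


def make_family(
    seed: int,
    n_members: int = 42,
    lengths: list[int] | None = None,
    codon_mut_prob: float = 0.3,
    flank_mut_prob: float = 0.02,
) -> Family:
    """Generate an ortholog ncRNA family with a consistent alignment.

    All members share the fixed elements (brackets, promoter hexamers,
    junction, RBS, start, HinfI site) and differ at the free codons, so
    the conservation profile dips inside the template at variable
    positions while fixed-element columns stay invariant. Member lengths
    vary by whole codons in the variable block; shorter members carry
    alignment gaps there.
    """
    if n_members < 2:
        raise ValidationError("need at least two family members")
    rng = np.random.default_rng(seed)
    ref = make_locus(int(rng.integers(0, 2**31 - 1)), 120)
    handle_ref = ref.sequence[:28]
    tail_ref = ref.sequence[28 + 120 + 3 :]
    repeat_ref = ref.repeat_unit
    var_ref = [
        repeat_ref[_HEAD_LEN + 3 * i : _HEAD_LEN + 3 * i + 3]
        for i in range(_BASE_VAR_CODONS)
    ]
    head_ref = list(repeat_ref[:_HEAD_LEN])
    tail_unit_ref = repeat_ref[_HEAD_LEN + 3 * _BASE_VAR_CODONS :]

    if lengths is None:
        lengths = [120] + [
            int(rng.choice(FAMILY_LENGTHS, p=FAMILY_LENGTH_WEIGHTS))
            for _ in range(n_members - 1)
        ]
    if len(lengths) != n_members:
        raise ValidationError("lengths must have one entry per member")
    max_m = max((L - 66) // 3 for L in lengths)
    max_m = max(max_m, _BASE_VAR_CODONS)

    def _mut_flank(s: str) -> str:
        out = list(s)
        for i in range(len(out)):
            if rng.random() < flank_mut_prob:
                out[i] = "ACGT"[rng.integers(0, 4)]
        return "".join(out)

    loci: list[NcrnaLocus] = []
    rows: list[tuple[str, str]] = []
    for idx, L in enumerate(lengths):
        if L % 3 != 0 or L < 66:
            raise ValidationError("family template lengths must be codon multiples")
        m = (L - 66) // 3
        var = list(var_ref[:m])
        while len(var) < m:
            var.append(_random_codons(rng, 1)[0])
        if idx > 0:
            var = [
                _random_codons(rng, 1)[0] if rng.random() < codon_mut_prob else c
                for c in var
            ]
            head = list(head_ref)
            for s in _FREE_HEAD_CODON_STARTS:
                if rng.random() < codon_mut_prob:
                    head[s - 1 : s + 2] = list(_random_codons(rng, 1)[0])
            for p in _FREE_HEAD_BASES:
                if rng.random() < codon_mut_prob / 3:
                    head[p - 1] = "ACGT"[rng.integers(0, 4)]
            tail_unit = (
                tail_unit_ref[:6]
                + _mut_flank(tail_unit_ref[6:8])
                + tail_unit_ref[8:]
            )
            handle = _mut_flank(handle_ref)
            tail3 = _mut_flank(tail_ref)
        else:
            head, tail_unit, handle, tail3 = (
                list(head_ref), tail_unit_ref, handle_ref, tail_ref,
            )
        repeat = "".join(head) + "".join(var) + tail_unit
        template = revcomp(repeat)
        seq = handle + template + "ACA" + tail3
        te = 28 + L
        member_id = f"ortholog-{idx:02d}-L{L}"
        loci.append(
            NcrnaLocus(
                id=member_id,
                sequence=seq,
                template_start=29,
                template_end=te,
                aca_positions=[29, te + 1],
                pbs_interval=(te - 6, te - 2),
            )
        )
        # aligned template: revcomp(tail_unit) | gaps | revcomp(var) | revcomp(head)
        aligned_template = (
            revcomp(tail_unit)
            + "-" * (3 * (max_m - m))
            + revcomp("".join(var))
            + revcomp("".join(head))
        )
        rows.append((member_id, handle + aligned_template + "ACA" + tail3))
    assert len({len(r[1]) for r in rows}) == 1
    return Family(loci, rows)


# ---------------------------------------------------------------------------
# molecule synthesis


def _zt_geometric(rng: np.random.Generator, mean: float) -> int:
    """Zero-truncated geometric draw with the given mean (support 1, 2, ...)."""
    return int(rng.geometric(1.0 / mean))


def simulate_synthesis(config: SimConfig) -> list[tuple[str, SimTruth]]:
    """Simulate ccDNA molecules with per-molecule ground-truth event logs."""
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    seq = locus.sequence
    ts, te = locus.template_start, locus.template_end
    pbs_hi = locus.pbs_interval[1]
    n = len(seq)
    out: list[tuple[str, SimTruth]] = []
    for i in range(config.n_reads):
        x = _zt_geometric(rng, config.mean_repeats)
        reversal = rng.random() < config.p_reversal
        jumps: list[TruthJump] = []
        minus_parts: list[str] = []
        for j in range(1, x + 1):
            hi = pbs_hi if j == 1 else te
            lo = ts + LOOP_TRUNC if (reversal and j == x) else ts
            minus_parts.append(revcomp(seq[lo - 1 : hi]))
            if j < x:
                jumps.append(TruthJump(ts, MINUS, te, MINUS, 1))
        y = 0
        readthrough = False
        plus_parts: list[str] = []
        if reversal:
            y = int(rng.integers(1, x + 1))
            jumps.append(TruthJump(ts + LOOP_TRUNC, MINUS, ts + LOOP_SKIP, PLUS, 2))
            for j in range(1, y + 1):
                lo = ts + LOOP_SKIP if j == 1 else ts
                hi = pbs_hi if (j == y and y == x) else te
                plus_parts.append(seq[lo - 1 : hi])
                if j < y:
                    jumps.append(TruthJump(te, PLUS, ts, PLUS, 3))
            if y == x and rng.random() < config.p_readthrough:
                readthrough = True
                # the first extension base, comp(A280) = T, matches the
                # template base after the PBS, so the detectable plus
                # diagonal runs one base past the PBS before the jump
                jumps.append(TruthJump(pbs_hi + 1, PLUS, n, MINUS, 4))
                plus_parts.append(revcomp(seq[te:]))
        minus_block = "".join(minus_parts)
        molecule = minus_block + "".join(plus_parts)
        out.append(
            (
                molecule,
                SimTruth(
                    read_id=f"read_{i:06d}",
                    jumps=jumps,
                    x=x,
                    y=y,
                    start_position=pbs_hi,
                    has_primer=True,
                    readthrough=readthrough,
                    minus_length=len(minus_block),
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# sequencing emulation


def _apply_errors(
    seq: str, rng: np.random.Generator, em: ErrorModel
) -> tuple[str, list[tuple[int, str]]]:
    n = len(seq)
    dels = rng.random(n) < em.deletion
    subs = rng.random(n) < em.substitution
    ins = rng.random(n) < em.insertion
    sub_picks = rng.integers(0, 3, size=n)
    ins_picks = rng.integers(0, 4, size=n)
    out: list[str] = []
    errors: list[tuple[int, str]] = []
    for i, base in enumerate(seq):
        if dels[i]:
            errors.append((i, "del"))
        else:
            if subs[i]:
                others = [b for b in "ACGT" if b != base]
                out.append(others[sub_picks[i]])
                errors.append((i, "sub"))
            else:
                out.append(base)
        if ins[i]:
            out.append("ACGT"[ins_picks[i]])
            errors.append((i, "ins"))
    return "".join(out), errors


def sequence_reads(
    sims: list[tuple[str, SimTruth]],
    error_model: ErrorModel | None = None,
    adapters: tuple[str, str] = (DEFAULT_ADAPTER_5, DEFAULT_ADAPTER_3),
    seed: int = 0,
) -> tuple[list[SimRead], list[SimTruth]]:
    """Turn molecules into adapter-flanked reads with logged errors."""
    em = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    a5, a3 = adapters
    reads: list[SimRead] = []
    truths: list[SimTruth] = []
    for molecule, truth in sims:
        mutated, errors = _apply_errors(molecule, rng, em)
        seq = a5 + mutated + a3
        reads.append(SimRead(truth.read_id, seq, "I" * len(seq)))
        truths.append(replace(truth, error_positions=errors))
    return reads, truths


# ---------------------------------------------------------------------------
# short-read emulation


@dataclass
class ShortReadSet:
    reads: list[str]
    labels: list[str]  # "plus" / "minus" / "spike"
    spike_sequence: str
    spike_count: int
    mode: str


def simulate_shortreads(
    sims: list[tuple[str, SimTruth]],
    mode: str = "untreated",
    seed: int = 0,
    n_fragments: int = 2000,
    fragment_length: tuple[int, int] = (50, 200),
    spike_count: int = 1000,
    spike_length: int = 200,
) -> ShortReadSet:
    """Randomly fragment molecules into strand-labeled short reads.

    In ``untreated`` mode only single-stranded (reversal-free, pure minus)
    molecules are accessible; hairpin molecules behave as dsDNA and are
    skipped. In ``s1`` mode hairpins are opened and fragments are drawn
    from minus and plus blocks alike. ``spike_count`` copies of a fixed
    single-strand control are always appended (label "spike").
    """
    if not sims:
        raise ValidationError("no molecules to fragment")
    if mode not in ("untreated", "s1"):
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, str]] = []  # (sequence, strand label)
    for molecule, truth in sims:
        minus_block = molecule[: truth.minus_length]
        plus_block = molecule[truth.minus_length :]
        if truth.y == 0:
            blocks.append((minus_block, MINUS))
        elif mode == "s1":
            blocks.append((minus_block, MINUS))
            if plus_block:
                blocks.append((plus_block, PLUS))
    reads: list[str] = []
    labels: list[str] = []
    if blocks:
        lengths = np.array([len(b) for b, _ in blocks], dtype=float)
        probs = lengths / lengths.sum()
        lo, hi = fragment_length
        for _ in range(n_fragments):
            bi = int(rng.choice(len(blocks), p=probs))
            block, label = blocks[bi]
            flen = min(int(rng.integers(lo, hi + 1)), len(block))
            start = int(rng.integers(0, len(block) - flen + 1))
            reads.append(block[start : start + flen])
            labels.append(label)
    spike = _random_bases(np.random.default_rng(seed + 7_919), spike_length)
    reads.extend([spike] * spike_count)
    labels.extend(["spike"] * spike_count)
    return ShortReadSet(reads, labels, spike, spike_count, mode)


# ---------------------------------------------------------------------------
# RNP primer-extension reads


def make_rnp_reads(
    locus: NcrnaLocus,
    n: int = 100,
    mode: str = "wt",
    mutant_pbs: str | None = None,
    read_span: int = 60,
) -> list[str]:
    """Reads of the ncRNA 3' end as captured from purified RNPs.

    ``wt`` reads carry the covalent primer (reverse complement of the PBS)
    directly after the ncRNA 3' terminus; ``rt_dead`` reads end at the
    terminus (primer synthesis needs the RT active site); ``pbs_mutant``
    reads carry the reverse complement of ``mutant_pbs`` instead.
    """
    tail = locus.sequence[-read_span:]
    if mode == "wt":
        ext = locus.primer
    elif mode == "rt_dead":
        ext = ""
    elif mode == "pbs_mutant":
        if not mutant_pbs:
            raise ValidationError("pbs_mutant mode needs mutant_pbs")
        ext = revcomp(mutant_pbs.upper())
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return [tail + ext] * n


__all__ = [
    "DEFAULT_ADAPTER_5",
    "DEFAULT_ADAPTER_3",
    "ErrorModel",
    "Family",
    "SimConfig",
    "SimRead",
    "SimTruth",
    "ShortReadSet",
    "TruthJump",
    "make_family",
    "make_locus",
    "make_rnp_reads",
    "sequence_reads",
    "simulate_shortreads",
    "simulate_synthesis",
]
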