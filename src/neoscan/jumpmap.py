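"""k-mer segmentation of long reads and template-jump analysis.

Reads are split into consecutive k-mers (default k=11, the minimum length
for unique hashing on the reference ncRNA) and each k-mer is assigned to
its position and strand on the ncRNA. Adjacent k-mers that map
non-adjacently define a template jump. Jump endpoints follow the jump-map
axis convention: the "from" coordinate is the mapped position of the
3' base of the 5' k-mer, the "to" coordinate is the mapped position of the
5' base of the 3' k-mer.

Jump categories (by strand pair of an off-diagonal transition):
  1  minus -> minus   repeat-junction jumps (template end -> start)
  2  minus -> plus    reversal to second-strand synthesis
  3  plus  -> plus    second-strand repeat junctions
  4  plus  -> minus   read-through past the primer into the ncRNA 3' domain
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import revcomp, validate_dna
from .errors import NormalizationError, ValidationError
from .locus import NcrnaLocus

PLUS = "plus"
MINUS = "minus"
UNMAPPED = "unmapped"

_CATEGORY_BY_STRANDS = {
    (MINUS, MINUS): 1,
    (MINUS, PLUS): 2,
    (PLUS, PLUS): 3,
    (PLUS, MINUS): 4,
}


# ---------------------------------------------------------------------------
# index


@dataclass
class KmerIndex:
    """Unique k-mers of a ncRNA, both strands, keyed to anchor coordinates.

    The anchor of a k-mer is its first base in read orientation, expressed
    in 1-based ncRNA coordinates: a plus-strand k-mer starting at ncRNA
    position p anchors at p; the minus-strand k-mer of the same window
    anchors at p+k-1 (minus-strand positions decrease along a read).
    k-mers occurring more than once across the union of both strands are
    ambiguous and excluded from the map.
    """

    k: int
    map: dict[str, tuple[int, str]]
    ambiguous: set[str]
    reference_length: int
    min_unique_k: int | None
    junction_excluded: set[str] = field(default_factory=set)


def _strand_kmers(seq: str, k: int):
    """Yield (kmer, anchor, strand) over both strands of ``seq``."""
    n = len(seq)
    for p in range(n - k + 1):
        window = seq[p : p + k]
        yield window, p + 1, PLUS
        yield revcomp(window), p + k, MINUS


def _all_unique(seq: str, k: int) -> bool:
    seen = set()
    for kmer, _, _ in _strand_kmers(seq, k):
        if kmer in seen:
            return False
        seen.add(kmer)
    return True


def build_index(
    ncrna: str, k: int = 11, template_interval: tuple[int, int] | None = None
) -> KmerIndex:
    """Build the unique-k-mer index of a ncRNA (both strands).

    When ``template_interval`` is given, k-mers spanning the junction of
    the theoretical ccDNA are also treated as ambiguous. The template
    starts at the leading ACA bracket and a second ACA follows it, so the
    ccDNA junction sequence reproduces the ncRNA region spanning the
    template end and the second bracket: a read k-mer there can come from
    either source and has no unique position. Excluding those k-mers keeps
    junction jumps anchored at the template boundaries.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ncrna = validate_dna(ncrna, what="ncRNA")
    if len(ncrna) < k:
        raise ValidationError("ncRNA shorter than k")
    counts: Counter[str] = Counter(km for km, _, _ in _strand_kmers(ncrna, k))
    ambiguous = {km for km, c in counts.items() if c > 1}
    junction_excluded: set[str] = set()
    if template_interval is not None:
        ts, te = template_interval
        repeat = revcomp(ncrna[ts - 1 : te])
        if len(repeat) >= k:
            junction_ctx = repeat[-(k - 1) :] + repeat[: k - 1]
            for i in range(len(junction_ctx) - k + 1):
                w = junction_ctx[i : i + k]
                junction_excluded.update(
                    q for q in (w, revcomp(w)) if q in counts
                )
    mapping: dict[str, tuple[int, str]] = {}
    for kmer, anchor, strand in _strand_kmers(ncrna, k):
        if kmer not in ambiguous and kmer not in junction_excluded:
            mapping[kmer] = (anchor, strand)
    min_unique = next(
        (kk for kk in range(1, len(ncrna) + 1) if _all_unique(ncrna, kk)), None
    )
    return KmerIndex(k, mapping, ambiguous, len(ncrna), min_unique, junction_excluded)


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class WindowAssignment:
    """One read window mapped to the ncRNA (or unmapped)."""

    read_id: str
    read_offset: int  # 0-based window start within the read
    position: int | None
    strand: str


def trim_adapters(
    read: str, adapter_5: str, adapter_3: str, max_mismatch: int = 3
) -> str:
    """Strip adapters by near-exact prefix/suffix match.

    The emulated library ligates fixed adapters outside the molecule, so a
    Hamming comparison at the read ends is sufficient.
    """
    read = read.upper()

    def _close(a: str, b: str) -> bool:
        return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= max_mismatch

    if len(read) >= len(adapter_5) and _close(read[: len(adapter_5)], adapter_5.upper()):
        read = read[len(adapter_5) :]
    if len(read) >= len(adapter_3) and _close(read[-len(adapter_3) :], adapter_3.upper()):
        read = read[: -len(adapter_3)]
    return read


def segment_read(
    read: str, index: KmerIndex, read_id: str = "read"
) -> list[WindowAssignment]:
    """Assign every consecutive k-length window of a read to the ncRNA."""
    read = read.upper()
    k = index.k
    if len(read) < k:
        warnings.warn(f"{read_id}: read shorter than k={k}; empty segmentation")
        return []
    out = []
    for i in range(len(read) - k + 1):
        hit = index.map.get(read[i : i + k])
        if hit is None:
            out.append(WindowAssignment(read_id, i, None, UNMAPPED))
        else:
            out.append(WindowAssignment(read_id, i, hit[0], hit[1]))
    return out


# ---------------------------------------------------------------------------
# jumps


@dataclass
class Jump:
    """An off-diagonal transition between adjacent mapped k-mers."""

    read_id: str
    from_position: int
    from_strand: str
    to_position: int
    to_strand: str
    category: int | None = None
    from_offset: int = -1  # read offset of the 5' window


@dataclass
class Transition:
    """Any adjacent-mapped-window transition, diagonal or not."""

    read_id: str
    from_position: int
    from_strand: str
    to_position: int
    to_strand: str
    is_jump: bool
    from_offset: int


def _direction(strand: str) -> int:
    return 1 if strand == PLUS else -1


def transitions(
    assignments: list[WindowAssignment],
    k: int,
    diagonal_tolerance: int = 0,
    max_skip: int | None = None,
) -> list[Transition]:
    """All transitions between successive mapped windows of one read.

    Unmapped windows are skipped; a transition is only evaluated when at
    most ``max_skip`` unmapped windows separate the two mapped windows
    (beyond that the read is split). One base error voids k windows and a
    junction itself voids k-1, so errors flanking a junction void up to
    ~3k; the default allowance is 4k. The expected
    next position continues the current diagonal (+1 per window on plus,
    -1 on minus); deviations beyond ``diagonal_tolerance`` or any strand
    change are jumps.
    """
    if max_skip is None:
        max_skip = 4 * k
    mapped = [a for a in assignments if a.strand != UNMAPPED]
    out: list[Transition] = []
    for a, b in zip(mapped, mapped[1:]):
        gap = b.read_offset - a.read_offset
        if gap - 1 > max_skip:
            continue
        expected = a.position + _direction(a.strand) * gap
        is_jump = (b.strand != a.strand) or (
            abs(b.position - expected) > diagonal_tolerance
        )
        out.append(
            Transition(
                read_id=a.read_id,
                from_position=a.position + _direction(a.strand) * (k - 1),
                from_strand=a.strand,
                to_position=b.position,
                to_strand=b.strand,
                is_jump=is_jump,
                from_offset=a.read_offset,
            )
        )
    return out


def quantify_jumps(
    assignments: list[WindowAssignment],
    k: int = 11,
    diagonal_tolerance: int = 0,
    max_skip: int | None = None,
) -> list[Jump]:
    """Jumps of one read: non-adjacent mapping of adjacent k-mers."""
    return [
        Jump(
            read_id=t.read_id,
            from_position=t.from_position,
            from_strand=t.from_strand,
            to_position=t.to_position,
            to_strand=t.to_strand,
            from_offset=t.from_offset,
        )
        for t in transitions(assignments, k, diagonal_tolerance, max_skip)
        if t.is_jump
    ]


def classify_jumps(
    jumps: list[Jump], locus: NcrnaLocus | None = None
) -> tuple[list[Jump], dict[int, float]]:
    """Assign categories 1–4 by strand pair; fractions over all jumps.

    ``locus`` is accepted for interface symmetry (category definitions are
    purely strand-based).
    """
    classified = [
        replace(j, category=_CATEGORY_BY_STRANDS[(j.from_strand, j.to_strand)])
        for j in jumps
    ]
    counts = Counter(j.category for j in classified)
    total = sum(counts.values())
    fractions = {c: counts.get(c, 0) / total if total else 0.0 for c in (1, 2, 3, 4)}
    return classified, fractions


def jump_map(
    items: list[Transition] | list[Jump], include_diagonal: bool = True
) -> pd.DataFrame:
    """2-D count table over signed (from, to) coordinates.

    Signed coordinate = +position on the plus strand, -position on the
    minus strand. When given transitions, diagonal (non-jump) pairs are
    kept unless ``include_diagonal`` is False; the table total then equals
    the number of adjacent mapped pairs counted.
    """
    rows = []
    for it in items:
        if isinstance(it, Transition) and not include_diagonal and not it.is_jump:
            continue
        sign_from = 1 if it.from_strand == PLUS else -1
        sign_to = 1 if it.to_strand == PLUS else -1
        rows.append((sign_from * it.from_position, sign_to * it.to_position))
    if not rows:
        return pd.DataFrame(columns=["from_coord", "to_coord", "count"])
    df = pd.DataFrame(rows, columns=["from_coord", "to_coord"])
    return (
        df.value_counts().rename("count").reset_index().sort_values(
            ["from_coord", "to_coord"]
        ).reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# read structure


@dataclass
class ReadStructure:
    """Repeat composition of one read: x minus repeats then y plus repeats."""

    read_id: str
    n_minus_repeats: int
    n_plus_repeats: int
    total_repeats: int
    start_position: int | None
    has_primer_start: bool
    readthrough: bool


def read_structure(
    assignments: list[WindowAssignment],
    locus: NcrnaLocus,
    k: int = 11,
    diagonal_tolerance: int = 0,
    max_skip: int | None = None,
) -> ReadStructure:
    """Derive repeat counts and start context from one read's assignments.

    Repeat counts are junction-jump counts plus one per strand block
    (Category 1 for minus, Category 3 for plus). ``has_primer_start`` is
    true when the read's first window is mapped, minus strand, anchored at
    the PBS 3' end — i.e. the read begins with the DNA primer.
    """
    mapped = [a for a in assignments if a.strand != UNMAPPED]
    read_id = assignments[0].read_id if assignments else "read"
    if not mapped:
        return ReadStructure(read_id, 0, 0, 0, None, False, False)
    jumps, _ = classify_jumps(
        quantify_jumps(assignments, k, diagonal_tolerance, max_skip)
    )
    n_cat = Counter(j.category for j in jumps)
    has_minus = any(a.strand == MINUS for a in mapped)
    has_plus = any(a.strand == PLUS for a in mapped)
    x = n_cat.get(1, 0) + 1 if has_minus else 0
    y = n_cat.get(3, 0) + 1 if has_plus else 0
    first = mapped[0]
    pbs_end = locus.pbs_interval[1]
    has_primer_start = (
        first.read_offset == 0
        and first.strand == MINUS
        and first.position == pbs_end
    )
    return ReadStructure(
        read_id=read_id,
        n_minus_repeats=x,
        n_plus_repeats=y,
        total_repeats=x + y,
        start_position=first.position,
        has_primer_start=has_primer_start,
        readthrough=n_cat.get(4, 0) > 0,
    )


# ---------------------------------------------------------------------------
# 3' extension consensus


def detect_3prime_extension(
    reads: list[str],
    locus: NcrnaLocus,
    anchor_length: int = 12,
    max_extension: int = 10,
) -> tuple[pd.DataFrame, str, int]:
    """Consensus of bases appended after the ncRNA 3' end.

    Each read is anchored at the ncRNA 3' terminus by exact match of the
    terminal ``anchor_length`` bases; the bases following the anchor are
    collected into a position-frequency matrix. The majority-rule consensus
    runs over positions covered by at least half of the anchored reads.

    Returns (PFM with one row per position and A/C/G/T columns, consensus,
    number of anchored reads).
    """
    anchor = locus.sequence[-anchor_length:]
    counts = np.zeros((max_extension, 4), dtype=int)
    bases = "ACGT"
    n_anchored = 0
    for read in reads:
        idx = read.upper().rfind(anchor)
        if idx == -1:
            continue
        n_anchored += 1
        tail = read.upper()[idx + anchor_length : idx + anchor_length + max_extension]
        for pos, base in enumerate(tail):
            if base in bases:
                counts[pos, bases.index(base)] += 1
    pfm = pd.DataFrame(counts, columns=list(bases))
    pfm.insert(0, "position", np.arange(1, max_extension + 1))
    if n_anchored == 0:
        warnings.warn("no reads anchored at the ncRNA 3' end")
        return pfm, "", 0
    consensus = []
    for pos in range(max_extension):
        if counts[pos].sum() < 0.5 * n_anchored:
            break
        consensus.append(bases[int(np.argmax(counts[pos]))])
    return pfm, "".join(consensus), n_anchored


# ---------------------------------------------------------------------------
# chimeric read layout


def layout_chimeric_reads(
    assignments_by_read: list[list[WindowAssignment]],
) -> tuple[pd.DataFrame, int]:
    """Plot-segment table for chimeric-read visualisation.

    For each read, the longest run of consecutively mapping windows (same
    strand, positions advancing one per window; leftmost run on ties)
    defines the x frame: windows in the run sit at their mapped positions
    and every other window is placed at its read-relative offset from that
    run. y is the read rank; the color index of a segment is its mapped
    position. Reads with no mapped windows are excluded and counted.
    """
    rows = []
    n_excluded = 0
    rank = 0
    for assignments in assignments_by_read:
        mapped = [a for a in assignments if a.strand != UNMAPPED]
        if not mapped:
            n_excluded += 1
            continue
        # maximal runs of consecutive offsets on one diagonal
        runs: list[list[WindowAssignment]] = [[mapped[0]]]
        for prev, cur in zip(mapped, mapped[1:]):
            contiguous = (
                cur.read_offset == prev.read_offset + 1
                and cur.strand == prev.strand
                and cur.position == prev.position + _direction(prev.strand)
            )
            if contiguous:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        best = max(runs, key=len)  # max() keeps the leftmost on ties
        o0 = best[0].read_offset
        p0 = best[0].position
        d = _direction(best[0].strand)
        read_id = assignments[0].read_id
        for a in assignments:
            rows.append(
                {
                    "read_id": read_id,
                    "y_rank": rank,
                    "read_offset": a.read_offset,
                    "x_coord": p0 + d * (a.read_offset - o0),
                    "position": a.position,
                    "strand": a.strand,
                    "in_longest_run": a in best,
                }
            )
        rank += 1
    return pd.DataFrame(rows), n_excluded


# ---------------------------------------------------------------------------
# strand-specific counts


@dataclass
class StrandCounts:
    """Raw and spike-normalized strand-specific read counts.

    ``raw`` is keyed by (read class, strand) with read classes "template"
    (read maps within the template region) and "junction" (read contains
    juxtaposed template regions). Normalized counts divide by
    spike_reads × volume_equivalents, making counts comparable across
    libraries with different single-strand-control recovery.
    """

    raw: dict[tuple[str, str], float]
    spike_reads: float
    volume_equivalents: float
    normalized: dict[tuple[str, str], float] | None = None


def normalize_strand_counts(counts: StrandCounts) -> StrandCounts:
    """normalized = raw / (spike_reads * volume_equivalents)."""
    if counts.spike_reads <= 0:
        raise NormalizationError("spike_reads must be > 0")
    if counts.volume_equivalents <= 0:
        raise NormalizationError("volume_equivalents must be > 0")
    scale = counts.spike_reads * counts.volume_equivalents
    counts.normalized = {k: v / scale for k, v in counts.raw.items()}
    return counts


def count_strand_reads(
    reads: list[str],
    index: KmerIndex,
    locus: NcrnaLocus,
    spike_reads: float,
    volume_equivalents: float = 1.0,
    diagonal_tolerance: int = 0,
) -> StrandCounts:
    """Build StrandCounts from short reads by segmentation.

    A read counts as "template" when any window maps within the template
    region, and additionally as "junction" when it contains a same-strand
    repeat-junction jump (Category 1 or 3). Read strand is the majority
    strand of its mapped windows.
    """
    raw: dict[tuple[str, str], float] = {
        (cls, strand): 0.0
        for cls in ("template", "junction")
        for strand in (PLUS, MINUS)
    }
    ts, te = locus.template_start, locus.template_end
    for read in reads:
        assignments = segment_read(read, index)
        mapped = [a for a in assignments if a.strand != UNMAPPED]
        if not mapped:
            continue
        strand = Counter(a.strand for a in mapped).most_common(1)[0][0]
        if any(ts <= a.position <= te for a in mapped):
            raw[("template", strand)] += 1
        jumps, _ = classify_jumps(
            quantify_jumps(assignments, index.k, diagonal_tolerance)
        )
        if any(j.category in (1, 3) for j in jumps):
            raw[("junction", strand)] += 1
    return normalize_strand_counts(
        StrandCounts(raw, spike_reads, volume_equivalents)
    )
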