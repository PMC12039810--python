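"""k-mer index, segmentation, jump quantification and derived summaries."""

import itertools

import pytest

from neoscan import (
    NormalizationError,
    StrandCounts,
    ValidationError,
    build_index,
    classify_jumps,
    detect_3prime_extension,
    jump_map,
    layout_chimeric_reads,
    normalize_strand_counts,
    quantify_jumps,
    read_structure,
    segment_read,
    transitions,
    trim_adapters,
)
from neoscan._seq import revcomp
from neoscan.jumpmap import Jump, MINUS, PLUS
from neoscan.simulate import make_rnp_reads


def brute_force_min_unique_k(seq: str) -> int | None:
    """Independent oracle: smallest k with all k-mers unique across strands."""
    for k in range(1, len(seq) + 1):
        kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        rc = revcomp(seq)
        kmers += [rc[i : i + k] for i in range(len(rc) - k + 1)]
        if len(set(kmers)) == len(kmers):
            return k
    return None


class TestIndex:
    @pytest.mark.parametrize("seq", ["AAAAC", "ACGT", "ACGGTCAT", "AAAAAAA"])
    def test_min_unique_k_matches_brute_force(self, seq):
        k = min(4, len(seq))
        assert build_index(seq, k).min_unique_k == brute_force_min_unique_k(seq)

    def test_toy_min_unique_k_value(self):
        # {AAAA, AAAC, GTTT, TTTT} are all distinct; 3-mers collide
        assert build_index("AAAAC", 4).min_unique_k == 4

    def test_palindrome_has_no_unique_k(self):
        # every k-mer of ACGT also occurs on the reverse complement strand
        assert build_index("ACGT", 2).min_unique_k is None

    def test_reference_locus_has_no_ambiguous_11mers(self, ref_index):
        assert ref_index.ambiguous == set()
        assert ref_index.min_unique_k is not None
        assert ref_index.min_unique_k <= 11

    def test_every_mapped_kmer_occurs_once(self, ref_locus, ref_index):
        seq = ref_locus.sequence
        rc = revcomp(seq)
        for kmer in itertools.islice(ref_index.map, 50):
            occurrences = sum(
                s[i : i + 11] == kmer
                for s in (seq, rc)
                for i in range(len(s) - 10)
            )
            assert occurrences == 1

    def test_invalid_k_raises(self):
        with pytest.raises(ValidationError):
            build_index("ACGTACGT", 0)


class TestSegmentation:
    def test_error_free_minus_read_steps_down_by_one(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit
        assignments = segment_read(read, ref_index)
        mapped = [a for a in assignments if a.strand != "unmapped"]
        assert mapped, "repeat windows must map"
        assert all(a.strand == MINUS for a in mapped)
        positions = [a.position for a in mapped]
        assert all(b == a - 1 for a, b in zip(positions, positions[1:]))

    def test_window_count_conservation(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit * 2
        assignments = segment_read(read, ref_index)
        assert len(assignments) == len(read) - 11 + 1

    def test_single_substitution_unmaps_exactly_k_windows(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit
        i = 60
        mutated = read[:i] + ("A" if read[i] != "A" else "C") + read[i + 1 :]
        before = [a.strand for a in segment_read(read, ref_index)]
        after = [a.strand for a in segment_read(mutated, ref_index)]
        newly_unmapped = [
            j for j, (b, a) in enumerate(zip(before, after))
            if b != "unmapped" and a == "unmapped"
        ]
        assert len(newly_unmapped) == 11
        assert newly_unmapped == list(range(i - 10, i + 1))

    def test_adapter_only_read_is_fully_unmapped(self, ref_index):
        assignments = segment_read("CCTGTACTTCGTTCAGTTAC", ref_index)
        assert all(a.strand == "unmapped" for a in assignments)

    def test_short_read_gives_empty_segmentation(self, ref_index):
        with pytest.warns(UserWarning):
            assert segment_read("ACGT", ref_index) == []

    def test_adapter_trimming(self, ref_locus):
        core = ref_locus.repeat_unit
        read = "CCTGTACTTCGTTCAGTTAC" + core + "GCAATACGTAACTGAACGAA"
        assert trim_adapters(read, "CCTGTACTTCGTTCAGTTAC", "GCAATACGTAACTGAACGAA") == core


class TestJumps:
    def test_junction_read_jumps_29_to_148(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit * 2
        jumps = quantify_jumps(segment_read(read, ref_index), k=11)
        assert len(jumps) == 1
        j = jumps[0]
        assert (j.from_position, j.from_strand) == (29, MINUS)
        assert (j.to_position, j.to_strand) == (148, MINUS)

    def test_contiguous_read_has_no_jumps(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit
        assert quantify_jumps(segment_read(read, ref_index), k=11) == []

    def test_category_assignment_by_strand_pair(self):
        jumps = [
            Jump("r", 29, MINUS, 148, MINUS),
            Jump("r", 31, MINUS, 34, PLUS),
            Jump("r", 148, PLUS, 29, PLUS),
            Jump("r", 147, PLUS, 280, MINUS),
        ]
        classified, fractions = classify_jumps(jumps)
        assert [j.category for j in classified] == [1, 2, 3, 4]
        assert fractions == {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}

    def test_jump_map_total_equals_adjacent_mapped_pairs(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit * 3
        trans = transitions(segment_read(read, ref_index), k=11)
        table = jump_map(trans, include_diagonal=True)
        assert table["count"].sum() == len(trans)
        off_diag = jump_map(trans, include_diagonal=False)
        assert off_diag["count"].sum() == 2  # two junctions

    def test_empty_input_gives_empty_table(self):
        assert jump_map([]).empty


class TestReadStructure:
    def test_pure_minus_concatemer(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit * 5
        s = read_structure(segment_read(read, ref_index), ref_locus)
        assert (s.n_minus_repeats, s.n_plus_repeats) == (5, 0)
        assert s.total_repeats == 5
        assert not s.readthrough

    def test_primer_started_read(self, ref_locus, ref_index, small_sims):
        molecule, truth = small_sims[0]
        s = read_structure(segment_read(molecule, ref_index), ref_locus)
        assert s.start_position == ref_locus.pbs_interval[1]
        assert s.has_primer_start
        assert molecule.startswith(ref_locus.primer)

    def test_no_mapped_windows_gives_zero_structure(self, ref_locus, ref_index):
        s = read_structure(segment_read("A" * 30, ref_index), ref_locus)
        assert s.total_repeats == 0 and s.start_position is None


class TestThreePrimeExtension:
    def test_wild_type_consensus_is_gatat(self, ref_locus):
        reads = make_rnp_reads(ref_locus, 40, "wt")
        pfm, consensus, n = detect_3prime_extension(reads, ref_locus)
        assert consensus == "GATAT"
        assert n == 40
        assert pfm.loc[0, "G"] == 40

    def test_rt_dead_consensus_is_empty(self, ref_locus):
        reads = make_rnp_reads(ref_locus, 40, "rt_dead")
        _, consensus, n = detect_3prime_extension(reads, ref_locus)
        assert consensus == "" and n == 40

    def test_pbs_mutant_extension_complements_mutant_pbs(self, ref_locus):
        reads = make_rnp_reads(ref_locus, 40, "pbs_mutant", mutant_pbs="ACCGT")
        _, consensus, _ = detect_3prime_extension(reads, ref_locus)
        assert consensus == revcomp("ACCGT")

    def test_unanchored_reads_warn(self, ref_locus):
        with pytest.warns(UserWarning):
            _, consensus, n = detect_3prime_extension(["ACGT" * 20], ref_locus)
        assert n == 0 and consensus == ""


class TestLayout:
    def test_contiguous_read_sits_at_mapped_positions(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit
        layout, n_excluded = layout_chimeric_reads([segment_read(read, ref_index)])
        assert n_excluded == 0
        mapped = layout.dropna(subset=["position"])
        assert (mapped["x_coord"] == mapped["position"]).all()
        assert mapped["in_longest_run"].all()

    def test_chimeric_read_extends_past_template_boundary(self, ref_locus, ref_index):
        read = ref_locus.repeat_unit * 2
        layout, _ = layout_chimeric_reads([segment_read(read, ref_index)])
        # windows outside the longest run get run-relative x past the boundary
        assert layout["x_coord"].min() < ref_locus.template_start or \
            layout["x_coord"].max() > ref_locus.template_end

    def test_unmappable_reads_are_excluded_and_counted(self, ref_index):
        layout, n_excluded = layout_chimeric_reads(
            [segment_read("A" * 40, ref_index)]
        )
        assert n_excluded == 1 and layout.empty

    def test_tie_breaks_to_leftmost_run(self, ref_locus, ref_index):
        # two equal maximal runs separated by a junction: leftmost wins
        read = ref_locus.repeat_unit * 2
        layout, _ = layout_chimeric_reads([segment_read(read, ref_index)])
        first_run_offset = layout[layout["in_longest_run"]]["read_offset"].min()
        assert first_run_offset == 0


class TestStrandCounts:
    def test_normalization_formula(self):
        counts = StrandCounts({("template", PLUS): 100.0}, 10, 2)
        assert normalize_strand_counts(counts).normalized[("template", PLUS)] == 5.0

    def test_scale_equivariance(self):
        a = normalize_strand_counts(StrandCounts({("template", MINUS): 80.0}, 10, 1))
        b = normalize_strand_counts(StrandCounts({("template", MINUS): 80.0}, 20, 1))
        assert a.normalized[("template", MINUS)] == 2 * b.normalized[("template", MINUS)]

    def test_zero_spike_raises(self):
        with pytest.raises(NormalizationError):
            normalize_strand_counts(StrandCounts({}, 0, 1))
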