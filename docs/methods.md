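# Methods

## The system being modelled

A DRT2-type defense operon couples a reverse transcriptase (RT) to a
~280-nt non-coding RNA. The RT reverse-transcribes a central template
region of the ncRNA — reference coordinates 29–148 (1-based, inclusive;
120 nt) — over and over, jumping from the template 5′ end back to its 3′
end at each completed copy. The product is concatemeric cDNA (ccDNA):
tandem minus-strand repeats of the reverse-complemented template.
Synthesis is primed by a 5-nt DNA primer (`GATAT`) covalently attached
after the ncRNA 3′ base A280 and annealed to the primer-binding site
(PBS, template bases 142–146). Two conserved `ACA` trinucleotides bracket
the template; the first is part of the template itself, which is why the
repeat unit ends in `TGT` and repeat junctions read `TGTTA`.

Concatemerization is what creates a gene. Inside one repeat the −10
(`TATAAT`, repeat positions 13–18) and −35 (`TTGACA`, 110–115) hexamers
are out of order with a 91-bp gap; across a junction, the −35 of repeat
*i* and the −10 of repeat *i+1* are separated by exactly
L − g − 12 = 120 − 91 − 12 = 17 bp — a canonical strong sigma-70
promoter. Because the repeat length is a multiple of three, one reading
frame runs through every junction without stop codons (the *neo* ORF).

All public coordinates are 1-based inclusive; minus strand means
antisense to the ncRNA (the sense of first-strand cDNA).

## Canonical fixture geometry

The generated reference repeat is pinned by the two printed spacings
(91 bp in-repeat, 17 bp across the junction), which fix the −10 at repeat
13–18 and the −35 at 110–115 for a 120-bp repeat. The remaining
placements are this package's own choices within that frame: RBS `GAG`
at 23–25, start codon `ATG` at 32–34 (a 13-nt gap after the −10 end, so
the start is found "13 nt downstream" of the −10; the RBS report returns
both the ATG and the upstream GAG since either reading of that distance
is defensible), and a single HinfI site fixed as `GACTC` at 50–54. The
*neo* frame is the codon grid at repeat positions ≡ 2 (mod 3); this grid
splits the −35 into codons `TTG|ACA` and leaves every partial codon at a
fixed-element border structurally unable to form a stop (e.g. codons
ending in the `T` of `TGT` can never be `TAA/TAG/TGA`), so filling all
free codons with sense codons guarantees a stop-free junction-spanning
frame by construction.

## k-mer jump analysis

Reads are segmented into consecutive k-mers (default k = 11); each k-mer
is assigned the ncRNA coordinate of its first base in read orientation
(plus strand: the window start; minus strand: the window end, so
positions decrease along a read) or left unmapped. Jump endpoints follow
the jump-map axis convention: from = position of the 3′ base of the 5′
k-mer, to = position of the 5′ base of the 3′ k-mer. A transition between
successive mapped windows is a jump when the strand changes or the
position deviates from the running diagonal by more than
`diagonal_tolerance` (0 for error-free data, 3 recommended for
error-bearing reads). Categories are purely strand-based: 1 = minus→minus,
2 = minus→plus, 3 = plus→plus, 4 = plus→minus.

Two index subtleties matter:

* **Ambiguity.** k-mers occurring more than once across the union of both
  strands are excluded (unique hashing). The generator verifies the
  reference locus has no ambiguous 11-mers and reports the minimum unique
  k (typically 8–9 for a random 280-mer).
* **Junction-duplicated k-mers.** Because the template begins at the
  leading ACA bracket and a second ACA follows the template, the ccDNA
  junction sequence (`…TGT|TAGATAT…`) is identical to the ncRNA region
  spanning the template end and the second bracket. A k-mer there cannot
  be attributed to one source, so when the template interval is supplied
  the index marks those k-mers excluded. This keeps junction jumps
  anchored at the template boundaries (29⁻ → 148⁻ for Category 1).

Unmapped-window skipping: one base error voids k consecutive windows and
a junction itself voids k − 1, so errors flanking a junction void about
3k; transitions are therefore evaluated across runs of up to
`max_skip` = 4k unmapped windows (configurable), beyond which the read is
split. At substitution 0.02 and indel 0.01/0.01 with tolerance 3 this
yields category-level jump recall and precision above 0.99 on the default
simulation; at 2k roughly 13% of junction jumps would be severed by
flanking errors.

## The simulator

`simulate_synthesis` builds each molecule mechanistically and logs every
event as ground truth:

* Repeat count x per molecule follows a zero-truncated geometric law with
  mean 5 (the observed modal repeat count is 5; the single-parameter
  geometric matches that mode and is the simplest law — the very heavy
  in-vivo tail of >100 repeats is deliberately not modelled).
* The first repeat starts at the primer (first emitted bases `GATAT`,
  complement of the PBS), so reads start at ncRNA position 146 on the
  minus strand; each completed repeat triggers the Category-1 jump
  (29⁻ → 148⁻).
* With probability `p_reversal` (default 0.5) synthesis reverses onto the
  nascent strand at a junction: the final minus repeat stops two bases
  into the template and the plus block resumes three bases later, so
  detected reversals read 31⁻ → 34⁺. The plus block copies y ≤ x repeat
  units (y uniform on [1, x] — y ≤ x is mechanical, the second strand can
  only copy what exists), with Category-3 junctions (148⁺ → 29⁺).
* When the plus block copies all the way back to the primer (y = x), the
  RT reads through into the ncRNA 3′ domain with probability
  `p_readthrough` (default 0.5), emitting minus-sense cDNA of ncRNA
  149–280. The extension's first base, comp(A280) = T, always equals the
  template base after the PBS, so the detectable plus diagonal runs one
  base past the PBS: the Category-4 truth jump is logged as 147⁺ → 280⁻.

Sequencing applies per-base substitution/insertion/deletion errors
(defaults 0.02/0.01/0.01, Nanopore-like magnitudes) with logged
positions, constant placeholder qualities, and fixed 20-nt adapters.
Short-read emulation fragments molecules uniformly (50–200 bp); in
`untreated` mode only reversal-free (single-stranded, minus) molecules
are accessible, while `s1` mode opens hairpins so both strands are
sampled — reproducing the observation that plus-strand junction reads
appear only after S1 nuclease treatment. Spike-in normalization divides
raw counts by spike reads × volume equivalents.

Locus generation is rejection sampling: free positions are filled with
sense codons on the *neo* grid, then the candidate is rejected unless the
doubled repeat contains each promoter hexamer and GANTC site exactly once
per repeat, no decoy ACA falls where the bracket-selection band could
pick it up, the whole ncRNA hashes uniquely at k = 11, and every
boundary-spanning chimeric 11-mer the simulator can produce (junctions,
reversal turn, read-through, adapter borders) is unmappable. These
guarantees are what make jump detection *exact* at zero error — the
oracle-equivalence tests compare detected jumps with the construction
trace read by read.

Ortholog families share the fixed elements and differ at free codons
(per-codon substitution probability 0.3 inside the template, 0.02 per
base in the flanks — the template is the least conserved part of the
ncRNA, while fixed-element columns stay invariant). Member template
lengths are drawn from {111, 117, 120, 129} (weights 0.10/0.55/0.25/0.10,
117 dominant, the reference 120), varying by whole codons in a designated
variable block; alignments carry gap columns there. A 119-nt variant
(sense-codon fill truncated by one base) provides the frameshift negative
control.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analyses assume:
repeat tandemness, junction promoter/ORF reconstitution, hairpin strand
composition with y ≤ x, primer-anchored read starts, and unique k-mer
hashing. It does not model basecaller-specific (homopolymer) error
profiles, the heavy repeat-count tail, chimeric library artifacts,
carrier DNA, or real ortholog phylogeny (family members are independent
draws around one reference, not a tree). Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance on arbitrary real libraries; the jump pipeline's
thresholds (`diagonal_tolerance`, `max_skip`, adapter trimming) are
exposed because real data will need them revisited.

## Numerical and degenerate-input choices

* Conservation: per column, 2 − H over A/C/G/T frequencies with gaps
  excluded; columns with > 50% gaps are reported missing (NaN) and
  listed. Smoothing is a centered moving average (window 10) with
  shrinking windows at the edges.
* Promoter scanning: exact consensus match by default (`max_mismatch`
  configurable); when no canonical call exists, each −10 is paired with
  the nearest downstream −35 as an out-of-order diagnostic.
* ORF scanning: all three frames are reported; `spans_junction` refers to
  the longest stop-free stretch of the frame; translation uses the
  standard genetic code.
* Digest: IUPAC site patterns with overlapping matches; cuts at offset 1
  (G^ANTC); fragment lengths always sum to the input length.
* Layout: ties between equal longest runs break to the leftmost run.
* ACA-bracket extraction: with an approximate start, the first bracket is
  the nearest ACA at/left of it and the second the nearest downstream ACA
  implying a template length of 90–150 nt; without one, the first two
  ACA occurrences are used (needed for short test sequences).
* All randomness flows from numpy `default_rng` seeds; every simulation
  is byte-reproducible given its seed.

## Problem sizes

Tests run desk-scale: 300-molecule oracle-equivalence sets, a
10,000-read robustness and convergence condition, 42-member families,
and 1,000-seed codon-uniformity checks. The acceptance script generates
a fresh locus and a ~50-molecule simulation per run; everything completes
in well under a minute per check on one CPU.
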