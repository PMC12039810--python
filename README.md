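# neoscan

Reconstruction and long-read analysis of the concatemeric cDNA (ccDNA)
synthesized by DRT2-type bacterial defense reverse transcriptases.

DRT2 systems pair a reverse transcriptase with a ~280-nt non-coding RNA
(ncRNA). Upon phage infection the RT rolls over a central 120-nt *template
region* of the ncRNA (bases 29–148, bracketed by conserved "ACA" motifs and
primed by a covalent 5-nt DNA primer `GATAT` annealed to the primer-binding
site, bases 142–146), producing tandem minus-strand repeats. Within one
repeat the sigma-70 promoter hexamers sit out of order — the −10 `TATAAT`
followed by the −35 `TTGACA` with a 91-bp gap — but across a repeat
junction the −35 of one repeat and the −10 of the next are juxtaposed with
a perfect 17-bp spacer: concatemerization reconstitutes a promoter.
Because every repeat length is divisible by three, the concatemer also
carries a single junction-spanning reading frame with no stop codons (the
nearly-endless ORF, *neo*). `neoscan` implements:

* **reconstitute** — theoretical ccDNA construction (reverse-complement +
  concatemerize), promoter scanning (canonical spacer 15–19 bp and
  out-of-order diagnostics), junction-spanning ORF scanning with the
  mod-3 frame rule, RBS/start-codon location 13 nt downstream of the −10,
  alignment-column conservation (2 − H bits per column, 10-bp moving
  average), in-silico `GANTC` (HinfI) digestion, Kyte–Doolittle protein
  properties, and a randomized-repeat null that preserves the fixed
  elements and fills gaps from the 61 sense codons.
* **jumpmap** — segmentation of long reads into consecutive 11-mers mapped
  to the ncRNA (both strands, unique hashing), quantification of template
  jumps (non-adjacent mapping of adjacent 11-mers), classification into
  Categories 1–4 (minus→minus junctions, minus→plus reversals, plus→plus
  second-strand junctions, plus→minus read-through), repeat counting and
  hairpin (x, y) structure, read-start and 3′-primer-extension consensus,
  chimeric-read layout tables, and spike-normalized strand-specific
  counts.
* **simulate** — a mechanistic simulator of rolling reverse transcription
  that generates reference-architecture loci and ortholog families, then
  ccDNA molecules with a full ground-truth event log (every jump, the
  hairpin constraint y ≤ x enforced mechanically), Nanopore-like
  sequencing errors, adapters, short-read fragmentation with strand
  labels and spike-ins.

## Worked example

```python
from neoscan import concatemerize, scan_promoters, scan_orfs, digest
from neoscan.simulate import make_locus

locus = make_locus(seed=1)          # 280-nt ncRNA, 120-nt template
ccdna = concatemerize(locus.template, 2)

call = scan_promoters(ccdna)[0]
print(call.arrangement, call.spacer_bp, call.spans_junction)
# canonical 17 True        <- junction promoter, 17-bp spacer

single = scan_promoters(concatemerize(locus.template, 1))[0]
print(single.arrangement, single.spacer_bp)
# out_of_order 91          <- within one repeat: no promoter

orfs = scan_orfs(concatemerize(locus.template, 3))
print([(o.frame, len(o.stop_positions)) for o in orfs])
# [(0, 12), (1, 0), (2, 15)]  <- one stop-free junction-spanning frame

print(digest(concatemerize(locus.template, 4).sequence))
# [50, 120, 120, 120, 70]  <- HinfI releases the 120-bp repeat unit
```

A single repeat carries the promoter motifs out of order at 91 bp; two
repeats reconstitute the canonical promoter with a 17-bp spacer across the
junction; exactly one reading frame of the concatemer is stop-free; and
HinfI digestion of multi-repeat ccDNA releases internal fragments exactly
one repeat (120 bp) long.

The same analyses run from the shell:

```bash
neoscan simulate --seed 17 --n-reads 1000 --out out/sim
neoscan jumpmap --reads out/sim/reads.fastq --locus out/sim/locus.fa \
    --locus-json out/sim/locus.json --tolerance 3 --out out/jm
neoscan reconstitute --ncrna out/sim/locus.fa --n-repeats 5 --out out/rec
```

`out/jm/summary.json` reports the jump-category fractions (Category 1
dominant) and `out/rec/summary.json` the promoter/ORF reconstitution
report per locus.

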