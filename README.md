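# replift

Quantitative ChIP-seq/exo analysis in **repeat consensus coordinates**.

## The problem

Transposable elements such as LINE-1 exist in thousands of near-identical
genomic copies. A KRAB-zinc-finger protein that silences a repeat family
produces ChIP reads that are overwhelmingly multi-mapping; standard
pipelines either drop them or assign them to one copy at random, leaving a
"black hole" exactly where the biology is. The remedy is to stop asking
*which copy* a read came from: every copy of a repeat descends from one
consensus sequence, so reads can be **lifted** from genomic coordinates
into the coordinate frame of that consensus, where a multi-mapping read
occupies a single, well-defined position regardless of its genomic copy.

`replift` implements that workflow end to end:

1. **Parse** RepeatMasker alignment (`.align`) and annotation (`.out`)
   files — each `.align` record is one genomic instance with its gapped
   pairwise alignment to the consensus.
2. **Compile chains**: each alignment becomes a UCSC-liftOver-style chain
   mapping the genomic span (target) onto the consensus span (query).
   Substitutions stay inside chain blocks; only indels break them, so the
   consensus coordinates agree exactly with the Dfam-style consensus the
   alignments were computed against.
3. **liftIn**: map reads or peaks (BED) through the chains onto consensus
   coordinates, piecewise-exactly. With deduplication on, a read mapped at
   k genomic copies counts **once** per consensus.
4. **F.C.C. signal**: windowed Fold-Change-over-Control on the consensus,

   ```
   fcc_k = ((chip_k + α) / N_chip) / ((input_k + α) / N_input)
   ```

   with window counts summed over a fixed grid (default 10 nt) and
   N_chip/N_input the *total* library sizes, so tracks are comparable
   across repeat families and insensitive to repeat copy number.
5. **liftOut**: for any consensus locus `(repeat, start, end)`, extract
   the underlying genomic sequence from every instance whose alignment
   covers it — the raw material for per-subfamily sequence logos.
6. **Binding model**: build position frequency matrices (PFM) from
   lifted-out sites and score each site with an additive position energy
   matrix (PEM, e.g. from Spec-seq), `E(s) = Σᵢ ε(sᵢ, i)` in kT (lower =
   stronger binding), including threshold censuses (fraction of sites
   below a cutoff such as −4.5 kT) and a double-strand consensus scan for
   the minimum-energy window.
7. **Annotate** peaks with their containing/nearest repeat instance and
   the consensus coordinates of the overlap.

A fully ground-truthed synthetic fixture generator (`replift.simulate`)
emulates the real inputs — consensus, diverged instances with indels on
both strands, RepeatMasker files that agree with the embedded truth by
construction, and ChIP/input libraries with a planted enrichment ratio —
so the whole stack is testable without any genome download.

## Worked example

`python examples/02_fcc_track.py` simulates 24 diverged copies of a 600 nt
consensus in a ~300 kb genome, plants an 8-fold ChIP enrichment over the
genomic projections of locus `L1toy:300-320`, lifts both libraries, and
prints the windowed F.C.C.:

```
libraries: 447088 ChIP / 434005 input reads
window    chip   input    fcc
[270,280)   35663   11670    2.97
[280,290)   58773   11742    4.86
[290,300)   81974   11808    6.74
[300,310)   94562   11640    7.89
[310,320)   96054   11345    8.22
[320,330)   82838   11193    7.18
[330,340)   59735   11503    5.04
[340,350)   36167   12082    2.91

max window (310, 320): F.C.C. = 8.22 (planted enrichment 8.0)
```

The max window recovers the planted ratio; the triangular shoulders are
reads that overlap the locus only partially; background windows (not
shown) sit at ≈ 1. The other examples cover chain building and interval
lifting (`01`), liftOut + PFM + PEM scoring (`03`), and peak annotation
(`04`).

The same operations are available as a CLI for shell pipelines:

```
replift simulate --consensus C.fa -n 200 --locus L1toy:300-320 -r 8 -o fx/
replift build-chain --align fx/fixture.align --consensus-fasta fx/consensus.fa \
    --chrom-sizes fx/chrom.sizes -o fx.chain
replift lift-in --chain fx.chain --reads fx/chip.bed -o chip_lifted.bed
replift fcc --chip chip_lifted.bed --input input_lifted.bed \
    --n-chip N --n-input M --consensus-fasta fx/consensus.fa --repeat L1toy
replift lift-out --align fx/fixture.align --genome fx/genome.fa \
    --consensus-fasta fx/consensus.fa --repeat L1toy --start 300 --end 320
replift score --pem pem.tsv --sites sites.fa --theta -4.5
```

## File formats

* **`.align` dialect** (also emitted by the fixture generator): per-record
  header `score div del ins chrom gbeg gend (gleft) [C] name#class …` with
  1-based inclusive coordinates, followed by interleaved aligned-sequence
  line pairs; complement ("C") records show the forward genomic strand
  against the reverse-complemented consensus with descending consensus
  coordinates, exactly as RepeatMasker prints them. Score-matrix and
  quality lines are skipped.
* **Chains** are standard UCSC chain format (target = genome, query =
  consensus) and are usable with the external liftOver tool.
* Matrices (PFM/PEM) are TSV: 4 rows labelled A,C,G,T, a header row of
  1-based positions.
* Everything else is BED, bedGraph, FASTA and TSV.

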