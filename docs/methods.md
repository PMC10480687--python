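# Methods

## Coordinate model

All internal coordinates are 0-based half-open, on the forward strand of
whichever sequence they index. RepeatMasker files are 1-based inclusive and
converted at the I/O boundary; nothing downstream ever sees a 1-based
number. For complement ("C") alignment records the genomic interval stays
on the forward genomic strand while the aligned strings are stored in
consensus-forward orientation (the stored genome string is the reverse
complement of the forward genomic strand, recorded by `strand == "-"`).
This makes every column walk strand-uniform: consensus position always
increases left to right, and the genome position either increases (+) or
decreases (−).

## Chains and lifting

Each alignment record compiles to one UCSC chain with target = genome
(always "+") and query = consensus. The single lift direction follows from
how UCSC liftOver works (target → query): liftIn is the chain as written,
liftOut inverts the per-record alignment in memory rather than keeping a
second chain file. Substitution columns stay inside blocks; a consensus
gap consumes `dt` (genome-only base), a genome gap consumes `dq`. Blocks
are merged canonically (no two adjacent gap-free blocks) so serialization
is unique and byte-stable; parsing re-validates the two span equations
`Σsize + Σdt = t_span` and `Σsize + Σdq = q_span`. Minus-strand instances
are walked in genome-forward order so the target ascends, placing query
coordinates in the reversed consensus frame per the UCSC convention.
Fragmented elements (one element split across several `.align` records)
are deliberately not stitched — there is no principled stitching rule, and
`record_id` lets a user do it upstream if desired.

Alignments whose first or last column is a gap cannot be represented as a
chain span and are rejected with a clear error; RepeatMasker alignments
(and the fixture generator) never produce them.

Interval lifting is piecewise-exact: the query interval is intersected
with each overlapping chain's blocks, each intersection maps linearly,
abutting output pieces from one chain merge, and bases inside `dt` gaps
map nowhere. There is no minimum-match fraction: a read straddling an
indel contributes its mappable pieces and nothing else, which keeps
windowed coverage exact and threshold-free.

### Multi-mapper deduplication

With dedup on, all lifted pieces of one read are grouped by (read id,
consensus); among the read's genomic mappings to that consensus, the
mapping whose first piece has the smallest `(q_start, chrom, g_start)` is
kept, with **all** of its pieces. Keeping whole mappings rather than
single pieces matters only for reads that straddle an indel — discarding
their secondary pieces would corrupt coverage — and is identical to
keeping "the smallest segment" when copies are exact. The rule is
deterministic and order-independent; which copy wins is immaterial for
exact copies (same consensus position either way) and documented as a
sensitivity caveat for diverged copies. A read overlapping two different
consensus names contributes once to each.

## F.C.C. signal

Per-base coverage from lifted segments is summed over a fixed window grid
anchored at consensus position 0 (default 10 nt, last partial window
kept), then

    fcc_k = ((chip_k + α) / N_chip) / ((input_k + α) / N_input).

Two decisions here were genuinely open:

* **Normalization constant.** N_chip/N_input are the *total* library
  sizes (pre-lift), not lifted-read counts. Normalizing by lifted totals
  would force the average track to 1 on every consensus and erase
  family-level enrichment — the opposite of the quantity's purpose
  (comparability across repeat families, independence from copy number).
  Both constants are surfaced as explicit arguments so either convention
  can be used.
* **Pseudocount.** α defaults to 1 (windows are small; a zero-input
  window otherwise produces an unusable ratio); α = 0 is fully supported
  and used by the identity tests. With α = 0 and zero input the window's
  F.C.C. is NaN and flagged — never a silent infinity. Windows with raw
  input below `min_input` (default 5) are flagged low-confidence without
  altering the ratio; the bedGraph exporter writes flagged windows to a
  companion mask file.

Total-library normalization has one quantifiable bias: the background
ratio is N_input/N_chip ≈ 1/(1 + (r−1)·f), where f is the fraction of the
genome under r-fold enrichment. On a real genome f is negligible; the
synthetic recovery conditions keep f < 1% (instances separated by ~12 kb
spacers) so the planted ratio is recovered within a few percent.

Per-strand tracks partition segments by the BED strand of the source read;
the combined track sums both (no combination rule beyond addition).

## liftOut and the binding model

liftOut considers only instances whose alignment fully covers the
requested locus; partial coverers are counted and skipped. Indel-free
sites are fetched from the genome (reverse-complemented for minus-strand
instances, so every site is in consensus orientation) and the invariant
that re-lifting the site's genomic interval returns exactly the requested
locus is enforced by test. With `allow_indel` on, deletions render as `-`
and insertions are dropped so sites keep fixed length; the default is off
because PFM/PEM arithmetic assumes ungapped, fixed-length sites.

PFM: `f(b,i) = (count(b,i) + β) / (n_i + 4β)` with N bases excluded from
both numerator and denominator at their position (imputing them would
bias the energy distributions the matrices feed). PEM energies are used
exactly as supplied, in kT, lower = stronger: thresholds such as −4.5 kT
refer to the matrix's own scale, so no re-anchoring is ever applied
implicitly (an explicit `anchored()` utility subtracts per-position
minima). Site energies are strict additive sums; sequences with N are
excluded from scoring and reported, not imputed. `scan_consensus` is the
only double-strand operation (lifted-out sites are already in consensus
orientation); ties break toward the smallest offset, then the + strand.

## Synthetic fixtures

The generator emulates: one consensus family, n independently diverged
instances (per-base substitutions at `sub_rate`; indel events at
`indel_rate` with geometric length, mean 2, never touching instance ends
so boundary coordinates stay exact), a configurable minus-strand fraction,
placement on one chromosome with random spacers, and optional 5′/3′
truncation. Emitted `.align`/`.out` files agree with the embedded truth by
construction, and an edit-script replay invariant is tested. Read
simulation is Poisson: input uniform at `background_depth`; ChIP identical
except an `enrichment`-fold start-rate multiplier for reads whose
footprint overlaps any instance's genomic projection of the planted locus.
Default conditions (8% substitutions, 1% indel starts, 30% minus strand,
50× depth, 8-fold enrichment, 36 nt reads) represent a moderately diverged
repeat family under a deep ChIP-exo-style experiment.

What the generator does **not** model — and therefore what passing tests
do not establish about real data: realistic repeat phylogeny (instances
diverge independently, not along a tree), sequencing error, paired-end
fragments, mappability bias, chromatin-driven input non-uniformity, and
alignment error in the `.align` records themselves (fixture alignments are
true by construction; real RepeatMasker alignments are heuristic).

### Problem sizes used in tests

Stochastic checks are sized so sampling noise is small against their
tolerances: the windowed-count CV under the generator is ≈ 0.95/√(depth·n).
The enrichment-recovery and copy-number checks run at depth 50 with 24
vs 48 instances (CV ≈ 2–3%, giving ≥3σ margin on the 15%/10% bands) on
~300–600 kb genomes; the end-to-end CLI check runs 200 instances on a
~2 Mb genome at 2× depth. All stochastic tests pin their seeds.

## Numerical and degenerate-input choices

* Window/interval arithmetic is integer throughout; F.C.C. is the only
  floating-point quantity in the signal path.
* PFM column sums are validated to 1 ± 1e-9 on construction and on read.
* Chain IDs are sequential in input order; identical inputs produce
  byte-identical chain files.
* Empty lift results (no overlapping chain) are valid empty lists, not
  errors; zero scoreable sites, unknown repeat names, stale consensus
  lengths and malformed records are errors with the offending record or
  line named.

## Known limitations

* One chain per `.align` record; no stitching of fragmented elements.
* `.out` subfamily names are not reconciled with `.align` grouped names
  (e.g. ORF-region groupings); a user-supplied lookup is expected where
  the two schemes must be joined.
* Reads enter as BED intervals; BAM/CIGAR interpretation (including
  spliced reads) is out of scope.
* No peak calling or significance testing on consensus tracks — the
  method reports ratios.
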