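"""Ground-truthed synthetic fixtures: a repeat-bearing genome plus read sets.

The generator emulates the real inputs of a repeat ChIP experiment — a
consensus sequence, diverged genomic instances (substitutions and small
indels, both strands) embedded in a synthetic chromosome, RepeatMasker-style
``.align``/``.out`` annotations that agree with the embedded truth by
construction, and ChIP/input read libraries with a planted enrichment ratio
over the genomic projections of a chosen consensus locus.

Every stochastic choice flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lift import LocusSpec, _consensus_to_genome_map
from .repeatmasker_io import (
    RepeatAlignment,
    RepeatInstance,
    revcomp,
    write_align,
    write_fasta,
    write_out,
)

BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class InstanceTruth:
    """One planted instance: where it sits and how it differs from consensus."""

    record_id: str
    repeat_id: str
    chrom: str
    g_start: int
    g_end: int
    strand: str
    c_start: int
    c_end: int
    # edit script on the consensus slice: ("sub", pos, base),
    # ("ins", pos, seq) inserts before pos, ("del", pos, k)
    edits: list[tuple] = field(default_factory=list)
    sequence: str = ""  # ungapped instance sequence, consensus orientation


@dataclass
class RepeatFixture:
    """A synthetic genome with planted repeat instances and full ground truth."""

    genome: dict[str, str]
    consensus: dict[str, str]
    align_records: list[RepeatAlignment]
    out_records: list[RepeatInstance]
    truth: list[InstanceTruth]
    seed: int

    def consensus_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.consensus.items()}

    def chrom_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.genome.items()}

    def align_text(self) -> str:
        return write_align(self.align_records)

    def out_text(self) -> str:
        return write_out(self.out_records)

    def genome_fasta(self) -> str:
        return write_fasta(self.genome)

    def consensus_fasta(self) -> str:
        return write_fasta(self.consensus)


def apply_edits(consensus: str, c_start: int, c_end: int, edits: list[tuple]) -> str:
    """Replay an edit script over consensus[c_start:c_end]; the result must
    equal the instance sequence embedded in the genome (consensus orientation)."""
    subs = {pos: b for op, pos, b in edits if op == "sub"}
    ins = {pos: s for op, pos, s in edits if op == "ins"}
    dels = {pos: k for op, pos, k in edits if op == "del"}
    out: list[str] = []
    c = c_start
    while c < c_end:
        if c in ins:
            out.append(ins[c])
        if c in dels:
            c += dels[c]
            continue
        out.append(subs.get(c, consensus[c]))
        c += 1
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(
    consensus: str,
    c_start: int,
    c_end: int,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    edge_margin: int = 5,
) -> tuple[str, str, list[tuple]]:
    """Mutated copy of consensus[c_start:c_end] as aligned string pair
    (genome, consensus), consensus-forward orientation, plus edit script.

    Indels have geometric length (mean 2) and never touch the instance
    ends, which keeps instance boundary coordinates exact.
    """
    gseq: list[str] = []
    cseq: list[str] = []
    edits: list[tuple] = []
    c = c_start
    while c < c_end:
        interior = c_start + edge_margin <= c < c_end - edge_margin
        if interior and rng.random() < indel_rate:
            k = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                inserted = _random_seq(rng, k)
                gseq.append(inserted)
                cseq.append("-" * k)
                edits.append(("ins", c, inserted))
            else:
                k = min(k, c_end - edge_margin - c)
                if k > 0:
                    gseq.append("-" * k)
                    cseq.append(consensus[c : c + k])
                    edits.append(("del", c, k))
                    c += k
                    continue
        ref = consensus[c]
        base = ref
        if rng.random() < sub_rate:
            base = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            edits.append(("sub", c, base))
        gseq.append(base)
        cseq.append(ref)
        c += 1
    return "".join(gseq), "".join(cseq), edits


def make_repeat_genome(
    consensus: dict[str, str],
    n_instances: int = 50,
    sub_rate: float = 0.08,
    indel_rate: float = 0.01,
    minus_fraction: float = 0.3,
    spacer_len: int = 1000,
    seed: int = 0,
    truncate_fraction: float = 0.0,
    repeat_class: str = "LINE/L1",
    chrom: str = "chrsyn",
) -> RepeatFixture:
    """Plant ``n_instances`` diverged copies of the consensus sequences on one
    synthetic chromosome, separated by random spacers.

    ``truncate_fraction`` of instances cover only a random consensus
    sub-span (5' and 3' truncation, as real repeat instances do); the rest
    are full-length.  ``minus_fraction`` are reverse-complemented in the
    genome.  Defaults (8% substitutions, 1% indel starts, 30% minus strand,
    ~1 kb spacers) emulate a moderately diverged repeat family.
    """
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise SimulationError("rates must be in [0, 1)")
    if n_instances < 1:
        raise SimulationError("need at least one instance")
    for name, seq in consensus.items():
        if len(seq) < 40:
            raise SimulationError(f"consensus {name!r} too short to plant instances")
    rng = np.random.default_rng(seed)
    names = sorted(consensus)
    parts: list[str] = []
    pos = 0
    align_records: list[RepeatAlignment] = []
    out_records: list[RepeatInstance] = []
    truth: list[InstanceTruth] = []
    for i in range(n_instances):
        name = names[int(rng.integers(0, len(names)))]
        cons = consensus[name].upper()
        L = len(cons)
        if rng.random() < truncate_fraction:
            min_len = max(30, L // 4)
            c0 = int(rng.integers(0, L - min_len))
            c1 = int(rng.integers(c0 + min_len, L)) + 1
        else:
            c0, c1 = 0, L
        gseq, cseq, edits = _mutate(cons, c0, c1, sub_rate, indel_rate, rng)
        inst_seq = gseq.replace("-", "")
        if not inst_seq:
            raise SimulationError("mutation produced a zero-length instance")
        strand = "-" if rng.random() < minus_fraction else "+"
        genomic_seq = revcomp(inst_seq) if strand == "-" else inst_seq
        spacer = _random_seq(rng, int(rng.integers(spacer_len // 2, spacer_len * 3 // 2 + 1)))
        parts.append(spacer)
        pos += len(spacer)
        g_start, g_end = pos, pos + len(genomic_seq)
        parts.append(genomic_seq)
        pos = g_end
        rec_id = f"r{i:04d}"
        n_cols = sum(a != b for a, b in zip(gseq, cseq) if a != "-" and b != "-")
        n_match_cols = sum(a != "-" and b != "-" for a, b in zip(gseq, cseq))
        div = 100.0 * n_cols / n_match_cols if n_match_cols else 0.0
        rec = RepeatAlignment(
            chrom=chrom,
            g_start=g_start,
            g_end=g_end,
            strand=strand,
            repeat_id=name,
            repeat_class=repeat_class,
            c_start=c0,
            c_end=c1,
            sw_score=2 * len(inst_seq),
            divergence_pct=round(div, 2),
            aligned_genome=gseq,
            aligned_consensus=cseq,
            record_id=rec_id,
        )
        rec.validate()
        align_records.append(rec)
        out_records.append(
            RepeatInstance(
                chrom=chrom,
                g_start=g_start,
                g_end=g_end,
                strand=strand,
                repeat_id=name,
                repeat_class=repeat_class,
                c_start=c0,
                c_end=c1,
                record_id=rec_id,
            )
        )
        truth.append(
            InstanceTruth(
                record_id=rec_id,
                repeat_id=name,
                chrom=chrom,
                g_start=g_start,
                g_end=g_end,
                strand=strand,
                c_start=c0,
                c_end=c1,
                edits=edits,
                sequence=inst_seq,
            )
        )
    parts.append(_random_seq(rng, spacer_len))
    return RepeatFixture(
        genome={chrom: "".join(parts)},
        consensus={k: v.upper() for k, v in consensus.items()},
        align_records=align_records,
        out_records=out_records,
        truth=truth,
        seed=seed,
    )


def locus_projections(
    fixture: RepeatFixture, locus: LocusSpec
) -> list[tuple[str, int, int]]:
    """Genomic intervals underlying the locus, one per fully covering instance."""
    out: list[tuple[str, int, int]] = []
    for rec in fixture.align_records:
        if rec.repeat_id != locus.repeat_id:
            continue
        if rec.c_start > locus.start or rec.c_end < locus.end:
            continue
        cmap = _consensus_to_genome_map(rec)
        gpos = [cmap[c] for c in range(locus.start, locus.end) if cmap[c] is not None]
        if gpos:
            out.append((rec.chrom, min(gpos), max(gpos) + 1))
    return out


@dataclass
class ReadSim:
    """Simulated ChIP/input libraries as BED-like tables plus library sizes."""

    chip: pd.DataFrame
    input: pd.DataFrame
    n_chip: int
    n_input: int
    enriched_intervals: list[tuple[str, int, int]]


def _uniform_reads(
    rng: np.random.Generator,
    chrom: str,
    starts: np.ndarray,
    read_len: int,
    prefix: str,
    offset: int = 0,
) -> pd.DataFrame:
    n = len(starts)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + read_len,
            "name": [f"{prefix}{offset + i:08d}" for i in range(n)],
            "score": 0,
            "strand": strands,
        }
    )


def simulate_reads(
    fixture: RepeatFixture,
    locus: LocusSpec,
    enrichment: float = 8.0,
    background_depth: float = 50.0,
    read_len: int = 36,
    seed: int = 0,
) -> ReadSim:
    """Uniform input library plus a ChIP library with ``enrichment``-fold
    read rate over genomic projections of the planted locus.

    Read counts are Poisson at the requested mean depth; every read has a
    unique name, so deduplication acts only on genuinely multi-mapped
    intervals downstream.
    """
    if enrichment < 1:
        raise SimulationError("enrichment ratio must be >= 1")
    enriched = locus_projections(fixture, locus)
    if not enriched:
        raise SimulationError(
            f"locus {locus} is not covered by any planted instance"
        )
    rng = np.random.default_rng(seed)
    (chrom, genome_seq), = fixture.genome.items()
    glen = len(genome_seq)
    n_positions = glen - read_len + 1
    if n_positions < 1:
        raise SimulationError("genome shorter than the read length")
    rate = background_depth / read_len  # read starts per bp

    def draw_uniform(prefix: str) -> pd.DataFrame:
        n = int(rng.poisson(rate * n_positions))
        starts = rng.integers(0, n_positions, size=n)
        return _uniform_reads(rng, chrom, starts, read_len, prefix)

    input_df = draw_uniform("input_")
    chip_bg = draw_uniform("chip_")
    extra_frames = [chip_bg]
    n_named = len(chip_bg)
    for _, g_lo, g_hi in enriched:
        lo = max(0, g_lo - read_len + 1)
        hi = min(n_positions, g_hi)
        if hi <= lo:
            continue
        n_extra = int(rng.poisson((enrichment - 1.0) * rate * (hi - lo)))
        if n_extra:
            starts = rng.integers(lo, hi, size=n_extra)
            extra_frames.append(
                _uniform_reads(rng, chrom, starts, read_len, "chip_", offset=n_named)
            )
            n_named += n_extra
    chip_df = pd.concat(extra_frames, ignore_index=True)
    return ReadSim(
        chip=chip_df,
        input=input_df,
        n_chip=len(chip_df),
        n_input=len(input_df),
        enriched_intervals=enriched,
    )
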