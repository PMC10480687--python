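"""Core coordinate lifting between genomic and repeat-consensus frames.

``liftIn`` maps genomic intervals (reads, peaks) onto consensus coordinates
through chains, piecewise-exactly: every aligned base lands where its chain
block sends it, bases inside genome-only (dt) gaps map nowhere, and a
multi-mapping read can be deduplicated so it counts once per consensus.

``liftOut`` inverts a single instance's alignment to pull the genomic
sequence underlying a consensus locus out of every instance that covers it.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .chain import Chain
from .repeatmasker_io import GenomeSource, RepeatAlignment


class LiftError(ValueError):
    pass


@dataclass(frozen=True)
class LocusSpec:
    """A consensus locus: (repeat, start, end), 0-based half-open."""

    repeat_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise LiftError(f"bad locus interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LiftedSegment:
    """A piece of a genomic interval mapped onto forward-consensus coordinates."""

    q_name: str
    q_start: int
    q_end: int
    read_id: str
    strand: str  # orientation of the chain the piece came through
    chrom: str
    g_start: int
    g_end: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class SiteEntry:
    record_id: str
    chrom: str
    g_start: int
    g_end: int
    strand: str
    sequence: str
    n_mismatch: int


@dataclass
class SiteSet:
    """All genomic sequences underlying one consensus locus, with provenance."""

    locus: LocusSpec
    consensus_sequence: str
    entries: list[SiteEntry] = field(default_factory=list)
    n_partial: int = 0  # instances not fully covering the locus
    n_indel_skipped: int = 0  # instances skipped because of indels in the locus

    def sequences(self) -> list[str]:
        return [e.sequence for e in self.entries]

    def to_fasta(self) -> str:
        lines = []
        for e in self.entries:
            lines.append(
                f">{e.record_id}|{e.chrom}:{e.g_start}-{e.g_end}|{e.strand}|nm={e.n_mismatch}"
            )
            lines.append(e.sequence)
        return "\n".join(lines) + "\n" if lines else ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.record_id, e.chrom, e.g_start, e.g_end, e.strand, e.sequence, e.n_mismatch)
                for e in self.entries
            ],
            columns=["record_id", "chrom", "g_start", "g_end", "strand", "sequence", "n_mismatch"],
        )


class _IndexedChain:
    """Chain with per-block absolute coordinates for O(log B) interval lookup."""

    __slots__ = ("chain", "t_abs", "q_abs", "sizes")

    def __init__(self, chain: Chain):
        self.chain = chain
        t = chain.t_start
        q = chain.q_start
        self.t_abs: list[int] = []
        self.q_abs: list[int] = []
        self.sizes: list[int] = []
        for b in chain.blocks:
            self.t_abs.append(t)
            self.q_abs.append(q)
            self.sizes.append(b.size)
            t += b.size + b.dt
            q += b.size + b.dq

    def map_interval(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map [start, end) to merged forward-consensus pieces, sorted."""
        ch = self.chain
        pieces: list[tuple[int, int]] = []
        i = max(0, bisect_right(self.t_abs, start) - 1)
        for j in range(i, len(self.sizes)):
            tb, qb, size = self.t_abs[j], self.q_abs[j], self.sizes[j]
            if tb >= end:
                break
            ps, pe = max(start, tb), min(end, tb + size)
            if pe <= ps:
                continue
            qs = qb + (ps - tb)
            qe = qs + (pe - ps)
            if ch.q_strand == "-":
                qs, qe = ch.q_size - qe, ch.q_size - qs
            pieces.append((qs, qe))
        pieces.sort()
        merged: list[list[int]] = []
        for s, e in pieces:
            if merged and merged[-1][1] == s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


class ChainIndex:
    """Chains indexed by chromosome for genomic interval queries."""

    def __init__(self, chains: Iterable[Chain]):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for ch in chains:
            idx = _IndexedChain(ch)
            self._trees.setdefault(ch.t_name, IntervalTree()).addi(
                ch.t_start, ch.t_end, idx
            )
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(self, chrom: str, start: int, end: int) -> list[_IndexedChain]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda ic: (ic.chain.t_start, ic.chain.chain_id))
        return hits


def lift_interval(
    index: ChainIndex, chrom: str, start: int, end: int, read_id: str = ""
) -> list[LiftedSegment]:
    """Map one genomic interval through every overlapping chain.

    Returns one LiftedSegment per (chain, merged consensus piece); bases
    falling in dt gaps are dropped.  No overlap is a valid empty result.
    """
    out: list[LiftedSegment] = []
    for ic in index.overlapping(chrom, start, end):
        ch = ic.chain
        for qs, qe in ic.map_interval(start, end):
            out.append(
                LiftedSegment(
                    q_name=ch.q_name,
                    q_start=qs,
                    q_end=qe,
                    read_id=read_id,
                    strand=ch.q_strand,
                    chrom=chrom,
                    g_start=max(start, ch.t_start),
                    g_end=min(end, ch.t_end),
                )
            )
    return out


def lift_reads(
    reads: pd.DataFrame, index: ChainIndex, dedup: bool = True
) -> list[LiftedSegment]:
    """liftIn for a BED-like read table (columns chrom, start, end, name).

    With ``dedup`` on, a read mapping to several genomic copies of one
    consensus contributes the pieces of exactly one mapping: the mapping
    whose first piece has the smallest (q_start, chrom, g_start).  This is
    how a multi-mapping read is counted once per consensus regardless of its
    genomic copy number.
    """
    has_name = "name" in reads.columns
    if dedup and not has_name:
        raise LiftError(
            "reads have no name column; name them or disable dedup"
        )
    segments: list[LiftedSegment] = []
    # best mapping per (read, consensus): key -> (sort_key, pieces)
    best: dict[tuple[str, str], tuple[tuple, list[LiftedSegment]]] = {}
    cols = ["chrom", "start", "end"] + (["name"] if has_name else [])
    for row in reads[cols].itertuples(index=False, name=None):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if has_name else ""
        if dedup and (name == "" or name == "."):
            raise LiftError("unnamed read encountered with dedup on")
        for ic in index.overlapping(chrom, start, end):
            ch = ic.chain
            pieces = [
                LiftedSegment(
                    q_name=ch.q_name,
                    q_start=qs,
                    q_end=qe,
                    read_id=name,
                    strand=ch.q_strand,
                    chrom=chrom,
                    g_start=max(start, ch.t_start),
                    g_end=min(end, ch.t_end),
                )
                for qs, qe in ic.map_interval(start, end)
            ]
            if not pieces:
                continue
            if not dedup:
                segments.extend(pieces)
                continue
            key = (name, ch.q_name)
            rank = (pieces[0].q_start, chrom, pieces[0].g_start)
            if key not in best or rank < best[key][0]:
                best[key] = (rank, pieces)
    if dedup:
        for _, pieces in best.values():
            segments.extend(pieces)
    return segments


def _consensus_to_genome_map(rec: RepeatAlignment) -> dict[int, int | None]:
    """Invert one record's alignment: consensus position -> forward-genome
    position (None where the consensus base is deleted in this instance)."""
    mapping: dict[int, int | None] = {}
    c = rec.c_start
    g, step = (rec.g_start, 1) if rec.strand == "+" else (rec.g_end - 1, -1)
    for gc, cc in zip(rec.aligned_genome, rec.aligned_consensus):
        if cc != "-":
            mapping[c] = g if gc != "-" else None
            c += 1
        if gc != "-":
            g += step
    return mapping


def _locus_has_insertion(rec: RepeatAlignment, start: int, end: int) -> bool:
    """True if the instance carries genome-only bases strictly inside the locus."""
    c = rec.c_start
    inside = False
    for gc, cc in zip(rec.aligned_genome, rec.aligned_consensus):
        if cc != "-":
            if c >= end:
                break
            inside = c >= start  # last consumed locus position is >= start
            c += 1
        elif gc != "-" and inside and c < end:
            # genome-only bases between two consumed locus positions
            return True
    return False


def lift_out(
    records: Sequence[RepeatAlignment],
    locus: LocusSpec,
    genome: GenomeSource,
    consensus_sequence: str,
    allow_indel: bool = False,
) -> SiteSet:
    """liftOut: extract the genomic sequence under ``locus`` from every
    instance of ``locus.repeat_id`` whose alignment fully covers it.

    Sequences are returned in consensus orientation (reverse complement of
    the genomic slice for minus-strand instances).  Instances with an indel
    inside the locus are skipped unless ``allow_indel``; then deletions are
    rendered as ``-`` and genomic insertions are dropped, so every sequence
    keeps length ``end - start``.
    """
    wanted = [r for r in records if r.repeat_id == locus.repeat_id]
    if not wanted:
        raise LiftError(f"no alignment records for repeat {locus.repeat_id!r}")
    if locus.end > len(consensus_sequence):
        raise LiftError("locus extends past the consensus sequence")
    ref = consensus_sequence[locus.start : locus.end].upper()
    result = SiteSet(locus=locus, consensus_sequence=ref)
    for rec in wanted:
        if rec.c_start > locus.start or rec.c_end < locus.end:
            result.n_partial += 1
            continue
        cmap = _consensus_to_genome_map(rec)
        gpos = [cmap[c] for c in range(locus.start, locus.end)]
        has_del = any(p is None for p in gpos)
        has_ins = _locus_has_insertion(rec, locus.start, locus.end)
        if (has_del or has_ins) and not allow_indel:
            result.n_indel_skipped += 1
            continue
        defined = [p for p in gpos if p is not None]
        g_lo, g_hi = min(defined), max(defined) + 1
        if not (has_del or has_ins):
            seq = genome.fetch(rec.chrom, g_lo, g_hi, rec.strand)
        else:
            span = genome.fetch(rec.chrom, g_lo, g_hi, "+")
            comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
            chars = []
            for p in gpos:
                if p is None:
                    chars.append("-")
                elif rec.strand == "+":
                    chars.append(span[p - g_lo])
                else:
                    chars.append(comp[span[p - g_lo]])
            seq = "".join(chars)
        nm = sum(a != b for a, b in zip(seq, ref))
        result.entries.append(
            SiteEntry(
                record_id=rec.record_id,
                chrom=rec.chrom,
                g_start=g_lo,
                g_end=g_hi,
                strand=rec.strand,
                sequence=seq,
                n_mismatch=nm,
            )
        )
    return result


def segments_to_bed(segments: Iterable[LiftedSegment]) -> str:
    """Lifted segments as BED on consensus coordinates (chrom = repeat_id)."""
    lines = [
        f"{s.q_name}\t{s.q_start}\t{s.q_end}\t{s.read_id or '.'}\t0\t{s.strand}"
        for s in segments
    ]
    return "\n".join(lines) + "\n" if lines else ""


def read_bed(source) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with chrom/start/end[/name/score/strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(
        source, sep="\t", header=None, comment="#", dtype={0: str}
    )
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", header=False, index=False)
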