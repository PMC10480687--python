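"""Compile repeat alignments into UCSC liftOver chains (genome -> consensus).

Each chain maps a genomic span (target, always "+" strand) onto a repeat
consensus span (query).  Substitution columns stay inside blocks; only
indels break blocks, matching liftOver semantics.  Minus-strand instances
produce ``q_strand == "-"`` with query coordinates expressed in the
reverse-complemented query frame, per the UCSC chain convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .repeatmasker_io import RepeatAlignment


class ChainError(ValueError):
    pass


@dataclass(frozen=True)
class Block:
    size: int
    dt: int  # target-only (genome) bases following the block
    dq: int  # query-only (consensus) bases following the block


@dataclass
class Chain:
    """A UCSC-style chain: ordered ungapped blocks between two coordinate frames."""

    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: tuple[Block, ...]
    t_strand: str = "+"

    def validate(self) -> None:
        sizes = sum(b.size for b in self.blocks)
        dts = sum(b.dt for b in self.blocks)
        dqs = sum(b.dq for b in self.blocks)
        if sizes + dts != self.t_end - self.t_start:
            raise ChainError(
                f"chain {self.chain_id}: target span {self.t_end - self.t_start} "
                f"!= blocks {sizes}+{dts}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ChainError(
                f"chain {self.chain_id}: query span {self.q_end - self.q_start} "
                f"!= blocks {sizes}+{dqs}"
            )
        if any(b.size <= 0 for b in self.blocks):
            raise ChainError(f"chain {self.chain_id}: zero-size block")
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise ChainError(f"chain {self.chain_id}: final block has gaps")
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ChainError(f"chain {self.chain_id}: target interval out of bounds")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ChainError(f"chain {self.chain_id}: query interval out of bounds")


def _merge(blocks: list[list[int]]) -> tuple[Block, ...]:
    """Canonical form: drop empty leading/trailing gaps, merge mergeable blocks."""
    merged: list[list[int]] = []
    for size, dt, dq in blocks:
        if merged and merged[-1][1] == 0 and merged[-1][2] == 0:
            merged[-1][0] += size
            merged[-1][1], merged[-1][2] = dt, dq
        else:
            merged.append([size, dt, dq])
    return tuple(Block(*b) for b in merged)


def columns_to_blocks(columns: Iterable[tuple[str, str]]) -> tuple[Block, ...]:
    """Scan aligned (genome_char, consensus_char) columns into chain blocks.

    Non-gap columns (matches and substitutions) extend the current block; a
    gap in the consensus consumes ``dt`` (genome-only base); a gap in the
    genome consumes ``dq``.
    """
    raw: list[list[int]] = []
    size = dt = dq = 0
    for g, c in columns:
        if g == "-" and c == "-":
            raise ChainError("column gapped on both sides")
        if g != "-" and c != "-":
            if dt or dq:
                raw.append([size, dt, dq])
                size = dt = dq = 0
            size += 1
        elif c == "-":
            if size == 0 and not raw:
                raise ChainError("alignment starts with a gap column")
            dt += 1
        else:
            if size == 0 and not raw:
                raise ChainError("alignment starts with a gap column")
            dq += 1
    if dt or dq:
        # a chain span cannot end in unaligned bases
        raise ChainError("alignment ends with a gap column")
    if size:
        raw.append([size, 0, 0])
    return _merge(raw)


def alignment_to_blocks(rec: RepeatAlignment) -> tuple[Block, ...]:
    """Blocks for a record's stored (consensus-forward) column order."""
    return columns_to_blocks(zip(rec.aligned_genome, rec.aligned_consensus))


def build_chains(
    records: Sequence[RepeatAlignment],
    consensus_sizes: dict[str, int],
    chrom_sizes: dict[str, int],
) -> list[Chain]:
    """One chain per alignment record; target = genome, query = consensus.

    chain_id is sequential in input order.  Minus-strand records are walked
    in genome-forward order so the target always ascends; their query
    coordinates land in the reversed consensus frame.
    """
    chains: list[Chain] = []
    for idx, rec in enumerate(records, 1):
        rec.validate()
        if rec.repeat_id not in consensus_sizes:
            raise ChainError(f"no consensus length for repeat {rec.repeat_id!r}")
        if rec.chrom not in chrom_sizes:
            raise ChainError(f"no chromosome length for {rec.chrom!r}")
        q_size = consensus_sizes[rec.repeat_id]
        if rec.c_end > q_size:
            raise ChainError(
                f"record {rec.record_id}: consensus end {rec.c_end} exceeds "
                f"length {q_size} of {rec.repeat_id} (stale consensus FASTA?)"
            )
        if rec.g_end > chrom_sizes[rec.chrom]:
            raise ChainError(f"record {rec.record_id}: beyond end of {rec.chrom}")
        if rec.strand == "+":
            cols = zip(rec.aligned_genome, rec.aligned_consensus)
            q_start, q_end = rec.c_start, rec.c_end
        else:
            # stored columns ascend in consensus; reverse so the genome
            # (target) ascends instead; gap roles are unchanged
            cols = zip(rec.aligned_genome[::-1], rec.aligned_consensus[::-1])
            q_start, q_end = q_size - rec.c_end, q_size - rec.c_start
        chain = Chain(
            score=rec.sw_score,
            t_name=rec.chrom,
            t_size=chrom_sizes[rec.chrom],
            t_start=rec.g_start,
            t_end=rec.g_end,
            q_name=rec.repeat_id,
            q_size=q_size,
            q_strand=rec.strand,
            q_start=q_start,
            q_end=q_end,
            chain_id=idx,
            blocks=columns_to_blocks(cols),
        )
        chain.validate()
        chains.append(chain)
    return chains


def write_chain(chains: Iterable[Chain]) -> str:
    """Serialize to the UCSC chain format consumed by liftOver."""
    parts: list[str] = []
    for ch in chains:
        ch.validate()
        parts.append(
            f"chain {ch.score} {ch.t_name} {ch.t_size} {ch.t_strand} "
            f"{ch.t_start} {ch.t_end} {ch.q_name} {ch.q_size} {ch.q_strand} "
            f"{ch.q_start} {ch.q_end} {ch.chain_id}"
        )
        for b in ch.blocks[:-1]:
            parts.append(f"{b.size}\t{b.dt}\t{b.dq}")
        parts.append(str(ch.blocks[-1].size))
        parts.append("")
    return "\n".join(parts) + "\n" if parts else ""


def parse_chain(text: str) -> list[Chain]:
    chains: list[Chain] = []
    header = None
    blocks: list[Block] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        ch = Chain(
            score=int(header[1]),
            t_name=header[2],
            t_size=int(header[3]),
            t_strand=header[4],
            t_start=int(header[5]),
            t_end=int(header[6]),
            q_name=header[7],
            q_size=int(header[8]),
            q_strand=header[9],
            q_start=int(header[10]),
            q_end=int(header[11]),
            chain_id=int(header[12]),
            blocks=tuple(blocks),
        )
        ch.validate()
        chains.append(ch)
        header, blocks = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("chain"):
            flush()
            header = line.split()
            if len(header) != 13:
                raise ChainError(f"bad chain header: {line!r}")
            continue
        toks = line.split()
        if header is None:
            raise ChainError(f"block line outside a chain: {line!r}")
        if len(toks) == 1:
            blocks.append(Block(int(toks[0]), 0, 0))
        elif len(toks) == 3:
            blocks.append(Block(int(toks[0]), int(toks[1]), int(toks[2])))
        else:
            raise ChainError(f"bad block line: {line!r}")
    flush()
    return chains
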