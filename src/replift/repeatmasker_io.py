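"""Parsers and writers for RepeatMasker ``.align`` / ``.out`` files and genome FASTA.

All coordinates are normalized to 0-based half-open at the I/O boundary
(RepeatMasker files are 1-based inclusive).  For complement ("C") records the
genomic interval stays on the forward genomic strand while the aligned
sequence strings are stored in *consensus-forward* orientation, i.e. the
stored ``aligned_genome`` is the reverse complement of the forward genomic
strand; ``strand == "-"`` records this.  This makes every downstream
column walk strand-uniform: the consensus coordinate always increases left
to right.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import reverse_complement as _rc

log = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN-")


class AlignParseError(ValueError):
    """Malformed ``.align`` / ``.out`` content; carries line number context."""


def revcomp(seq: str) -> str:
    """Reverse complement preserving ``-`` gap characters."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
    return "".join(comp[c] for c in reversed(seq))


@dataclass
class RepeatAlignment:
    """One genomic repeat instance and its gapped alignment to a consensus.

    ``aligned_genome`` / ``aligned_consensus`` are equal-length strings over
    ``ACGTN-`` in consensus-forward orientation (see module docstring).
    """

    chrom: str
    g_start: int
    g_end: int
    strand: str
    repeat_id: str
    repeat_class: str
    c_start: int
    c_end: int
    sw_score: int
    divergence_pct: float
    aligned_genome: str
    aligned_consensus: str
    record_id: str

    def validate(self) -> None:
        if len(self.aligned_genome) != len(self.aligned_consensus):
            raise AlignParseError(
                f"record {self.record_id}: aligned string lengths differ "
                f"({len(self.aligned_genome)} vs {len(self.aligned_consensus)})"
            )
        bad = set(self.aligned_genome) | set(self.aligned_consensus)
        if not bad <= _VALID_CHARS:
            raise AlignParseError(
                f"record {self.record_id}: invalid characters {bad - _VALID_CHARS}"
            )
        ng = sum(c != "-" for c in self.aligned_genome)
        if ng != self.g_end - self.g_start:
            raise AlignParseError(
                f"record {self.record_id}: genome span {self.g_end - self.g_start} "
                f"!= {ng} aligned genome bases"
            )
        nc = sum(c != "-" for c in self.aligned_consensus)
        if nc != self.c_end - self.c_start:
            raise AlignParseError(
                f"record {self.record_id}: consensus span {self.c_end - self.c_start} "
                f"!= {nc} aligned consensus bases"
            )
        for i, (a, b) in enumerate(zip(self.aligned_genome, self.aligned_consensus)):
            if a == "-" and b == "-":
                raise AlignParseError(
                    f"record {self.record_id}: column {i} gapped on both sides"
                )
        if self.strand not in "+-":
            raise AlignParseError(f"record {self.record_id}: bad strand {self.strand!r}")
        if not (0 <= self.g_start < self.g_end):
            raise AlignParseError(f"record {self.record_id}: bad genomic interval")
        if not (0 <= self.c_start < self.c_end):
            raise AlignParseError(f"record {self.record_id}: bad consensus interval")


@dataclass
class RepeatInstance:
    """One row of a RepeatMasker ``.out`` table, normalized."""

    chrom: str
    g_start: int
    g_end: int
    strand: str
    repeat_id: str
    repeat_class: str
    c_start: int
    c_end: int
    record_id: str

    def __post_init__(self) -> None:
        if self.g_start >= self.g_end:
            raise AlignParseError(f"instance {self.record_id}: g_start >= g_end")
        if self.strand not in "+-":
            raise AlignParseError(f"instance {self.record_id}: bad strand")


class GenomeSource:
    """In-memory genome: uppercase sequence fetch by (chrom, interval, strand)."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSource":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self._seqs[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} outside [0, {len(seq)})")
        sub = seq[start:end]
        return _rc(sub) if strand == "-" else sub


def _split_name(name: str) -> tuple[str, str]:
    """Split ``L1toy#LINE/L1`` into (repeat_id, repeat_class)."""
    if "#" in name:
        rid, rclass = name.split("#", 1)
        return rid, rclass
    return name, ""


# header: score div del ins chrom gbeg gend (gleft) [C] name cbeg cend (cleft) id
#     or: score div del ins chrom gbeg gend (gleft) C name (cleft) cend cbeg id
_HEADER_RE = re.compile(
    r"^\s*(\d+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+(\S+)\s+(\d+)\s+(\d+)\s+\((\d+)\)\s+"
    r"(C\s+)?(\S+)\s+(\(?\d+\)?)\s+(\d+)\s+(\(?\d+\)?)(?:\s+(\S+))?\s*$"
)

_SKIP_PREFIXES = ("Matrix", "Transitions", "Gap_init", "Kimura")


def _parse_int(tok: str) -> int:
    return int(tok.strip("()"))


def parse_align(stream: Iterable[str] | str) -> list[RepeatAlignment]:
    """Parse a RepeatMasker-style ``.align`` file into RepeatAlignment records.

    The dialect accepted is the one :func:`write_align` emits plus common
    RepeatMasker noise lines (``Matrix``, ``Transitions``, ``Gap_init``,
    per-column quality marks), which are skipped.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    records: list[RepeatAlignment] = []
    header = None
    header_lineno = 0
    g_parts: list[str] = []
    c_parts: list[str] = []
    auto_id = 0

    def flush() -> None:
        nonlocal header, g_parts, c_parts, auto_id
        if header is None:
            return
        (score, div, chrom, gbeg, gend, is_c, name, f1, f2, f3, rec_id) = header
        repeat_id, repeat_class = _split_name(name)
        if is_c:
            # fields: (cleft) cend cbeg
            c_end, c_beg = _parse_int(f2), _parse_int(f3)
        else:
            c_beg, c_end = _parse_int(f1), _parse_int(f2)
        if not g_parts or not c_parts:
            raise AlignParseError(
                f"line {header_lineno}: record {rec_id or name} has no alignment lines"
            )
        g_seq = "".join(g_parts).upper()
        c_seq = "".join(c_parts).upper()
        if is_c:
            # file shows forward genome vs revcomp consensus; store
            # consensus-forward
            g_seq, c_seq = revcomp(g_seq), revcomp(c_seq)
        if rec_id is None:
            auto_id += 1
            rec_id = f"rec{auto_id}"
        rec = RepeatAlignment(
            chrom=chrom,
            g_start=gbeg - 1,
            g_end=gend,
            strand="-" if is_c else "+",
            repeat_id=repeat_id,
            repeat_class=repeat_class,
            c_start=c_beg - 1,
            c_end=c_end,
            sw_score=score,
            divergence_pct=div,
            aligned_genome=g_seq,
            aligned_consensus=c_seq,
            record_id=rec_id,
        )
        rec.validate()
        records.append(rec)
        header = None
        g_parts, c_parts = [], []

    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        m = _HEADER_RE.match(line)
        if m and stripped[0].isdigit():
            flush()
            (score, div, _dele, _ins, chrom, gbeg, gend, _gleft,
             c_flag, name, f1, f2, f3, rec_id) = m.groups()
            header = (int(score), float(div), chrom, int(gbeg), int(gend),
                      c_flag is not None, name, f1, f2, f3, rec_id)
            header_lineno = lineno
            continue
        if stripped[0].isdigit():
            raise AlignParseError(f"line {lineno}: malformed header: {stripped!r}")
        if header is None or stripped.startswith(_SKIP_PREFIXES):
            if header is None and not stripped.startswith(_SKIP_PREFIXES):
                log.warning("skipping unrecognized line %d: %r", lineno, stripped)
            continue
        # alignment line: [C] label start SEQ end  (or quality-mark row)
        toks = stripped.split()
        if toks[0] == "C":
            toks = toks[1:]
        if len(toks) == 4 and toks[1].isdigit() and toks[3].isdigit():
            label, _, seq, _ = toks
            chrom = header[2]
            if label == chrom:
                g_parts.append(seq)
            else:
                c_parts.append(seq)
        else:
            # quality / annotation row between the pair -> skip
            continue
    flush()
    return records


def write_align(records: Iterable[RepeatAlignment], width: int = 50) -> str:
    """Serialize records into the ``.align`` dialect parsed by :func:`parse_align`.

    Records are validated first; C records are rendered RepeatMasker-style
    (forward genome vs reverse-complemented consensus, descending consensus
    coordinates).
    """
    records = list(records)
    for rec in records:
        rec.validate()
    out: list[str] = []
    for rec in records:
        name = rec.repeat_id + (f"#{rec.repeat_class}" if rec.repeat_class else "")
        is_c = rec.strand == "-"
        if is_c:
            repeat_fields = f"(0) {rec.c_end} {rec.c_start + 1}"
            flag = "C "
        else:
            repeat_fields = f"{rec.c_start + 1} {rec.c_end} (0)"
            flag = ""
        out.append(
            f"{rec.sw_score} {rec.divergence_pct:.2f} 0.00 0.00 "
            f"{rec.chrom} {rec.g_start + 1} {rec.g_end} (0) "
            f"{flag}{name} {repeat_fields} {rec.record_id}"
        )
        out.append("")
        if is_c:
            g_seq = revcomp(rec.aligned_genome)  # forward genomic strand
            c_seq = revcomp(rec.aligned_consensus)
        else:
            g_seq, c_seq = rec.aligned_genome, rec.aligned_consensus
        g_pos = rec.g_start + 1  # 1-based running coordinates
        c_pos = rec.c_end if is_c else rec.c_start + 1
        for off in range(0, len(g_seq), width):
            g_chunk = g_seq[off : off + width]
            c_chunk = c_seq[off : off + width]
            n_g = sum(c != "-" for c in g_chunk)
            n_c = sum(c != "-" for c in c_chunk)
            g_last = g_pos + n_g - 1 if n_g else g_pos - 1
            out.append(f"  {rec.chrom} {g_pos} {g_chunk} {g_last}")
            if is_c:
                c_last = c_pos - n_c + 1 if n_c else c_pos + 1
                out.append(f"C {rec.repeat_id} {c_pos} {c_chunk} {c_last}")
                c_pos = c_last - 1
            else:
                c_last = c_pos + n_c - 1 if n_c else c_pos - 1
                out.append(f"  {rec.repeat_id} {c_pos} {c_chunk} {c_last}")
                c_pos = c_last + 1
            g_pos = g_last + 1
            out.append("")
        out.append("Matrix = synthetic")
        out.append("")
    return "\n".join(out) + "\n"


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)  ID\n"
    "\n"
)


def parse_out(stream: Iterable[str] | str) -> list[RepeatInstance]:
    """Parse a RepeatMasker ``.out`` table (3 header lines then rows)."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    instances: list[RepeatInstance] = []
    for lineno, line in enumerate(lines, 1):
        toks = line.split()
        if not toks or not toks[0].isdigit():
            continue  # header / blank
        try:
            chrom = toks[4]
            gbeg, gend = int(toks[5]), int(toks[6])
            strand_tok = toks[8]
            repeat_id = toks[9]
            repeat_class = toks[10]
            if strand_tok == "C":
                strand = "-"
                c_end, c_beg = _parse_int(toks[12]), _parse_int(toks[13])
            else:
                strand = "+"
                c_beg, c_end = _parse_int(toks[11]), _parse_int(toks[12])
            rec_id = toks[14] if len(toks) > 14 else str(len(instances) + 1)
        except (IndexError, ValueError) as exc:
            raise AlignParseError(f"line {lineno}: bad .out row: {exc}") from exc
        instances.append(
            RepeatInstance(
                chrom=chrom,
                g_start=gbeg - 1,
                g_end=gend,
                strand=strand,
                repeat_id=repeat_id,
                repeat_class=repeat_class,
                c_start=c_beg - 1,
                c_end=c_end,
                record_id=rec_id,
            )
        )
    return instances


def write_out(instances: Iterable[RepeatInstance]) -> str:
    """Serialize instances into a ``.out`` table readable by :func:`parse_out`."""
    rows = [_OUT_HEADER.rstrip("\n")]
    for inst in instances:
        if inst.strand == "-":
            repeat_fields = f"(0) {inst.c_end} {inst.c_start + 1}"
            strand_tok = "C"
        else:
            repeat_fields = f"{inst.c_start + 1} {inst.c_end} (0)"
            strand_tok = "+"
        rows.append(
            f"  100 10.0  0.0  0.0  {inst.chrom} {inst.g_start + 1} {inst.g_end} (0) "
            f"{strand_tok} {inst.repeat_id} {inst.repeat_class or 'Unknown'} "
            f"{repeat_fields} {inst.record_id}"
        )
    return "\n".join(rows) + "\n"


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], width: int = 70) -> str:
    chunks = []
    for name, seq in sequences.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    return "\n".join(chunks) + "\n"
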