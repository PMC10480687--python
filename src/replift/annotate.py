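"""Annotate peaks / binding-site intervals with containing or nearby repeats.

Each peak is assigned the repeat instance with maximal overlap (ties broken
by smallest distance, then alphabetical repeat name, then genomic start);
peaks without overlap are "near" an instance within ``max_distance`` bp
(edge-to-edge) or "none".  Overlapping peaks also get the consensus
coordinates of their overlap, lifted through the chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .lift import ChainIndex, lift_interval
from .repeatmasker_io import RepeatInstance


@dataclass
class PeakAnnotation:
    chrom: str
    start: int
    end: int
    name: str
    status: str  # within | near | none
    repeat_id: str | None = None
    repeat_class: str | None = None
    overlap_bp: int = 0
    distance_bp: int = 0
    consensus_pieces: list[tuple[str, int, int]] = field(default_factory=list)


def _distance(p_start: int, p_end: int, i_start: int, i_end: int) -> int:
    if p_end <= i_start:
        return i_start - p_end
    if i_end <= p_start:
        return p_start - i_end
    return 0


def annotate_intervals(
    peaks: pd.DataFrame,
    instances: Sequence[RepeatInstance],
    chains: ChainIndex | None = None,
    max_distance: int = 500,
) -> list[PeakAnnotation]:
    """Annotate BED-like peaks (chrom/start/end[/name]) against repeat instances.

    ``max_distance`` bounds the "near" call (edge-to-edge, default 500 bp).
    The chosen-instance rule is order-free: instance list permutations give
    identical annotations.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for inst in instances:
        trees.setdefault(inst.chrom, IntervalTree()).addi(
            inst.g_start, inst.g_end, inst
        )
    has_name = "name" in peaks.columns
    out: list[PeakAnnotation] = []
    cols = ["chrom", "start", "end"] + (["name"] if has_name else [])
    for row in peaks[cols].itertuples(index=False, name=None):
        chrom, p_start, p_end = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if has_name else f"peak_{len(out) + 1}"
        tree = trees.get(chrom)
        candidates = (
            [iv.data for iv in tree.overlap(p_start - max_distance, p_end + max_distance)]
            if tree is not None
            else []
        )
        best = None
        best_key = None
        for inst in candidates:
            ov = min(p_end, inst.g_end) - max(p_start, inst.g_start)
            ov = max(ov, 0)
            dist = _distance(p_start, p_end, inst.g_start, inst.g_end)
            key = (-ov, dist, inst.repeat_id, inst.g_start, inst.record_id)
            if best_key is None or key < best_key:
                best, best_key = inst, key
        ann = PeakAnnotation(chrom=chrom, start=p_start, end=p_end, name=name,
                             status="none")
        if best is not None:
            ov = max(0, min(p_end, best.g_end) - max(p_start, best.g_start))
            dist = _distance(p_start, p_end, best.g_start, best.g_end)
            if ov > 0:
                ann.status = "within"
                ann.overlap_bp = ov
                ann.distance_bp = 0
            elif dist <= max_distance:
                ann.status = "near"
                ann.distance_bp = dist
            if ann.status != "none":
                ann.repeat_id = best.repeat_id
                ann.repeat_class = best.repeat_class
            if ov > 0 and chains is not None:
                o_start = max(p_start, best.g_start)
                o_end = min(p_end, best.g_end)
                ann.consensus_pieces = [
                    (seg.q_name, seg.q_start, seg.q_end)
                    for seg in lift_interval(chains, chrom, o_start, o_end)
                ]
        out.append(ann)
    return out


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        pieces = ";".join(f"{q}:{s}-{e}" for q, s, e in a.consensus_pieces)
        rows.append(
            (a.chrom, a.start, a.end, a.name, a.status, a.repeat_id or ".",
             a.repeat_class or ".", a.overlap_bp, a.distance_bp, pieces or ".")
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "status", "repeat_id",
                 "repeat_class", "overlap_bp", "distance_bp", "consensus_pieces"],
    )
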