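"""Windowed coverage and Fold-Change-over-Control on consensus coordinates.

ChIP and input reads are lifted onto a repeat consensus, summed into fixed
windows (default 10 nt), and the F.C.C. ratio

    fcc_k = ((chip_k + alpha) / N_chip) / ((input_k + alpha) / N_input)

is computed per window, where N_chip / N_input are the TOTAL library sizes
(pre-lift).  Normalizing by library totals rather than lifted-read counts
keeps F.C.C. comparable across repeat families: the ratio reflects the mean
per-site enrichment of all instances regardless of repeat copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lift import LiftedSegment


class SignalError(ValueError):
    pass


def coverage(
    segments: Iterable[LiftedSegment | tuple[int, int]],
    length: int,
    window: int = 10,
) -> np.ndarray:
    """Per-window base-coverage sums for segments on one consensus.

    Every segment base increments per-base coverage; window ``k`` sums
    coverage over ``[k*w, (k+1)*w)``; the last window may be partial.
    """
    if window <= 0 or length <= 0:
        raise SignalError("length and window must be positive")
    base = np.zeros(length, dtype=np.int64)
    for seg in segments:
        if isinstance(seg, tuple):
            s, e = seg
        else:
            s, e = seg.q_start, seg.q_end
        if s < 0 or e > length:
            raise SignalError(
                f"segment [{s}, {e}) outside consensus [0, {length}) — corrupt chain?"
            )
        base[s:e] += 1
    edges = np.arange(0, length, window)
    return np.add.reduceat(base, edges)


@dataclass
class SignalTrack:
    """Per-window ChIP/input counts and F.C.C. on one consensus."""

    q_name: str
    length: int
    window: int
    chip: np.ndarray
    input: np.ndarray
    fcc: np.ndarray
    low_confidence: np.ndarray
    n_chip: int
    n_input: int
    alpha: float

    @property
    def n_windows(self) -> int:
        return len(self.chip)

    def window_bounds(self) -> list[tuple[int, int]]:
        return [
            (k * self.window, min((k + 1) * self.window, self.length))
            for k in range(self.n_windows)
        ]

    def to_frame(self) -> pd.DataFrame:
        bounds = self.window_bounds()
        return pd.DataFrame(
            {
                "q_name": self.q_name,
                "win_start": [b[0] for b in bounds],
                "win_end": [b[1] for b in bounds],
                "chip": self.chip,
                "input": self.input,
                "fcc": self.fcc,
                "low_confidence": self.low_confidence,
            }
        )


def compute_fcc(
    chip_counts: np.ndarray,
    input_counts: np.ndarray,
    n_chip: int,
    n_input: int,
    alpha: float = 1.0,
    q_name: str = "",
    length: int | None = None,
    window: int = 10,
    min_input: int = 5,
) -> SignalTrack:
    """F.C.C. per window; zero-denominator windows get NaN and are flagged.

    ``min_input`` flags windows whose raw input count is too low to trust
    the ratio (default 5); the flag never alters the ratio itself.
    """
    chip_counts = np.asarray(chip_counts, dtype=np.int64)
    input_counts = np.asarray(input_counts, dtype=np.int64)
    if chip_counts.shape != input_counts.shape:
        raise SignalError("ChIP and input window grids differ")
    if n_chip <= 0 or n_input <= 0:
        raise SignalError("library sizes must be positive")
    num = (chip_counts + alpha) / n_chip
    den = (input_counts + alpha) / n_input
    fcc = np.full(chip_counts.shape, np.nan)
    ok = den > 0
    fcc[ok] = num[ok] / den[ok]
    low = (input_counts < min_input) | ~ok
    if length is None:
        length = len(chip_counts) * window
    n_expected = math.ceil(length / window)
    if n_expected != len(chip_counts):
        raise SignalError("window count inconsistent with consensus length")
    return SignalTrack(
        q_name=q_name,
        length=length,
        window=window,
        chip=chip_counts,
        input=input_counts,
        fcc=fcc,
        low_confidence=low,
        n_chip=n_chip,
        n_input=n_input,
        alpha=alpha,
    )


_HEADER = "track type=bedGraph"


def export_track(track: SignalTrack) -> tuple[str, str]:
    """Serialize to (bedGraph text, low-confidence mask text).

    The bedGraph carries finite F.C.C. values on consensus coordinates
    (chrom column = consensus name); the mask lists flagged windows.
    """
    lines = [f"{_HEADER} name={track.q_name or 'fcc'}"]
    mask = [f"{_HEADER} name={track.q_name or 'fcc'}_lowconf_mask"]
    for (s, e), v, flagged in zip(
        track.window_bounds(), track.fcc, track.low_confidence
    ):
        if np.isfinite(v):
            lines.append(f"{track.q_name}\t{s}\t{e}\t{v:.6g}")
        if flagged:
            mask.append(f"{track.q_name}\t{s}\t{e}\t1")
    return "\n".join(lines) + "\n", "\n".join(mask) + "\n"


def import_track(text: str) -> pd.DataFrame:
    """Read a bedGraph produced by :func:`export_track` back into a table."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("track"):
            continue
        chrom, s, e, v = line.split("\t")
        rows.append((chrom, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["q_name", "win_start", "win_end", "fcc"])


def stranded_tracks(
    segments: Sequence[LiftedSegment],
    read_strands: dict[str, str] | None,
    length: int,
    window: int = 10,
) -> dict[str, np.ndarray]:
    """Window counts partitioned by source-read BED strand, plus combined.

    ``read_strands`` maps read id -> "+"/"-"; missing or None means all
    reads land in the combined track only.
    """
    out: dict[str, list] = {"+": [], "-": [], "both": []}
    for seg in segments:
        out["both"].append(seg)
        if read_strands is not None:
            st = read_strands.get(seg.read_id)
            if st in ("+", "-"):
                out[st].append(seg)
    return {k: coverage(v, length, window) for k, v in out.items()}
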