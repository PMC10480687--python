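"""Independent brute-force oracles used to cross-check the lifting code.

These walk aligned columns directly and never touch the chain machinery.
"""

from __future__ import annotations

from replift import RepeatAlignment


def column_pairs(rec: RepeatAlignment) -> list[tuple[int, int]]:
    """(forward-genome position, forward-consensus position) for every
    aligned (non-gap/non-gap) column, by naive column walk."""
    pairs: list[tuple[int, int]] = []
    c = rec.c_start
    g, step = (rec.g_start, 1) if rec.strand == "+" else (rec.g_end - 1, -1)
    for gc, cc in zip(rec.aligned_genome, rec.aligned_consensus):
        if gc != "-" and cc != "-":
            pairs.append((g, c))
        if gc != "-":
            g += step
        if cc != "-":
            c += 1
    return pairs


def genome_to_consensus_map(rec: RepeatAlignment) -> dict[int, int]:
    return dict(column_pairs(rec))


def brute_force_scan(matrix, consensus: str) -> tuple[int, str, float]:
    """Exhaustive double-strand window evaluation with plain Python loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    order = "ACGT"
    L = matrix.shape[1]
    best = None
    for off in range(len(consensus) - L + 1):
        window = consensus[off : off + L]
        if "N" in window:
            continue
        for strand in "+-":
            seq = window if strand == "+" else "".join(
                comp[c] for c in reversed(window)
            )
            e = 0.0
            for i, ch in enumerate(seq):
                e += matrix[order.index(ch), i]
            if best is None or e < best[2]:
                best = (off, strand, e)
    return best
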