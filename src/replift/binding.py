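"""Position frequency matrices and additive position-energy binding models.

A PFM records per-position base frequencies of a lifted-out site set.  A
PEM (position energy matrix, e.g. derived from Spec-seq) assigns each base
at each position an energy contribution in kT, lower = stronger binding;
under the additive model the energy of a site ``s`` is

    E(s) = sum_i  eps(s_i, i)

Energies are kept on the matrix's own scale (no implicit re-anchoring), so
thresholds such as -4.5 kT refer to the matrix as supplied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lift import SiteSet
from .repeatmasker_io import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class BindingError(ValueError):
    pass


def _matrix_to_tsv(matrix: np.ndarray) -> str:
    L = matrix.shape[1]
    df = pd.DataFrame(matrix, index=list(BASES), columns=range(1, L + 1))
    df.index.name = "base"
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", float_format="%.10g")
    return buf.getvalue()


def write_matrix(matrix: np.ndarray) -> str:
    """4 x L TSV, row order A,C,G,T, header row of 1-based positions."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != 4 or matrix.ndim != 2:
        raise BindingError(f"matrix must be 4 x L, got shape {matrix.shape}")
    return _matrix_to_tsv(matrix)


def read_matrix(text: str) -> np.ndarray:
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    if list(df.index) != list(BASES):
        raise BindingError(
            f"expected 4 rows labelled A,C,G,T; got {list(df.index)}"
        )
    mat = df.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise BindingError("matrix contains non-finite values")
    return mat


@dataclass
class PFM:
    """Position frequency matrix with the pseudocount used to build it."""

    matrix: np.ndarray  # shape (4, L), columns sum to 1
    n_sites: int
    beta: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise BindingError(f"PFM columns must sum to 1; got {sums}")
        if (self.matrix < 0).any():
            raise BindingError("PFM has negative frequencies")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (2 + sum f log2 f)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.matrix > 0, self.matrix * np.log2(self.matrix), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def to_tsv(self) -> str:
        return _matrix_to_tsv(self.matrix)

    @classmethod
    def from_tsv(cls, text: str, n_sites: int = 0, beta: float = 0.0) -> "PFM":
        return cls(read_matrix(text), n_sites=n_sites, beta=beta)


@dataclass
class PEM:
    """Position energy matrix in kT; lower energy = stronger binding."""

    matrix: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise BindingError("PEM must be 4 x L")
        if not np.isfinite(self.matrix).all():
            raise BindingError("PEM has non-finite energies")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def minimum_energy_sequence(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmin(axis=0))

    def minimum_energy(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    def anchored(self) -> "PEM":
        """Re-anchor so each position's minimum contribution is 0 (explicit
        utility; never applied implicitly)."""
        return PEM(self.matrix - self.matrix.min(axis=0, keepdims=True))

    def to_tsv(self) -> str:
        return _matrix_to_tsv(self.matrix)

    @classmethod
    def from_tsv(cls, text: str) -> "PEM":
        return cls(read_matrix(text))


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise BindingError(f"sequence contains non-ACGT character {exc}") from exc


def build_pfm(sites: SiteSet | Sequence[str], beta: float = 0.0) -> PFM:
    """PFM from equal-length ungapped sites: f(b,i) = (count(b,i)+beta)/(n_i+4*beta).

    ``N`` bases are excluded from both numerator and denominator at their
    position; gapped sequences are rejected (re-extract with allow_indel off).
    """
    seqs = sites.sequences() if isinstance(sites, SiteSet) else list(sites)
    if not seqs:
        raise BindingError("no sites")
    L = len(seqs[0])
    counts = np.zeros((4, L), dtype=float)
    for s in seqs:
        if len(s) != L:
            raise BindingError("sites differ in length")
        if "-" in s:
            raise BindingError(
                "gapped site encountered; build the PFM from allow_indel=False sites"
            )
        for i, c in enumerate(s.upper()):
            if c == "N":
                continue
            try:
                counts[_BASE_INDEX[c], i] += 1
            except KeyError:
                raise BindingError(f"invalid base {c!r} at position {i}") from None
    denom = counts.sum(axis=0) + 4 * beta
    if (denom == 0).any():
        raise BindingError("a position has no informative (non-N) bases")
    freq = (counts + beta) / denom
    return PFM(freq, n_sites=len(seqs), beta=beta)


def predict_energy(pem: PEM, seq: str) -> float:
    """Additive binding energy E(s) = sum_i eps(s_i, i), in kT.

    The sequence must match the matrix length exactly and contain no N
    (no implicit trimming or imputation).
    """
    seq = seq.upper()
    if len(seq) != pem.length:
        raise BindingError(
            f"sequence length {len(seq)} != matrix length {pem.length}"
        )
    idx = _encode(seq)
    return float(pem.matrix[idx, np.arange(pem.length)].sum())


@dataclass
class EnergySummary:
    """Predicted energies of a site set with a threshold census."""

    energies: list[float]
    threshold: float
    fraction_below: float
    n_excluded: int = 0  # sites containing N, not scored

    @property
    def n(self) -> int:
        return len(self.energies)


def score_siteset(
    pem: PEM, sites: SiteSet | Sequence[str], threshold: float
) -> EnergySummary:
    """Score every scoreable site; fraction_below = |{E < threshold}| / n."""
    seqs = sites.sequences() if isinstance(sites, SiteSet) else list(sites)
    energies: list[float] = []
    n_excluded = 0
    for s in seqs:
        s = s.upper()
        if "N" in s:
            n_excluded += 1
            continue
        energies.append(predict_energy(pem, s))
    if not energies:
        raise BindingError("no scoreable (N-free) sites")
    frac = sum(e < threshold for e in energies) / len(energies)
    return EnergySummary(
        energies=energies,
        threshold=threshold,
        fraction_below=frac,
        n_excluded=n_excluded,
    )


def scan_consensus(pem: PEM, consensus: str) -> tuple[int, str, float]:
    """Best (lowest-energy) window on either strand of a consensus.

    Slides by 1; ties broken by smallest offset, then "+" strand.  Windows
    containing N are skipped.  Returns (offset, strand, E_min); the offset
    always refers to the forward consensus coordinate of the window start.
    """
    consensus = consensus.upper()
    L = pem.length
    if len(consensus) < L:
        raise BindingError("consensus shorter than the matrix")
    best: tuple[int, str, float] | None = None
    for off in range(len(consensus) - L + 1):
        window = consensus[off : off + L]
        if "N" in window:
            continue
        for strand, s in (("+", window), ("-", revcomp(window))):
            e = predict_energy(pem, s)
            if best is None or e < best[2]:
                best = (off, strand, e)
    if best is None:
        raise BindingError("no N-free window to scan")
    return best
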