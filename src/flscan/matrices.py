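"""Motif matrix data model, log-odds transformation, and file formats.

A motif travels through three representations:

``CountMatrix``       observation counts per position and nucleotide,
                      e.g. a JASPAR position frequency matrix;
``ProbabilityMatrix`` per-position nucleotide probabilities, obtained from
                      counts by background-proportional pseudocounting;
``ScoringMatrix``     the log-odds PWM ``M(i, a) = log(I(i, a) / q_a)``
                      together with an integer-discretized twin
                      (scores x 10^d, round half away from zero) that the
                      threshold dynamic program and the scanning engines
                      share, so score comparisons carry exact p-value
                      semantics.

Matrices are oriented JASPAR-style: rows A, C, G, T; columns are motif
positions.  The alphabet is strictly {A, C, G, T}; other symbols are
tolerated in sequences (they exclude windows from scoring) but not in
motifs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}

#: byte-level lookup: A/C/G/T (either case) -> 0..3, anything else -> 4
ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _s in enumerate(ALPHABET):
    ENCODE_TABLE[ord(_s)] = _i
    ENCODE_TABLE[ord(_s.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ENCODE_TABLE[raw]


class MatrixError(ValueError):
    """Invalid motif matrix or background input."""


@dataclass(frozen=True)
class Background:
    """Nucleotide background distribution q over {A, C, G, T}.

    Conceptually this is the constant-row background matrix B with
    B(i, a) = q_a for every position i; only the single row is stored.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise MatrixError(f"background must have exactly 4 probabilities, got shape {p.shape}")
        if np.any(p < 0):
            raise MatrixError("background probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise MatrixError(f"background probabilities must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "probs", p)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_dict(cls, d: dict) -> "Background":
        return cls(np.array([d[s] for s in ALPHABET], dtype=float))

    def __getitem__(self, symbol: Union[str, int]) -> float:
        if isinstance(symbol, str):
            symbol = _SYMBOL_INDEX[symbol.upper()]
        return float(self.probs[symbol])

    def as_dict(self) -> dict:
        return {s: float(self.probs[i]) for i, s in enumerate(ALPHABET)}


@dataclass(frozen=True)
class CountMatrix:
    """Observation counts per motif position: shape (width, 4), rows=positions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise MatrixError(f"counts must be (width, 4) with width >= 1, got {c.shape}")
        if np.any(c < 0):
            raise MatrixError("counts must be nonnegative")
        if np.any(c.sum(axis=1) <= 0):
            bad = int(np.flatnonzero(c.sum(axis=1) <= 0)[0]) + 1
            raise MatrixError(f"position {bad} has no observations")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Signal model I(i, a): per-position nucleotide probabilities, shape (width, 4)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise MatrixError(f"probs must be (width, 4) with width >= 1, got {p.shape}")
        colsums = p.sum(axis=1)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(colsums - 1.0))) + 1
            raise MatrixError(f"position {bad} probabilities sum to {colsums[bad - 1]!r}, not 1")
        if np.any(p <= 0):
            i, a = np.unravel_index(int(np.argmin(p)), p.shape)
            raise MatrixError(
                f"probability for symbol {ALPHABET[a]} at position {i + 1} is not "
                f"strictly positive ({p[i, a]!r}); add pseudocounts first"
            )
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class ScoringMatrix:
    """Log-odds PWM plus its integer grid twin.

    ``scores`` holds real log-odds values, shape (width, 4), rows=positions.
    ``int_scores[i, a] == round(scores[i, a] * 10**scale_digits)`` with
    round-half-away-from-zero; all engines and the threshold DP operate on
    ``int_scores`` so that "score >= threshold" means exactly what the DP
    computed.
    """

    scores: np.ndarray
    scale_digits: int = 3
    int_scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4 or s.shape[0] < 1:
            raise MatrixError(f"scores must be (width, 4) with width >= 1, got {s.shape}")
        object.__setattr__(self, "scores", s)
        expected = _round_half_away(s * 10.0**self.scale_digits).astype(np.int64)
        if self.int_scores is None:
            object.__setattr__(self, "int_scores", expected)
        else:
            given = np.asarray(self.int_scores, dtype=np.int64)
            if not np.array_equal(given, expected):
                raise MatrixError("int_scores inconsistent with scores at this scale")
            object.__setattr__(self, "int_scores", given)

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def scale(self) -> float:
        """Multiplier from real scores to the integer grid (10**scale_digits)."""
        return 10.0**self.scale_digits

    def to_real(self, grid_score) -> float:
        """Convert an integer grid score back to real score units."""
        return float(grid_score) / self.scale


def add_pseudocounts(
    counts: CountMatrix, bg: Background, total_weight: float = 1.0
) -> ProbabilityMatrix:
    """Turn counts into probabilities with background-proportional pseudocounts.

    Each position i gets ``total_weight`` pseudo-observations distributed
    as the background:

        I(i, a) = (counts[i, a] + total_weight * q_a) / (colsum_i + total_weight)

    With total_weight > 0 and a strictly positive background every entry is
    strictly positive, so the log-odds transform is well defined.
    """
    if total_weight < 0:
        raise MatrixError("total_weight must be nonnegative")
    c = counts.counts
    if total_weight == 0 and np.any(c == 0):
        i, a = map(int, next(zip(*np.nonzero(c == 0))))
        raise MatrixError(
            f"count for symbol {ALPHABET[a]} at position {i + 1} is zero and "
            "total_weight is 0: a zero probability would remain"
        )
    pseudo = total_weight * bg.probs
    probs = (c + pseudo[None, :]) / (c.sum(axis=1, keepdims=True) + total_weight)
    return ProbabilityMatrix(probs)


def ensure_strictly_positive(
    probs: np.ndarray, bg: Background, epsilon: float = 0.01
) -> ProbabilityMatrix:
    """Repair a probability matrix that contains zeros (e.g. read from a file).

    Blends ``epsilon`` pseudo-mass of the background into every column,
    exactly as :func:`add_pseudocounts` would for a count matrix whose
    columns sum to 1.  A strictly positive input is passed through
    unchanged.
    """
    arr = np.asarray(probs, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    if np.all(arr > 0):
        return ProbabilityMatrix(arr)
    return add_pseudocounts(CountMatrix(arr), bg, total_weight=epsilon)


def log_odds(
    I: ProbabilityMatrix,
    bg: Background,
    base: str = "e",
    scale_digits: int = 3,
) -> ScoringMatrix:
    """Log-odds transform: M(i, a) = log(I(i, a) / q_a).

    ``base`` is "e" (natural log, default) or "2".  The integer grid twin is
    populated at ``scale_digits`` decimal digits.
    """
    if base not in ("e", "2"):
        raise MatrixError(f"log base must be 'e' or '2', got {base!r}")
    if np.any(bg.probs <= 0):
        a = int(np.argmin(bg.probs))
        raise MatrixError(f"background probability for symbol {ALPHABET[a]} is not positive")
    # ProbabilityMatrix guarantees strictly positive entries.
    ratio = I.probs / bg.probs[None, :]
    scores = np.log2(ratio) if base == "2" else np.log(ratio)
    return ScoringMatrix(scores, scale_digits=scale_digits)


def score_kmer(M: ScoringMatrix, kmer: str, integer: bool = False):
    """Score a single k-mer: sum of M(i, s_i) over positions.

    With ``integer=True`` the sum runs over the integer grid scores and an
    int is returned.
    """
    if len(kmer) != M.width:
        raise MatrixError(f"k-mer length {len(kmer)} != matrix width {M.width}")
    codes = encode_sequence(kmer)
    if np.any(codes > 3):
        bad = kmer[int(np.argmax(codes > 3))]
        raise MatrixError(f"k-mer contains non-ACGT symbol {bad!r}")
    idx = np.arange(M.width)
    if integer:
        return int(M.int_scores[idx, codes].sum())
    return float(M.scores[idx, codes].sum())


def estimate_background(seq: Union[str, np.ndarray]) -> Background:
    """Estimate q by counting A/C/G/T in one streaming pass over ``seq``.

    Non-ACGT symbols are excluded from both numerator and denominator.
    Accepts a string or an already encoded uint8 array.  Warns if any
    nucleotide is entirely absent (the resulting zero probability would be
    rejected by the log-odds transform).
    """
    codes = encode_sequence(seq) if isinstance(seq, str) else seq
    counts = np.bincount(codes, minlength=5)[:4].astype(float)
    total = counts.sum()
    if total == 0:
        raise MatrixError("sequence contains no A/C/G/T symbols")
    if np.any(counts == 0):
        absent = ",".join(ALPHABET[i] for i in np.flatnonzero(counts == 0))
        warnings.warn(
            f"symbols {absent} never occur; estimated background has zero entries",
            stacklevel=2,
        )
    return Background(counts / total)


def information_content(I: ProbabilityMatrix, bg: Background) -> tuple[np.ndarray, float]:
    """Per-column and total information content in bits.

    Defined as the relative entropy of each column against the background,
    IC_i = sum_a I(i, a) * log2(I(i, a) / q_a); under a uniform background
    this is the familiar 2 - H(column).  Each IC_i is >= 0.
    """
    if np.any(bg.probs <= 0):
        a = int(np.argmin(bg.probs))
        raise MatrixError(f"background probability for symbol {ALPHABET[a]} is not positive")
    per_col = np.sum(I.probs * np.log2(I.probs / bg.probs[None, :]), axis=1)
    return per_col, float(per_col.sum())


def reverse_complement_matrix(M: ScoringMatrix) -> ScoringMatrix:
    """PWM for the reverse strand: positions reversed, A<->T and C<->G swapped."""
    comp = [3, 2, 1, 0]  # A<->T, C<->G
    return ScoringMatrix(M.scores[::-1][:, comp], scale_digits=M.scale_digits)


# ---------------------------------------------------------------------------
# File formats


def _parse_matrix_rows(lines: list[str]) -> np.ndarray:
    """Parse 4 motif rows in A,C,G,T order; tolerates row labels and brackets."""
    rows = []
    labels = []
    for line in lines:
        line = line.replace("[", " ").replace("]", " ").strip()
        fields = line.split()
        if not fields:
            continue
        if fields[0].upper() in _SYMBOL_INDEX and not _is_number(fields[0]):
            labels.append(fields[0].upper())
            fields = fields[1:]
        rows.append([float(x) for x in fields])
    if len(rows) != 4:
        raise MatrixError(f"expected 4 matrix rows (A, C, G, T), found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise MatrixError("matrix rows have unequal lengths")
    arr = np.array(rows, dtype=float)
    if labels:
        if sorted(labels) != list(ALPHABET):
            raise MatrixError(f"row labels must be A, C, G, T; got {labels}")
        order = [labels.index(s) for s in ALPHABET]
        arr = arr[order]
    return arr.T  # -> (width, 4)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_matrix(source: Union[str, Path, TextIO]) -> tuple[np.ndarray, str]:
    """Read a motif matrix file; returns (array of shape (width, 4), name).

    Accepts the JASPAR bracket dialect (``>MA0037.1 GATA3`` header, rows
    like ``A [ 0 14 ... ]``), bare labeled/unlabeled whitespace rows, and a
    plain 4 x width TSV.  Rows are A, C, G, T; columns are positions.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        name = Path(source).stem
    else:
        text = source.read()
        name = ""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].strip() or name
        lines = lines[1:]
    return _parse_matrix_rows(lines), name


def read_count_matrix(source: Union[str, Path, TextIO]) -> CountMatrix:
    arr, _ = read_matrix(source)
    return CountMatrix(arr)


def matrix_kind(arr: np.ndarray) -> str:
    """Guess whether a raw matrix holds counts or probabilities."""
    colsums = arr.sum(axis=1)
    return "probabilities" if np.allclose(colsums, 1.0, atol=1e-6) else "counts"


def write_jaspar(
    arr: Union[np.ndarray, CountMatrix, ProbabilityMatrix],
    dest: Union[str, Path, TextIO],
    name: str = "motif",
    fmt: str = "%g",
) -> None:
    """Write a matrix in the JASPAR bracket dialect (rows A, C, G, T)."""
    if isinstance(arr, CountMatrix):
        arr = arr.counts
    elif isinstance(arr, ProbabilityMatrix):
        arr = arr.probs
    lines = [f">{name}"]
    for a, symbol in enumerate(ALPHABET):
        values = " ".join(fmt % v for v in arr[:, a])
        lines.append(f"{symbol} [ {values} ]")
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def read_fasta(source: Union[str, Path, TextIO]) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercase sequence) for each FASTA record.

    A file whose first non-blank character is not ``>`` is treated as raw
    sequence text (one anonymous record, whitespace stripped).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        head = path.open().read(1)
        if head != ">":
            seq = "".join(path.read_text().split())
            yield path.stem, seq.upper()
            return
        handle = path.open()
        close = True
    else:
        handle = source
        close = False
    try:
        for record in SeqIO.parse(handle, "fasta"):
            yield record.id, str(record.seq).upper()
    finally:
        if close:
            handle.close()


def read_background(source: Union[str, Path]) -> Background:
    """Read 4 whitespace-separated probabilities in A, C, G, T order."""
    text = Path(source).read_text()
    values = [float(x) for x in text.replace(",", " ").split()]
    if len(values) != 4:
        raise MatrixError(f"background file must contain 4 numbers, found {len(values)}")
    return Background(np.array(values))


def parse_background(spec: str) -> Background:
    """Parse an inline background like '0.3,0.2,0.2,0.3' (A, C, G, T order)."""
    values = [float(x) for x in spec.replace(",", " ").split()]
    if len(values) != 4:
        raise MatrixError(f"inline background must contain 4 numbers, found {len(values)}")
    return Background(np.array(values))
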