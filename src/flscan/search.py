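"""The three scanning engines: naive, lookahead, and faster lookahead.

All three report exactly the same hits — every window position whose
integer-grid score reaches the threshold k — and differ only in cost:

* naive (NA) scores every clean window in full: (m - n + 1) * n column
  lookups.
* lookahead scoring (LS) visits columns left to right and abandons a
  window at the first depth t where the running prefix score R_t falls
  below the intermediate threshold T_t = k - P_t, with P_t the best
  achievable score of the remaining columns t+1..n.  Since R_t + P_t is an
  upper bound on the final score, pruning is lossless.
* faster lookahead scoring (FLS) applies the same pruning but visits
  columns in decreasing order of a per-column "matching failed
  expectation" E_i — columns where a random background symbol is expected
  to fall far short of the column maximum are checked first, so doomed
  windows tend to be abandoned earlier.

Costs are instrumented as column lookups (matrix-cell accesses during
scoring) and a prune-depth histogram: a hardware-independent proxy for
runtime.  All score comparisons happen on the integer grid shared with the
threshold DP.

Windows containing non-ACGT symbols are skipped (and counted), never
scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .matrices import (
    Background,
    CountMatrix,
    ProbabilityMatrix,
    ScoringMatrix,
    add_pseudocounts,
    encode_sequence,
    estimate_background,
    log_odds,
    reverse_complement_matrix,
)
from .threshold import ThresholdResult, compute_pmf, p_to_threshold

logger = logging.getLogger(__name__)

ENGINES = ("na", "ls", "fls")


@dataclass(frozen=True)
class Hit:
    """One reported match: 1-based window start, strand, and real score."""

    position: int
    score: float
    strand: str = "+"
    record_id: str = ""


@dataclass
class ScanStats:
    """Cost instrumentation for one scan."""

    windows_scanned: int = 0
    skipped_windows: int = 0
    column_lookups: int = 0
    hits: int = 0
    #: windows_pruned_at[t-1] = windows abandoned after their t-th compared column
    windows_pruned_at: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def merge(self, other: "ScanStats") -> None:
        self.windows_scanned += other.windows_scanned
        self.skipped_windows += other.skipped_windows
        self.column_lookups += other.column_lookups
        self.hits += other.hits
        if len(self.windows_pruned_at) < len(other.windows_pruned_at):
            grown = np.zeros(len(other.windows_pruned_at), dtype=np.int64)
            grown[: len(self.windows_pruned_at)] = self.windows_pruned_at
            self.windows_pruned_at = grown
        self.windows_pruned_at[: len(other.windows_pruned_at)] += other.windows_pruned_at

    def to_dict(self) -> dict:
        return {
            "windows_scanned": int(self.windows_scanned),
            "skipped_windows": int(self.skipped_windows),
            "column_lookups": int(self.column_lookups),
            "hits": int(self.hits),
            "windows_pruned_at": [int(x) for x in self.windows_pruned_at],
        }


@dataclass(frozen=True)
class LookaheadTables:
    """Precomputed pruning tables for a (matrix, threshold, order) triple.

    ``order`` is the 1-based permutation of columns in match order;
    ``suffix_max[t]`` (t = 0..n) is the best achievable grid score of the
    still-unmatched columns order[t+1..n]; ``thresholds[t] = k -
    suffix_max[t]``, so thresholds[n] == k.  ``expectations`` carries the
    failure expectations that produced the order (None for identity/LS).
    """

    order: tuple
    suffix_max: np.ndarray
    thresholds: np.ndarray
    expectations: Optional[np.ndarray] = None


def failure_expectations(M: ScoringMatrix, bg: Background) -> np.ndarray:
    """Per-column matching-failed expectation, on real scores.

    E_i = |min_a M(i, a)| + max_a M(i, a) - sum_a q_a * M(i, a): the column
    score range (anchored at zero via the absolute minimum) minus the score
    a random background symbol is expected to contribute.  Large E_i marks
    a column where background symbols typically fall far short of the best
    case, i.e. where mismatches reveal themselves fastest.
    """
    s = M.scores
    return np.abs(s.min(axis=1)) + s.max(axis=1) - s @ bg.probs


def matching_order(E: Sequence[float]) -> tuple:
    """Columns sorted by decreasing E; ties broken by ascending position (1-based)."""
    E = np.asarray(E, dtype=float)
    return tuple(int(i) + 1 for i in np.argsort(-E, kind="stable"))


def build_tables(
    M: ScoringMatrix,
    k: int,
    order: Optional[Sequence[int]] = None,
    expectations: Optional[np.ndarray] = None,
) -> LookaheadTables:
    """Intermediate thresholds for lookahead pruning, in grid units.

    ``order`` defaults to the identity (plain lookahead scoring).  The
    suffix maxima are computed over the PERMUTED column sequence, so the
    same tables serve LS and FLS.
    """
    n = M.width
    if order is None:
        order = tuple(range(1, n + 1))
    order = tuple(int(t) for t in order)
    if sorted(order) != list(range(1, n + 1)):
        raise ValueError(f"order must be a permutation of 1..{n}")
    col_max = M.int_scores.max(axis=1)
    permuted_max = col_max[np.array(order) - 1]
    suffix_max = np.zeros(n + 1, dtype=np.int64)
    suffix_max[:n] = permuted_max[::-1].cumsum()[::-1]
    thresholds = int(k) - suffix_max
    return LookaheadTables(
        order=order, suffix_max=suffix_max, thresholds=thresholds, expectations=expectations
    )


def _clean_window_starts(codes: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """0-based starts of windows free of non-ACGT symbols, and the skipped count."""
    m = len(codes)
    total = m - n + 1
    ambiguous = (codes > 3).astype(np.int64)
    if not ambiguous.any():
        return np.arange(total, dtype=np.int64), 0
    csum = np.concatenate([[0], np.cumsum(ambiguous)])
    window_amb = csum[n:] - csum[:total]
    starts = np.flatnonzero(window_amb == 0)
    return starts, total - len(starts)


def _as_codes(seq: Union[str, np.ndarray]) -> np.ndarray:
    return encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)


def _make_hits(
    starts: np.ndarray, grid_scores: np.ndarray, M: ScoringMatrix, record_id: str, strand: str
) -> list[Hit]:
    return [
        Hit(position=int(i) + 1, score=M.to_real(g), strand=strand, record_id=record_id)
        for i, g in zip(starts, grid_scores)
    ]


def _empty_result(M: ScoringMatrix, m: int) -> tuple[list[Hit], ScanStats]:
    warnings.warn(
        f"sequence length {m} is shorter than matrix width {M.width}: no windows",
        stacklevel=3,
    )
    return [], ScanStats(windows_pruned_at=np.zeros(M.width, dtype=np.int64))


def naive_search(
    seq: Union[str, np.ndarray],
    M: ScoringMatrix,
    k: int,
    record_id: str = "",
    strand: str = "+",
) -> tuple[list[Hit], ScanStats]:
    """Score every clean window in full and report those with grid score >= k."""
    codes = _as_codes(seq)
    n = M.width
    if len(codes) < n:
        return _empty_result(M, len(codes))
    starts, skipped = _clean_window_starts(codes, n)
    scores = np.zeros(len(starts), dtype=np.int64)
    for t in range(n):
        scores += M.int_scores[t][codes[starts + t]]
    keep = scores >= k
    stats = ScanStats(
        windows_scanned=len(starts),
        skipped_windows=skipped,
        column_lookups=len(starts) * n,
        hits=int(keep.sum()),
        windows_pruned_at=np.zeros(n, dtype=np.int64),
    )
    return _make_hits(starts[keep], scores[keep], M, record_id, strand), stats


def _pruned_search(
    codes: np.ndarray,
    M: ScoringMatrix,
    tables: LookaheadTables,
    record_id: str,
    strand: str,
) -> tuple[list[Hit], ScanStats]:
    """Shared LS/FLS core: vectorized over the set of still-active windows.

    At depth t the t-th column in ``tables.order`` is added for every
    active window, then windows whose running score falls below
    thresholds[t] are abandoned.  Surviving windows at depth n are hits
    (thresholds[n] == k).
    """
    n = M.width
    if len(codes) < n:
        return _empty_result(M, len(codes))
    starts, skipped = _clean_window_starts(codes, n)
    active = starts
    scores = np.zeros(len(active), dtype=np.int64)
    lookups = 0
    pruned_at = np.zeros(n, dtype=np.int64)
    perm0 = np.array(tables.order, dtype=np.int64) - 1
    for t in range(n):
        if len(active) == 0:
            break
        col = int(perm0[t])
        scores = scores + M.int_scores[col][codes[active + col]]
        lookups += len(active)
        keep = scores >= tables.thresholds[t + 1]
        pruned_at[t] = len(active) - int(keep.sum())
        active = active[keep]
        scores = scores[keep]
    stats = ScanStats(
        windows_scanned=len(starts),
        skipped_windows=skipped,
        column_lookups=lookups,
        hits=len(active),
        windows_pruned_at=pruned_at,
    )
    # survivors of the final depth satisfy scores >= thresholds[n] == k
    order_sorted = np.argsort(active, kind="stable")
    return _make_hits(active[order_sorted], scores[order_sorted], M, record_id, strand), stats


def lookahead_search(
    seq: Union[str, np.ndarray],
    M: ScoringMatrix,
    k: int,
    record_id: str = "",
    strand: str = "+",
) -> tuple[list[Hit], ScanStats]:
    """Lookahead scoring: identity column order with intermediate thresholds."""
    tables = build_tables(M, k)
    return _pruned_search(_as_codes(seq), M, tables, record_id, strand)


def fls_search(
    seq: Union[str, np.ndarray],
    M: ScoringMatrix,
    bg: Background,
    k: int,
    record_id: str = "",
    strand: str = "+",
    order: Optional[Sequence[int]] = None,
) -> tuple[list[Hit], ScanStats]:
    """Faster lookahead scoring: columns visited in decreasing failure expectation.

    ``order`` can be forced (e.g. the identity, which makes FLS degenerate
    to LS exactly); by default it is derived from ``failure_expectations``.
    """
    E = failure_expectations(M, bg)
    if order is None:
        order = matching_order(E)
    tables = build_tables(M, k, order=order, expectations=E)
    return _pruned_search(_as_codes(seq), M, tables, record_id, strand)


@dataclass
class ScanResult:
    """Everything a full pipeline run produced."""

    hits: list[Hit]
    stats: ScanStats
    threshold: ThresholdResult
    background: Background
    matrix: ScoringMatrix
    order: tuple


def scan(
    records: Iterable[tuple[str, str]],
    motif: Union[CountMatrix, ProbabilityMatrix, ScoringMatrix],
    bg: Optional[Background] = None,
    p: Optional[float] = None,
    k: Optional[int] = None,
    engine: str = "fls",
    both_strands: bool = False,
    scale_digits: int = 3,
    pseudocount_weight: float = 1.0,
    log_base: str = "e",
) -> ScanResult:
    """Run the full pipeline: background, log-odds, threshold, then scan.

    ``records`` is an iterable of (id, sequence).  Exactly one of ``p``
    (p-value) and ``k`` (explicit grid threshold) must be given.  If ``bg``
    is None it is estimated from the records in a single streaming pass
    (counting non-ACGT-free symbols); count/probability motifs are
    pseudocounted and log-odds transformed against that background.
    Reverse-strand scanning scores each record against the
    reverse-complement matrix and reports hits with strand "-" at their
    forward-strand window start.
    """
    if engine not in ENGINES:
        raise ValueError(f"engine must be one of {ENGINES}, got {engine!r}")
    if (p is None) == (k is None):
        raise ValueError("exactly one of p (p-value) and k (grid threshold) must be set")
    records = list(records)
    if not records:
        raise ValueError("no sequence records supplied")

    if bg is None:
        counts = np.zeros(5, dtype=np.int64)
        for _, seq in records:
            counts += np.bincount(encode_sequence(seq), minlength=5)
        if counts[:4].sum() == 0:
            raise ValueError("records contain no A/C/G/T symbols; cannot estimate background")
        bg = Background(counts[:4] / counts[:4].sum())
    logger.info("background (A,C,G,T): %s", np.array2string(bg.probs, precision=4))

    if isinstance(motif, CountMatrix):
        motif = add_pseudocounts(motif, bg, total_weight=pseudocount_weight)
    if isinstance(motif, ProbabilityMatrix):
        M = log_odds(motif, bg, base=log_base, scale_digits=scale_digits)
    else:
        M = motif

    if p is not None:
        thr = p_to_threshold(compute_pmf(M, bg), p)
    else:
        thr = ThresholdResult(float("nan"), int(k), float("nan"), M.scale_digits)
    logger.info(
        "threshold k=%d (%.4f real), p_achieved=%g", thr.k, thr.k_real, thr.p_achieved
    )

    order = matching_order(failure_expectations(M, bg)) if engine == "fls" else tuple(
        range(1, M.width + 1)
    )
    logger.info("column match order: %s", order)

    matrices = [(M, "+")]
    if both_strands:
        matrices.append((reverse_complement_matrix(M), "-"))

    all_hits: list[Hit] = []
    total = ScanStats(windows_pruned_at=np.zeros(M.width, dtype=np.int64))
    for rec_id, seq in records:
        codes = encode_sequence(seq)
        for mat, strand in matrices:
            if engine == "na":
                hits, stats = naive_search(codes, mat, thr.k, rec_id, strand)
            elif engine == "ls":
                hits, stats = lookahead_search(codes, mat, thr.k, rec_id, strand)
            else:
                hits, stats = fls_search(codes, mat, bg, thr.k, rec_id, strand)
            all_hits.extend(hits)
            total.merge(stats)
    return ScanResult(
        hits=all_hits, stats=total, threshold=thr, background=bg, matrix=M, order=order
    )
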