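"""p-value to score-threshold conversion via an exact score-distribution DP.

Under an i.i.d. background q, the score of a random k-mer is a sum of n
independent per-position scores.  On the integer grid (scores x 10^d) its
probability mass function is computed exactly by a pseudopolynomial dynamic
program, column by column:

    f^(0) = delta(0)
    f^(i)(x) = sum_a q_a * f^(i-1)(x - s_i(a))

The complementary CDF G(gamma) = P(X >= gamma) then yields the significance
threshold for a requested p-value as the discrete quantile: the smallest
grid score k with G(k) <= p.  Because the scanning engines compare window
scores on the very same integer grid, a hit "score >= k" has exactly the
tail probability the DP computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import Background, ScoringMatrix


class GridOverflowError(ValueError):
    """Score grid too large for the dense DP table."""


@dataclass(frozen=True)
class ScorePMF:
    """Distribution of the random k-mer score on the integer grid.

    ``mass[j]`` is the probability of grid score ``min_score + j``;
    ``max_score - min_score + 1 == len(mass)`` and the mass sums to 1.
    """

    min_score: int
    max_score: int
    mass: np.ndarray
    scale_digits: int

    def __post_init__(self) -> None:
        if self.max_score - self.min_score + 1 != len(self.mass):
            raise ValueError("grid bounds inconsistent with mass array length")

    @property
    def grid(self) -> np.ndarray:
        """Integer grid scores aligned with ``mass``."""
        return np.arange(self.min_score, self.max_score + 1)

    def to_real(self, grid_score) -> float:
        return float(grid_score) / 10.0**self.scale_digits


@dataclass(frozen=True)
class ThresholdResult:
    """A p-value converted to a grid score threshold.

    ``k`` is the smallest grid score whose tail probability is <= the
    requested p; ``p_achieved`` is that attained tail probability (0 when
    even the maximum score is too probable and no window can qualify).
    """

    p_requested: float
    k: int
    p_achieved: float
    scale_digits: int

    @property
    def k_real(self) -> float:
        return self.k / 10.0**self.scale_digits


def compute_pmf(M: ScoringMatrix, bg: Background, cell_cap: int = 10**7) -> ScorePMF:
    """Exact PMF of the random k-mer score under background ``bg``.

    Processes columns in their stored order (the result is column-order
    invariant: the per-column distributions commute under convolution).
    Raises :class:`GridOverflowError` if the dense grid would exceed
    ``cell_cap`` cells; reduce ``scale_digits`` on the matrix in that case.
    """
    s = M.int_scores
    min_score = int(s.min(axis=1).sum())
    max_score = int(s.max(axis=1).sum())
    size = max_score - min_score + 1
    if size > cell_cap:
        raise GridOverflowError(
            f"score grid needs {size} cells (cap {cell_cap}); "
            "rebuild the matrix with fewer scale_digits"
        )
    q = bg.probs
    f = np.ones(1)
    lo = 0
    for i in range(M.width):
        col = s[i]
        col_min = int(col.min())
        col_max = int(col.max())
        new = np.zeros(len(f) + (col_max - col_min))
        for a in range(4):
            if q[a] == 0.0:
                continue
            off = int(col[a]) - col_min
            new[off : off + len(f)] += q[a] * f
        f = new
        lo += col_min
    assert lo == min_score and len(f) == size
    return ScorePMF(min_score=min_score, max_score=max_score, mass=f, scale_digits=M.scale_digits)


def complementary_cdf(pmf: ScorePMF) -> np.ndarray:
    """Upper-tail probabilities G(gamma) = P(X >= gamma) on the PMF's grid.

    ``G[j]`` corresponds to grid score ``min_score + j``; G(min_score) = 1
    and G is nonincreasing.  The suffix sum is accumulated from the top of
    the grid so that the smallest tail masses are added first.
    """
    return np.cumsum(pmf.mass[::-1])[::-1]


def p_to_threshold(pmf: ScorePMF, p: float) -> ThresholdResult:
    """Discrete quantile: smallest grid score k with G(k) <= p.

    For p = 1 this is ``min_score`` (every window passes).  If even
    G(max_score) > p, k is one grid step above ``max_score`` and no window
    can qualify (p_achieved = 0).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p!r}")
    G = complementary_cdf(pmf)
    if p == 1.0:
        # guard against the total mass summing to 1 + epsilon
        return ThresholdResult(p, pmf.min_score, min(float(G[0]), 1.0), pmf.scale_digits)
    qualifying = np.flatnonzero(G <= p)
    if len(qualifying) == 0:
        return ThresholdResult(p, pmf.max_score + 1, 0.0, pmf.scale_digits)
    j = int(qualifying[0])
    return ThresholdResult(p, pmf.min_score + j, float(G[j]), pmf.scale_digits)
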