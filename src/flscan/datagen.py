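"""Synthetic evaluation inputs: background sequences and IC-targeted motifs.

Two families of fixtures drive the benchmark and test suites:

* long i.i.d. background sequences drawn from a specified nucleotide
  distribution (approximately uniform by default), and
* probability matrices of a given width whose total information content
  (relative entropy against the background, in bits) hits a target value.

The standard sweeps mirror the two synthetic study designs: a fixed-width
sweep (width 22, total IC stepping 5..30 bits) probing the effect of motif
conservation, and a width sweep (widths 5..30) with IC pinned at 70% of
the per-width maximum (2 bits/column under a uniform background) probing
the effect of motif length.

IC targeting works by drawing each column from a symmetric Dirichlet and
then sharpening the whole matrix with a single exponent beta (column
probabilities proportional to p^beta, renormalized).  Total IC is monotone
increasing in beta — beta=0 gives uniform columns (0 bits under uniform
background), beta -> infinity approaches one-hot columns (2 bits each) —
so a bisection on beta converges to any feasible target.

A small hand-curated GATA-3 log-odds matrix (6 positions, with its printed
background) ships as a fixture for worked examples and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrices import ALPHABET, Background, ProbabilityMatrix, ScoringMatrix, information_content

#: Log-odds scores of the GATA-3 binding motif (rows A, C, G, T, columns =
#: positions 1..6), as published in the JASPAR-derived example, built with
#: background (0.278, 0.312, 0.212, 0.198) and per-symbol pseudocounts.
GATA3_LOG_ODDS = np.array(
    [
        [0.14, -4.16, 1.03, -4.16, 0.58, -0.36],
        [0.17, -2.31, -4.16, -4.16, -2.31, -1.32],
        [-1.06, 1.64, -2.32, -0.85, -1.06, 1.12],
        [0.12, -4.16, -2.64, 1.18, 0.07, -0.77],
    ]
)

GATA3_BACKGROUND = np.array([0.278, 0.312, 0.212, 0.198])

_PROB_FLOOR = 1e-12


def gata3_matrix(scale_digits: int = 3) -> ScoringMatrix:
    """The packaged GATA-3 example PWM (width 6)."""
    return ScoringMatrix(GATA3_LOG_ODDS.T.copy(), scale_digits=scale_digits)


def gata3_background() -> Background:
    """The background distribution the example PWM was built with."""
    return Background(GATA3_BACKGROUND.copy())


class GenerationError(ValueError):
    """Infeasible target or failed convergence in a generator."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for one synthetic fixture.

    ``length`` is the sequence length in bases, or the matrix width in
    positions; ``target_ic`` (matrices only) is the total information
    content in bits, feasible up to 2 bits per position under a uniform
    background; ``ic_tolerance`` is the acceptable |achieved - target| gap.
    """

    seed: int
    length: int
    background: Background = field(default_factory=Background.uniform)
    target_ic: Optional[float] = None
    ic_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GenerationError("length must be >= 1")
        if self.target_ic is not None:
            if not (0.0 <= self.target_ic <= 2.0 * self.length + 1e-9):
                raise GenerationError(
                    f"target IC {self.target_ic} bits is outside [0, {2 * self.length}] "
                    f"for width {self.length}"
                )


_SYMBOLS = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(spec: GeneratorSpec, rng: Optional[np.random.Generator] = None) -> str:
    """An i.i.d. DNA sequence of ``spec.length`` bases drawn from the background."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    codes = rng.choice(4, size=spec.length, p=spec.background.probs)
    return _SYMBOLS[codes].tobytes().decode("ascii")


def _sharpen(log_probs: np.ndarray, beta: float) -> np.ndarray:
    """Column-wise softmax of beta * log p, floored to keep entries positive."""
    z = beta * log_probs
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    p = np.maximum(p, _PROB_FLOOR)
    p /= p.sum(axis=1, keepdims=True)
    return p


def random_matrix_with_ic(
    spec: GeneratorSpec,
    rng: Optional[np.random.Generator] = None,
    dirichlet_alpha: float = 1.0,
    max_iter: int = 100,
) -> ProbabilityMatrix:
    """A random probability matrix whose total IC hits ``spec.target_ic``.

    Columns are drawn from a symmetric Dirichlet(alpha) and the whole
    matrix is sharpened by one exponent beta found by bisection so that
    the total information content against ``spec.background`` lands within
    ``spec.ic_tolerance`` bits of the target.
    """
    if spec.target_ic is None:
        raise GenerationError("spec.target_ic must be set for matrix generation")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    width = spec.length
    bg = spec.background
    target = spec.target_ic
    tol = spec.ic_tolerance

    base = rng.dirichlet(np.full(4, dirichlet_alpha), size=width)
    base = np.maximum(base, _PROB_FLOOR)
    log_base = np.log(base)

    def achieved(beta: float) -> float:
        _, total = information_content(ProbabilityMatrix(_sharpen(log_base, beta)), bg)
        return total

    lo, hi = 0.0, 1.0
    ic_lo = achieved(lo)
    if target < ic_lo - tol:
        raise GenerationError(
            f"target IC {target} bits is below the {ic_lo:.3f}-bit floor of uniform "
            "columns under this background"
        )
    ic_hi = achieved(hi)
    expansions = 0
    while ic_hi < target and expansions < 60:
        hi *= 2.0
        ic_hi = achieved(hi)
        expansions += 1
    if ic_hi < target - tol:
        raise GenerationError(
            f"cannot reach target IC {target} bits for width {width} "
            f"(maximum attained {ic_hi:.3f} bits)"
        )

    beta = hi
    best = ic_hi
    if abs(ic_lo - target) <= abs(best - target):
        beta, best = lo, ic_lo
    for _ in range(max_iter):
        if abs(best - target) <= 0.5 * tol:
            break
        mid = 0.5 * (lo + hi)
        ic_mid = achieved(mid)
        if abs(ic_mid - target) < abs(best - target):
            beta, best = mid, ic_mid
        if ic_mid < target:
            lo = mid
        else:
            hi = mid
    if abs(best - target) > tol:
        raise GenerationError(
            f"IC bisection did not converge: target {target}, best {best:.4f} bits"
        )
    return ProbabilityMatrix(_sharpen(log_base, beta))


@dataclass(frozen=True)
class GeneratedMatrix:
    """One matrix from a sweep, with its provenance."""

    matrix: ProbabilityMatrix
    target_ic: float
    achieved_ic: float
    width: int
    replicate: int


def mod_sweeps(
    kind: str,
    replicates: int = 100,
    seed: int = 0,
    background: Optional[Background] = None,
    ic_tolerance: float = 0.1,
) -> list[GeneratedMatrix]:
    """The two standard synthetic motif sweeps.

    ``kind="MOD1"``: width fixed at 22, total IC stepping over the
    integers 5..30 bits, ``replicates`` matrices per IC level.
    ``kind="MOD2"``: widths 5..30, total IC pinned at 70% of the per-width
    maximum (0.7 * 2 * width bits under a uniform background).

    Deterministic for a given seed: each (level, replicate) cell gets an
    independent child generator.
    """
    kind = kind.upper()
    if kind not in ("MOD1", "MOD2"):
        raise GenerationError(f"kind must be 'MOD1' or 'MOD2', got {kind!r}")
    if replicates < 1:
        raise GenerationError("replicates must be >= 1")
    bg = background if background is not None else Background.uniform()
    if kind == "MOD1":
        cells = [(22, float(ic)) for ic in range(5, 31)]
    else:
        cells = [(width, 0.7 * 2.0 * width) for width in range(5, 31)]
    children = np.random.SeedSequence(seed).spawn(len(cells) * replicates)
    out = []
    idx = 0
    for width, target in cells:
        for rep in range(replicates):
            rng = np.random.default_rng(children[idx])
            idx += 1
            spec = GeneratorSpec(
                seed=0, length=width, background=bg, target_ic=target, ic_tolerance=ic_tolerance
            )
            pm = random_matrix_with_ic(spec, rng=rng)
            _, total = information_content(pm, bg)
            out.append(
                GeneratedMatrix(
                    matrix=pm, target_ic=target, achieved_ic=total, width=width, replicate=rep
                )
            )
    return out
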