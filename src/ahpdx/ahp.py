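"""Analytic Hierarchy Process core: pairwise comparison matrices and
priority weights.

The AHP derives a normalized weight per criterion (here: per illness risk
factor) from pairwise importance judgments on the 1-3-5-7-9 Saaty scale.
Weights are computed by the classical square-and-normalize iteration:
repeatedly square the reciprocal matrix, take row sums and normalize to
sum 1, until the normalized vector stops changing.  Each squaring doubles
the effective matrix power, so the iteration converges to the dominant
(principal) eigenvector in a handful of steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import (
    DuplicateJudgmentError,
    IncompleteJudgmentsError,
    InvalidProfileError,
    InvalidRatioError,
    NumericFailureError,
    UnsupportedSizeError,
)

__all__ = [
    "COMPARISON_LEVELS",
    "ComparisonLevel",
    "PairwiseMatrix",
    "WeightVector",
    "required_comparisons",
    "parse_ratio",
    "build_matrix",
    "principal_weights",
    "to_percentages",
    "consistency_ratio",
]

_RECIPROCITY_RTOL = 1e-9

#: Random consistency index by matrix order (Saaty's table).
RANDOM_INDEX = {3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}


@dataclass(frozen=True)
class ComparisonLevel:
    """One of the five Saaty importance levels."""

    value: int
    label: str

    @property
    def reciprocal(self) -> Fraction:
        return Fraction(1, self.value)


#: The five-level Saaty scale, in ascending order of importance.
COMPARISON_LEVELS = (
    ComparisonLevel(1, "Equal Importance"),
    ComparisonLevel(3, "Moderate Importance"),
    ComparisonLevel(5, "Strong Importance"),
    ComparisonLevel(7, "Very Strong Importance"),
    ComparisonLevel(9, "Extreme Importance"),
)

_LEVEL_VALUES = frozenset(l.value for l in COMPARISON_LEVELS)


@dataclass(frozen=True)
class PairwiseMatrix:
    """Square reciprocal matrix of importance ratios over risk factors.

    ``entries[i, j]`` holds how many times more important factor ``i`` is
    than factor ``j``; the diagonal is 1 and ``entries[j, i] ==
    1 / entries[i, j]``.
    """

    factors: tuple[str, ...]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        n = len(self.factors)
        if n < 2:
            raise InvalidProfileError("a pairwise matrix needs at least 2 factors")
        if a.shape != (n, n):
            raise InvalidProfileError(f"entries must be {n}x{n}, got {a.shape}")
        if not np.all(a > 0):
            raise InvalidRatioError("all matrix entries must be strictly positive")
        if not np.allclose(np.diag(a), 1.0, rtol=_RECIPROCITY_RTOL):
            raise InvalidRatioError("diagonal entries must equal 1")
        if not np.allclose(a * a.T, 1.0, rtol=_RECIPROCITY_RTOL):
            raise InvalidRatioError("matrix is not reciprocal: a[j][i] * a[i][j] != 1")

    @property
    def n(self) -> int:
        return len(self.factors)


@dataclass(frozen=True)
class WeightVector:
    """Normalized priority weights per risk factor."""

    factors: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    iterations_used: int = 0
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.factors),):
            raise InvalidProfileError("weights and factors must have the same length")
        if np.any(w < 0) or np.any(w > 1):
            raise InvalidProfileError("each weight must lie in [0, 1]")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise InvalidProfileError("weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.factors, map(float, self.weights)))

    def __getitem__(self, factor: str) -> float:
        return float(self.weights[self.factors.index(factor)])


def required_comparisons(n_factors: int) -> int:
    """Number of pairwise judgments needed for ``n_factors`` criteria.

    Every unordered pair is judged once, so the count is n(n-1)/2.
    """
    if n_factors < 2:
        raise InvalidProfileError("at least 2 factors are required for comparisons")
    return n_factors * (n_factors - 1) // 2


def parse_ratio(ratio) -> float:
    """Parse an importance ratio given as a number or a ``"p/q"`` string."""
    if isinstance(ratio, str):
        try:
            value = float(Fraction(ratio.strip()))
        except (ValueError, ZeroDivisionError) as exc:
            raise InvalidRatioError(f"cannot parse ratio {ratio!r}") from exc
    else:
        value = float(ratio)
    if not np.isfinite(value) or value <= 0:
        raise InvalidRatioError(f"importance ratio must be positive, got {ratio!r}")
    return value


def _warn_if_off_scale(ratio: float) -> None:
    # A ratio is on the five-level scale if it or its reciprocal is 1/3/5/7/9.
    for candidate in (ratio, 1.0 / ratio):
        if any(abs(candidate - lv) <= 1e-9 for lv in _LEVEL_VALUES):
            return
    warnings.warn(
        f"ratio {ratio:g} is not one of the five Saaty levels (1,3,5,7,9) "
        "or their reciprocals; accepting it as an intermediate judgment",
        stacklevel=3,
    )


def build_matrix(factors, judgments) -> PairwiseMatrix:
    """Assemble a reciprocal comparison matrix from pairwise judgments.

    Parameters
    ----------
    factors : sequence of str
        Ordered factor identifiers (defines row/column order).
    judgments : iterable of (factor_i, factor_j, ratio)
        One judgment per unordered pair; ``ratio`` means factor_i is
        ``ratio`` times as important as factor_j.  Ratios may be numbers
        or ``"p/q"`` strings.  Values off the five-level scale are
        accepted with a warning.

    Raises
    ------
    IncompleteJudgmentsError
        If any unordered pair is missing (the error names the pairs).
    DuplicateJudgmentError
        If a pair is judged twice.
    InvalidRatioError
        If a ratio is not a positive number.
    """
    factors = tuple(factors)
    if len(set(factors)) != len(factors):
        raise InvalidProfileError("factor identifiers must be unique")
    n = len(factors)
    if n < 2:
        raise InvalidProfileError("at least 2 factors are required")
    index = {f: i for i, f in enumerate(factors)}

    a = np.eye(n)
    seen: set[frozenset] = set()
    for fi, fj, ratio in judgments:
        if fi not in index or fj not in index:
            unknown = fi if fi not in index else fj
            raise InvalidProfileError(f"judgment references unknown factor {unknown!r}")
        if fi == fj:
            raise DuplicateJudgmentError(f"self-comparison for factor {fi!r}")
        key = frozenset((fi, fj))
        if key in seen:
            raise DuplicateJudgmentError(f"pair ({fi}, {fj}) judged more than once")
        seen.add(key)
        r = parse_ratio(ratio)
        _warn_if_off_scale(r)
        i, j = index[fi], index[fj]
        a[i, j] = r
        a[j, i] = 1.0 / r

    missing = [
        (factors[i], factors[j])
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((factors[i], factors[j])) not in seen
    ]
    if missing:
        raise IncompleteJudgmentsError(missing)
    return PairwiseMatrix(factors, a)


def principal_weights(
    matrix: PairwiseMatrix, tol: float = 1e-6, max_iter: int = 20
) -> WeightVector:
    """Derive priority weights by the square-and-normalize iteration.

    The running matrix is squared, its row sums normalized to 1, and the
    loop stops when the maximum absolute per-component change between
    successive normalized vectors falls below ``tol`` (or ``max_iter``
    squarings are exhausted, in which case ``converged`` is False).

    The running matrix is rescaled by its maximum entry before each
    squaring; row-sum normalization makes the weights invariant to this
    rescaling, and it prevents overflow for larger matrices.
    """
    if tol <= 0:
        raise InvalidProfileError("tol must be positive")
    if max_iter < 1:
        raise InvalidProfileError("max_iter must be at least 1")

    a = matrix.entries.copy()
    prev = _normalized_row_sums(a)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        a = a / a.max()
        a = a @ a
        if not np.all(np.isfinite(a)):
            raise NumericFailureError("matrix squaring produced NaN or overflow")
        w = _normalized_row_sums(a)
        if float(np.max(np.abs(w - prev))) < tol:
            prev = w
            converged = True
            break
        prev = w
    return WeightVector(matrix.factors, prev, iterations_used=iterations, converged=converged)


def _normalized_row_sums(a: np.ndarray) -> np.ndarray:
    s = a.sum(axis=1)
    return s / s.sum()


def to_percentages(weights: WeightVector) -> dict[str, int]:
    """Integer-percentage view of a weight vector, summing exactly to 100.

    Uses largest-remainder rounding: each factor gets floor(100*w), then
    the leftover points go to the largest fractional remainders, ties
    broken by factor order.
    """
    scaled = 100.0 * weights.weights
    floors = np.floor(scaled).astype(int)
    leftover = 100 - int(floors.sum())
    # ties: stable sort on -remainder keeps factor order among equals
    order = np.argsort(-(scaled - floors), kind="stable")
    out = floors.copy()
    for k in range(leftover):
        out[order[k]] += 1
    return dict(zip(weights.factors, map(int, out)))


def consistency_ratio(matrix: PairwiseMatrix) -> float:
    """Saaty consistency ratio CR = (lambda_max - n) / ((n - 1) * RI(n)).

    ``lambda_max`` is estimated from the converged priority vector w as
    the mean of (A w) / w.  A perfectly consistent matrix gives CR = 0;
    CR < 0.10 is conventionally acceptable.  Only orders 3..10 are
    supported (the span of the random-index table).
    """
    n = matrix.n
    if n not in RANDOM_INDEX:
        raise UnsupportedSizeError(
            f"consistency ratio is defined for 3..10 factors, got {n}"
        )
    w = principal_weights(matrix).weights
    lam = float(np.mean((matrix.entries @ w) / w))
    cr = (lam - n) / ((n - 1) * RANDOM_INDEX[n])
    # consistency forces lam >= n; clip the tiny negative float noise
    return max(cr, 0.0)
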