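"""Exact binned null distributions of ungapped-alignment scores.

The null model: each column of a random target is an independent draw
from the target database's empirical column distribution (multiplicity-
weighted over the distinct hashed columns; complement-closed when both
strands are searched). Under that model

* the null of one query column's score is the weighted histogram of its
  binned scores over the distinct columns (:func:`column_null`);
* the null of a contiguous alignment window is the convolution of its
  columns' nulls (:func:`sum_null`) - exact, because the scores are
  integers;
* the null of the *best* score over all ungapped offsets (and both
  orientations, when enabled) treats the per-offset alignment scores as
  independent draws from their respective nulls, so its CDF is the
  product of the per-offset CDFs (:func:`max_alignment_null`). The
  independence across offsets is the one modelling assumption in the
  pipeline; it errs on the conservative side, because sharing target
  columns across offsets makes the true maximum stochastically smaller
  than the independent maximum.

With the unaligned-position adjustment (the "complete score"), the
query is implicitly padded with background columns so that every target
column is scored at every offset: an offset with overlap ``v`` against
a length-``n`` target adds ``n - v`` independent draws of the
background column's score null. This removes the bias that would
otherwise favour short overlaps.

Survival functions are carried explicitly (via ``log1p``/``expm1``)
so that very small tail probabilities keep full relative precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError
from .scoring import ScoreGrid

logger = logging.getLogger(__name__)


@dataclass
class BinnedDistribution:
    """Probability mass on consecutive integer scores.

    ``pmf[k]`` is the probability of integer score ``offset + k``. An
    optional precomputed survival array ``sf_`` (same indexing,
    ``sf_[k] = P(X >= offset + k)``) preserves tail precision when the
    distribution was built from a product of CDFs.
    """

    pmf: np.ndarray
    offset: int = 0
    sf_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 1 or self.pmf.size == 0:
            raise ValueError("pmf must be a non-empty 1-D array")
        if np.any(self.pmf < -1e-12):
            raise ValueError("pmf has negative entries")
        self.pmf = np.maximum(self.pmf, 0.0)
        total = self.pmf.sum()
        if abs(total - 1.0) > 1e-12:
            self.pmf = self.pmf / total

    @property
    def support(self):
        """(min, max) integer scores with defined mass."""
        return self.offset, self.offset + len(self.pmf) - 1

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def survival_array(self) -> np.ndarray:
        if self.sf_ is not None:
            return self.sf_
        return np.cumsum(self.pmf[::-1])[::-1]

    def survival(self, x: int) -> float:
        """Inclusive survival ``P(X >= x)``."""
        lo, hi = self.support
        if x <= lo:
            return 1.0
        if x > hi:
            return 0.0
        return float(self.survival_array()[x - lo])

    def convolve(self, other: "BinnedDistribution") -> "BinnedDistribution":
        return BinnedDistribution(
            np.convolve(self.pmf, other.pmf), self.offset + other.offset
        )

    @classmethod
    def point_mass(cls, x: int) -> "BinnedDistribution":
        return cls(np.array([1.0]), x)


def column_null(grid: ScoreGrid, i: int) -> BinnedDistribution:
    """Null of query column ``i``'s binned score against a random
    database column (multiplicity-weighted histogram over slots)."""
    if grid.n_slots == 0:
        raise EmptyInputError("score grid has no target columns")
    pmf = np.bincount(grid.binned[i], weights=grid.weights, minlength=grid.bins)
    return BinnedDistribution(pmf, grid.int_offset)


def background_null(grid: ScoreGrid) -> BinnedDistribution:
    """Null of the background column's score (for unaligned positions)."""
    pmf = np.bincount(grid.background_row, weights=grid.weights, minlength=grid.bins)
    return BinnedDistribution(pmf, grid.int_offset)


def sum_null(grid: ScoreGrid, start: int, stop: int) -> BinnedDistribution:
    """Null of the summed score of the contiguous query columns
    ``start..stop-1`` (convolution of their column nulls)."""
    if not 0 <= start < stop <= grid.width:
        raise EmptyInputError(
            f"empty or out-of-range query column run [{start}, {stop})"
        )
    dist = column_null(grid, start)
    for i in range(start + 1, stop):
        dist = dist.convolve(column_null(grid, i))
    return dist


def offset_windows(w: int, n: int):
    """All ungapped placements of a width-``w`` query on a length-``n``
    target. Yields ``(offset, a, b)``: query columns ``a..b-1`` are
    aligned; ``offset`` is the query start relative to the target start
    (may be negative); overlap is ``b - a >= 1``."""
    if w < 1 or n < 1:
        raise EmptyInputError(f"need query width >= 1 and target length >= 1, got {w}, {n}")
    for o in range(-(w - 1), n):
        a = max(0, -o)
        b = min(w, n - o)
        yield o, a, b


def adjust_for_unaligned(
    null: BinnedDistribution,
    overlap: int,
    n_t: int,
    bg: BinnedDistribution,
) -> BinnedDistribution:
    """Complete-score correction of a window null: convolve in one
    background-column draw per unaligned target position. Identity when
    every target column is aligned (``overlap == n_t``)."""
    if not 1 <= overlap <= n_t:
        raise ValueError(f"overlap {overlap} outside [1, {n_t}]")
    out = null
    for _ in range(n_t - overlap):
        out = out.convolve(bg)
    return out


class NullCache:
    """Memo of max-alignment nulls keyed by
    ``(query id, target length, strand mode, config digest)``.

    Nulls depend on the target database only through the empirical
    column distribution, so every equal-length target of one query
    shares a single entry; a hit is bitwise identical to recomputation.
    """

    def __init__(self):
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    def get_or_compute(self, key, compute):
        try:
            value = self._store[key]
            self.hits += 1
            return value
        except KeyError:
            self.misses += 1
            value = compute()
            self._store[key] = value
            return value

    def __len__(self):
        return len(self._store)


def max_alignment_null(
    grid: ScoreGrid,
    n_t: int,
    adjust: bool = True,
    strand_mode: str | None = None,
) -> BinnedDistribution:
    """Null of the maximum (adjusted) alignment score over all offsets.

    Per-offset nulls are exact convolutions; the maximum combines them
    as independent draws: ``F_max(x) = prod_o F_o(x)``, with every
    offset counted twice when both orientations are searched (the
    complement-closed column distribution makes the minus-orientation
    window nulls equal to the plus ones). The survival function is
    accumulated in log space for tail precision.
    """
    w = grid.width
    strand_mode = strand_mode or grid.strand_mode
    strand_factor = 2 if strand_mode == "both" else 1

    # group offsets by window: the full window repeats n - w + 1 times
    window_counts: dict = {}
    for _, a, b in offset_windows(w, n_t):
        window_counts[(a, b)] = window_counts.get((a, b), 0) + 1

    cols = [column_null(grid, i) for i in range(w)]
    window_nulls: dict = {}

    def window_null(a, b):
        # prefixes extend right, suffixes extend left, so the usual
        # n >= w case needs only O(w) convolutions in total
        key = (a, b)
        if key not in window_nulls:
            if b - a == 1:
                window_nulls[key] = cols[a]
            elif b == w and a > 0:
                window_nulls[key] = window_null(a + 1, b).convolve(cols[a])
            else:
                window_nulls[key] = window_null(a, b - 1).convolve(cols[b - 1])
        return window_nulls[key]

    bg = background_null(grid) if adjust else None
    bg_powers: dict = {0: None}

    def bg_power(k):
        if k not in bg_powers:
            prev = bg_power(k - 1)
            bg_powers[k] = bg if prev is None else prev.convolve(bg)
        return bg_powers[k]

    dists = []
    counts = []
    for (a, b), m in window_counts.items():
        d = window_null(a, b)
        if adjust:
            pad = bg_power(n_t - (b - a))
            if pad is not None:
                d = d.convolve(pad)
        dists.append(d)
        counts.append(m * strand_factor)

    lo = min(d.offset for d in dists)
    hi = max(d.support[1] for d in dists)
    xs_len = hi - lo + 2  # one past the top so the final survival is 0
    log_cdf_prev = np.zeros(xs_len)  # sum over offsets of log F_o(x - 1)
    for d, m in zip(dists, counts):
        sf = np.zeros(xs_len)
        dlo, dhi = d.support
        sa = d.survival_array()
        sf[dlo - lo : dhi - lo + 1] = sa
        sf[: dlo - lo] = 1.0
        np.clip(sf, 0.0, 1.0, out=sf)
        with np.errstate(divide="ignore"):
            log_cdf_prev += m * np.log1p(-sf)
    surv = -np.expm1(log_cdf_prev)  # P(max >= x)
    surv = np.clip(surv, 0.0, 1.0)
    pmf = surv[:-1] - surv[1:]
    return BinnedDistribution(np.maximum(pmf, 0.0), lo, sf_=surv[:-1].copy())


def pvalue(null: BinnedDistribution, x: int) -> float:
    """Inclusive P-value ``P(X >= x)`` of an observed integer score.

    Below the support the answer is 1; above it, the smallest positive
    representable value (a binned null assigns such scores probability
    zero, but a P-value of exactly 0 would be anti-conservative to
    report).
    """
    lo, hi = null.support
    if x <= lo:
        return 1.0
    if x > hi:
        return float(np.finfo(float).tiny)
    p = null.survival(x)
    return p if p > 0 else float(np.finfo(float).tiny)
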