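"""Column-score computation, median centering, and integer quantization.

The comparison engine never scores whole motifs directly. It scores
every query column against every *distinct* column in the target
database (redundant columns are hashed to one slot and carry a
multiplicity), recenters each query column's scores by their
database-wide median so that sums over alignment windows of different
lengths are comparable, and quantizes the centered scores to ``B``
integer bins. All downstream alignment scores and null distributions
live on that integer grid, which is what makes the null distribution of
a sum an exact convolution.

Score-to-integer convention: a centered score ``s`` maps to bin
``k = floor((s - lo) / delta)`` in ``[0, B-1]`` and to the *integer
score* ``k + z`` where ``z = round(lo/delta + 1/2)``. The integer score
of an alignment is the sum of its columns' integer scores, so windows
of different lengths live on one additive scale (each column
contributes at most one bin width of rounding error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, ShapeMismatchError, UnsupportedAlphabetError
from .motifs import Motif

logger = logging.getLogger(__name__)

SCORE_KINDS = ("neg_euclidean", "pearson")

#: Decimals used for the column hash key; coarse enough that float noise
#: and low-precision database columns collapse onto one slot.
HASH_DECIMALS = 6


def column_score(q, t, kind: str = "neg_euclidean") -> float:
    """Similarity between two alphabet-length column vectors.

    ``neg_euclidean``
        ``-||q - t||_2``; 0 for identical columns, more negative the
        further apart. This is the engine's default.
    ``pearson``
        sample correlation in [-1, 1]; defined as 0 when either vector
        is constant.
    """
    q = np.asarray(q, dtype=float)
    t = np.asarray(t, dtype=float)
    if q.shape != t.shape or q.ndim != 1:
        raise ShapeMismatchError(f"column shapes differ: {q.shape} vs {t.shape}")
    return float(_score_rows(q[None, :], t[None, :], kind)[0, 0])


def _score_rows(rows: np.ndarray, cols: np.ndarray, kind: str) -> np.ndarray:
    """Score matrix between R row-vectors and C column-vectors: (R, C)."""
    if kind == "neg_euclidean":
        d2 = ((rows[:, None, :] - cols[None, :, :]) ** 2).sum(axis=-1)
        return -np.sqrt(d2)
    if kind == "pearson":
        rc = rows - rows.mean(axis=1, keepdims=True)
        cc = cols - cols.mean(axis=1, keepdims=True)
        rn = np.linalg.norm(rc, axis=1)
        cn = np.linalg.norm(cc, axis=1)
        num = rc @ cc.T
        denom = rn[:, None] * cn[None, :]
        out = np.zeros_like(num)
        ok = denom > 0
        if not np.all(ok):
            logger.debug("pearson on constant column(s): score defined as 0")
        np.divide(num, denom, out=out, where=ok)
        return np.clip(out, -1.0, 1.0)
    raise ValueError(f"unknown score kind {kind!r}; expected one of {SCORE_KINDS}")


def hash_target_columns(
    targets,
    strand_mode: str = "given",
    key_decimals: int = HASH_DECIMALS,
    deduplicate: bool = True,
):
    """Collect the distinct columns of a target database.

    Returns ``(slots, multiplicities, column_ids)`` where ``slots`` is a
    ``(C, A)`` array of distinct columns, ``multiplicities`` counts how
    many database positions map to each slot, and ``column_ids`` maps
    ``(target_index, column_index, strand)`` to a slot. With
    ``strand_mode="both"`` the complemented column at each position is
    hashed too (strand ``"-"``), so the empirical column distribution is
    complement-closed. Columns are rounded to ``key_decimals`` before
    hashing so float noise cannot split identical columns;
    ``deduplicate=False`` gives every position its own slot (the scores
    are unchanged either way).
    """
    strands = ("+",) if strand_mode == "given" else ("+", "-")
    if strand_mode == "both":
        for m in targets:
            if m.alphabet_size != 4:
                raise UnsupportedAlphabetError(
                    f"strand_mode='both' requires a 4-letter alphabet "
                    f"(motif {m.name!r} has {m.alphabet_size} rows)"
                )
    slots: list = []
    mult: list = []
    ids: dict = {}
    key_to_slot: dict = {}
    for ti, m in enumerate(targets):
        for strand in strands:
            mat = m.matrix if strand == "+" else m.matrix[::-1, :]
            for j in range(m.width):
                col = mat[:, j]
                if deduplicate:
                    key = tuple(np.round(col, key_decimals))
                    slot = key_to_slot.get(key)
                    if slot is None:
                        slot = len(slots)
                        key_to_slot[key] = slot
                        slots.append(col)
                        mult.append(0)
                else:
                    slot = len(slots)
                    slots.append(col)
                    mult.append(0)
                mult[slot] += 1
                ids[(ti, j, strand)] = slot
    return np.array(slots), np.array(mult, dtype=float), ids


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= 1/2."""
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    idx = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(values[order[min(idx, len(values) - 1)]])


def center_scores(
    raw: np.ndarray,
    weights: np.ndarray,
    method: str = "approximate",
    bins: int = 100,
):
    """Subtract each row's (multiplicity-weighted) median score.

    ``method="exact"`` sorts; ``method="approximate"`` takes the
    midpoint of the histogram bin holding the 50% mass point, using
    ``bins`` bins over the row's range. The true median lies inside
    that bin, so the two methods agree within one bin width by
    construction.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0 or raw.shape[1] == 0:
        raise EmptyInputError("cannot center scores against an empty target database")
    weights = np.asarray(weights, dtype=float)
    medians = np.empty(raw.shape[0])
    for i, row in enumerate(raw):
        if method == "exact":
            medians[i] = _weighted_median(row, weights)
        elif method == "approximate":
            lo, hi = row.min(), row.max()
            if hi - lo <= bins * np.spacing(max(abs(lo), abs(hi))):
                # zero or underflowing bin width: the exact median is
                # free here and trivially satisfies the one-bin contract
                medians[i] = _weighted_median(row, weights)
                continue
            hist, edges = np.histogram(row, bins=bins, range=(lo, hi), weights=weights)
            cum = np.cumsum(hist)
            k = int(np.searchsorted(cum, 0.5 * cum[-1]))
            medians[i] = 0.5 * (edges[k] + edges[k + 1])
        else:
            raise ValueError(f"unknown centering method {method!r}")
    return medians, raw - medians[:, None]


@dataclass
class Quantization:
    """Integer binning of centered scores (see module docstring)."""

    binned: np.ndarray  # int bins in [0, B-1], same shape as input
    bins: int
    raw_range: tuple
    bin_width: float
    int_offset: int  # z: integer score of bin k is k + z

    def midpoints(self, binned=None) -> np.ndarray:
        """Invert bins to bin-midpoint centered scores (for reporting)."""
        b = self.binned if binned is None else np.asarray(binned)
        return self.raw_range[0] + (b + 0.5) * self.bin_width


def quantize(centered: np.ndarray, bins: int = 100, value_range=None) -> Quantization:
    """Quantize centered scores onto ``bins`` uniform integer bins.

    The range endpoints map to bins 0 and ``B - 1``; binning is monotone
    and invertible to bin midpoints with error at most half a bin
    width. A degenerate range (max == min) collapses to a single bin.
    """
    centered = np.asarray(centered, dtype=float)
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    if value_range is None:
        lo, hi = float(centered.min()), float(centered.max())
    else:
        lo, hi = map(float, value_range)
        if centered.size and (centered.min() < lo or centered.max() > hi):
            raise ValueError("value_range does not cover the observed scores")
    if hi == lo:
        logger.warning("degenerate score range [%g, %g]: single-bin grid", lo, hi)
        return Quantization(
            binned=np.zeros(centered.shape, dtype=np.int64),
            bins=1,
            raw_range=(lo, hi),
            bin_width=1.0,
            int_offset=0,
        )
    width = (hi - lo) / bins
    binned = np.clip(np.floor((centered - lo) / width).astype(np.int64), 0, bins - 1)
    z = int(np.rint(lo / width + 0.5))
    return Quantization(binned, bins, (lo, hi), width, z)


@dataclass
class ScoreGrid:
    """Quantized column scores of one query against a target database.

    Rows 0..w-1 are the query columns; when ``has_background_row`` the
    final row is the query-side background column, used to score
    unaligned target positions under the complete-score adjustment.
    """

    binned: np.ndarray  # (R, C) int bins
    quant: Quantization
    medians: np.ndarray  # (R,) centering offsets, raw score units
    multiplicities: np.ndarray  # (C,)
    column_ids: dict  # (target_idx, col_idx, strand) -> slot
    width: int  # number of query columns w
    strand_mode: str
    score_kind: str
    has_background_row: bool = True
    median_method: str = "approximate"

    @property
    def bins(self) -> int:
        return self.quant.bins

    @property
    def int_offset(self) -> int:
        return self.quant.int_offset

    @property
    def n_slots(self) -> int:
        return self.binned.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return self.multiplicities / self.multiplicities.sum()

    @property
    def background_row(self) -> np.ndarray:
        if not self.has_background_row:
            raise EmptyInputError("grid was built without a background row")
        return self.binned[self.width]


def build_score_grid(
    query: Motif,
    targets,
    kind: str = "neg_euclidean",
    bins: int = 100,
    strand_mode: str = "given",
    median_method: str = "approximate",
    key_decimals: int = HASH_DECIMALS,
    deduplicate: bool = True,
) -> ScoreGrid:
    """Score one query against a target database and quantize.

    ``targets`` is either a MotifSet or a prebuilt
    ``(slots, multiplicities, column_ids)`` triple from
    :func:`hash_target_columns` (so the hash can be shared across
    queries).
    """
    if isinstance(targets, tuple):
        slots, mult, ids = targets
    else:
        if len(targets) == 0:
            raise EmptyInputError("empty target motif set")
        slots, mult, ids = hash_target_columns(
            targets, strand_mode, key_decimals, deduplicate
        )
    if slots.shape[1] != query.alphabet_size:
        raise ShapeMismatchError(
            f"query {query.name!r} has {query.alphabet_size} rows but target "
            f"columns have {slots.shape[1]}"
        )
    rows = np.vstack([query.matrix.T, query.background[None, :]])
    raw = _score_rows(rows, slots, kind)
    medians, centered = center_scores(raw, mult, median_method, bins)
    quant = quantize(centered, bins)
    return ScoreGrid(
        binned=quant.binned,
        quant=quant,
        medians=medians,
        multiplicities=mult,
        column_ids=ids,
        width=query.width,
        strand_mode=strand_mode,
        score_kind=kind,
        has_background_row=True,
        median_method=median_method,
    )
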