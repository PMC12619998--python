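"""Top-level comparison engine: query set x target set -> hit table.

For every query-target pair the engine finds the best (adjusted)
alignment score over all ungapped offsets and orientations, converts it
to a P-value against the exact binned null of that maximum, and reports
E-values (P x number of targets) and per-query Benjamini-Hochberg
q-values. Nulls depend on a target only through its length, so they are
cached per (query, target length) and reused across the database -
the main reason comparisons against large databases stay fast.

Work is partitioned over queries; each query's pipeline is sequential,
so the thread count cannot change any reported number.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UnsupportedAlphabetError
from .io import HIT_COLUMNS, MotifSet
from .nulls import NullCache, max_alignment_null, pvalue
from .scoring import HASH_DECIMALS, build_score_grid, hash_target_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TomtomConfig:
    """Knobs of the comparison engine (defaults are the recommended
    settings; every one is exposed on the CLI)."""

    score_kind: str = "neg_euclidean"
    bins: int = 100
    strand_mode: str = "both"  # "both" or "given"
    adjust_unaligned: bool = True
    median_method: str = "approximate"  # "approximate" or "exact"
    hash_columns: bool = True
    cache_nulls: bool = True
    threads: int = 1
    key_decimals: int = HASH_DECIMALS
    p_threshold: float | None = None
    top_k: int | None = None

    def digest(self) -> str:
        """Scoring-relevant fingerprint used in null-cache keys, so a
        configuration change can never serve a stale null."""
        return (
            f"{self.score_kind}|B={self.bins}|{self.strand_mode}"
            f"|adj={self.adjust_unaligned}|med={self.median_method}"
            f"|dec={self.key_decimals}"
        )


def _orientation_slots(column_ids, ti, n, orientation):
    """Slot sequence of target ``ti`` read in the given orientation."""
    if orientation == "+":
        return np.array([column_ids[(ti, j, "+")] for j in range(n)])
    # the reverse complement read: complemented columns in reverse order
    return np.array([column_ids[(ti, n - 1 - j, "-")] for j in range(n)])


def _best_alignment(grid, slot_seqs, n, adjust):
    """Best integer alignment score over offsets x orientations.

    Ties break toward the smallest offset, then the '+' orientation,
    so output is reproducible. Returns (score, offset, orientation,
    overlap).
    """
    w = grid.width
    z = grid.int_offset
    offs = np.arange(-(w - 1), n)
    a = np.maximum(0, -offs)
    b = np.minimum(w, n - offs)
    v = b - a
    flat_off = (np.arange(n)[None, :] - np.arange(w)[:, None] + (w - 1)).ravel()
    best = None
    for orientation, seq in slot_seqs:
        q = grid.binned[:w, seq]
        diag = np.bincount(flat_off, weights=q.ravel(), minlength=w + n - 1)
        scores = np.rint(diag).astype(np.int64) + v * z
        if adjust:
            bg = grid.background_row[seq]
            cs = np.concatenate([[0], np.cumsum(bg)])
            jlo = np.maximum(0, offs)
            jhi = np.minimum(n, offs + w)
            unaligned = int(cs[-1]) - (cs[jhi] - cs[jlo]).astype(np.int64)
            scores = scores + unaligned + (n - v) * z
        k = int(np.argmax(scores))  # first max -> smallest offset
        sc = int(scores[k])
        if best is None or sc > best[0]:
            best = (sc, int(offs[k]), orientation, int(v[k]))
    return best


def tomtom(
    queries: MotifSet,
    targets: MotifSet,
    config: TomtomConfig | None = None,
    **overrides,
) -> pd.DataFrame:
    """Compare every query against every target.

    Returns a hit table with one row per pair, sorted by
    (query, P-value), with columns ``Query_ID, Target_ID,
    Optimal_offset, p-value, E-value, q-value, Overlap, Orientation,
    Score``. ``Optimal_offset`` is the query start relative to the
    target start in the reported orientation's coordinates; ``Score``
    is the best alignment score reconstructed from the integer grid
    (raw centered-score units).
    """
    cfg = config or TomtomConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    if len(queries) == 0 or len(targets) == 0:
        raise EmptyInputError("tomtom needs non-empty query and target sets")
    if queries.alphabet != targets.alphabet:
        raise UnsupportedAlphabetError(
            f"query alphabet {queries.alphabet} != target alphabet {targets.alphabet}"
        )

    t0 = time.perf_counter()
    hashed = hash_target_columns(
        targets, cfg.strand_mode, cfg.key_decimals, deduplicate=cfg.hash_columns
    )
    slots, mult, ids = hashed
    logger.info(
        "hashed %d target columns into %d distinct slots (%.1f ms)",
        int(mult.sum()),
        len(mult),
        1e3 * (time.perf_counter() - t0),
    )

    lengths = [t.width for t in targets]
    orientations = ("+", "-") if cfg.strand_mode == "both" else ("+",)
    target_seqs = [
        [(o, _orientation_slots(ids, ti, n, o)) for o in orientations]
        for ti, n in enumerate(lengths)
    ]

    cache = NullCache()
    n_targets = len(targets)

    def run_query(qi):
        query = queries[qi]
        grid = build_score_grid(
            query,
            hashed,
            kind=cfg.score_kind,
            bins=cfg.bins,
            strand_mode=cfg.strand_mode,
            median_method=cfg.median_method,
        )
        rows = []
        for ti, target in enumerate(targets):
            n = lengths[ti]
            sc, off, orient, overlap = _best_alignment(
                grid, target_seqs[ti], n, cfg.adjust_unaligned
            )
            key = (query.name, n, cfg.strand_mode, cfg.digest())

            def compute():
                return max_alignment_null(grid, n, adjust=cfg.adjust_unaligned)

            null = cache.get_or_compute(key, compute) if cfg.cache_nulls else compute()
            p = pvalue(null, sc)
            rows.append(
                {
                    "Query_ID": query.name,
                    "Target_ID": target.name,
                    "Optimal_offset": off,
                    "p-value": p,
                    "E-value": p * n_targets,
                    "Overlap": overlap,
                    "Orientation": orient,
                    "Score": sc * grid.quant.bin_width,
                }
            )
        ps = [r["p-value"] for r in rows]
        for r, q in zip(rows, bh_qvalues(ps)):
            r["q-value"] = q
        return rows

    t0 = time.perf_counter()
    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            per_query = list(pool.map(run_query, range(len(queries))))
    else:
        per_query = [run_query(qi) for qi in range(len(queries))]
    logger.info(
        "scored %d x %d pairs in %.2f s (null cache: %d entries, %d hits, %d misses)",
        len(queries),
        n_targets,
        time.perf_counter() - t0,
        len(cache),
        cache.hits,
        cache.misses,
    )

    frames = []
    for qi, rows in enumerate(per_query):
        df = pd.DataFrame(rows)
        df = df.sort_values(
            ["p-value", "Target_ID"], kind="stable", ignore_index=True
        )
        if cfg.p_threshold is not None:
            df = df[df["p-value"] <= cfg.p_threshold]
        if cfg.top_k is not None:
            df = df.head(cfg.top_k)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[HIT_COLUMNS]


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} n * p_(j) / j``, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def annotate_seqlets(
    seqlets: MotifSet,
    database: MotifSet,
    p_threshold: float,
    config: TomtomConfig | None = None,
    **overrides,
):
    """Label each seqlet with its best database hit.

    A seqlet gets the database motif with the lowest P-value if that
    P-value is at or below ``p_threshold``, else the label
    ``"unassigned"``. Returns ``(assignments, counts)``: one row per
    seqlet, and the number of seqlets assigned to each database motif
    (zero-filled so every motif appears).
    """
    counts = pd.Series(0, index=database.names, name="n_seqlets", dtype=int)
    if len(seqlets) == 0:
        empty = pd.DataFrame(columns=["Seqlet_ID", "Match_ID", "p-value"])
        return empty, counts
    hits = tomtom(seqlets, database, config, **overrides)
    best = hits.loc[hits.groupby("Query_ID", sort=False)["p-value"].idxmin()]
    rows = []
    for name in seqlets.names:
        r = best[best["Query_ID"] == name].iloc[0]
        if r["p-value"] <= p_threshold:
            rows.append({"Seqlet_ID": name, "Match_ID": r["Target_ID"], "p-value": r["p-value"]})
            counts[r["Target_ID"]] += 1
        else:
            rows.append({"Seqlet_ID": name, "Match_ID": "unassigned", "p-value": r["p-value"]})
    return pd.DataFrame(rows), counts
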