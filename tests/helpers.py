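"""Independent oracles used by the test suite.

Everything here is deliberately brute force and shares no code path
with the package internals it checks: window score distributions are
enumerated outcome by outcome (no convolution), and the distribution of
a maximum of independent draws is composed by a pairwise double loop
over probability dictionaries (no CDF products, no log-space survival).
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np

from tomtomlite.io import MotifSet
from tomtomlite.motifs import Motif
from tomtomlite.nulls import offset_windows


def dirichlet_motifs(rng, n_motifs, width, conc=0.5, prefix="m", column_pool=None):
    """Random motifs; optionally with columns sampled from a small pool
    so the database has few distinct columns."""
    motifs = []
    for i in range(n_motifs):
        w = width if isinstance(width, int) else int(rng.integers(width[0], width[1] + 1))
        if column_pool is not None:
            idx = rng.integers(0, len(column_pool), size=w)
            mat = np.array([column_pool[k] for k in idx]).T
        else:
            mat = rng.dirichlet([conc] * 4, size=w).T
        motifs.append(Motif(name=f"{prefix}{i}", matrix=mat))
    return MotifSet(motifs, source="test")


def enumerate_window_pmf(grid, a, b, n_t, adjust):
    """Null pmf of one offset's (adjusted) integer alignment score, by
    exhaustive enumeration of every slot assignment of the aligned
    window and, when adjusting, of every unaligned target position."""
    z = grid.int_offset
    weights = grid.weights
    n_slots = grid.n_slots
    v = b - a
    pad = (n_t - v) if adjust else 0
    rows = list(range(a, b)) + [grid.width] * pad  # bg row for padding
    pmf: dict = defaultdict(float)
    for assign in itertools.product(range(n_slots), repeat=len(rows)):
        prob = 1.0
        score = 0
        for row, s in zip(rows, assign):
            prob *= weights[s]
            score += int(grid.binned[row, s]) + z
        pmf[score] += prob
    return dict(pmf)


def pmf_of_max_independent(pmfs):
    """Distribution of the max of independent discrete variables, by
    pairwise composition with a double loop."""
    cur = None
    for pmf in pmfs:
        if cur is None:
            cur = dict(pmf)
            continue
        nxt: dict = defaultdict(float)
        for x, px in cur.items():
            for y, py in pmf.items():
                nxt[max(x, y)] += px * py
        cur = dict(nxt)
    return cur


def enumerate_max_null(grid, n_t, adjust, strand_mode):
    """Brute-force null of the best alignment score over all offsets
    (each offset once per searched orientation)."""
    reps = 2 if strand_mode == "both" else 1
    pmfs = []
    for _, a, b in offset_windows(grid.width, n_t):
        pmf = enumerate_window_pmf(grid, a, b, n_t, adjust)
        pmfs.extend([pmf] * reps)
    return pmf_of_max_independent(pmfs)


def dist_to_dict(dist):
    lo, _ = dist.support
    return {lo + i: p for i, p in enumerate(dist.pmf)}


def max_abs_pmf_diff(dist, oracle_pmf):
    d = dist_to_dict(dist)
    keys = set(d) | set(oracle_pmf)
    return max(abs(d.get(k, 0.0) - oracle_pmf.get(k, 0.0)) for k in keys)


def bh_reference(p):
    """Independent BH step-up reimplementation (direct formula)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    best = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        best = min(best, n * p[idx] / rank)
        q[idx] = min(best, 1.0)
    return q
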