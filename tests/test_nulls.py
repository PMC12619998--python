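import itertools

import numpy as np
import pytest

from helpers import (
    dirichlet_motifs,
    dist_to_dict,
    enumerate_max_null,
    max_abs_pmf_diff,
)
from tomtomlite.errors import EmptyInputError
from tomtomlite.io import MotifSet
from tomtomlite.motifs import Motif
from tomtomlite.nulls import (
    BinnedDistribution,
    NullCache,
    adjust_for_unaligned,
    background_null,
    column_null,
    max_alignment_null,
    pvalue,
    sum_null,
)
from tomtomlite.scoring import build_score_grid


def small_grid(rng, w_q, n_t, n_pool, bins, strand="given", n_targets=3):
    """Grid of a random width-w_q query against a tiny database whose
    columns come from a pool of n_pool distinct columns."""
    pool = [rng.dirichlet([0.7] * 4) for _ in range(n_pool)]
    targets = dirichlet_motifs(rng, n_targets, n_t, column_pool=pool)
    query = Motif(name="q", matrix=rng.dirichlet([0.7] * 4, size=w_q).T)
    return build_score_grid(query, targets, bins=bins, strand_mode=strand), targets


class TestColumnNull:
    def test_identical_target_columns_give_point_mass(self, rng):
        grid, _ = small_grid(rng, 2, 4, 1, 8)
        d = column_null(grid, 0)
        assert np.count_nonzero(d.pmf) == 1

    def test_two_equal_multiplicity_columns_split_mass(self, rng):
        col_a = np.array([1.0, 0, 0, 0])
        col_b = np.array([0, 0, 0, 1.0])
        targets = MotifSet(
            [Motif(name="t", matrix=np.array([col_a, col_b]).T)], source="test"
        )
        query = Motif(name="q", matrix=rng.dirichlet([1] * 4, size=1).T)
        grid = build_score_grid(query, targets, bins=8)
        d = column_null(grid, 0)
        nz = d.pmf[d.pmf > 0]
        np.testing.assert_allclose(np.sort(nz), [0.5, 0.5])

    def test_matches_monte_carlo_histogram(self, rng):
        grid, _ = small_grid(rng, 1, 5, 4, 8)
        d = column_null(grid, 0)
        draws = rng.choice(grid.n_slots, size=100_000, p=grid.weights)
        vals = grid.binned[0, draws] + grid.int_offset
        lo, hi = d.support
        for x in range(lo, hi + 1):
            p = d.pmf[x - lo]
            emp = np.mean(vals == x)
            sigma = np.sqrt(max(p * (1 - p), 1e-12) / 100_000)
            assert abs(emp - p) <= 3.5 * sigma + 1e-9


class TestSumNull:
    def test_convolution_of_point_masses(self):
        d = BinnedDistribution.point_mass(3).convolve(BinnedDistribution.point_mass(-1))
        assert dist_to_dict(d) == {2: 1.0}

    def test_two_fair_binary_columns(self):
        d = BinnedDistribution([0.5, 0.5], 0).convolve(BinnedDistribution([0.5, 0.5], 0))
        np.testing.assert_allclose(d.pmf, [0.25, 0.5, 0.25])

    def test_matches_exhaustive_triple_enumeration(self, rng):
        grid, _ = small_grid(rng, 3, 4, 4, 8)
        d = sum_null(grid, 0, 3)
        z = grid.int_offset
        exact = {}
        C = grid.n_slots
        for a, b, c in itertools.product(range(C), repeat=3):
            s = int(grid.binned[0, a] + grid.binned[1, b] + grid.binned[2, c]) + 3 * z
            p = grid.weights[a] * grid.weights[b] * grid.weights[c]
            exact[s] = exact.get(s, 0.0) + p
        got = dist_to_dict(d)
        for k in set(exact) | set(got):
            assert got.get(k, 0.0) == pytest.approx(exact.get(k, 0.0), abs=1e-12)

    def test_empty_run_rejected(self, rng):
        grid, _ = small_grid(rng, 2, 3, 2, 8)
        with pytest.raises(EmptyInputError):
            sum_null(grid, 1, 1)


class TestMaxAlignmentNull:
    def test_single_offset_degenerate_case_equals_column_null(self, rng):
        # w_q = n_t = 1: exactly one admissible alignment, so the max
        # is a single draw and the null is the column null itself
        grid, _ = small_grid(rng, 1, 1, 3, 8, n_targets=1)
        d = max_alignment_null(grid, 1, adjust=False, strand_mode="given")
        c = column_null(grid, 0)
        assert max_abs_pmf_diff(d, dist_to_dict(c)) <= 1e-12

    @pytest.mark.parametrize("n_t", [1, 5, 20])
    def test_width_one_max_is_order_statistic(self, rng, n_t):
        """For a single-column query the offsets draw disjoint target
        columns, so the max-null CDF is exactly F(x)**n_t."""
        grid, _ = small_grid(rng, 1, max(n_t, 2), 5, 8)
        d = max_alignment_null(grid, n_t, adjust=False, strand_mode="given")
        base = column_null(grid, 0)
        lo, hi = base.support
        F = np.cumsum(base.pmf)
        dlo, _ = d.support
        got_cdf = np.cumsum(d.pmf)
        for x in range(lo, hi + 1):
            want = F[x - lo] ** n_t
            idx = x - dlo
            got = got_cdf[idx] if 0 <= idx < len(d.pmf) else (0.0 if idx < 0 else 1.0)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("strand", ["given", "both"])
    @pytest.mark.parametrize("adjust", [False, True])
    def test_matches_brute_force_enumeration(self, rng, strand, adjust):
        """The DP (shared convolutions + log-space CDF combination) must
        reproduce outcome-by-outcome enumeration of the null's sample
        space for every small configuration."""
        for w_q, n_t in [(1, 3), (2, 2), (2, 3), (3, 4)]:
            grid, _ = small_grid(rng, w_q, n_t, 3, 8, strand=strand)
            d = max_alignment_null(grid, n_t, adjust=adjust, strand_mode=strand)
            oracle = enumerate_max_null(grid, n_t, adjust, strand)
            assert max_abs_pmf_diff(d, oracle) <= 1e-12

    def test_adjustment_is_identity_when_target_fully_aligned(self, rng):
        grid, _ = small_grid(rng, 3, 1, 3, 8)
        # n_t = 1 < w_q: every offset aligns the whole target, so
        # adjusted and unadjusted nulls coincide exactly
        a = max_alignment_null(grid, 1, adjust=True, strand_mode="given")
        b = max_alignment_null(grid, 1, adjust=False, strand_mode="given")
        assert max_abs_pmf_diff(a, dist_to_dict(b)) == 0

    def test_adjust_for_unaligned_full_overlap_identity(self, rng):
        grid, _ = small_grid(rng, 2, 3, 3, 8)
        base = sum_null(grid, 0, 2)
        bg = background_null(grid)
        out = adjust_for_unaligned(base, overlap=2, n_t=2, bg=bg)
        np.testing.assert_array_equal(out.pmf, base.pmf)
        with pytest.raises(ValueError):
            adjust_for_unaligned(base, overlap=0, n_t=2, bg=bg)

    def test_invalid_sizes_rejected(self, rng):
        grid, _ = small_grid(rng, 2, 3, 3, 8)
        with pytest.raises(EmptyInputError):
            max_alignment_null(grid, 0)


class TestPvalue:
    def test_extremes_of_support(self, rng):
        grid, _ = small_grid(rng, 2, 3, 4, 8)
        d = max_alignment_null(grid, 3, strand_mode="given")
        lo, hi = d.support
        assert pvalue(d, lo) == 1.0
        assert pvalue(d, lo - 10) == 1.0
        top = pvalue(d, hi)
        assert top == pytest.approx(d.pmf[-1], rel=1e-9, abs=1e-300)
        assert pvalue(d, hi + 1) > 0  # never exactly zero

    def test_monotone_nonincreasing_in_score(self, rng):
        grid, _ = small_grid(rng, 3, 4, 4, 16)
        d = max_alignment_null(grid, 4)
        lo, hi = d.support
        ps = [pvalue(d, x) for x in range(lo - 1, hi + 2)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_simulated_null_maxima(self, rng):
        """Empirical P from 100k simulated draws of the null model (an
        independent window per offset) agrees with pvalue at probe
        scores within binomial error."""
        from tomtomlite.nulls import offset_windows

        grid, _ = small_grid(rng, 2, 3, 4, 8)
        n_t, n_sim = 3, 100_000
        d = max_alignment_null(grid, n_t, adjust=False, strand_mode="given")
        z = grid.int_offset
        maxima = np.full(n_sim, -(10**9))
        for _, a, b in offset_windows(grid.width, n_t):
            v = b - a
            draws = rng.choice(grid.n_slots, size=(n_sim, v), p=grid.weights)
            scores = np.zeros(n_sim, dtype=np.int64)
            for k, i in enumerate(range(a, b)):
                scores += grid.binned[i, draws[:, k]] + z
            maxima = np.maximum(maxima, scores)
        lo, hi = d.support
        probes = np.unique(np.linspace(lo + 1, hi, 5).astype(int))
        for x in probes:
            p = pvalue(d, int(x))
            emp = np.mean(maxima >= x)
            sigma = np.sqrt(max(p * (1 - p), 1e-12) / n_sim)
            assert abs(emp - p) <= 3.5 * sigma + 1e-9


class TestNullCache:
    def test_equal_length_targets_share_one_entry(self, rng):
        grid, _ = small_grid(rng, 2, 4, 3, 8)
        cache = NullCache()
        key = ("q", 4, "given", "cfg")
        a = cache.get_or_compute(key, lambda: max_alignment_null(grid, 4))
        b = cache.get_or_compute(key, lambda: max_alignment_null(grid, 4))
        assert a is b
        assert len(cache) == 1 and cache.hits == 1 and cache.misses == 1

    def test_cache_hit_is_bitwise_identical_to_recomputation(self, rng):
        grid, _ = small_grid(rng, 3, 5, 4, 16)
        cache = NullCache()
        cached = cache.get_or_compute(("q", 5), lambda: max_alignment_null(grid, 5))
        fresh = max_alignment_null(grid, 5)
        np.testing.assert_array_equal(cached.pmf, fresh.pmf)
        assert cached.offset == fresh.offset
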