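# Methods

This note documents the model implemented by `tomtomlite`, the
numerical choices behind it, what the synthetic data generator does and
does not emulate, and the package's known limits.

## The comparison model

A query motif is an `A × w` matrix (alphabet rows, position columns);
frequency matrices (PWMs) have probability columns, attribution
matrices (CWMs) are unconstrained real values. The engine never
compares whole matrices directly; everything is built from column
scores.

**Column scores.** Every query column (plus one query-side background
column, see *Unaligned positions*) is scored against every distinct
column of the target database. The default score is the negative
Euclidean distance `γ(q, t) = −‖q − t‖₂`, maximized (at 0) exactly when
the columns are identical; Pearson correlation is provided as an
alternative, with the convention that correlation against a constant
vector is 0 rather than an error. Scores are symmetric in their
arguments.

**Column hashing.** Target columns are deduplicated by hashing their
values rounded to 1e-6 (coarse enough that float noise or low-precision
database entries cannot split identical columns). Each distinct column
becomes a *slot* carrying a multiplicity; a position map records which
slot every (target, column, strand) position landed in. Scoring slots
and expanding through the map is exactly equivalent to scoring every
column directly — hashing is an acceleration, not an approximation,
and the test suite asserts bitwise-identical hit tables with hashing
disabled.

**Median centering.** For each query row, the multiplicity-weighted
median of its scores over the whole database is subtracted. Centering
is what makes alignment scores comparable across overlap widths: sums
of centered scores over a random window of any length have median-zero
summands, so longer overlaps are not automatically favored. Medians
are computed once per query against the whole database (never per
target pair); this is precisely what makes one null distribution valid
for every equal-length target, and hence what makes caching sound.

Two median methods exist. `exact` sorts (weighted lower median).
`approximate` — the default — histograms the row into `B` bins over its
range and returns the midpoint of the bin containing the 50% mass
point. The true median lies inside that bin, so the two methods agree
within one bin width *by construction*; the measured worst deviation on
10⁶ random scores is half a bin. When a row's range is so narrow that
the histogram bin width would underflow (all scores essentially equal),
the exact median is used — it costs nothing there and keeps the
contract trivially.

**Quantization.** Centered scores are binned onto `B = 100` uniform
bins over their global observed range (`bin k` covers a half-open
interval; the endpoints map to bins 0 and `B − 1`; a degenerate range
collapses to one bin). Each column's *integer score* is `k + z` where
`z = round(lo/δ + ½)` and `δ` is the bin width, so sums over windows of
different lengths live on one additive integer scale; each column
contributes at most one bin width of rounding error relative to its
raw centered score. A degenerate range (all scores identical) is
handled as a single-bin grid and logged.

`B` trades null-DP cost (each convolution step is linear in support
size, which grows with `B`) against quantization error (half a bin per
column at reconstruction); 100 matches the resolution customary for
this statistic and is a CLI flag.

## Null distributions

**Null model.** A random target of length `n` has i.i.d. columns drawn
from the database's empirical column distribution — the
multiplicity-weighted distribution over distinct slots, and
complement-closed when both strands are searched (each position
contributes its given and complemented column). This empirical null is
what the per-column score histograms imply; no parametric background is
fitted.

**Per-window nulls are exact.** Because scores are integers, the null
of one query column's score is its weighted histogram over slots, and
the null of a contiguous window's sum is the convolution of its
columns' nulls. Prefix windows extend right and suffix windows extend
left, so all `w + n − 1` offsets of the usual `n ≥ w` case need only
`O(w)` convolutions; the full-width window, which repeats `n − w + 1`
times, is convolved once.

**The maximum over offsets.** The best-score null combines the
per-offset nulls as *independent* draws:
`P(max ≥ s) = 1 − ∏_o F_o(s − 1)`, with every offset counted twice when
both orientations are searched (the complement-closed column
distribution makes the minus-orientation window nulls equal to the
plus ones, which the reverse-complement consistency test exercises).
Independence across offsets is the model's one approximation to the
physical situation, in which overlapping offsets share target columns.
It is the standard choice for this family of statistics, and it errs
conservative: sharing columns correlates offset scores positively, so
the true maximum is stochastically smaller than the independent
maximum, and reported P-values can only be inflated, never deflated.
Two facts pin this down empirically in the test suite: (i) the
distribution the engine computes matches brute-force enumeration of
its own sample space to 1e-12 on all small configurations, via an
oracle that shares no code with the engine (outcome-by-outcome window
enumeration and pairwise max composition, no convolutions or CDF
products); and (ii) on targets whose columns really are i.i.d. draws
from the database distribution — where offsets do share columns — the
empirical fraction of P-values at or below α stays within binomial
noise of α at α ∈ {0.01, 0.05, 0.25} over 40 000 pairs, i.e. the
P-values are calibrated-to-conservative.

For a width-1 query the approximation vanishes (offsets draw disjoint
columns), and the max-null CDF equals the order-statistic closed form
`F(x)^n` to 1e-12.

**Unaligned positions (complete scores).** Without correction, the
maximum over offsets is biased toward short overlaps, whose nulls have
thinner tails. The adjustment pads the query with background columns
so every target column is scored at every offset: observed scores add
the background row's binned score at each unaligned target position,
and each offset's null is convolved with `(n − overlap)` independent
draws of the background-column null. When the target is fully covered
(`overlap = n ≤ w`) the adjustment is the identity, exactly. The
correction is on by default and can be disabled
(`--no-adjust-unaligned`).

**P-values, E-values, q-values.** P-values are inclusive survival
probabilities `P(S* ≥ s)`, which keeps them conservative under
quantization ties; survival functions are accumulated via
`log1p`/`expm1` so tails near 1e-300 keep full relative precision, and
a score above the null's support reports the smallest positive float
rather than 0. E-value = P × number of targets. q-values are
Benjamini–Hochberg step-up per query across its targets. Null pmfs are
accumulated in double precision and renormalized once if they drift
more than 1e-12 from unit mass.

## Caching and parallelism

Max-score nulls are cached per (query, target length, strand mode,
configuration digest); equal-length targets share one entry, and the
digest guarantees a configuration change can never serve a stale null.
Work is partitioned over queries with each query's pipeline sequential,
so the thread count cannot change any number. Both properties — and
hashing — are asserted bitwise on a 50 × 200 fixture.

One caveat on bitwise claims: a reverse-complemented *query* convolves
the same column nulls in a different order, so its P-values agree with
the forward run only to float associativity (relative differences at
the 1e-16 level); the consistency tests assert a 1e-12 relative
tolerance for that case and exact equality everywhere else. When the
best scores of the two orientations tie exactly, both runs report `+`
(the deterministic tie-break: smallest offset, then `+`), so the
orientation label does not flip for tied pairs.

## Synthetic data

The fixture generator emulates a motif database at desk scale: columns
are i.i.d. Dirichlet(0.5) draws — sharp, TF-like columns — with widths
uniform on 8–16 (the JASPAR-like range; tests use smaller widths where
exhaustive enumeration must stay cheap). Planted annotation scenarios
copy database motifs into "seqlets" with an optional column shift
(vacated positions refilled with fresh Dirichlet columns), optional
reverse complementation, and columnwise mixing toward uniform at a
noise rate ε; decoys are pure Dirichlet motifs. Everything regenerates
bitwise-identically from the seed.

What the generator does *not* emulate: within-motif column dependence,
database family structure (near-duplicate motifs), realistic
information-content profiles (flanking low-IC columns), or the noise
statistics of real attribution tracks. Passing recovery tests
therefore demonstrates the engine's ranking behaviour under the stated
noise model, not performance on any particular real database.

Problem sizes used by the shipped checks: exhaustive-enumeration
equivalence runs on queries up to width 3, targets up to length 4, a
handful of distinct columns, and 8 bins (the largest sizes where
enumeration is exact and immediate); calibration uses 20 replicates of
10 queries × 200 targets at the default width range; transparency uses
50 × 200; recovery uses 20 replicates of 10 planted seqlets against
50-motif databases.

## Limitations

- The independence-across-offsets null is conservative rather than
  exact for multi-column queries; precise ranking *among* very strong
  hits inherits quantization and independence error (the discriminative
  regime — is this a match at all — is unaffected in practice).
- CWMs are scored as-is, with no normalization or log transform;
  whether to pre-scale attribution values is left to the caller.
- Reverse-complement handling requires a 4-row alphabet; protein or
  embedding-valued matrices must use single-strand mode.
- No gapped alignments, no KL/Sandelin–Wasserman/ALLR column scores,
  no E-value extrapolation beyond the binned support, no motif
  trimming or clustering.
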