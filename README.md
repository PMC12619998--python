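# tomtomlite

Motif similarity scoring with exact integer-binned null distributions —
a fast, pure-Python comparator for position matrices, built for
regulatory genomics.

## The problem

Transcription-factor binding motifs are not discrete sequences: they are
**position-weight matrices** (PWMs) whose columns give per-position
nucleotide probabilities, or — increasingly, as attribution methods are
applied to sequence-to-activity models — **contribution-weight
matrices** (CWMs) of real-valued, possibly negative attribution scores.
Asking "which known motif does this matrix resemble?" requires scoring a
query matrix against every matrix in a database over **all ungapped
alignments** (every relative offset, and both orientations), keeping the
**maximum** score, and then asking how surprising that maximum is. The
last step is the hard one: a proper P-value must account for the whole
max-over-alignments procedure, not just a single column comparison, and
must do so for queries and targets of any width and information content.

This package implements the Tomtom family of statistics for that
problem, as a reusable library plus a thin CLI, with three accelerations
that leave the results unchanged (or change them by less than one score
bin): null-distribution caching across equal-length targets,
target-column hashing, and an approximate (histogram) median.

## The statistic

For query columns `q_1..q_w` and a target database, every query column
is scored against every distinct database column with
`γ(q, t) = −‖q − t‖₂` (Pearson correlation is available as an
alternative), recentered by its database-wide median `m_i`, and
quantized to `B = 100` integer bins. For a target of length `n`, the
score of the alignment at offset `o` is the sum of its aligned binned
column scores; with the complete-score adjustment, every *unaligned*
target column additionally contributes the background column's score,
removing the bias toward short overlaps. The reported score is

    S* = max over offsets o (and orientations) of S_o

Under the null, target columns are i.i.d. draws from the database's
empirical (multiplicity-weighted, complement-closed when both strands
are searched) column distribution. Because scores are integers, the
null of each `S_o` is an **exact convolution** of per-column nulls, and
the null of `S*` combines the per-offset nulls as independent draws:

    P(S* ≥ s) = 1 − ∏_o F_o(s − 1)

computed in log space so tiny tails keep full relative precision. The
reported P-value is inclusive (`P(S* ≥ s)`), an E-value is P × number
of targets, and q-values are Benjamini–Hochberg per query. See
`docs/methods.md` for assumptions, parameter choices, and limits.

## Worked example

```python
import tomtomlite as tl

# a synthetic 100-motif database, and a probe cut from one of its motifs
db = tl.random_pwm_set(tl.FixtureSpec(seed=7, n_motifs=100, width_range=(8, 14)),
                       prefix="db")
probe = tl.MotifSet([tl.Motif(name="probe", matrix=db["db_42"].matrix[:, 2:11])])
hits = tl.tomtom(probe, db)
print(hits.head(3).to_string(index=False))
```

prints

```
Query_ID Target_ID  Optimal_offset      p-value      E-value      q-value  Overlap Orientation    Score
   probe     db_42               2 1.086309e-14 1.086309e-12 1.086309e-12        8           + 5.321136
   probe     db_53              -1 1.163244e-02 1.163244e+00 5.157493e-01        7           - 2.732475
   probe     db_65               4 1.547248e-02 1.547248e+00 5.157493e-01        8           + 2.746857
```

The probe was carved out of `db_42` starting at column 2: the engine
recovers that source at offset 2 on the `+` strand with P ≈ 1e−14,
fourteen orders of magnitude clear of the best decoy. `Score` is the
best summed centered column score (bin-midpoint reconstructed);
`Optimal_offset` is the query start relative to the target start in the
reported orientation; `E-value` multiplies P by the 100 targets
searched.

The same engine runs from the shell:

```bash
tomtomlite run --query query.meme --targets database.meme -o hits.tsv
tomtomlite annotate --seqlets seqlets.meme --database database.meme \
    --threshold 0.01 -o annotated.tsv
tomtomlite fixtures --spec spec.json -o fixtures/
```

MEME minimal motif files and JASPAR-style PFM text are read natively;
CWMs use a dense TSV sidecar format (`write_dense_tsv`).

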