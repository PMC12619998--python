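"""Core motif data type and elementary transforms.

A motif is a named ``A x W`` real matrix: ``A`` alphabet rows (default
A, C, G, T) and ``W`` position columns. Two kinds of matrix share the
type, distinguished by ``semantics``:

``frequency``
    a position-weight matrix (PWM): every column is a probability
    distribution over the alphabet.
``attribution``
    a contribution-weight matrix (CWM) of feature-attribution values
    from a predictive model; entries may be negative and carry no
    normalization constraint. The only structural requirement is that
    rows mean the same thing in every column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    MotifWidthError,
    NormalizationError,
    ShapeMismatchError,
    UnsupportedAlphabetError,
    UnsupportedSemanticsError,
)

DNA = ("A", "C", "G", "T")

#: Tolerance on frequency column sums; loose enough to accept PFMs whose
#: entries were rounded to a few decimals before normalization.
FREQ_TOL = 1e-4

_SEMANTICS = ("frequency", "attribution")


@dataclass
class Motif:
    """A named position matrix.

    Parameters
    ----------
    name : str
        Identifier, unique within a :class:`~tomtomlite.io.MotifSet`.
    matrix : ndarray of shape (A, W)
        Alphabet rows by position columns.
    alphabet : tuple of str
        Ordered row labels; complementation pairs row ``i`` with row
        ``A - 1 - i`` (so ACGT order gives A<->T, C<->G).
    semantics : {"frequency", "attribution"}
    background : ndarray of shape (A,)
        Background probabilities; uniform if not given.
    """

    name: str
    matrix: np.ndarray
    alphabet: tuple = DNA
    semantics: str = "frequency"
    background: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise MotifWidthError(
                f"motif {self.name!r}: matrix must be 2-D (A x W), "
                f"got ndim={self.matrix.ndim}"
            )
        self.alphabet = tuple(self.alphabet)
        if self.background is None:
            a = len(self.alphabet)
            self.background = np.full(a, 1.0 / a)
        else:
            self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def alphabet_size(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other):
        if not isinstance(other, Motif):
            return NotImplemented
        return (
            self.name == other.name
            and self.alphabet == other.alphabet
            and self.semantics == other.semantics
            and self.matrix.shape == other.matrix.shape
            and np.array_equal(self.matrix, other.matrix)
            and np.array_equal(self.background, other.background)
        )


def validate_motif(m: Motif) -> Motif:
    """Check all structural invariants; return ``m`` unchanged if valid.

    Raises
    ------
    MotifWidthError
        zero-width or zero-alphabet matrix.
    ValueError
        non-finite entries, bad semantics flag, background not a
        distribution.
    NormalizationError
        a frequency column off by more than ``FREQ_TOL`` from sum 1, or
        a negative frequency entry.
    """
    a, w = m.matrix.shape
    if w < 1:
        raise MotifWidthError(f"motif {m.name!r}: width must be >= 1, got {w}")
    if a < 2:
        raise MotifWidthError(f"motif {m.name!r}: alphabet size must be >= 2, got {a}")
    if len(m.alphabet) != a:
        raise ShapeMismatchError(
            f"motif {m.name!r}: alphabet has {len(m.alphabet)} letters "
            f"but matrix has {a} rows"
        )
    if not np.all(np.isfinite(m.matrix)):
        raise ValueError(f"motif {m.name!r}: matrix contains non-finite entries")
    if m.semantics not in _SEMANTICS:
        raise ValueError(
            f"motif {m.name!r}: semantics must be one of {_SEMANTICS}, got {m.semantics!r}"
        )
    if m.semantics == "frequency":
        if np.any(m.matrix < 0):
            raise NormalizationError(f"motif {m.name!r}: negative frequency entries")
        sums = m.matrix.sum(axis=0)
        bad = np.abs(sums - 1.0) > FREQ_TOL
        if np.any(bad):
            j = int(np.argmax(bad))
            raise NormalizationError(
                f"motif {m.name!r}: column {j} sums to {sums[j]:.6g}, not 1"
            )
    if m.background.shape != (a,) or not np.all(np.isfinite(m.background)):
        raise ValueError(f"motif {m.name!r}: background must be a finite length-{a} vector")
    if abs(m.background.sum() - 1.0) > 1e-9 or np.any(m.background < 0):
        raise ValueError(f"motif {m.name!r}: background is not a probability vector")
    return m


def reverse_complement(m: Motif) -> Motif:
    """Reverse-complement a 4-row motif.

    Columns are reversed and rows swapped positionally (row ``i`` with
    row ``3 - i``), which is Watson-Crick pairing in ACGT row order.
    Works for attribution matrices too - complementation is purely
    positional, which is why non-4-letter alphabets are rejected rather
    than silently mis-complemented.
    """
    if m.alphabet_size != 4 or len(m.alphabet) != 4:
        raise UnsupportedAlphabetError(
            f"motif {m.name!r}: reverse complement requires a 4-letter alphabet, "
            f"got {len(m.alphabet)}"
        )
    return replace(m, matrix=m.matrix[::-1, ::-1].copy())


def information_content(m: Motif, per_column: bool = True):
    """Per-column information content in bits.

    ``IC_j = sum_a p_aj * log2(p_aj / bg_a)`` with ``0 * log 0 := 0``.
    Only defined for frequency motifs; the total IC is the sum over
    columns (``per_column=False``).
    """
    if m.semantics != "frequency":
        raise UnsupportedSemanticsError(
            f"motif {m.name!r}: information content requires frequency semantics"
        )
    p = m.matrix
    bg = m.background[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / bg), 0.0)
    ic = terms.sum(axis=0)
    return ic if per_column else float(ic.sum())
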