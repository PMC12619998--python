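"""Deterministic generators of motifs and planted-truth scenarios.

Every test and example in this package runs on synthetic data from this
module - no downloads. Random PWMs emulate a motif database: column
distributions are independent Dirichlet draws whose concentration sets
column sharpness (0.5 by default, giving the peaked, TF-like columns
real databases are full of), with widths uniform over a range chosen to
look like JASPAR-scale motifs. Planted scenarios emulate seqlet
annotation: seqlets are shifted / reverse-complemented / noised copies
of chosen database motifs mixed with pure-noise decoys, with a truth
table recording each seqlet's source.

What this generator does *not* emulate: columnwise dependence within
real motifs, database redundancy structure (motif families), or
attribution-track noise of real CWMs. Recovery rates measured here
speak to the engine's ranking behaviour under the stated noise model,
not to performance on any particular real database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import MotifSet
from .motifs import DNA, Motif

DEFAULT_CONCENTRATION = 0.5
DEFAULT_WIDTH_RANGE = (8, 16)


@dataclass
class PlantedPair:
    """One seqlet to plant: a copy of ``source`` (an index into the
    database), shifted by ``shift`` columns, optionally on the '-'
    orientation, with each column mixed toward uniform at rate
    ``noise``."""

    source: int
    shift: int = 0
    orientation: str = "+"
    noise: float = 0.0


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic motif database.

    The same spec always regenerates bitwise-identical sets.
    """

    seed: int
    n_motifs: int = 50
    width_range: tuple = DEFAULT_WIDTH_RANGE
    alphabet: tuple = DNA
    concentration: float = DEFAULT_CONCENTRATION
    planted: list = field(default_factory=list)
    n_decoys: int = 0

    def __post_init__(self):
        lo, hi = self.width_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid width range {self.width_range}")
        self.planted = [
            p if isinstance(p, PlantedPair) else PlantedPair(**p) for p in self.planted
        ]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        return cls(**json.loads(text))


def _random_motif(rng, name, spec) -> Motif:
    lo, hi = spec.width_range
    w = int(rng.integers(lo, hi + 1))
    a = len(spec.alphabet)
    cols = rng.dirichlet(np.full(a, spec.concentration), size=w)
    return Motif(name=name, matrix=cols.T, alphabet=spec.alphabet)


def random_pwm_set(spec: FixtureSpec, prefix: str = "random") -> MotifSet:
    """Generate ``spec.n_motifs`` random PWMs (i.i.d. Dirichlet columns)."""
    rng = np.random.default_rng(spec.seed)
    motifs = [_random_motif(rng, f"{prefix}_{i}", spec) for i in range(spec.n_motifs)]
    return MotifSet(motifs, source=f"random_pwm_set(seed={spec.seed})")


def _noisy(matrix, rng, noise):
    if noise == 0:
        return matrix.copy()
    a = matrix.shape[0]
    return (1 - noise) * matrix + noise / a


def _shifted(matrix, rng, shift, concentration):
    """Shift columns by ``shift`` (positive = rightward), refilling the
    vacated positions with fresh Dirichlet columns; width preserved."""
    a, w = matrix.shape
    if abs(shift) >= w:
        raise ValueError(f"shift {shift} exceeds motif width {w}")
    out = rng.dirichlet(np.full(a, concentration), size=w).T
    if shift >= 0:
        out[:, shift:] = matrix[:, : w - shift]
    else:
        out[:, : w + shift] = matrix[:, -shift:]
    return out


def planted_database(spec: FixtureSpec):
    """Build a (seqlets, database, truth) triple.

    The database is ``random_pwm_set(spec)``. Each planted pair yields
    one seqlet derived from its source motif; ``spec.n_decoys`` extra
    seqlets are pure Dirichlet noise with no source. ``truth`` has one
    row per planted seqlet: seqlet name, source name, shift,
    orientation, noise.
    """
    database = random_pwm_set(spec, prefix="db")
    rng = np.random.default_rng(spec.seed + 1)
    seqlets = []
    truth = []
    for i, pair in enumerate(spec.planted):
        src = database[pair.source]
        mat = src.matrix
        if pair.orientation == "-":
            mat = mat[::-1, ::-1]
        mat = _shifted(mat, rng, pair.shift, spec.concentration)
        mat = _noisy(mat, rng, pair.noise)
        name = f"seqlet_{i}"
        seqlets.append(Motif(name=name, matrix=mat, alphabet=spec.alphabet))
        truth.append(
            {
                "seqlet": name,
                "source": src.name,
                "shift": pair.shift,
                "orientation": pair.orientation,
                "noise": pair.noise,
            }
        )
    for d in range(spec.n_decoys):
        seqlets.append(_random_motif(rng, f"decoy_{d}", spec))
    import pandas as pd

    return (
        MotifSet(seqlets, source=f"planted(seed={spec.seed})"),
        database,
        pd.DataFrame(truth, columns=["seqlet", "source", "shift", "orientation", "noise"]),
    )
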