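"""Reading and writing motif collections.

Supported on-disk formats:

* MEME minimal motif format (version line, ``ALPHABET=``, optional
  background frequencies, ``MOTIF`` blocks with a
  ``letter-probability matrix:`` header) - frequency motifs only.
* JASPAR-style PFM text: ``>name`` headers followed by four count rows,
  either bracketed (``A [ 1 2 3 ]``) or plain whitespace-separated,
  with or without the leading letter.
* A dense TSV sidecar format for attribution matrices (CWMs), since the
  MEME format presumes probabilities.

Hit tables are plain pandas DataFrames and are written as TSV.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateNameError,
    MotifFormatError,
    ShapeMismatchError,
    UnsupportedSemanticsError,
)
from .motifs import DNA, Motif, validate_motif

logger = logging.getLogger(__name__)

#: Column order of hit-table TSVs, matching the reference tool's vocabulary.
HIT_COLUMNS = [
    "Query_ID",
    "Target_ID",
    "Optimal_offset",
    "p-value",
    "E-value",
    "q-value",
    "Overlap",
    "Orientation",
    "Score",
]


@dataclass
class MotifSet:
    """An ordered collection of motifs sharing one alphabet."""

    motifs: list = field(default_factory=list)
    source: str = "<memory>"

    def __post_init__(self):
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise DuplicateNameError(f"duplicate motif name {dup!r} in {self.source}")
        alphabets = {m.alphabet for m in self.motifs}
        if len(alphabets) > 1:
            raise ShapeMismatchError(
                f"motifs in {self.source} use more than one alphabet: {alphabets}"
            )

    def __len__(self):
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, key):
        if isinstance(key, str):
            for m in self.motifs:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.motifs[key]

    @property
    def names(self):
        return [m.name for m in self.motifs]

    @property
    def alphabet(self):
        return self.motifs[0].alphabet if self.motifs else DNA


def _as_text(path_or_text) -> str:
    """Accept a Path, a filesystem path string, or raw format text."""
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    if isinstance(path_or_text, str):
        if "\n" not in path_or_text and os.path.exists(path_or_text):
            return Path(path_or_text).read_text()
        return path_or_text
    return path_or_text.read()  # file-like


_VERSION_RE = re.compile(r"^MEME\s+version\s+\S+", re.IGNORECASE)
_KV_RE = re.compile(r"(\w+)=\s*(\S+)")


def read_meme(path_or_text, source: str | None = None) -> MotifSet:
    """Parse MEME minimal motif format into a :class:`MotifSet`.

    Only the matrices and their headers are interpreted; other blocks of
    full MEME output files (sites, diagrams, ...) are ignored. The
    declared ``w`` and ``alength`` must match the parsed matrix shape.
    """
    text = _as_text(path_or_text)
    lines = text.splitlines()
    i = 0
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines) or not _VERSION_RE.match(lines[i].strip()):
        raise MotifFormatError("missing 'MEME version' line at top of file")

    alphabet = DNA
    background = None
    motifs = []
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            letters = line.split("=", 1)[1].split()
            # either "ALPHABET= ACGT" or spaced letters
            joined = "".join(letters)
            alphabet = tuple(joined)
            i += 1
        elif line.lower().startswith("background letter frequencies"):
            i += 1
            pairs = []
            while i < n:
                toks = lines[i].split()
                if len(toks) >= 2 and len(toks) % 2 == 0 and toks[0] in alphabet:
                    pairs.extend(toks)
                    i += 1
                else:
                    break
            freqs = dict(zip(pairs[0::2], map(float, pairs[1::2])))
            background = np.array([freqs.get(a, 0.0) for a in alphabet])
        elif line.startswith("MOTIF"):
            toks = line.split()
            if len(toks) < 2:
                raise MotifFormatError(f"MOTIF line without a name: {line!r}")
            name = toks[1]
            i += 1
            # find the letter-probability header
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifFormatError(
                        f"motif {name!r}: no letter-probability matrix header"
                    )
                i += 1
            if i >= n:
                raise MotifFormatError(
                    f"motif {name!r}: no letter-probability matrix header"
                )
            attrs = dict(_KV_RE.findall(lines[i]))
            i += 1
            rows = []
            while i < n:
                toks = lines[i].split()
                try:
                    vals = [float(t) for t in toks]
                except ValueError:
                    break
                if not vals:
                    break
                rows.append(vals)
                i += 1
            if not rows:
                raise MotifFormatError(f"motif {name!r}: empty matrix")
            widths = {len(r) for r in rows}
            if len(widths) != 1:
                raise ShapeMismatchError(f"motif {name!r}: ragged matrix rows")
            mat = np.array(rows).T  # lines are positions; transpose to A x W
            declared_w = attrs.get("w")
            declared_a = attrs.get("alength")
            if declared_w is not None and int(declared_w) != mat.shape[1]:
                raise ShapeMismatchError(
                    f"motif {name!r}: header says w= {declared_w} but matrix "
                    f"has {mat.shape[1]} positions"
                )
            if declared_a is not None and int(declared_a) != mat.shape[0]:
                raise ShapeMismatchError(
                    f"motif {name!r}: header says alength= {declared_a} but "
                    f"matrix has {mat.shape[0]} letters"
                )
            motifs.append(
                Motif(
                    name=name,
                    matrix=mat,
                    alphabet=alphabet,
                    semantics="frequency",
                    background=background,
                )
            )
        else:
            i += 1

    for m in motifs:
        validate_motif(m)
    return MotifSet(motifs, source=source or "<meme>")


def write_meme(motif_set: MotifSet, path=None) -> str:
    """Serialize frequency motifs to MEME minimal format (6 decimals).

    Returns the text; also writes it to ``path`` when given. Attribution
    motifs are rejected - use :func:`write_dense_tsv` for CWMs.
    """
    for m in motif_set:
        if m.semantics != "frequency":
            raise UnsupportedSemanticsError(
                f"motif {m.name!r} has attribution semantics; MEME format "
                "presumes probabilities (use write_dense_tsv)"
            )
    alphabet = motif_set.alphabet
    if motif_set.motifs:
        background = motif_set[0].background
    else:
        background = np.full(len(alphabet), 1.0 / len(alphabet))
    out = ["MEME version 4", "", f"ALPHABET= {''.join(alphabet)}", ""]
    out.append("Background letter frequencies")
    out.append(" ".join(f"{a} {b:.6f}" for a, b in zip(alphabet, background)))
    out.append("")
    for m in motif_set:
        out.append(f"MOTIF {m.name}")
        out.append(
            f"letter-probability matrix: alength= {m.alphabet_size} w= {m.width}"
        )
        for col in m.matrix.T:
            out.append(" ".join(f"{v:.6f}" for v in col))
        out.append("")
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


_BRACKET_RE = re.compile(r"^\s*([A-Za-z])?\s*\[?\s*([-\d.\seEd+]*?)\s*\]?\s*$")


def read_jaspar_pfm(path_or_text, source: str | None = None) -> MotifSet:
    """Parse JASPAR-style PFM records into frequency motifs.

    Each record is a ``>name`` header plus four count rows in A, C, G, T
    order; bracketed (``A [ 1 2 3 ]``) and plain dialects parse
    identically. Counts are normalized per column; an all-zero column
    becomes uniform (with a warning) so real databases stay loadable.
    """
    text = _as_text(path_or_text)
    motifs = []
    name = None
    rows: list = []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise MotifFormatError(
                f"record {name!r}: expected 4 count rows, got {len(rows)}"
            )
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ShapeMismatchError(f"record {name!r}: ragged count rows")
        counts = np.array(rows, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"record {name!r}: negative counts")
        sums = counts.sum(axis=0)
        zero = sums == 0
        if np.any(zero):
            logger.warning(
                "record %r: %d all-zero column(s) set to uniform", name, zero.sum()
            )
            counts[:, zero] = 0.25
            sums = counts.sum(axis=0)
        motifs.append(
            Motif(name=name, matrix=counts / sums, alphabet=DNA, semantics="frequency")
        )

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else line[1:]
            rows = []
        else:
            m = _BRACKET_RE.match(line)
            if m is None or not m.group(2).strip():
                raise MotifFormatError(f"unparseable PFM row: {raw!r}")
            vals = [float(t) for t in m.group(2).split()]
            rows.append(vals)
    flush()
    return MotifSet(motifs, source=source or "<jaspar>")


def write_dense_tsv(motif_set: MotifSet, path=None) -> str:
    """Serialize motifs (any semantics) to the dense TSV sidecar format.

    One block per motif::

        #MOTIF <tab> name <tab> semantics <tab> alphabet
        row_A ...
        ...
    """
    out = []
    for m in motif_set:
        out.append(f"#MOTIF\t{m.name}\t{m.semantics}\t{''.join(m.alphabet)}")
        for row in m.matrix:
            out.append("\t".join(repr(float(v)) for v in row))
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_dense_tsv(path_or_text, source: str | None = None) -> MotifSet:
    """Inverse of :func:`write_dense_tsv` (lossless round-trip)."""
    text = _as_text(path_or_text)
    motifs = []
    name = semantics = None
    alphabet = DNA
    rows: list = []

    def flush():
        if name is None:
            return
        motifs.append(
            Motif(name=name, matrix=np.array(rows), alphabet=alphabet, semantics=semantics)
        )

    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#MOTIF"):
            flush()
            _, name, semantics, letters = line.split("\t")
            alphabet = tuple(letters)
            rows = []
        else:
            rows.append([float(t) for t in line.split("\t")])
    flush()
    return MotifSet(motifs, source=source or "<dense-tsv>")


def write_hits_tsv(hits: pd.DataFrame, path) -> None:
    """Write a hit table as TSV with the standard column order."""
    cols = [c for c in HIT_COLUMNS if c in hits.columns]
    cols += [c for c in hits.columns if c not in cols]
    hits.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")
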