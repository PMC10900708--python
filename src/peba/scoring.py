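"""Residue-pair scoring: scaled embedding cosine similarity or substitution tables.

The embedding score of residues x_i and y_j is

    delta(x_i, y_j) = scale * cosine(Emb(x_i), Emb(y_j)),    scale = 10,

which replaces the substitution-table lookup of a classical aligner.  The
baseline path builds the same m x n score matrix from BLOSUM-style tables.
Scores are kept in full precision; no rounding happens before the dynamic
program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from Bio.Align import substitution_matrices

from .embeddings import ResidueEmbeddings
from .seqio import ProteinSequence

log = logging.getLogger(__name__)

DEFAULT_SCALE = 10.0


@dataclass(frozen=True)
class ScoreMatrix:
    """m x n matrix of residue-pair match scores delta(x_i, y_j)."""

    values: np.ndarray
    origin: str  # "embedding" | "substitution"
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"score matrix must be 2-D, got shape {v.shape}")
        if self.origin not in ("embedding", "substitution"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "embedding" and v.size and np.max(np.abs(v)) > self.scale * (1 + 1e-9):
            raise ValueError("embedding scores must lie within [-scale, +scale]")
        object.__setattr__(self, "values", v)

    @property
    def qry_len(self) -> int:
        return self.values.shape[0]

    @property
    def ref_len(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.values, delimiter="\t")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity, clamped to [-1, 1]; zero-norm inputs score 0."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector dimensions differ: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        log.warning("zero-norm embedding vector; cosine defined as 0")
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def embedding_score_matrix(
    emb_a: ResidueEmbeddings,
    emb_b: ResidueEmbeddings,
    scale: float = DEFAULT_SCALE,
) -> ScoreMatrix:
    """values[i, j] = scale * cosine(row_a[i], row_b[j])."""
    if emb_a.dim != emb_b.dim:
        raise ValueError(
            f"embedding dimensions differ: {emb_a.seq_id!r} has d={emb_a.dim}, "
            f"{emb_b.seq_id!r} has d={emb_b.dim}"
        )
    na = np.linalg.norm(emb_a.matrix, axis=1)
    nb = np.linalg.norm(emb_b.matrix, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        log.warning("zero-norm embedding rows present; they score 0 everywhere")
    sa = np.divide(emb_a.matrix, na[:, None], where=na[:, None] != 0,
                   out=np.zeros_like(emb_a.matrix))
    sb = np.divide(emb_b.matrix, nb[:, None], where=nb[:, None] != 0,
                   out=np.zeros_like(emb_b.matrix))
    cos = np.clip(sa @ sb.T, -1.0, 1.0)
    return ScoreMatrix(values=scale * cos, origin="embedding", scale=scale)


_WILDCARD = "X"
_BUILTIN_NAMES = {"BLOSUM62", "BLOSUM45", "BLOSUM50", "BLOSUM80", "BLOSUM90"}


@dataclass(frozen=True)
class SubstitutionTable:
    """A symmetric residue-pair score table with wildcard fallback.

    Residues absent from the table (e.g. ``J``) are looked up as ``X``.
    """

    name: str
    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if self.scores.get((b, a), s) != s:
                raise ValueError(f"asymmetric table: ({a},{b})={s} vs ({b},{a})")
        object.__setattr__(self, "_alphabet", frozenset(a for a, _ in self.scores))
        if _WILDCARD not in self._alphabet:
            raise ValueError(f"table {self.name!r} lacks a wildcard ({_WILDCARD}) row")

    @property
    def alphabet(self) -> frozenset[str]:
        return self._alphabet

    def score(self, a: str, b: str) -> float:
        a = a if a in self._alphabet else _WILDCARD
        b = b if b in self._alphabet else _WILDCARD
        return self.scores[(a, b)]

    def __call__(self, a: str, b: str) -> float:
        return self.score(a, b)


def load_substitution_table(name_or_path: Union[str, Path]) -> SubstitutionTable:
    """Load a table by built-in name (BLOSUM62, BLOSUM45, ...) or from an
    NCBI-style matrix text file (e.g. a PFASUM60 download)."""
    key = str(name_or_path)
    if key.upper() in _BUILTIN_NAMES:
        arr = substitution_matrices.load(key.upper())
        name = key.upper()
    elif Path(key).is_file():
        arr = substitution_matrices.read(key)
        name = Path(key).stem
    else:
        raise ValueError(
            f"unknown substitution table {key!r}: not a built-in name "
            f"({sorted(_BUILTIN_NAMES)}) and not an existing file"
        )
    scores: dict[tuple[str, str], float] = {}
    letters = [c for c in arr.alphabet if c != "*"]
    for a in letters:
        for b in letters:
            scores[(a, b)] = float(arr[a, b])
    return SubstitutionTable(name=name, scores=scores)


def substitution_score_matrix(
    seq_a: ProteinSequence, seq_b: ProteinSequence, table: SubstitutionTable
) -> ScoreMatrix:
    """values[i, j] = table(a_i, b_j), with wildcard mapping for rare codes."""
    letters = sorted(table.alphabet | {_WILDCARD})
    index = {c: k for k, c in enumerate(letters)}
    lut = np.zeros((len(letters), len(letters)))
    for a in letters:
        for b in letters:
            lut[index[a], index[b]] = table.score(a, b)

    def codes(residues: str) -> np.ndarray:
        return np.array([index.get(c, index[_WILDCARD]) for c in residues])

    values = lut[np.ix_(codes(seq_a.residues), codes(seq_b.residues))]
    return ScoreMatrix(values=values, origin="substitution", scale=DEFAULT_SCALE)
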