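"""Affine-gap pairwise alignment by dynamic programming.

Smith-Waterman (local, the default) and Needleman-Wunsch (global) over an
arbitrary pre-computed score matrix, using the three-state Gotoh recurrence
(match state M, gap-in-reference state consuming query residues, and
gap-in-query state consuming reference residues).  A gap of length k costs
``|open| + (k-1) * |extend|``: the opening charge covers the first gapped
position.  Defaults are open = -11, extend = -1.

Tie-breaking is fully deterministic and is defined declaratively so the
exhaustive test oracle can implement the *same* rule independently of the
DP: among optimal alignments, prefer (1) for local mode, the end cell with
the smallest i+j, then the smallest i; (2) the alignment whose move string,
read from the end backwards, is lexicographically greatest under
diagonal > up (gap in reference) > left (gap in query), with "alignment
starts here" ranking above diagonal (so a local traceback stops at the
first cell whose score is fully explained by its own pair).  Equal-cost
interleavings of adjacent gap runs therefore canonicalize to the
left-run-before-up-run order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .scoring import ScoreMatrix
from .seqio import ProteinSequence

log = logging.getLogger(__name__)

NEG_INF = float("-inf")

# move codes, ranked for reversed-lexicographic tie comparison
_STOP, _DIAG, _UP, _LEFT = 3, 2, 1, 0
_MOVE_CHAR = {_DIAG: "D", _UP: "U", _LEFT: "L"}


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap costs, as (negative) scores added per gap event."""

    open: float = -11.0
    extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.open <= self.extend <= 0):
            raise ValueError(
                f"need open <= extend <= 0, got open={self.open} extend={self.extend}"
            )

    def run_cost(self, k: int) -> float:
        """Score contribution of one gap run of length k (0 for k=0)."""
        return 0.0 if k == 0 else self.open + (k - 1) * self.extend


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment: aligned index pairs, move string, raw score.

    ``pairs`` are 0-based (i, j) residue indices, strictly increasing in
    both coordinates.  ``moves`` is the aligned region's move string over
    {D, U, L} (D = aligned pair, U = query residue against gap, L =
    reference residue against gap).  ``gapped_a``/``gapped_b`` are rendered
    only when residue strings are attached (see :meth:`with_sequences`).
    """

    pairs: tuple[tuple[int, int], ...]
    score: float
    mode: str  # "local" | "global"
    moves: str = ""
    qry_span: tuple[int, int] = (0, 0)
    ref_span: tuple[int, int] = (0, 0)
    gapped_a: Optional[str] = None
    gapped_b: Optional[str] = None
    qry_id: Optional[str] = None
    ref_id: Optional[str] = None
    qry_residues: Optional[str] = None
    ref_residues: Optional[str] = None

    def __post_init__(self) -> None:
        pi, pj = -1, -1
        for i, j in self.pairs:
            if not (i > pi and j > pj):
                raise ValueError(f"pairs not strictly increasing at ({i},{j})")
            pi, pj = i, j
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "local" and self.score < 0:
            raise ValueError("local alignment score must be >= 0")

    @property
    def is_empty(self) -> bool:
        return not self.moves

    def with_sequences(
        self,
        seq_a: Union[str, ProteinSequence],
        seq_b: Union[str, ProteinSequence],
    ) -> "AlignmentResult":
        """Attach residue strings and render the gapped rows."""
        res_a = seq_a.residues if isinstance(seq_a, ProteinSequence) else seq_a
        res_b = seq_b.residues if isinstance(seq_b, ProteinSequence) else seq_b
        id_a = seq_a.id if isinstance(seq_a, ProteinSequence) else None
        id_b = seq_b.id if isinstance(seq_b, ProteinSequence) else None
        ga, gb = [], []
        i, j = self.qry_span[0], self.ref_span[0]
        for mv in self.moves:
            if mv == "D":
                ga.append(res_a[i]); gb.append(res_b[j]); i += 1; j += 1
            elif mv == "U":
                ga.append(res_a[i]); gb.append("-"); i += 1
            else:
                ga.append("-"); gb.append(res_b[j]); j += 1
        return replace(
            self,
            gapped_a="".join(ga),
            gapped_b="".join(gb),
            qry_id=id_a,
            ref_id=id_b,
            qry_residues=res_a,
            ref_residues=res_b,
        )


def _moves_to_spans(moves: str, start_i: int, start_j: int) -> tuple[tuple[int, int], tuple[int, int]]:
    di = sum(1 for m in moves if m in "DU")
    dj = sum(1 for m in moves if m in "DL")
    return (start_i, start_i + di), (start_j, start_j + dj)


def _empty_result(mode: str) -> AlignmentResult:
    return AlignmentResult(pairs=(), score=0.0, mode=mode)


def _fill(S: np.ndarray, gaps: GapPenalties, local: bool):
    """Gotoh fill.  Returns the three (m+1) x (n+1) state matrices."""
    m, n = S.shape
    go, ge = gaps.open, gaps.extend
    M = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)  # ends consuming a query residue (U)
    Iy = np.full((m + 1, n + 1), NEG_INF)  # ends consuming a reference residue (L)
    if not local:
        M[0, 0] = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i > 0 and j > 0:
                prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
                if local:
                    prev = max(prev, 0.0)
                if prev > NEG_INF:
                    M[i, j] = S[i - 1, j - 1] + prev
            if i > 0:
                Ix[i, j] = max(M[i - 1, j] + go, Ix[i - 1, j] + ge, Iy[i - 1, j] + go)
            if j > 0:
                Iy[i, j] = max(M[i, j - 1] + go, Ix[i, j - 1] + go, Iy[i, j - 1] + ge)
    return M, Ix, Iy


def _traceback(S, gaps, M, Ix, Iy, i, j, state, local: bool):
    """Walk predecessors greedily under the declared preference order."""
    go, ge = gaps.open, gaps.extend
    rev_moves: list[str] = []
    rev_pairs: list[tuple[int, int]] = []
    while True:
        if state == "M":
            rev_moves.append("D")
            rev_pairs.append((i - 1, j - 1))
            s = S[i - 1, j - 1]
            if local and M[i, j] == s:  # fully explained by this pair: start here
                break
            if not local and i == 1 and j == 1:
                break
            # predecessor preference: M (diag) > Ix (up) > Iy (left)
            if M[i, j] == s + M[i - 1, j - 1]:
                state = "M"
            elif M[i, j] == s + Ix[i - 1, j - 1]:
                state = "Ix"
            elif M[i, j] == s + Iy[i - 1, j - 1]:
                state = "Iy"
            else:  # pragma: no cover - fill/traceback invariant
                raise AssertionError(f"broken traceback at M[{i},{j}]")
            i, j = i - 1, j - 1
        elif state == "Ix":
            rev_moves.append("U")
            v = Ix[i, j]
            if not local and i == 1 and j == 0:
                break
            if M[i - 1, j] + go == v:
                state = "M"
            elif Ix[i - 1, j] + ge == v:
                state = "Ix"
            elif Iy[i - 1, j] + go == v:
                state = "Iy"
            else:  # pragma: no cover
                raise AssertionError(f"broken traceback at Ix[{i},{j}]")
            i = i - 1
        else:  # Iy
            rev_moves.append("L")
            v = Iy[i, j]
            if not local and i == 0 and j == 1:
                break
            if M[i, j - 1] + go == v:
                state = "M"
            elif Ix[i, j - 1] + go == v:
                state = "Ix"
            elif Iy[i, j - 1] + ge == v:
                state = "Iy"
            else:  # pragma: no cover
                raise AssertionError(f"broken traceback at Iy[{i},{j}]")
            j = j - 1
    return "".join(reversed(rev_moves)), tuple(reversed(rev_pairs))


def smith_waterman(
    S: ScoreMatrix, gaps: GapPenalties = GapPenalties()
) -> AlignmentResult:
    """Optimal local alignment; empty (score 0) if no positive-scoring cell."""
    V = S.values
    m, n = V.shape
    if m == 0 or n == 0:
        return _empty_result("local")
    M, Ix, Iy = _fill(V, gaps, local=True)
    best, bi, bj = 0.0, -1, -1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            v = M[i, j]
            if v > best or (v == best and (i + j, i) < (bi + bj, bi)):
                best, bi, bj = v, i, j
    if best <= 0.0:
        return _empty_result("local")
    moves, pairs = _traceback(V, gaps, M, Ix, Iy, bi, bj, "M", local=True)
    start_i, start_j = pairs[0]
    qs, rs = _moves_to_spans(moves, start_i, start_j)
    return AlignmentResult(
        pairs=pairs, score=float(best), mode="local", moves=moves,
        qry_span=qs, ref_span=rs,
    )


def needleman_wunsch(
    S: ScoreMatrix, gaps: GapPenalties = GapPenalties()
) -> AlignmentResult:
    """Optimal global alignment; end gaps are penalized like interior gaps."""
    V = S.values
    m, n = V.shape
    if m == 0 and n == 0:
        return _empty_result("global")
    if m == 0 or n == 0:  # one row is pure gap
        moves = "L" * n + "U" * m
        return AlignmentResult(
            pairs=(), score=gaps.run_cost(n) + gaps.run_cost(m), mode="global",
            moves=moves, qry_span=(0, m), ref_span=(0, n),
        )
    M, Ix, Iy = _fill(V, gaps, local=False)
    finals = [("M", M[m, n]), ("Ix", Ix[m, n]), ("Iy", Iy[m, n])]
    best = max(v for _, v in finals)
    state = next(s for s, v in finals if v == best)
    moves, pairs = _traceback(V, gaps, M, Ix, Iy, m, n, state, local=False)
    return AlignmentResult(
        pairs=pairs, score=float(best), mode="global", moves=moves,
        qry_span=(0, m), ref_span=(0, n),
    )


# ---------------------------------------------------------------------------
# exhaustive oracle


_BRUTE_LIMIT = 36


def _chain_moves_local(pairs) -> str:
    """Canonical move string of a local chain (left runs before up runs)."""
    out = []
    pi, pj = pairs[0]
    out.append("D")
    for i, j in pairs[1:]:
        out.append("L" * (j - pj - 1) + "U" * (i - pi - 1) + "D")
        pi, pj = i, j
    return "".join(out)


def _chain_moves_global(pairs, m, n) -> str:
    if not pairs:
        return "L" * n + "U" * m
    i0, j0 = pairs[0]
    ik, jk = pairs[-1]
    return (
        "L" * j0 + "U" * i0
        + _chain_moves_local(pairs)
        + "L" * (n - 1 - jk) + "U" * (m - 1 - ik)
    )


def _moves_score(moves: str, pairs, S, gaps: GapPenalties) -> float:
    total = sum(float(S[i, j]) for i, j in pairs)
    for mv, run in itertools.groupby(moves):
        if mv in "UL":
            total += gaps.run_cost(sum(1 for _ in run))
    return total


def _rev_key(moves: str) -> tuple[int, ...]:
    """Reversed move string as comparable ranks; end-of-string outranks all."""
    code = {"D": _DIAG, "U": _UP, "L": _LEFT}
    return tuple(code[c] for c in reversed(moves)) + (_STOP,)


def brute_force_align(
    S: ScoreMatrix, gaps: GapPenalties = GapPenalties(), mode: str = "local"
) -> AlignmentResult:
    """Exact optimum by enumerating every monotone pair set (test oracle).

    Applies the same declarative tie-breaking order as the DP traceback.
    Guarded to score matrices with at most 36 cells.
    """
    V = S.values
    m, n = V.shape
    if m * n > _BRUTE_LIMIT:
        raise ValueError(f"brute force limited to m*n <= {_BRUTE_LIMIT}, got {m}x{n}")
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")

    def chains():
        for k in range(1, min(m, n) + 1):
            for rows in itertools.combinations(range(m), k):
                for cols in itertools.combinations(range(n), k):
                    yield tuple(zip(rows, cols))

    if mode == "local":
        best_key, best = None, None
        for chain in chains():
            moves = _chain_moves_local(chain)
            score = _moves_score(moves, chain, V, gaps)
            ie, je = chain[-1]
            key = (score, -(ie + je), -ie, _rev_key(moves))
            if best_key is None or key > best_key:
                best_key, best = key, (chain, moves, score)
        if best is None or best[2] <= 0.0:
            return _empty_result("local")
        chain, moves, score = best
        qs, rs = _moves_to_spans(moves, chain[0][0], chain[0][1])
        return AlignmentResult(
            pairs=chain, score=score, mode="local", moves=moves,
            qry_span=qs, ref_span=rs,
        )

    best_key, best = None, None
    for chain in itertools.chain([()], chains()):
        moves = _chain_moves_global(chain, m, n)
        score = _moves_score(moves, chain, V, gaps)
        key = (score, _rev_key(moves))
        if best_key is None or key > best_key:
            best_key, best = key, (chain, moves, score)
    chain, moves, score = best
    return AlignmentResult(
        pairs=chain, score=score, mode="global", moves=moves,
        qry_span=(0, m), ref_span=(0, n),
    )


def score_audit(
    aln: AlignmentResult, S: ScoreMatrix, gaps: GapPenalties = GapPenalties()
) -> float:
    """Recompute an alignment's score from its pairs and gap runs.

    The recomputed value must equal ``aln.score`` up to float tolerance;
    raising on structurally inconsistent input.
    """
    V = S.values
    m, n = V.shape
    for i, j in aln.pairs:
        if not (0 <= i < m and 0 <= j < n):
            raise ValueError(f"pair ({i},{j}) outside the {m}x{n} score matrix")
    if aln.is_empty:
        if aln.mode == "local":
            return 0.0
        return gaps.run_cost(m) + gaps.run_cost(n)
    if aln.moves:
        return _moves_score(aln.moves, aln.pairs, V, gaps)
    # no move string: assume canonical contiguous gap runs between pairs
    moves = (
        _chain_moves_local(aln.pairs)
        if aln.mode == "local"
        else _chain_moves_global(aln.pairs, m, n)
    )
    return _moves_score(moves, aln.pairs, V, gaps)
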