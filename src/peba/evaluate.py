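"""Alignment-quality evaluation against reference alignments.

Sum-of-Pairs (SP) score is the fraction of the reference's aligned residue
pairs recovered by the test alignment (for pairwise alignments SP equals
the Total Column score, since each column holds exactly one pair).  F1 is
the harmonic mean of recall (SP) and precision (fraction of the test's
pairs that are in the reference).  Results can be binned by reference
percent identity or by reference alignment length (columns, residues and
gaps); bins holding fewer than 10 alignments are suppressed so sparse bins
do not print skewed means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .align import AlignmentResult
from .seqio import PairwiseReference, _reference_pairs

log = logging.getLogger(__name__)

#: bins below this many alignments report no mean
SUPPRESS_BELOW = 10

IDENTITY_EDGES = tuple(float(x) for x in range(0, 110, 10))
LENGTH_EDGES = tuple(float(x) for x in range(0, 3000, 500))


@dataclass(frozen=True)
class ColumnPairSet:
    """The aligned residue index pairs of one alignment, gap columns excluded."""

    pairs: frozenset[tuple[int, int]]
    source: str = "test"  # "test" | "reference"

    def __post_init__(self) -> None:
        lefts = [i for i, _ in self.pairs]
        rights = [j for _, j in self.pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise ValueError("alignment is not one-to-one: repeated index in pairs")

    def __len__(self) -> int:
        return len(self.pairs)


def column_pairs(
    aln: Union[AlignmentResult, PairwiseReference], source: str = "test"
) -> ColumnPairSet:
    """Aligned (i, j) residue index pairs of an alignment, as a set."""
    if isinstance(aln, PairwiseReference):
        pairs = _reference_pairs(aln)
    elif isinstance(aln, AlignmentResult):
        pairs = aln.pairs
    else:
        raise TypeError(f"cannot take column pairs of {type(aln).__name__}")
    return ColumnPairSet(pairs=frozenset((int(i), int(j)) for i, j in pairs), source=source)


def sp_score(test: ColumnPairSet, ref: ColumnPairSet) -> float:
    """|test ∩ ref| / |ref| — fraction of reference pairs recovered."""
    if len(ref) == 0:
        raise ValueError("cannot evaluate against an empty reference alignment")
    return len(test.pairs & ref.pairs) / len(ref)


def f1_score(test: ColumnPairSet, ref: ColumnPairSet) -> float:
    """Harmonic mean of recall (|∩|/|ref|) and precision (|∩|/|test|)."""
    if len(ref) == 0:
        raise ValueError("cannot evaluate against an empty reference alignment")
    if len(test) == 0:
        return 0.0
    inter = len(test.pairs & ref.pairs)
    recall = inter / len(ref)
    precision = inter / len(test)
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-pair evaluation record: SP, F1, and the reference's covariates."""

    sp: float
    f1: float
    recall: float
    precision: float
    identity_pct: float
    alignment_length: int
    qry_id: str = ""
    ref_id: str = ""
    method: str = ""


def evaluate_alignment(
    test: Union[AlignmentResult, ColumnPairSet],
    ref: PairwiseReference,
    method: str = "",
) -> EvaluationResult:
    """Score one test alignment against its reference."""
    tset = test if isinstance(test, ColumnPairSet) else column_pairs(test)
    rset = column_pairs(ref, source="reference")
    inter = len(tset.pairs & rset.pairs)
    recall = inter / len(rset) if len(rset) else 0.0
    precision = inter / len(tset) if len(tset) else 0.0
    return EvaluationResult(
        sp=sp_score(tset, rset),
        f1=f1_score(tset, rset),
        recall=recall,
        precision=precision,
        identity_pct=ref.identity_pct,
        alignment_length=ref.alignment_length,
        qry_id=ref.seq_a.id,
        ref_id=ref.seq_b.id,
        method=method,
    )


@dataclass(frozen=True)
class BinnedSummary:
    """Mean SP/F1 per half-open bin, with sparse bins suppressed."""

    axis: str  # "identity" | "length"
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    mean_sp: tuple[Optional[float], ...]  # None where suppressed
    mean_f1: tuple[Optional[float], ...]
    suppressed: tuple[bool, ...]

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"{int(lo)}-{int(hi) - 1}"
            for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
        ]
        return pd.DataFrame(
            {
                "bin": labels,
                "count": self.counts,
                "mean_sp": [s if s is not None else float("nan") for s in self.mean_sp],
                "mean_f1": [s if s is not None else float("nan") for s in self.mean_f1],
                "suppressed": self.suppressed,
            }
        )


def bin_results(
    results: Sequence[EvaluationResult],
    axis: str = "identity",
    edges: Optional[Sequence[float]] = None,
) -> BinnedSummary:
    """Bin per-pair results by identity or reference alignment length.

    Bins are half-open [lo, hi); values at or beyond the final edge are
    clamped into the last bin with a warning.  Bins with fewer than
    ``SUPPRESS_BELOW`` results report no mean.
    """
    if axis == "identity":
        edges = tuple(edges) if edges is not None else IDENTITY_EDGES
        values = np.array([r.identity_pct for r in results], dtype=float)
    elif axis == "length":
        edges = tuple(edges) if edges is not None else LENGTH_EDGES
        values = np.array([r.alignment_length for r in results], dtype=float)
    else:
        raise ValueError(f"unknown binning axis {axis!r}")
    if any(b <= a for a, b in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("edges must be strictly increasing with >= 2 values")

    idx = np.searchsorted(edges, values, side="right") - 1
    if np.any(values >= edges[-1]) or np.any(values < edges[0]):
        log.warning("values outside the bin range were clamped into the edge bins")
    idx = np.clip(idx, 0, len(edges) - 2)

    counts, mean_sp, mean_f1, suppressed = [], [], [], []
    sp = np.array([r.sp for r in results], dtype=float)
    f1 = np.array([r.f1 for r in results], dtype=float)
    for b in range(len(edges) - 1):
        mask = idx == b
        c = int(mask.sum())
        counts.append(c)
        if c < SUPPRESS_BELOW:
            suppressed.append(True)
            mean_sp.append(None)
            mean_f1.append(None)
        else:
            suppressed.append(False)
            mean_sp.append(float(sp[mask].mean()))
            mean_f1.append(float(f1[mask].mean()))
    return BinnedSummary(
        axis=axis,
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(counts),
        mean_sp=tuple(mean_sp),
        mean_f1=tuple(mean_f1),
        suppressed=tuple(suppressed),
    )


def results_frame(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    """One row per evaluated pair; includes the SP==0 bookkeeping column."""
    df = pd.DataFrame(
        {
            "qry_id": [r.qry_id for r in results],
            "ref_id": [r.ref_id for r in results],
            "identity_pct": [r.identity_pct for r in results],
            "alignment_length": [r.alignment_length for r in results],
            "sp": [r.sp for r in results],
            "f1": [r.f1 for r in results],
            "method": [r.method for r in results],
        }
    )
    df["sp_is_zero"] = df["sp"] == 0.0
    return df


def plot_sp_comparison(results_x, results_y, path, label_x="method X",
                       label_y="method Y") -> None:
    """Minimal per-pair SP scatter of one method against another.

    Points above the diagonal favor method Y.  Results must be aligned
    (same pair order).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = [r.sp for r in results_x]
    y = [r.sp for r in results_y]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=10, alpha=0.6)
    ax.plot([0, 1], [0, 1], lw=0.8, color="grey")
    ax.set_xlabel(f"SP ({label_x})")
    ax.set_ylabel(f"SP ({label_y})")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sample_score_distributions(
    grouped_refs: Sequence[Sequence[PairwiseReference]],
    scorer: Callable[[PairwiseReference], np.ndarray],
    n_pairs: int = 100,
    first_k: int = 5,
    n_random_seqs: int = 5,
    n_random_res: int = 4,
    seed: int = 0,
) -> tuple[list[float], list[float]]:
    """Sample match-score distributions for aligned vs random residue pairs.

    ``grouped_refs`` holds the pairwise references of each MSA.  From each
    MSA, ``n_pairs`` aligned residue pairs are sampled from its first
    ``first_k`` pairwise alignments (the aligned-pair distribution), and
    ``n_random_res`` residues from each of ``n_random_seqs`` random rows are
    scored all-against-all (the random-pair distribution).  ``scorer`` maps
    a PairwiseReference to its full m x n score matrix.
    """
    rng = np.random.default_rng(seed)
    aligned: list[float] = []
    background: list[float] = []
    for refs in grouped_refs:
        if not refs:
            continue
        take = list(refs[:first_k])
        if len(refs) < first_k:
            log.info("MSA group has only %d pairwise alignments", len(refs))
        # aligned residue pairs, sampled across the first_k alignments
        pool: list[float] = []
        for ref in take:
            S = np.asarray(scorer(ref))
            for i, j in _reference_pairs(ref):
                pool.append(float(S[i, j]))
        if pool:
            k = min(n_pairs, len(pool))
            if len(pool) < n_pairs:
                log.info("only %d aligned pairs available (wanted %d)", len(pool), n_pairs)
            aligned.extend(rng.choice(pool, size=k, replace=False).tolist())
        # random residues from random sequence pairs of the same MSA,
        # scored all-against-all across the two rows
        rows = min(n_random_seqs, len(refs))
        chosen = rng.choice(len(refs), size=rows, replace=False)
        for r in chosen:
            ref = refs[int(r)]
            S = np.asarray(scorer(ref))
            pa = rng.choice(len(ref.seq_a), size=min(n_random_res, len(ref.seq_a)), replace=False)
            pb = rng.choice(len(ref.seq_b), size=min(n_random_res, len(ref.seq_b)), replace=False)
            for i in pa:
                for j in pb:
                    background.append(float(S[int(i), int(j)]))
    return aligned, background
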