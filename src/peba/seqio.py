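"""Sequence and alignment I/O.

Reads FASTA sequence files, gapped-FASTA and MSF multiple alignments,
extracts all pairwise reference alignments from an MSA (the benchmark
protocol: every unordered pair of rows, dual-gap columns removed), and
computes pairwise percent identity over gapless columns.

Coordinates are 0-based half-open internally; gap characters accepted on
input are ``-`` and ``.``, and only ``-`` is ever emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import AlignIO, SeqIO

log = logging.getLogger(__name__)

GAP_CHARS = "-."

#: 20 standard residues plus ambiguity/rare codes B, Z, X, J and U (Sec), O (Pyl).
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZXJUO")


class FastaParseError(ValueError):
    """Malformed FASTA / alignment input."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified, ungapped amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) & set(GAP_CHARS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains gap characters {sorted(bad)}"
            )
        unknown = set(self.residues) - AMINO_ALPHABET
        if unknown:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino characters {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """An MSA as ordered (id, gapped string) rows of equal length."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) > 1:
            raise FastaParseError(
                f"alignment rows have unequal lengths {sorted(lengths)}"
            )
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise FastaParseError("duplicate row ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


def _degap(gapped: str) -> str:
    return "".join(c for c in gapped if c not in GAP_CHARS)


@dataclass(frozen=True)
class PairwiseReference:
    """A ground-truth pairwise alignment extracted from a benchmark MSA.

    ``columns`` holds one ``(char_a, char_b)`` tuple per alignment column;
    dual-gap columns were removed at extraction, so de-gapping each row
    reproduces the stored sequences exactly.
    """

    seq_a: ProteinSequence
    seq_b: ProteinSequence
    columns: tuple[tuple[str, str], ...]
    identity_pct: float
    alignment_length: int

    def __post_init__(self) -> None:
        for k, (ca, cb) in enumerate(self.columns):
            if ca in GAP_CHARS and cb in GAP_CHARS:
                raise ValueError(f"dual-gap column at position {k}")
        if _degap("".join(c for c, _ in self.columns)) != self.seq_a.residues:
            raise ValueError("row A of columns does not de-gap to seq_a")
        if _degap("".join(c for _, c in self.columns)) != self.seq_b.residues:
            raise ValueError("row B of columns does not de-gap to seq_b")
        if self.alignment_length != len(self.columns):
            raise ValueError("alignment_length disagrees with column count")

    @property
    def gapped_a(self) -> str:
        return "".join(c for c, _ in self.columns)

    @property
    def gapped_b(self) -> str:
        return "".join(c for _, c in self.columns)


def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    """Read an (ungapped) protein FASTA file.

    Lowercase residues are uppercased and terminal ``*`` stop marks are
    stripped.  Raises :class:`FastaParseError` on empty records (with the
    offending line number) and on duplicate ids.
    """
    path = Path(path)
    # map record order -> header line number for error messages
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append(lineno)

    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines[k] if k < len(header_lines) else -1
        if not rec.id:
            raise FastaParseError(f"{path}:{lineno}: record with empty header")
        residues = str(rec.seq).upper().rstrip("*")
        if not residues:
            raise FastaParseError(
                f"{path}:{lineno}: record {rec.id!r} has an empty sequence"
            )
        if rec.id in seen:
            raise FastaParseError(f"{path}:{lineno}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        out.append(ProteinSequence(id=rec.id, residues=residues))
    if not out and header_lines:
        raise FastaParseError(f"{path}:{header_lines[0]}: no parseable records")
    return out


def read_msa(path: Union[str, Path], format: str = "gapped-fasta") -> MultipleAlignment:
    """Read a multiple alignment in gapped FASTA or MSF format.

    MSF interleaved blocks are concatenated per sequence by the parser;
    ``.`` gaps are normalized to ``-``.
    """
    if format == "gapped-fasta":
        bio_fmt = "fasta"
    elif format == "msf":
        bio_fmt = "msf"
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), bio_fmt)
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    rows = tuple(
        (rec.id, str(rec.seq).upper().replace(".", "-")) for rec in aln
    )
    return MultipleAlignment(rows=rows)


def write_msa(msa: MultipleAlignment, path: Union[str, Path]) -> None:
    """Write an alignment as gapped FASTA (round-trips with read_msa)."""
    with open(path, "w") as fh:
        for rid, gapped in msa.rows:
            fh.write(f">{rid}\n{gapped}\n")


def pairwise_identity(ref_or_columns) -> float:
    """Percent identity: 100 x identical gapless columns / gapless columns.

    Accepts a :class:`PairwiseReference` or a raw column iterable.  With zero
    gapless columns the identity is defined as 0 and a warning is emitted.
    """
    columns = (
        ref_or_columns.columns
        if isinstance(ref_or_columns, PairwiseReference)
        else tuple(ref_or_columns)
    )
    gapless = [
        (a, b) for a, b in columns if a not in GAP_CHARS and b not in GAP_CHARS
    ]
    if not gapless:
        warnings.warn("alignment has no gapless columns; identity defined as 0")
        return 0.0
    same = sum(1 for a, b in gapless if a == b)
    return 100.0 * same / len(gapless)


def make_pairwise_reference(
    id_a: str, gapped_a: str, id_b: str, gapped_b: str
) -> PairwiseReference:
    """Build a PairwiseReference from two gapped rows, dropping dual-gap columns."""
    if len(gapped_a) != len(gapped_b):
        raise FastaParseError("gapped rows have different lengths")
    columns = tuple(
        (ca if ca not in GAP_CHARS else "-", cb if cb not in GAP_CHARS else "-")
        for ca, cb in zip(gapped_a, gapped_b)
        if not (ca in GAP_CHARS and cb in GAP_CHARS)
    )
    seq_a = ProteinSequence(id=id_a, residues=_degap(gapped_a))
    seq_b = ProteinSequence(id=id_b, residues=_degap(gapped_b))
    return PairwiseReference(
        seq_a=seq_a,
        seq_b=seq_b,
        columns=columns,
        identity_pct=pairwise_identity(columns),
        alignment_length=len(columns),
    )


def extract_pairwise(msa: MultipleAlignment) -> list[PairwiseReference]:
    """Extract every unordered pair of rows as a PairwiseReference.

    Returns k(k-1)/2 references for a k-row MSA, in row order; an MSA with
    fewer than two rows yields an empty list.
    """
    refs: list[PairwiseReference] = []
    for p in range(len(msa.rows)):
        for q in range(p + 1, len(msa.rows)):
            (ida, ga), (idb, gb) = msa.rows[p], msa.rows[q]
            refs.append(make_pairwise_reference(ida, ga, idb, gb))
    return refs


def write_pairwise_alignment(aln, path: Union[str, Path], format: str = "gapped-fasta") -> None:
    """Serialize an AlignmentResult or PairwiseReference.

    ``gapped-fasta`` writes the two gapped rows; ``tsv-pairs`` writes one
    line per aligned residue pair with 0-based indices and the residues.
    """
    # late import keeps seqio free of a hard dependency on align
    from .align import AlignmentResult

    if isinstance(aln, PairwiseReference):
        ida, idb = aln.seq_a.id, aln.seq_b.id
        ga, gb = aln.gapped_a, aln.gapped_b
        pairs = _reference_pairs(aln)
        res_a, res_b = aln.seq_a.residues, aln.seq_b.residues
    elif isinstance(aln, AlignmentResult):
        ida, idb = aln.qry_id or "query", aln.ref_id or "reference"
        ga, gb = aln.gapped_a, aln.gapped_b
        pairs = aln.pairs
        res_a, res_b = aln.qry_residues, aln.ref_residues
    else:
        raise TypeError(f"cannot serialize {type(aln).__name__}")

    if format == "gapped-fasta":
        if ga is None or not ga:
            raise ValueError("empty alignment cannot be written as gapped FASTA")
        with open(path, "w") as fh:
            fh.write(f">{ida}\n{ga}\n>{idb}\n{gb}\n")
    elif format == "tsv-pairs":
        with open(path, "w") as fh:
            fh.write("qry_idx\tref_idx\tqry_res\tref_res\n")
            for i, j in pairs:
                ra = res_a[i] if res_a else "?"
                rb = res_b[j] if res_b else "?"
                fh.write(f"{i}\t{j}\t{ra}\t{rb}\n")
    else:
        raise ValueError(f"unknown output format {format!r}")


def _reference_pairs(ref: PairwiseReference) -> list[tuple[int, int]]:
    """(i, j) residue index pairs for the gapless columns of a reference."""
    pairs = []
    i = j = 0
    for ca, cb in ref.columns:
        if ca != "-" and cb != "-":
            pairs.append((i, j))
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    return pairs
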