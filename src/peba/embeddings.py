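"""Per-residue embeddings: containers, storage, adapters, synthetic pairs.

A protein language model maps a sequence of L residues to an L x d matrix
of contextual feature vectors (one row per residue, special tokens
stripped).  This module stores and loads such matrices, defines the adapter
contract real models plug into, and generates synthetic embedding pairs
with a *planted* alignment: selected residue pairs share a latent unit
vector (high expected cosine), everything else is an independent random
direction (expected cosine near 0 for large d).  The synthetic path makes
the whole alignment stack testable without any model download.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence, Union, runtime_checkable

import h5py
import numpy as np

from .seqio import PairwiseReference, ProteinSequence, make_pairwise_reference

log = logging.getLogger(__name__)

#: embedding width of the ProtT5-XL-U50 encoder's last hidden layer
PROTT5_DIM = 1024
#: embedding width of the ESM2-T36-3B-UR50D final layer
ESM2_3B_DIM = 2560


class EmbeddingDimensionError(ValueError):
    """Row count of an embedding matrix disagrees with the sequence length."""


@dataclass(frozen=True)
class ResidueEmbeddings:
    """An L x d matrix of per-residue feature vectors for one sequence."""

    seq_id: str
    matrix: np.ndarray
    model_tag: str = "unknown"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim == 1:  # a stored vector-of-vectors may collapse; reject scalars
            m = m.reshape(1, -1)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
            raise ValueError(f"embedding matrix must be 2-D L x d, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError(f"embeddings for {self.seq_id!r} contain non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def check_length(self, expected: int) -> "ResidueEmbeddings":
        if self.length != expected:
            raise EmbeddingDimensionError(
                f"{self.seq_id!r}: embedding has {self.length} rows "
                f"but the sequence has {expected} residues"
            )
        return self


@runtime_checkable
class EmbedderAdapter(Protocol):
    """Contract for anything that turns a residue string into embeddings.

    Implementations must strip padding and special tokens so the output row
    count equals the residue count.
    """

    name: str
    dim: int

    def embed(self, residues: str, seq_id: str = "seq") -> ResidueEmbeddings: ...


def embed_with_adapter(seq: ProteinSequence, adapter: EmbedderAdapter) -> ResidueEmbeddings:
    """Run an adapter and enforce the row-count contract."""
    emb = adapter.embed(seq.residues, seq_id=seq.id)
    if emb.length != len(seq.residues):
        raise EmbeddingDimensionError(
            f"adapter {adapter.name!r} returned {emb.length} rows for the "
            f"{len(seq.residues)}-residue sequence {seq.id!r}; special tokens "
            "were probably not stripped"
        )
    return emb


@dataclass
class MockAdapter:
    """Deterministic stand-in embedder for tests and examples.

    Each row is drawn from a normal distribution seeded by a hash of the
    sequence, so the same sequence always embeds identically, with no model
    download.  The vectors carry no biological signal.
    """

    name: str = "mock"
    dim: int = 32

    def embed(self, residues: str, seq_id: str = "seq") -> ResidueEmbeddings:
        digest = hashlib.blake2b(residues.encode(), digest_size=4).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        matrix = rng.standard_normal((len(residues), self.dim))
        return ResidueEmbeddings(seq_id=seq_id, matrix=matrix, model_tag=self.name)


@dataclass
class ProtT5Adapter:
    """ProtT5-XL-U50 encoder adapter (optional extra; needs torch + transformers).

    Embeds by tokenizing each residue and taking the last hidden layer of the
    encoder, then dropping the trailing special token so rows match residues.
    """

    name: str = "prott5-xl-u50"
    dim: int = PROTT5_DIM
    device: str = "cpu"

    def embed(self, residues: str, seq_id: str = "seq") -> ResidueEmbeddings:
        try:
            import torch  # noqa: F401
            from transformers import T5EncoderModel, T5Tokenizer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "ProtT5 embedding needs the optional 'models' extra "
                "(pip install peba[models]); alternatively precompute embeddings "
                "and pass them as files"
            ) from exc
        return _prott5_embed(self, residues, seq_id)  # pragma: no cover


@dataclass
class ESM2Adapter:
    """ESM2-T36-3B-UR50D adapter (optional extra; needs fair-esm).

    ``layer`` selects the representation layer, defaulting to the final one.
    """

    name: str = "esm2-t36-3b"
    dim: int = ESM2_3B_DIM
    layer: int = 36
    device: str = "cpu"

    def embed(self, residues: str, seq_id: str = "seq") -> ResidueEmbeddings:
        try:
            import esm  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "ESM-2 embedding needs the optional 'models' extra "
                "(pip install peba[models]); alternatively precompute embeddings "
                "and pass them as files"
            ) from exc
        return _esm2_embed(self, residues, seq_id)  # pragma: no cover


def _prott5_embed(adapter, residues, seq_id):  # pragma: no cover - needs model weights
    import re

    import torch
    from transformers import T5EncoderModel, T5Tokenizer

    tok = T5Tokenizer.from_pretrained("Rostlab/prot_t5_xl_half_uniref50-enc")
    model = T5EncoderModel.from_pretrained("Rostlab/prot_t5_xl_half_uniref50-enc")
    model = model.to(adapter.device).eval()
    spaced = " ".join(re.sub(r"[UZOB]", "X", residues))
    ids = tok([spaced], add_special_tokens=True, return_tensors="pt").to(adapter.device)
    with torch.no_grad():
        out = model(**ids).last_hidden_state[0]
    matrix = out[: len(residues)].float().cpu().numpy()  # drop trailing </s>
    return ResidueEmbeddings(seq_id=seq_id, matrix=matrix, model_tag=adapter.name)


def _esm2_embed(adapter, residues, seq_id):  # pragma: no cover - needs model weights
    import esm
    import torch

    model, alphabet = esm.pretrained.esm2_t36_3B_UR50D()
    model = model.to(adapter.device).eval()
    batch = alphabet.get_batch_converter()([(seq_id, residues)])
    with torch.no_grad():
        out = model(batch[2].to(adapter.device), repr_layers=[adapter.layer])
    rep = out["representations"][adapter.layer][0]
    matrix = rep[1 : len(residues) + 1].float().cpu().numpy()  # strip BOS/EOS
    return ResidueEmbeddings(seq_id=seq_id, matrix=matrix, model_tag=adapter.name)


ADAPTERS: dict[str, Callable[[], EmbedderAdapter]] = {
    "mock": MockAdapter,
    "prott5": ProtT5Adapter,
    "prott5-xl-u50": ProtT5Adapter,
    "esm2": ESM2Adapter,
    "esm2-t36-3b": ESM2Adapter,
}


def get_adapter(model_tag: str) -> EmbedderAdapter:
    try:
        return ADAPTERS[model_tag.lower()]()
    except KeyError:
        raise ValueError(
            f"unknown model tag {model_tag!r}; known: {sorted(ADAPTERS)}"
        ) from None


# ---------------------------------------------------------------------------
# storage: HDF5 container (one dataset per seq_id) or whitespace text matrix


def save_embeddings(emb: ResidueEmbeddings, path: Union[str, Path]) -> None:
    """Write embeddings to an HDF5 container (.h5/.hdf5) or a text matrix.

    The HDF5 container keys datasets by ``seq_id`` and stores ``model_tag``
    as a dataset attribute; the text format holds the bare matrix.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "a") as fh:
            if emb.seq_id in fh:
                del fh[emb.seq_id]
            ds = fh.create_dataset(emb.seq_id, data=emb.matrix)
            ds.attrs["model_tag"] = emb.model_tag
    else:
        np.savetxt(path, emb.matrix)


def load_embeddings(
    path: Union[str, Path],
    seq_id: Optional[str] = None,
    expected_length: Optional[int] = None,
) -> ResidueEmbeddings:
    """Load an embedding matrix from HDF5 or a whitespace text matrix.

    For HDF5, ``seq_id`` selects the dataset; if omitted and the file holds a
    single dataset, that one is used.  ``expected_length`` enforces the
    row-count contract against a known sequence length.
    """
    path = Path(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as fh:
            keys = list(fh.keys())
            if seq_id is None:
                if len(keys) != 1:
                    raise ValueError(
                        f"{path} holds {len(keys)} datasets; pass seq_id to pick one"
                    )
                seq_id = keys[0]
            if seq_id not in fh:
                raise KeyError(f"{path} has no dataset {seq_id!r} (has {keys})")
            ds = fh[seq_id]
            matrix = np.asarray(ds)
            tag = str(ds.attrs.get("model_tag", "unknown"))
    else:
        try:
            matrix = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: not a numeric matrix ({exc})") from exc
        tag = "unknown"
        if seq_id is None:
            seq_id = path.stem
    emb = ResidueEmbeddings(seq_id=seq_id, matrix=matrix, model_tag=tag)
    if expected_length is not None:
        emb.check_length(expected_length)
    return emb


# ---------------------------------------------------------------------------
# synthetic pairs with a planted alignment


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Parameters of a synthetic homologous embedding pair.

    ``planted_pairs`` are the ground-truth aligned residue index pairs,
    strictly increasing in both coordinates.  Planted rows share a latent
    unit vector perturbed by isotropic noise of scale ``noise_sigma``
    (expected planted cosine roughly 1/(1+noise_sigma^2)); all other rows
    are independent uniform random directions.
    """

    planted_pairs: tuple[tuple[int, int], ...]
    len_a: int
    len_b: int
    dim: int = 256
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_pairs", tuple(map(tuple, self.planted_pairs)))
        if self.len_a < 1 or self.len_b < 1 or self.dim < 1:
            raise ValueError("len_a, len_b and dim must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        prev_i, prev_j = -1, -1
        for i, j in self.planted_pairs:
            if not (prev_i < i < self.len_a and prev_j < j < self.len_b):
                raise ValueError(
                    "planted_pairs must be strictly increasing in both "
                    f"coordinates and in range; offending pair ({i},{j})"
                )
            prev_i, prev_j = i, j


def _unit(rows: np.ndarray) -> np.ndarray:
    return rows / np.linalg.norm(rows, axis=-1, keepdims=True)


def random_pair_spec(
    n_pairs: int = 100,
    dim: int = 256,
    noise_sigma: float = 0.2,
    n_indel_runs: int = 3,
    mean_indel_len: float = 3.0,
    seed: int = 0,
) -> SyntheticPairSpec:
    """Draw a realistic planted-alignment spec from an indel-run process.

    Starts from ``n_pairs`` matched columns and inserts ``n_indel_runs``
    unaligned runs (geometric lengths, mean ``mean_indel_len``) into each
    sequence at random positions — emulating loop indels between conserved
    blocks rather than uniformly scattered single gaps.
    """
    rng = np.random.default_rng(seed)
    ins_a = _indel_runs(rng, n_pairs, n_indel_runs, mean_indel_len)
    ins_b = _indel_runs(rng, n_pairs, n_indel_runs, mean_indel_len)
    pairs, ia, ib = [], 0, 0
    for k in range(n_pairs):
        ia += ins_a.get(k, 0)
        ib += ins_b.get(k, 0)
        pairs.append((ia, ib))
        ia += 1
        ib += 1
    len_a = ia + ins_a.get(n_pairs, 0)
    len_b = ib + ins_b.get(n_pairs, 0)
    return SyntheticPairSpec(
        planted_pairs=tuple(pairs),
        len_a=len_a,
        len_b=len_b,
        dim=dim,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _indel_runs(rng, n_pairs, n_runs, mean_len) -> dict[int, int]:
    """Map from pre-pair slot (0..n_pairs) to inserted run length."""
    runs: dict[int, int] = {}
    slots = rng.choice(n_pairs + 1, size=min(n_runs, n_pairs + 1), replace=False)
    for s in slots:
        runs[int(s)] = int(rng.geometric(1.0 / mean_len))
    return runs


def generate_synthetic_pair(
    spec: SyntheticPairSpec,
) -> tuple[ResidueEmbeddings, ResidueEmbeddings, PairwiseReference]:
    """Build two embedding matrices with the planted alignment of ``spec``.

    For each planted pair (i, j) a shared latent unit vector z is drawn and
    the two rows are normalize(z + eps) with eps components i.i.d.
    N(0, noise_sigma/sqrt(dim)); unplanted rows are independent random unit
    vectors.  Also returns the planted alignment as a PairwiseReference over
    synthetic residue labels drawn uniformly from the 20-letter alphabet —
    deliberately uncorrelated with the planted structure, emulating
    twilight-zone homologs whose letters alone carry no alignment signal.
    """
    rng = np.random.default_rng(spec.seed)
    a = _unit(rng.standard_normal((spec.len_a, spec.dim)))
    b = _unit(rng.standard_normal((spec.len_b, spec.dim)))
    sigma = spec.noise_sigma / np.sqrt(spec.dim)
    for i, j in spec.planted_pairs:
        z = _unit(rng.standard_normal(spec.dim))
        a[i] = _unit(z + sigma * rng.standard_normal(spec.dim))
        b[j] = _unit(z + sigma * rng.standard_normal(spec.dim))

    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    res_a = rng.choice(alphabet, size=spec.len_a)
    res_b = rng.choice(alphabet, size=spec.len_b)
    gapped_a, gapped_b = _planted_gapped_rows(spec, res_a, res_b)

    emb_a = ResidueEmbeddings(seq_id="synthA", matrix=a, model_tag="synthetic")
    emb_b = ResidueEmbeddings(seq_id="synthB", matrix=b, model_tag="synthetic")
    ref = make_pairwise_reference("synthA", gapped_a, "synthB", gapped_b)
    return emb_a, emb_b, ref


def _planted_gapped_rows(spec, res_a, res_b) -> tuple[str, str]:
    """Render the planted pair list as two gapped strings (gaps clustered)."""
    ga, gb = [], []
    ia = ib = 0
    for i, j in spec.planted_pairs:
        for k in range(ib, j):  # unaligned b residues first, then a's
            ga.append("-")
            gb.append(res_b[k])
        for k in range(ia, i):
            ga.append(res_a[k])
            gb.append("-")
        ga.append(res_a[i])
        gb.append(res_b[j])
        ia, ib = i + 1, j + 1
    for k in range(ib, spec.len_b):
        ga.append("-")
        gb.append(res_b[k])
    for k in range(ia, spec.len_a):
        ga.append(res_a[k])
        gb.append("-")
    return "".join(ga), "".join(gb)
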