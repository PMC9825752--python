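"""k-mer embedding encoding of nucleotide sequences.

A transcript is tokenized into overlapping k-mers (sliding window, step 1)
and each k-mer is mapped to a ``dim``-dimensional real vector, turning the
sequence into an ``(L - k + 1) x dim`` matrix the classifiers consume.
Vectors normally come from a pretrained dna2vec-style table supplied in the
plain word2vec text format; when no table is given, a seeded standard-normal
table scaled by ``1/sqrt(dim)`` keeps the pipeline self-contained (a real
pretrained table is a drop-in replacement).

Tokens containing an ambiguous base (N) map to the table's ``unk_vector``
(all zeros by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .io import LabeledSequence

DEFAULT_K = 3
DEFAULT_DIM = 100

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def tokenize_kmers(seq: str, k: int = DEFAULT_K, step: int = 1) -> list[str]:
    """Sliding-window k-mers of ``seq``: ``seq[i:i+k]`` for each valid i.

    A sequence shorter than ``k`` yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, step)]


def all_kmers(k: int = DEFAULT_K) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass
class KmerEmbeddingTable:
    """Map from canonical k-mers to embedding vectors.

    ``vectors`` need not cover all 4**k k-mers; missing tokens (and any
    token containing N) fall back to ``unk_vector``.
    """

    k: int
    dim: int
    vectors: dict[str, np.ndarray]
    unk_vector: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unk_vector is None:
            self.unk_vector = np.zeros(self.dim, dtype=np.float32)
        self.unk_vector = np.asarray(self.unk_vector, dtype=np.float32)
        if self.unk_vector.shape != (self.dim,):
            raise ValueError("unk_vector dimension mismatch")
        for token, vec in self.vectors.items():
            if len(token) != self.k or any(c not in _BASE_INDEX for c in token):
                raise ValueError(f"invalid k-mer token {token!r}")
            v = np.asarray(vec, dtype=np.float32)
            if v.shape != (self.dim,):
                raise ValueError(
                    f"vector for {token!r} has dimension {v.shape}, expected {self.dim}"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite vector for {token!r}")
            self.vectors[token] = v

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self.unk_vector)

    def matrix(self) -> np.ndarray:
        """Dense ``(4**k + 1) x dim`` matrix in lexicographic k-mer order.

        The final row is the unknown-token vector; row indices match
        :func:`token_ids`.
        """
        M = np.empty((4**self.k + 1, self.dim), dtype=np.float32)
        for i, kmer in enumerate(all_kmers(self.k)):
            M[i] = self.lookup(kmer)
        M[-1] = self.unk_vector
        return M

    @classmethod
    def random(
        cls, k: int = DEFAULT_K, dim: int = DEFAULT_DIM, seed: int = 0
    ) -> "KmerEmbeddingTable":
        """Seeded standard-normal table scaled by 1/sqrt(dim)."""
        rng = np.random.default_rng(seed)
        kmers = all_kmers(k)
        vecs = rng.standard_normal((len(kmers), dim)) / np.sqrt(dim)
        return cls(k, dim, dict(zip(kmers, vecs.astype(np.float32))))


def load_embedding_table(path, k: int = DEFAULT_K) -> KmerEmbeddingTable:
    """Parse a plain word-vector text file (word2vec format).

    Each line holds a token followed by whitespace-separated floats; an
    optional first line ``count dim`` is accepted.  Inconsistent vector
    dimensions or malformed tokens are hard errors.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty embedding file {path}")
    start = 0
    head = lines[0].split()
    if len(head) == 2 and all(p.lstrip("-").isdigit() for p in head):
        dim = int(head[1])
        start = 1
    for ln in lines[start:]:
        parts = ln.split()
        token, vals = parts[0].upper().replace("U", "T"), parts[1:]
        if dim is None:
            dim = len(vals)
        if len(vals) != dim:
            raise ValueError(
                f"inconsistent dimension for token {token!r}: "
                f"got {len(vals)}, expected {dim}"
            )
        if len(token) != k or any(c not in _BASE_INDEX for c in token):
            raise ValueError(f"token {token!r} is not a {k}-mer over ACGT")
        if token in vectors:
            raise ValueError(f"duplicate token {token!r}")
        vectors[token] = np.array([float(v) for v in vals], dtype=np.float32)
    assert dim is not None
    return KmerEmbeddingTable(k, dim, vectors)


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence as a matrix of k-mer embedding rows."""

    id: str
    matrix: np.ndarray

    @property
    def n_tokens(self) -> int:
        return self.matrix.shape[0]


def encode_sequence(
    seq: LabeledSequence | str, table: KmerEmbeddingTable, seq_id: str = ""
) -> EncodedSequence:
    """Encode a sequence as an ``(L - k + 1) x dim`` embedding matrix.

    Row i is the table vector of token i (``unk_vector`` for tokens that
    contain N or are absent from the table).  Encoding is a pure lookup:
    it depends only on the sequence and the table.
    """
    if isinstance(seq, LabeledSequence):
        seq_id, s = seq.id, seq.seq
    else:
        s = seq
    tokens = tokenize_kmers(s, table.k)
    if not tokens:
        return EncodedSequence(seq_id, np.zeros((0, table.dim), dtype=np.float32))
    mat = np.stack([table.lookup(t) for t in tokens])
    return EncodedSequence(seq_id, mat)


def token_ids(seq: str, k: int = DEFAULT_K) -> np.ndarray:
    """Integer ids of sliding-window k-mers.

    Canonical k-mers get their base-4 rank (A=0 ... T=3, most significant
    first); any token containing an ambiguous base gets id ``4**k`` (the
    unknown row of :meth:`KmerEmbeddingTable.matrix`).  This is the compact
    representation the training stack uses internally; gathering rows of the
    table matrix by these ids reproduces :func:`encode_sequence` exactly.
    """
    n = len(seq) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    unk = 4**k
    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        ids = ids * 4 + np.where(window < 0, 0, window)
        bad |= window < 0
    ids[bad] = unk
    return ids.astype(np.int16)
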