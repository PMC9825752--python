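"""Hand-crafted transcript features, ORF extraction and set-overlap testing.

The feature set is a compact, fully specified subset of the composition /
ORF descriptors commonly used by coding-potential tools: longest-ORF length
and coverage, ORF count, GC content, mono- and di-nucleotide frequencies and
per-frame stop-codon density.  Deliberately excluded are descriptors that
need external models or tables (translated-peptide stability, codon-usage
bias, hexamer scores); candidate lists from such tools enter only as id
lists for overlap testing.

ORF conventions: forward strand only (transcripts are already stranded),
three frames, 0-based half-open coordinates, an ORF runs from the 5'-most
ATG to the first in-frame stop inclusive, and codons containing N match
neither ATG nor a stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import LabeledSequence

START = "ATG"
STOPS = ("TAA", "TAG", "TGA")

_BASES = "ACGT"
_DINUCS = tuple(a + b for a in _BASES for b in _BASES)


@dataclass(frozen=True)
class OpenReadingFrame:
    """A maximal ATG-to-stop open reading frame on the forward strand.

    ``start`` indexes the A of the ATG; ``end`` is exclusive, one past the
    last base of the stop codon, so ``length == end - start`` is a multiple
    of three and includes the stop.
    """

    start: int
    end: int
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def extract(self, seq: str) -> str:
        return seq[self.start : self.end]


def find_orfs(seq: str) -> list[OpenReadingFrame]:
    """Return all maximal ORFs in the three forward frames.

    Within a frame, the 5'-most ATG after the previous stop opens the ORF;
    internal in-frame ATGs are suppressed (conventional longest-ORF rule).
    ORFs lacking a stop codon before the sequence end are not reported.
    """
    seq = seq.upper()
    n = len(seq)
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START:
                    start = pos
            elif codon in STOPS:
                orfs.append(OpenReadingFrame(start, pos + 3, frame))
                start = None
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def longest_orf(seq: str) -> OpenReadingFrame | None:
    """The longest maximal ORF, or None if the sequence contains none.

    Ties break on the 5'-most start, then lowest frame, for determinism.
    """
    orfs = find_orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.length, -o.start, -o.frame))


def longest_orf_length(seq: str) -> int:
    orf = longest_orf(seq)
    return orf.length if orf is not None else 0


@dataclass(frozen=True)
class FeatureVector:
    """Hand-crafted descriptors for one transcript."""

    id: str
    longest_orf_length: int
    orf_coverage: float
    orf_count: int
    gc_content: float
    mono_freqs: tuple[float, float, float, float]
    di_freqs: tuple[float, ...] = field(repr=False)
    stop_density: float = 0.0

    def to_dict(self) -> dict[str, float]:
        d: dict[str, float] = {
            "id": self.id,
            "longest_orf_length": self.longest_orf_length,
            "orf_coverage": self.orf_coverage,
            "orf_count": self.orf_count,
            "gc_content": self.gc_content,
            "stop_density": self.stop_density,
        }
        for b, f in zip(_BASES, self.mono_freqs):
            d[f"freq_{b}"] = f
        for dn, f in zip(_DINUCS, self.di_freqs):
            d[f"freq_{dn}"] = f
        return d


#: ORFs shorter than this are not counted in orf_count (25 codons incl. stop)
MIN_COUNTED_ORF = 75


def compute_feature_vector(seq: LabeledSequence | str, seq_id: str = "") -> FeatureVector:
    """Compute the descriptor set for a transcript.

    Lengths refer to the full (normalized, untruncated) sequence.  Frequency
    blocks are computed over unambiguous positions only and each sums to 1;
    a sequence with no unambiguous (di)nucleotide yields a uniform block.
    """
    if isinstance(seq, LabeledSequence):
        seq_id = seq.id
        s = seq.seq
    else:
        s = seq.upper()
    n = len(s)
    if n < 3:
        raise ValueError("sequence shorter than 3 nt")

    orfs = find_orfs(s)
    longest = max((o.length for o in orfs), default=0)
    counted = sum(1 for o in orfs if o.length >= MIN_COUNTED_ORF)

    mono = np.array([s.count(b) for b in _BASES], dtype=float)
    mono_total = mono.sum()
    if mono_total > 0:
        gc = (mono[1] + mono[2]) / mono_total
        mono_f = mono / mono_total
    else:
        gc = 0.0
        mono_f = np.full(4, 0.25)

    di = np.zeros(16)
    for i in range(n - 1):
        pair = s[i : i + 2]
        try:
            di[_DINUCS.index(pair)] += 1
        except ValueError:
            continue
    di_total = di.sum()
    di_f = di / di_total if di_total > 0 else np.full(16, 1 / 16)

    # stop codons per 100 nt, averaged over the three frames
    densities = []
    for frame in range(3):
        span = ((n - frame) // 3) * 3
        if span == 0:
            densities.append(0.0)
            continue
        stops = sum(
            1 for pos in range(frame, frame + span, 3) if s[pos : pos + 3] in STOPS
        )
        densities.append(stops / span * 100.0)

    return FeatureVector(
        id=seq_id,
        longest_orf_length=longest,
        orf_coverage=longest / n,
        orf_count=counted,
        gc_content=float(gc),
        mono_freqs=tuple(mono_f),
        di_freqs=tuple(di_f),
        stop_density=float(np.mean(densities)),
    )


def feature_table(seqs: Iterable[LabeledSequence]) -> pd.DataFrame:
    """Feature vectors for a dataset as a DataFrame indexed by id."""
    rows = [compute_feature_vector(s).to_dict() for s in seqs]
    return pd.DataFrame(rows).set_index("id")


def orf_table(seqs: Iterable[LabeledSequence]) -> pd.DataFrame:
    """All maximal ORFs as a BED-like table (id, start, end, frame, length)."""
    rows = [
        (s.id, o.start, o.end, o.frame, o.length)
        for s in seqs
        for o in find_orfs(s.seq)
    ]
    return pd.DataFrame(rows, columns=["id", "start", "end", "frame", "length"])


@dataclass(frozen=True)
class OverlapTest:
    """Result of an upper-tail hypergeometric set-overlap test."""

    population_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


def hypergeometric_overlap(
    population_size: int, set_a_size: int, set_b_size: int, overlap: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeom(population, set_a, set_b).

    One-tailed upper test for over-representation of shared members between
    two candidate sets drawn from a common background (e.g. all annotated
    lncRNAs).  ``overlap == 0`` gives p = 1 exactly.
    """
    if not (0 <= set_a_size <= population_size and 0 <= set_b_size <= population_size):
        raise ValueError("set sizes must lie within the population")
    if not (0 <= overlap <= min(set_a_size, set_b_size)):
        raise ValueError("overlap must not exceed the smaller set")
    if overlap == 0:
        return 1.0
    p = float(
        _stats.hypergeom.sf(overlap - 1, population_size, set_a_size, set_b_size)
    )
    return min(max(p, 0.0), 1.0)


def overlap_test(
    population_size: int, set_a: Iterable[str], set_b: Iterable[str]
) -> OverlapTest:
    """Hypergeometric overlap test between two explicit id lists."""
    a, b = set(set_a), set(set_b)
    k = len(a & b)
    p = hypergeometric_overlap(population_size, len(a), len(b), k)
    return OverlapTest(population_size, len(a), len(b), k, p)


def embed_2d(
    features: pd.DataFrame | np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Standardize a feature matrix and embed it in 2-D with t-SNE.

    Class labels play no part in the embedding; they are only used downstream
    to color the resulting scatter.  Constant feature columns are dropped
    with a warning (they carry no information and break standardization).
    """
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("need a 2-D matrix with at least 5 rows")
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            f"dropping {int((sd == 0).sum())} constant feature column(s)",
            stacklevel=2,
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
        if X.shape[1] == 0:
            raise ValueError("all feature columns are constant")
    X = (X - X.mean(axis=0)) / sd
    perplexity = min(perplexity, (X.shape[0] - 1) / 3)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    )
    return tsne.fit_transform(X)
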