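"""Synthetic coding-like / non-coding-like transcript generator.

The generator emulates the minimal sequence property separating mRNAs from
lncRNAs that the classifiers are meant to pick up: coding-like transcripts
carry exactly one long in-frame ORF (ATG ... stop, no internal in-frame
stop) embedded in random UTR sequence, while non-coding-like transcripts are
i.i.d. nucleotide strings whose longest ORF is capped well below the coding
ORF range.  The gap between ``orf_length_range.min`` and
``max_noncoding_orf`` makes the two classes separable by construction, so
every downstream stage (training, cartography, flip experiments) can be
validated against a known truth table without any external download.

Deliberate misannotations are injected by swapping the *assigned* label of a
seeded random subset of transcripts; the truth table records both labels for
every transcript.

No attempt is made to mimic codon usage, splice structure, Kozak context or
hexamer statistics of real transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .features import STOPS, longest_orf
from .io import CODING, NONCODING, LabeledSequence, write_labeled_fasta

#: rejection sampling gives up after this many attempts per sequence
MAX_ATTEMPTS = 10_000

#: the 61 sense codons (everything but TAA/TAG/TGA)
NON_STOP_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOPS
)

_BIOTYPE = {CODING: "protein_coding", NONCODING: "lncRNA"}


def biotype_for(label: str) -> str:
    """Annotation biotype consistent with an assigned label."""
    return _BIOTYPE[label]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Defaults give 1,200 coding-like and 800 non-coding-like transcripts
    (mirroring the roughly 2:1 coding majority of curated human sets),
    dataset lengths spanning 400-1,500 nt, coding ORFs of 300-900 nt against
    a 150-nt cap for non-coding ORFs, and uniform 50% GC.  All lengths
    respect the 200-nt lncRNA definition; coding transcripts must be able to
    contain the largest ORF, so their length range starts at
    ``orf_length_range[1]``.
    """

    n_coding: int = 1200
    n_noncoding: int = 800
    length_range_coding: tuple[int, int] = (900, 1500)
    length_range_noncoding: tuple[int, int] = (400, 1500)
    orf_length_range: tuple[int, int] = (300, 900)
    max_noncoding_orf: int = 150
    gc_content: float = 0.5
    misannotation_fraction: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("class sizes must be non-negative")
        for lo, hi in (self.length_range_coding, self.length_range_noncoding):
            if not (200 <= lo <= hi):
                raise ValueError("transcript lengths must satisfy 200 <= min <= max")
        lo, hi = self.orf_length_range
        if lo % 3 or hi % 3:
            raise ValueError("orf_length_range bounds must be multiples of 3")
        if not (6 <= lo <= hi):
            raise ValueError("orf_length_range must satisfy 6 <= min <= max")
        if lo < self.max_noncoding_orf + 3:
            raise ValueError(
                "orf_length_range.min must exceed max_noncoding_orf by >= 3 "
                "(class separability)"
            )
        if self.length_range_coding[0] < hi:
            raise ValueError(
                "coding transcripts must be at least orf_length_range.max long"
            )
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        if not (0.0 <= self.misannotation_fraction < 1.0):
            raise ValueError("misannotation_fraction must lie in [0, 1)")


@dataclass
class TruthTable:
    """Assigned vs. true label for every generated transcript."""

    records: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, transcript_id: str, assigned: str, true: str) -> None:
        self.records[transcript_id] = (assigned, true)

    @property
    def misannotated_ids(self) -> list[str]:
        return [t for t, (a, y) in self.records.items() if a != y]

    def true_label(self, transcript_id: str) -> str:
        return self.records[transcript_id][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, a, y, a != y) for t, (a, y) in self.records.items()
        ]
        return pd.DataFrame(
            rows, columns=["transcript_id", "assigned_label", "true_label", "misannotated"]
        ).set_index("transcript_id")


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """An ORF of exactly ``length`` nt: ATG, sense codons, one stop."""
    n_internal = length // 3 - 2
    codons = rng.choice(len(NON_STOP_CODONS), size=n_internal)
    stop = STOPS[rng.integers(len(STOPS))]
    return "ATG" + "".join(NON_STOP_CODONS[c] for c in codons) + stop


def _orf_lengths(cfg: SynthConfig) -> np.ndarray:
    lo, hi = cfg.orf_length_range
    return np.arange(lo, hi + 1, 3)


def generate_coding_transcript(
    cfg: SynthConfig, rng: np.random.Generator, transcript_id: str = "synth_c"
) -> LabeledSequence:
    """One coding-like transcript: a single long ORF flanked by random UTRs.

    The embedded ORF's length is drawn uniformly from the multiples of 3 in
    ``orf_length_range``; its codons are drawn uniformly from the 61 sense
    codons, so no internal in-frame stop can occur.  The candidate is
    rejected and re-drawn whenever the random flanks create an ORF rivalling
    the embedded one, so the longest ORF of the returned sequence equals the
    drawn length exactly.
    """
    lengths = _orf_lengths(cfg)
    lo, hi = cfg.length_range_coding
    for _ in range(MAX_ATTEMPTS):
        orf_len = int(lengths[rng.integers(len(lengths))])
        total = int(rng.integers(lo, hi + 1))
        utr5 = int(rng.integers(0, total - orf_len + 1))
        utr3 = total - orf_len - utr5
        seq = (
            _random_nt(rng, utr5, cfg.gc_content)
            + _random_orf(rng, orf_len)
            + _random_nt(rng, utr3, cfg.gc_content)
        )
        best = longest_orf(seq)
        # accept only if the embedded ORF is the unique longest one
        if best is not None and best.length == orf_len and best.start == utr5:
            return LabeledSequence(transcript_id, seq, CODING, biotype_for(CODING))
    raise RuntimeError(
        f"could not generate a coding transcript in {MAX_ATTEMPTS} attempts; "
        "configuration is likely infeasible"
    )


def generate_noncoding_transcript(
    cfg: SynthConfig,
    rng: np.random.Generator,
    transcript_id: str = "synth_n",
    stats: dict | None = None,
) -> LabeledSequence:
    """One non-coding-like transcript: i.i.d. sequence with only short ORFs.

    Candidates are resampled until the longest forward-frame ORF is at most
    ``max_noncoding_orf`` nucleotides.  When a ``stats`` dict is supplied its
    ``"attempts"`` entry is incremented per candidate drawn (used to verify
    the rejection rate against an independent estimate).
    """
    lo, hi = cfg.length_range_noncoding
    for _ in range(MAX_ATTEMPTS):
        if stats is not None:
            stats["attempts"] = stats.get("attempts", 0) + 1
        total = int(rng.integers(lo, hi + 1))
        seq = _random_nt(rng, total, cfg.gc_content)
        orf = longest_orf(seq)
        if orf is None or orf.length <= cfg.max_noncoding_orf:
            return LabeledSequence(
                transcript_id, seq, NONCODING, biotype_for(NONCODING)
            )
    raise RuntimeError(
        f"could not generate a non-coding transcript in {MAX_ATTEMPTS} attempts; "
        "configuration is likely infeasible"
    )


def misannotation_count(fraction: float, n: int) -> int:
    """Number of labels to corrupt: round-half-away-from-zero of fraction*n."""
    return int(np.floor(fraction * n + 0.5))


def generate_dataset(cfg: SynthConfig) -> tuple[list[LabeledSequence], TruthTable]:
    """Generate the full dataset and its truth table.

    Output is a pure function of ``cfg`` (including ``cfg.seed``).  A seeded
    uniform sample of ``round(misannotation_fraction * N)`` transcripts has
    its assigned label (and biotype) swapped to the opposite class; the truth
    table records every assignment.
    """
    rng = np.random.default_rng(cfg.seed)
    seqs: list[LabeledSequence] = []
    for i in range(cfg.n_coding):
        seqs.append(generate_coding_transcript(cfg, rng, f"synth_c{i + 1:05d}"))
    for i in range(cfg.n_noncoding):
        seqs.append(generate_noncoding_transcript(cfg, rng, f"synth_n{i + 1:05d}"))

    n_total = len(seqs)
    n_mis = misannotation_count(cfg.misannotation_fraction, n_total)
    flip_idx = set(rng.choice(n_total, size=n_mis, replace=False).tolist()) if n_mis else set()

    truth = TruthTable()
    out: list[LabeledSequence] = []
    for i, s in enumerate(seqs):
        true = s.assigned_label
        if i in flip_idx:
            assigned = CODING if true == NONCODING else NONCODING
            s = s.with_label(assigned, biotype_for(assigned))
        truth.add(s.id, s.assigned_label, true)
        out.append(s)
    return out, truth


def write_dataset(
    seqs: list[LabeledSequence], truth: TruthTable, out_prefix
) -> tuple[str, str]:
    """Write dataset as ``<prefix>.fasta`` + ``<prefix>.labels.tsv``."""
    fasta = f"{out_prefix}.fasta"
    manifest = f"{out_prefix}.labels.tsv"
    write_labeled_fasta(
        seqs, fasta, manifest,
        true_labels={t: y for t, (_, y) in truth.records.items()},
    )
    return fasta, manifest
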