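"""Reading, writing and filtering labeled transcript sequences.

Transcripts travel through the toolkit as :class:`LabeledSequence` records:
a nucleotide string over ``{A, C, G, T, N}`` plus the *assigned* class label
(``coding`` / ``noncoding``) and an optional annotation biotype (``lncRNA``,
``protein_coding``, ``misc_RNA`` ...).  The assigned label is what the
classifier trains on; whether it matches the (unknown) true label is exactly
what the cartography downstream tries to judge.

On-disk representation is a plain multi-FASTA (wrapped at 80 columns) plus a
tab-separated label manifest with a header line::

    transcript_id    assigned_label    true_label    biotype

``true_label`` is only ever populated for synthetic data, where ground truth
is known; for real data the column holds the assigned label again.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

CODING = "coding"
NONCODING = "noncoding"
LABELS = (NONCODING, CODING)

#: nucleotides the toolkit understands; everything else becomes N on ingest
_VALID = set("ACGTN")

_NORMALIZE = str.maketrans({"U": "T", "u": "T"})

MANIFEST_COLUMNS = ("transcript_id", "assigned_label", "true_label", "biotype")

#: lncRNA definition: non-coding RNAs longer than 200 nt
MIN_NONCODING_LENGTH = 200

#: model input truncation length in nucleotides
MAX_MODEL_LENGTH = 4000


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T and replace any other character by N."""
    s = seq.translate(_NORMALIZE).upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class LabeledSequence:
    """One transcript with its assigned class label.

    Parameters
    ----------
    id : str
        Transcript identifier, unique within a dataset.
    seq : str
        Nucleotide sequence over ``{A, C, G, T, N}`` (normalized on ingest).
    assigned_label : str
        ``"coding"`` or ``"noncoding"`` -- the label the dataset asserts.
    biotype : str, optional
        Free-text annotation biotype (e.g. ``lncRNA``).
    """

    id: str
    seq: str
    assigned_label: str
    biotype: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.assigned_label not in LABELS:
            raise ValueError(
                f"record {self.id!r}: assigned_label must be one of {LABELS}, "
                f"got {self.assigned_label!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def with_label(self, label: str, biotype: str | None = None) -> "LabeledSequence":
        """Return a copy carrying a different assigned label."""
        return dataclasses.replace(self, assigned_label=label, biotype=biotype)


def read_labeled_fasta(fasta_path, manifest_path) -> list[LabeledSequence]:
    """Read a FASTA file and its label manifest into LabeledSequence records.

    The FASTA ids and manifest ids must correspond one-to-one; records are
    returned in FASTA order.  Sequences are normalized (uppercase, U->T,
    unknown characters to N).

    Raises
    ------
    ValueError
        On duplicate ids, ids present on only one side, or empty records;
        the error message names the offending id.
    """
    manifest = read_manifest(manifest_path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        records.append((rec.id, seq))

    manifest_ids = set(manifest.index)
    for rid, _ in records:
        if rid not in manifest_ids:
            raise ValueError(f"FASTA id {rid!r} missing from manifest")
    for rid in manifest.index:
        if rid not in seen:
            raise ValueError(f"manifest id {rid!r} missing from FASTA")

    out = []
    for rid, seq in records:
        row = manifest.loc[rid]
        biotype = row["biotype"]
        if pd.isna(biotype) or biotype == "":
            biotype = None
        out.append(LabeledSequence(rid, seq, str(row["assigned_label"]), biotype))
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a TSV label manifest indexed by transcript_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("transcript_id", "assigned_label") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    if "true_label" not in df.columns:
        df["true_label"] = df["assigned_label"]
    if "biotype" not in df.columns:
        df["biotype"] = ""
    dup = df["transcript_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate manifest id {df.loc[dup, 'transcript_id'].iloc[0]!r}"
        )
    return df.set_index("transcript_id")


def write_labeled_fasta(
    seqs: Sequence[LabeledSequence],
    fasta_path,
    manifest_path,
    true_labels: dict[str, str] | None = None,
) -> None:
    """Write records as 80-column FASTA plus a TSV manifest.

    ``true_labels`` optionally maps id -> true label (synthetic data); when
    absent the assigned label is repeated in the true_label column.
    """
    fasta_path = Path(fasta_path)
    fasta_path.parent.mkdir(parents=True, exist_ok=True)
    with open(fasta_path, "w") as fh:
        writer = FastaWriter(fh, wrap=80)
        writer.write_file(
            SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs
        )
    rows = []
    for s in seqs:
        true = true_labels.get(s.id, s.assigned_label) if true_labels else s.assigned_label
        rows.append((s.id, s.assigned_label, true, s.biotype or ""))
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, sep="\t", index=False
    )


def filter_noncoding_min_length(
    seqs: Iterable[LabeledSequence], min_len: int = MIN_NONCODING_LENGTH
) -> list[LabeledSequence]:
    """Drop non-coding records shorter than ``min_len`` nucleotides.

    Coding records pass through untouched, order is preserved, and a record
    of length exactly ``min_len`` is kept (the filter is strictly ``<``):
    lncRNAs are non-coding RNAs longer than 200 nt, and shorter ncRNAs would
    let sequence length act as a proxy for the class label.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [
        s
        for s in seqs
        if s.assigned_label == CODING or len(s.seq) >= min_len
    ]


def truncate_sequences(
    seqs: Iterable[LabeledSequence], max_len: int = MAX_MODEL_LENGTH
) -> list[LabeledSequence]:
    """Truncate every sequence to its 5' ``max_len``-nt prefix.

    Model input is capped (default 4000 nt) to bound compute; the 5' end is
    kept since it contains the canonical start-proximal ORF region.
    """
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    return [
        s if len(s.seq) <= max_len else dataclasses.replace(s, seq=s.seq[:max_len])
        for s in seqs
    ]
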