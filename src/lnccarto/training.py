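"""Training configuration, encoded datasets, trace recording and evaluation.

The central artifact of this module is the :class:`TrainingTrace`: an
``N x E`` matrix whose entry ``(i, e)`` is the probability the classifier
assigned, at the end of epoch ``e`` and in inference mode, to sample ``i``'s
*currently assigned* label.  The cartography statistics (confidence and
variability) are computed from this trace downstream.

Training uses a class-weighted cross-entropy: class weights are inversely
proportional to class frequency, and the coding class weight is additionally
multiplied by a penalty (default 5) because a transcript annotated as coding
is unlikely to be misannotated, so misclassifying it should cost more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import DEFAULT_K, token_ids
from .io import CODING, NONCODING, LabeledSequence

#: class index order used throughout: column 0 noncoding, column 1 coding
CLASSES = (NONCODING, CODING)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run."""

    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    coding_penalty: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 2:
            raise ValueError("epochs must be >= 2 (the trace needs >= 2 columns)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.coding_penalty <= 0:
            raise ValueError("coding_penalty must be > 0")


def compute_class_weights(labels, coding_penalty: float = 5.0) -> dict[str, float]:
    """Inverse-frequency class weights with a coding misclassification penalty.

    The base weight of class c is ``N / (2 * N_c)`` (balanced weighting);
    the coding weight is then multiplied by ``coding_penalty``.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    labels = list(labels)
    n = len(labels)
    n_coding = sum(1 for l in labels if l == CODING)
    n_noncoding = n - n_coding
    if n_coding == 0 or n_noncoding == 0:
        raise ValueError("both classes must be present to compute class weights")
    return {
        CODING: n / (2.0 * n_coding) * coding_penalty,
        NONCODING: n / (2.0 * n_noncoding),
    }


@dataclass(frozen=True)
class Batch:
    """A padded minibatch of token-id sequences."""

    tok: np.ndarray       # (B, Lmax) int16, padded with pad_id
    lengths: np.ndarray   # (B,) int64, valid token counts (possibly clamped)
    idx: np.ndarray       # (B,) int64, positions in the parent dataset


class EncodedDataset:
    """Token-encoded, labeled dataset ready for minibatch training.

    Sequences are stored as compact k-mer token-id arrays; batches are built
    by grouping length-sorted samples (which minimizes padding) and padding
    each group to its longest member.  Batch composition is fixed; training
    shuffles batch *order* each epoch.
    """

    def __init__(self, ids, token_arrays, labels, k=DEFAULT_K, biotypes=None):
        self.ids = list(ids)
        self.tokens = [np.asarray(t, dtype=np.int16) for t in token_arrays]
        self.labels = np.asarray(labels, dtype=np.int8)
        self.k = k
        self.biotypes = list(biotypes) if biotypes is not None else [None] * len(self.ids)
        if not (len(self.ids) == len(self.tokens) == len(self.labels)):
            raise ValueError("ids, tokens and labels must align")
        self.lengths = np.array([len(t) for t in self.tokens], dtype=np.int64)
        self._batch_cache: dict[tuple[int, int], list[Batch]] = {}

    # vocabulary layout: 0..4^k-1 canonical k-mers, 4^k unknown, 4^k+1 padding
    @property
    def unk_id(self) -> int:
        return 4**self.k

    @property
    def pad_id(self) -> int:
        return 4**self.k + 1

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def label_names(self) -> list[str]:
        return [CLASSES[i] for i in self.labels]

    @classmethod
    def from_sequences(cls, seqs: list[LabeledSequence], k: int = DEFAULT_K):
        return cls(
            ids=[s.id for s in seqs],
            token_arrays=[token_ids(s.seq, k) for s in seqs],
            labels=[CLASSES.index(s.assigned_label) for s in seqs],
            k=k,
            biotypes=[s.biotype for s in seqs],
        )

    def with_labels(self, labels_by_id: dict[str, str]) -> "EncodedDataset":
        """A view of this dataset with some assigned labels replaced.

        Token storage (and the batch cache) is shared; only the label vector
        differs.  Used by the flip experiments.
        """
        new = object.__new__(EncodedDataset)
        new.ids = self.ids
        new.tokens = self.tokens
        new.k = self.k
        new.biotypes = self.biotypes
        new.lengths = self.lengths
        new._batch_cache = self._batch_cache
        labels = self.labels.copy()
        index = {t: i for i, t in enumerate(self.ids)}
        for tid, name in labels_by_id.items():
            labels[index[tid]] = CLASSES.index(name)
        new.labels = labels
        return new

    def subset(self, indices) -> "EncodedDataset":
        indices = np.asarray(indices)
        return EncodedDataset(
            [self.ids[i] for i in indices],
            [self.tokens[i] for i in indices],
            self.labels[indices],
            k=self.k,
            biotypes=[self.biotypes[i] for i in indices],
        )

    def _make_batch(self, idx: np.ndarray, min_len: int) -> Batch:
        lens = np.maximum(self.lengths[idx], min_len)
        Lmax = int(lens.max())
        tok = np.full((len(idx), Lmax), self.pad_id, dtype=np.int16)
        for row, i in enumerate(idx):
            tok[row, : self.lengths[i]] = self.tokens[i]
        return Batch(tok=tok, lengths=lens, idx=np.asarray(idx, dtype=np.int64))

    def batches(self, batch_size: int, min_len: int = 1) -> list[Batch]:
        """Length-sorted padded batches (cached per (batch_size, min_len)).

        Used for inference, where only padding efficiency matters.
        """
        key = (batch_size, min_len)
        if key in self._batch_cache:
            return self._batch_cache[key]
        order = np.argsort(self.lengths, kind="stable")
        out = [
            self._make_batch(order[s : s + batch_size], min_len)
            for s in range(0, len(order), batch_size)
        ]
        self._batch_cache[key] = out
        return out

    def step_groups(self, batch_size: int, min_len: int = 1) -> list[list[Batch]]:
        """Class-stratified optimizer steps of length-homogeneous sub-batches.

        Plain length-sorted batching would make short batches single-class
        here (non-coding transcripts are shorter), and single-class
        minibatches under a class-weighted loss make the updates oscillate
        between class priors instead of learning.  Each step group instead
        holds every class in dataset proportion (~``batch_size`` samples in
        total) but keeps each class's samples length-sorted and padded
        separately, so gradients are class-mixed while the padding overhead
        stays near the length-sorted optimum.  Membership is deterministic;
        training shuffles only the group order.
        """
        key = ("groups", batch_size, min_len, self.labels.tobytes())
        if key in self._batch_cache:
            return self._batch_cache[key]
        n = len(self)
        n_groups = max(1, int(np.ceil(n / batch_size)))
        groups: list[list[Batch]] = [[] for _ in range(n_groups)]
        for c in np.unique(self.labels):
            cls_idx = np.flatnonzero(self.labels == c)
            cls_idx = cls_idx[np.argsort(self.lengths[cls_idx], kind="stable")]
            nc = len(cls_idx)
            start = 0
            for k in range(n_groups):
                end = int(round((k + 1) * nc / n_groups))
                if end > start:
                    groups[k].append(self._make_batch(cls_idx[start:end], min_len))
                start = end
        groups = [g for g in groups if g]
        self._batch_cache[key] = groups
        return groups


@dataclass
class TrainingTrace:
    """Per-sample, per-epoch probability of the currently assigned label."""

    sample_ids: list[str]
    labels: list[str]
    probs: np.ndarray  # (N, E)
    biotypes: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != len(self.sample_ids):
            raise ValueError("probs must be (N, E) aligned with sample_ids")
        if np.any(~np.isfinite(self.probs)) or self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("trace entries must be finite probabilities in [0, 1]")
        if not self.biotypes:
            self.biotypes = [None] * len(self.sample_ids)

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": self.labels,
                "biotype": [b or "" for b in self.biotypes],
            }
        )
        for e in range(self.n_epochs):
            df[f"p_epoch_{e + 1}"] = self.probs[:, e]
        return df

    def to_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrainingTrace":
        df = pd.read_csv(path, sep="\t")
        pcols = [c for c in df.columns if c.startswith("p_epoch_")]
        pcols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
        biotypes = [
            None if (pd.isna(b) or b == "") else str(b)
            for b in df.get("biotype", [""] * len(df))
        ]
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["label"].tolist(),
            probs=df[pcols].to_numpy(),
            biotypes=biotypes,
        )


def train_with_recording(handle, data: EncodedDataset, cfg: TrainConfig) -> TrainingTrace:
    """Train for ``cfg.epochs`` epochs, scoring every sample after each one.

    After every completed epoch the model is evaluated in inference mode
    (dropout disabled) on the full training set with the post-epoch
    parameters; column ``e`` of the returned trace holds the probability
    assigned to each sample's current label.

    Raises
    ------
    RuntimeError
        If the training loss becomes non-finite.
    """
    weights = compute_class_weights(data.label_names, cfg.coding_penalty)
    class_w = np.array([weights[NONCODING], weights[CODING]])
    probs = np.empty((len(data), cfg.epochs))
    rows = np.arange(len(data))
    for e in range(cfg.epochs):
        loss = handle.fit_epoch(
            data, class_w, batch_size=cfg.batch_size, lr=cfg.learning_rate
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss {loss!r} at epoch {e + 1}"
            )
        p = handle.predict_proba(data, batch_size=cfg.batch_size)
        probs[:, e] = p[rows, data.labels]
    return TrainingTrace(
        sample_ids=list(data.ids),
        labels=data.label_names,
        probs=probs,
        biotypes=list(data.biotypes),
    )


@dataclass(frozen=True)
class EvalMetrics:
    """Held-out classification performance (coding = positive class)."""

    auroc: float
    aupr: float
    f1_coding: float
    f1_noncoding: float


def evaluate_classifier(handle, test_data: EncodedDataset) -> EvalMetrics:
    """AUROC / AUPR / per-class F1 on a held-out set.

    Coding is the positive class for AUROC and AUPR; F1 uses the 0.5
    probability threshold.  A single-class test set is an error (AUROC is
    undefined).
    """
    from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

    y = test_data.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class; AUROC is undefined")
    p = handle.predict_proba(test_data)[:, 1]
    pred = (p >= 0.5).astype(int)
    return EvalMetrics(
        auroc=float(roc_auc_score(y, p)),
        aupr=float(average_precision_score(y, p)),
        f1_coding=float(f1_score(y, pred, pos_label=1, zero_division=0)),
        f1_noncoding=float(f1_score(y, pred, pos_label=0, zero_division=0)),
    )
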