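"""Model/Results facade over the cartography workflow.

:class:`LncRNACartography` bundles a labeled transcript dataset, an
architecture and a training configuration; :meth:`fit` trains the classifier
while recording per-epoch assigned-label probabilities and returns a
:class:`CartographyResults` carrying the trace, the per-sample confidence /
variability estimates with region labels, misannotation candidates and a
text summary.  Flip simulations and the QC scatter hang off the results
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cartography import (
    AMBIGUOUS,
    EASY,
    HARD,
    CartographyStats,
    RegionThresholds,
    WeightingScheme,
    assign_region,
    compute_confidence_variability,
    plot_map,
    select_misannotation_candidates,
)
from .classifiers import ArchitectureSpec, SequenceClassifier, build_classifier
from .encoding import KmerEmbeddingTable
from .flips import FlipConfig, FlipExperimentResult, run_flip_experiment
from .io import (
    LabeledSequence,
    filter_noncoding_min_length,
    read_labeled_fasta,
    truncate_sequences,
)
from .synthetic import SynthConfig, TruthTable, generate_dataset
from .training import (
    EncodedDataset,
    EvalMetrics,
    TrainConfig,
    TrainingTrace,
    evaluate_classifier,
    train_with_recording,
)


class LncRNACartography:
    """Misannotation detector built from a labeled transcript dataset.

    Parameters
    ----------
    sequences : list of LabeledSequence
        Transcripts with assigned coding / non-coding labels.  Non-coding
        records shorter than 200 nt are dropped and all sequences are
        truncated to their 5' 4000 nt before encoding.
    arch : str or ArchitectureSpec
        Classifier family: ``"cnn"``, ``"lstm"`` or ``"transformer"``.
    embedding : KmerEmbeddingTable, optional
        Pretrained k-mer embedding table; a seeded random table is used
        when omitted.
    train_config : TrainConfig, optional
    scheme : WeightingScheme, optional
        Epoch weighting for the cartography statistics (default: base).
    thresholds : RegionThresholds, optional
    """

    def __init__(
        self,
        sequences: list[LabeledSequence],
        arch: str | ArchitectureSpec = "cnn",
        embedding: KmerEmbeddingTable | None = None,
        train_config: TrainConfig | None = None,
        scheme: WeightingScheme | None = None,
        thresholds: RegionThresholds | None = None,
    ):
        self.arch = ArchitectureSpec(family=arch) if isinstance(arch, str) else arch
        self.train_config = train_config or TrainConfig()
        self.scheme = scheme or WeightingScheme.base()
        self.thresholds = thresholds or RegionThresholds()
        self.embedding = embedding or KmerEmbeddingTable.random(
            seed=self.train_config.seed
        )
        self.sequences = truncate_sequences(filter_noncoding_min_length(sequences))
        if not self.sequences:
            raise ValueError("no sequences remain after filtering")
        self.data = EncodedDataset.from_sequences(self.sequences, k=self.embedding.k)
        self.truth: TruthTable | None = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_fasta(cls, fasta_path, manifest_path, **kwargs) -> "LncRNACartography":
        """Build from a FASTA file plus a TSV label manifest."""
        return cls(read_labeled_fasta(fasta_path, manifest_path), **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: SynthConfig | None = None, **kwargs
    ) -> "LncRNACartography":
        """Build from the synthetic generator, keeping the truth table."""
        cfg = config or SynthConfig()
        seqs, truth = generate_dataset(cfg)
        model = cls(seqs, **kwargs)
        model.truth = truth
        return model

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "CartographyResults":
        """Train with per-epoch recording and compute the cartography."""
        handle = build_classifier(
            self.arch, self.embedding, seed=self.train_config.seed
        )
        trace = train_with_recording(handle, self.data, self.train_config)
        stats = assign_region(
            compute_confidence_variability(trace, self.scheme), self.thresholds
        )
        return CartographyResults(model=self, handle=handle, trace=trace, stats=stats)


@dataclass
class CartographyResults:
    """Fitted cartography: trace, per-sample estimates and diagnostics."""

    model: LncRNACartography
    handle: SequenceClassifier
    trace: TrainingTrace
    stats: CartographyStats
    _flip_cache: dict = field(default_factory=dict, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        """Per-sample estimates: label, biotype, mu, sigma, region."""
        return self.stats.frame

    def candidates(self, biotype: str | None = None) -> list[str]:
        """Misannotation candidates (hard-to-learn, assigned non-coding)."""
        return select_misannotation_candidates(self.stats, biotype=biotype)

    def rescored(self, scheme: WeightingScheme) -> CartographyStats:
        """Cartography under a different epoch-weighting scheme."""
        return assign_region(
            compute_confidence_variability(self.trace, scheme), self.model.thresholds
        )

    def evaluate(self, test: "LncRNACartography | EncodedDataset") -> EvalMetrics:
        """Held-out classification metrics of the fitted classifier."""
        data = test.data if isinstance(test, LncRNACartography) else test
        return evaluate_classifier(self.handle, data)

    def flip_experiment(self, flip_config: FlipConfig) -> FlipExperimentResult:
        """Flip-simulation validation reusing this fit as the baseline."""
        return run_flip_experiment(
            self.model.sequences,
            self.model.arch,
            self.model.train_config,
            flip_config,
            table=self.model.embedding,
            baseline_trace=self.trace,
            encoded=self.model.data,
        )

    def plot_map(self, path=None, ax=None):
        """Confidence/variability scatter colored by region."""
        return plot_map(self.stats, path=path, ax=ax)

    def summary(self) -> str:
        """statsmodels-style text summary of the fitted cartography."""
        df = self.frame
        n = len(df)
        counts = df["region"].value_counts()
        cands = self.candidates()
        t = self.model.thresholds
        lines = [
            "           Training-Dynamics Cartography",
            "=" * 58,
            f"architecture:     {self.model.arch.family:<12} epochs: {self.trace.n_epochs}",
            f"samples:          {n:<12} scheme: {self.stats.scheme.name}",
            f"coding:           {int((df['label'] == 'coding').sum()):<12} "
            f"noncoding: {int((df['label'] == 'noncoding').sum())}",
            "-" * 58,
            f"mean confidence (mu):     {df['mu'].mean():8.4f}",
            f"mean variability (sigma): {df['sigma'].mean():8.4f}",
            "-" * 58,
            "region counts "
            f"(hard: mu<={t.hard_mu_max}, sigma<={t.hard_sigma_max}; "
            f"easy: mu>={t.easy_mu_min}, sigma<={t.easy_sigma_max})",
        ]
        for region in (EASY, AMBIGUOUS, HARD):
            c = int(counts.get(region, 0))
            lines.append(f"  {region:<10} {c:6d}  ({c / n:6.1%})")
        lines += [
            "-" * 58,
            f"misannotation candidates (hard + assigned noncoding): {len(cands)}",
        ]
        if self.model.truth is not None:
            true_mis = set(self.model.truth.misannotated_ids)
            kept = {s.id for s in self.model.sequences}
            true_mis &= kept
            hit = len(true_mis & set(df.index[df["region"] == HARD]))
            lines.append(
                f"injected misannotations: {len(true_mis)}; "
                f"flagged hard-to-learn: {hit}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)
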