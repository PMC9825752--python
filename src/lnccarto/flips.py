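"""Label-flip simulation: the detector's internal validation.

Protocol: train once on the unmodified dataset and compute baseline
cartography; select the flip-eligible pool (confidently learned samples,
mu >= 0.8 and sigma <= 0.2); flip the assigned labels of a seeded random
sample of ``round(flip_fraction * N)`` transcripts drawn from that pool;
retrain from fresh initialization, recording per-epoch probabilities of the
*flipped* labels; recompute cartography under one or more epoch-weighting
schemes; and measure which fraction of the deliberately mislabeled samples
lands in the hard-to-learn region (mu <= 0.6, sigma <= 0.4).

A high recovery rate demonstrates that the cartography flags mislabeled
training data; comparing recovery across weighting schemes selects the
scheme (equal weighting of all epochs wins).

The flip count is a fraction of the *whole* dataset but is drawn from the
eligible pool only, and each repeat re-seeds both the flip draw and the
model initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cartography import (
    HARD,
    CartographyStats,
    RegionThresholds,
    WeightingScheme,
    assign_region,
    compute_confidence_variability,
)
from .classifiers import ArchitectureSpec, build_classifier
from .encoding import KmerEmbeddingTable
from .io import CODING, NONCODING, LabeledSequence
from .synthetic import biotype_for
from .training import EncodedDataset, TrainConfig, TrainingTrace, train_with_recording


@dataclass(frozen=True)
class FlipConfig:
    """Settings of one flip-simulation experiment."""

    flip_fraction: float = 0.05
    eligibility_mu_min: float = 0.8
    eligibility_sigma_max: float = 0.2
    detection: RegionThresholds = field(default_factory=RegionThresholds)
    n_repeats: int = 4
    scheme_grid: tuple[WeightingScheme, ...] = (WeightingScheme.base(),)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.flip_fraction < 1.0):
            raise ValueError("flip_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.scheme_grid:
            raise ValueError("scheme_grid must not be empty")


def select_flip_eligible(
    stats: CartographyStats, mu_min: float = 0.8, sigma_max: float = 0.2
) -> list[str]:
    """Ids of confidently learned samples (mu >= mu_min, sigma <= sigma_max).

    These are the samples whose assigned labels the model reproduces with
    medium-to-high confidence, so flipping them creates known mislabels.
    An empty pool is an error: the baseline model learned nothing.
    """
    df = stats.frame
    mask = (df["mu"] >= mu_min) & (df["sigma"] <= sigma_max)
    ids = list(df.index[mask])
    if not ids:
        raise ValueError(
            "no flip-eligible samples: the baseline model never learned any "
            "sample confidently"
        )
    return ids


def flip_labels(
    dataset: list[LabeledSequence],
    eligible_ids: list[str],
    flip_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[LabeledSequence], set[str]]:
    """Swap coding<->noncoding labels for a seeded draw from the pool.

    ``round(flip_fraction * N_total)`` ids are sampled uniformly without
    replacement from ``eligible_ids``; all other records pass through
    untouched.  The flipped records' biotype follows the new label (the
    flip emulates an annotation error, not a sequence change).
    """
    n_total = len(dataset)
    n_flip = int(np.floor(flip_fraction * n_total + 0.5))
    pool = sorted(set(eligible_ids))
    if n_flip > len(pool):
        raise ValueError(
            f"requested {n_flip} flips but only {len(pool)} eligible samples"
        )
    chosen = set(rng.choice(pool, size=n_flip, replace=False).tolist()) if n_flip else set()
    out = []
    for s in dataset:
        if s.id in chosen:
            new = CODING if s.assigned_label == NONCODING else NONCODING
            out.append(s.with_label(new, biotype_for(new)))
        else:
            out.append(s)
    return out, chosen


def recovery_rate(flipped_ids: set[str], detected_ids: set[str]) -> float:
    """Fraction of deliberately flipped samples present in the detected set."""
    if not flipped_ids:
        raise ValueError("flipped set is empty; recovery is undefined")
    return len(set(flipped_ids) & set(detected_ids)) / len(set(flipped_ids))


@dataclass
class FlipExperimentResult:
    """Recovery of deliberately flipped labels, per scheme and repeat."""

    config: FlipConfig
    recovery: pd.DataFrame               # columns: scheme, repeat, recovery
    flipped_ids: dict[int, set[str]]     # repeat -> flipped ids
    detected_ids: dict[tuple[str, int], set[str]]  # (scheme, repeat) -> ids
    baseline_stats: CartographyStats | None = None
    traces: dict[int, TrainingTrace] | None = None

    def mean_recovery(self, scheme: str | WeightingScheme | None = None) -> float:
        name = _scheme_name(scheme) if scheme else self.config.scheme_grid[0].name
        sub = self.recovery[self.recovery["scheme"] == name]
        if sub.empty:
            raise KeyError(f"no recovery rows for scheme {name!r}")
        return float(sub["recovery"].mean())

    @property
    def scheme_ranking(self) -> list[tuple[str, float]]:
        """Schemes ordered best-first by mean fraction of missed flips."""
        means = self.recovery.groupby("scheme")["recovery"].mean()
        missed = (1.0 - means).sort_values(kind="stable")
        return [(s, float(m)) for s, m in missed.items()]

    def to_json(self, path) -> None:
        payload = {
            "config": {
                "flip_fraction": self.config.flip_fraction,
                "eligibility_mu_min": self.config.eligibility_mu_min,
                "eligibility_sigma_max": self.config.eligibility_sigma_max,
                "n_repeats": self.config.n_repeats,
                "schemes": [s.name for s in self.config.scheme_grid],
                "seed": self.config.seed,
            },
            "recovery": self.recovery.to_dict(orient="records"),
            "flipped_ids": {r: sorted(v) for r, v in self.flipped_ids.items()},
            "detected_ids": {
                f"{s}/{r}": sorted(v) for (s, r), v in self.detected_ids.items()
            },
            "scheme_ranking_by_missed": self.scheme_ranking,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _scheme_name(s) -> str:
    return s.name if isinstance(s, WeightingScheme) else str(s)


def run_flip_experiment(
    dataset: list[LabeledSequence],
    arch_spec: ArchitectureSpec | str,
    train_cfg: TrainConfig,
    flip_cfg: FlipConfig,
    table: KmerEmbeddingTable | None = None,
    baseline_trace: TrainingTrace | None = None,
    encoded: EncodedDataset | None = None,
    verbose: bool = False,
) -> FlipExperimentResult:
    """Run the full flip-simulation protocol on one dataset.

    A precomputed ``baseline_trace`` (from an identical unflipped training
    run) can be supplied to share the baseline across experiments with
    different flip fractions; otherwise the baseline is trained here.
    Repeat ``r`` seeds both its flip draw and its fresh model initialization
    from ``flip_cfg.seed + r``.
    """
    if isinstance(arch_spec, str):
        arch_spec = ArchitectureSpec(family=arch_spec)
    table = table or KmerEmbeddingTable.random(seed=train_cfg.seed)
    data = encoded if encoded is not None else EncodedDataset.from_sequences(dataset)

    if baseline_trace is None:
        handle = build_classifier(arch_spec, table, seed=train_cfg.seed)
        baseline_trace = train_with_recording(handle, data, train_cfg)
    base_stats = compute_confidence_variability(baseline_trace, WeightingScheme.base())
    eligible = select_flip_eligible(
        base_stats, flip_cfg.eligibility_mu_min, flip_cfg.eligibility_sigma_max
    )

    rows = []
    flipped_by_repeat: dict[int, set[str]] = {}
    detected: dict[tuple[str, int], set[str]] = {}
    traces: dict[int, TrainingTrace] = {}
    for r in range(flip_cfg.n_repeats):
        rep_seed = flip_cfg.seed + r
        rng = np.random.default_rng(rep_seed)
        flipped_seqs, flipped = flip_labels(
            dataset, eligible, flip_cfg.flip_fraction, rng
        )
        flipped_by_repeat[r] = flipped
        flip_data = data.with_labels(
            {s.id: s.assigned_label for s in flipped_seqs if s.id in flipped}
        )
        handle = build_classifier(arch_spec, table, seed=rep_seed)
        trace = train_with_recording(handle, flip_data, train_cfg)
        traces[r] = trace
        for scheme in flip_cfg.scheme_grid:
            stats = assign_region(
                compute_confidence_variability(trace, scheme), flip_cfg.detection
            )
            hard_ids = set(stats.region_ids(HARD))
            detected[(scheme.name, r)] = hard_ids
            rows.append(
                {
                    "scheme": scheme.name,
                    "repeat": r,
                    "recovery": recovery_rate(flipped, hard_ids),
                }
            )
        if verbose:  # pragma: no cover
            got = [r_ for r_ in rows if r_["repeat"] == r]
            print(f"repeat {r}: " + ", ".join(f"{g['scheme']}={g['recovery']:.3f}" for g in got))

    return FlipExperimentResult(
        config=flip_cfg,
        recovery=pd.DataFrame(rows),
        flipped_ids=flipped_by_repeat,
        detected_ids=detected,
        baseline_stats=base_stats,
        traces=traces,
    )
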