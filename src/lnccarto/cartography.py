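"""Training-dynamics cartography: confidence, variability and regions.

For sample *i* with per-epoch assigned-label probabilities
:math:`p_{i1}, \\dots, p_{iE}` the *confidence* and *variability* are the
(weighted) mean and population standard deviation

.. math::

    \\hat\\mu_i = \\frac{\\sum_e w_e\\, p_{ie}}{\\sum_e w_e}, \\qquad
    \\hat\\sigma_i = \\sqrt{\\frac{\\sum_e w_e (p_{ie} - \\hat\\mu_i)^2}
                                 {\\sum_e w_e}}.

Three epoch-weighting schemes are supported: ``base`` (all epochs equal,
the default -- flip simulations favour it), ``weighted`` (:math:`w_e = e`,
later epochs count more) and ``ignore_first(f)`` (drop the first
``floor(f*E)`` epochs, equal weights on the rest).

The (mu, sigma) plane splits into three regions: *easy-to-learn* (high mu,
low sigma -- confidently and stably learned), *hard-to-learn* (low mu, low
sigma -- consistently classified against the assigned label) and
*ambiguous* (everything else).  Hard-to-learn transcripts whose assigned
label is non-coding are the misannotation candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NONCODING, LabeledSequence
from .training import TrainingTrace

EASY = "easy"
AMBIGUOUS = "ambiguous"
HARD = "hard"


@dataclass(frozen=True)
class WeightingScheme:
    """How per-epoch probabilities are combined into (mu, sigma)."""

    kind: str = "base"
    ignore_fraction: float = 0.0

    #: the canonical grid of ignored-prefix fractions explored by the
    #: flip-simulation scheme comparison
    IGNORE_GRID = (0.05, 0.10, 0.20, 0.40, 0.60, 0.80)

    def __post_init__(self) -> None:
        if self.kind not in ("base", "weighted", "ignore_first"):
            raise ValueError(f"unknown weighting scheme kind {self.kind!r}")
        if self.kind == "ignore_first":
            if not (0.0 < self.ignore_fraction < 1.0):
                raise ValueError("ignore_fraction must lie in (0, 1)")
        elif self.ignore_fraction:
            raise ValueError("ignore_fraction applies only to ignore_first")

    @classmethod
    def base(cls) -> "WeightingScheme":
        return cls("base")

    @classmethod
    def weighted(cls) -> "WeightingScheme":
        return cls("weighted")

    @classmethod
    def ignore_first(cls, fraction: float) -> "WeightingScheme":
        return cls("ignore_first", fraction)

    @property
    def name(self) -> str:
        if self.kind == "ignore_first":
            return f"ignore_1st_{int(round(self.ignore_fraction * 100))}"
        return self.kind

    @classmethod
    def parse(cls, name: str) -> "WeightingScheme":
        """Inverse of :attr:`name`, e.g. ``"ignore_1st_20"``."""
        if name in ("base", "weighted"):
            return cls(name)
        if name.startswith("ignore_1st_"):
            return cls.ignore_first(int(name.rsplit("_", 1)[1]) / 100.0)
        raise ValueError(f"cannot parse weighting scheme {name!r}")


@dataclass(frozen=True)
class RegionThresholds:
    """Cutoffs for the easy / ambiguous / hard partition (inclusive)."""

    hard_mu_max: float = 0.6
    hard_sigma_max: float = 0.4
    easy_mu_min: float = 0.8
    easy_sigma_max: float = 0.2

    def __post_init__(self) -> None:
        if self.hard_mu_max >= self.easy_mu_min:
            raise ValueError(
                "hard_mu_max must be below easy_mu_min (regions must be disjoint)"
            )


@dataclass
class CartographyStats:
    """Per-sample (mu, sigma) under a weighting scheme, with region labels.

    ``frame`` is indexed by sample id with columns ``label``, ``biotype``,
    ``mu``, ``sigma`` and (after :func:`assign_region`) ``region``.
    """

    frame: pd.DataFrame
    scheme: WeightingScheme

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    def region_ids(self, region: str) -> list[str]:
        if "region" not in self.frame.columns:
            raise ValueError("regions not assigned yet; call assign_region first")
        return list(self.frame.index[self.frame["region"] == region])

    def to_tsv(self, path) -> None:
        df = self.frame.copy()
        df.insert(len(df.columns), "scheme", self.scheme.name)
        df.to_csv(path, sep="\t", index_label="sample_id")


def epoch_weights(scheme: WeightingScheme, n_epochs: int) -> np.ndarray:
    """Per-epoch weights of a scheme (zeros for ignored epochs).

    Raises ValueError when fewer than two epochs retain positive weight.
    """
    if scheme.kind == "base":
        w = np.ones(n_epochs)
    elif scheme.kind == "weighted":
        w = np.arange(1, n_epochs + 1, dtype=float)
    else:
        drop = int(np.floor(scheme.ignore_fraction * n_epochs))
        w = np.ones(n_epochs)
        w[:drop] = 0.0
    if int((w > 0).sum()) < 2:
        raise ValueError(
            f"scheme {scheme.name} retains fewer than 2 of {n_epochs} epochs"
        )
    return w


def compute_confidence_variability(
    trace: TrainingTrace, scheme: WeightingScheme | None = None
) -> CartographyStats:
    """Weighted mean and population standard deviation of the trace rows."""
    scheme = scheme or WeightingScheme.base()
    P = trace.probs
    if P.shape[1] < 2:
        raise ValueError("trace must contain at least 2 epochs")
    w = epoch_weights(scheme, P.shape[1])
    wsum = w.sum()
    mu = P @ w / wsum
    sigma = np.sqrt(np.maximum((P - mu[:, None]) ** 2 @ w / wsum, 0.0))
    frame = pd.DataFrame(
        {
            "label": trace.labels,
            "biotype": [b or "" for b in trace.biotypes],
            "mu": mu,
            "sigma": sigma,
        },
        index=pd.Index(trace.sample_ids, name="sample_id"),
    )
    return CartographyStats(frame=frame, scheme=scheme)


def assign_region(
    stats: CartographyStats, thresholds: RegionThresholds | None = None
) -> CartographyStats:
    """Label each sample easy / ambiguous / hard (cutoffs inclusive).

    hard: mu <= hard_mu_max and sigma <= hard_sigma_max;
    easy: mu >= easy_mu_min and sigma <= easy_sigma_max;
    ambiguous otherwise.  Disjointness of hard and easy is guaranteed by
    ``hard_mu_max < easy_mu_min``.
    """
    t = thresholds or RegionThresholds()
    mu = stats.frame["mu"].to_numpy()
    sigma = stats.frame["sigma"].to_numpy()
    hard = (mu <= t.hard_mu_max) & (sigma <= t.hard_sigma_max)
    easy = (mu >= t.easy_mu_min) & (sigma <= t.easy_sigma_max)
    region = np.where(hard, HARD, np.where(easy, EASY, AMBIGUOUS))
    frame = stats.frame.copy()
    frame["region"] = region
    return CartographyStats(frame=frame, scheme=stats.scheme)


def select_misannotation_candidates(
    stats: CartographyStats,
    dataset: Sequence[LabeledSequence] | None = None,
    biotype: str | None = None,
) -> list[str]:
    """Hard-to-learn transcripts assigned non-coding, most confident first.

    Only transcripts whose *assigned* label is non-coding qualify (a coding
    transcript is unlikely to be misannotated); ``biotype`` optionally
    restricts further (e.g. to ``"lncRNA"``).  The list is sorted by
    ascending mu -- the most consistently contradicted annotations first --
    with ties broken by id.
    """
    df = stats.frame
    if "region" not in df.columns:
        raise ValueError("regions not assigned yet; call assign_region first")
    if dataset is not None:
        labels = {s.id: s.assigned_label for s in dataset}
        biotypes = {s.id: (s.biotype or "") for s in dataset}
        label_col = df.index.map(labels)
        bio_col = df.index.map(biotypes)
    else:
        label_col = df["label"]
        bio_col = df["biotype"]
    mask = (df["region"] == HARD) & (np.asarray(label_col) == NONCODING)
    if biotype is not None:
        mask &= np.asarray(bio_col) == biotype
    sel = df[mask]
    order = sel.loc[sorted(sel.index)].sort_values("mu", kind="stable")
    return list(order.index)


@dataclass
class ConsensusResult:
    """Membership of candidate ids across several models' candidate lists."""

    membership: pd.DataFrame       # bool, one column per model, union index
    cell_counts: dict[frozenset, int]  # exclusive Venn cells -> size

    @property
    def union(self) -> set[str]:
        return set(self.membership.index)

    @property
    def intersection(self) -> set[str]:
        return set(self.membership.index[self.membership.all(axis=1)])

    def count(self, *models: str) -> int:
        """Size of the exclusive Venn cell containing exactly ``models``."""
        return self.cell_counts.get(frozenset(models), 0)


def consensus_candidates(candidate_lists: Mapping[str, Iterable[str]]) -> ConsensusResult:
    """Venn-style comparison of named candidate lists.

    Returns per-id membership bits and the size of every exclusive subset
    cell; cell counts sum to the union size.
    """
    names = list(candidate_lists)
    if len(names) < 2:
        raise ValueError("need at least two candidate lists")
    sets = {m: set(candidate_lists[m]) for m in names}
    union = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {m: [i in sets[m] for i in union] for m in names},
        index=pd.Index(union, name="sample_id"),
    )
    cells: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = membership[list(combo)].all(axis=1)
            outside = ~membership[[m for m in names if m not in combo]].any(axis=1) \
                if len(combo) < len(names) else pd.Series(True, index=membership.index)
            cells[frozenset(combo)] = int((inside & outside).sum())
    return ConsensusResult(membership=membership, cell_counts=cells)


def plot_map(stats: CartographyStats, path=None, ax=None):
    """Scatter of variability (x) vs confidence (y), colored by region."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    df = stats.frame
    colors = {EASY: "#2b8cbe", AMBIGUOUS: "#bdbdbd", HARD: "#e34a33"}
    regions = df["region"] if "region" in df.columns else pd.Series(
        AMBIGUOUS, index=df.index
    )
    for region, color in colors.items():
        sub = df[regions == region]
        ax.scatter(sub["sigma"], sub["mu"], s=6, alpha=0.6, c=color, label=region)
    ax.set_xlabel("variability (sigma)")
    ax.set_ylabel("confidence (mu)")
    ax.set_xlim(0, 0.5)
    ax.set_ylim(0, 1)
    ax.legend(loc="center right", fontsize=8)
    ax.set_title(f"training-dynamics map ({stats.scheme.name})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
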