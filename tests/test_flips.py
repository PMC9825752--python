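"""Label-flip simulation mechanics (cheap paths; the full experiment runs
in the acceptance suite)."""

import numpy as np
import pandas as pd
import pytest

from lnccarto.cartography import (
    RegionThresholds,
    WeightingScheme,
    assign_region,
    compute_confidence_variability,
)
from lnccarto.flips import (
    FlipConfig,
    flip_labels,
    recovery_rate,
    run_flip_experiment,
    select_flip_eligible,
)
from lnccarto.io import LabeledSequence
from lnccarto.synthetic import SynthConfig, generate_dataset
from lnccarto.training import TrainConfig, TrainingTrace


def stats_from(mu_sigma, labels=None):
    ids = [f"s{i}" for i in range(len(mu_sigma))]
    trace = TrainingTrace(
        sample_ids=ids,
        labels=labels or ["noncoding"] * len(ids),
        probs=np.full((len(ids), 2), 0.5),
    )
    stats = compute_confidence_variability(trace)
    stats.frame["mu"] = [m for m, _ in mu_sigma]
    stats.frame["sigma"] = [s for _, s in mu_sigma]
    return stats


class TestEligibility:
    def test_thresholds(self):
        stats = stats_from([(0.85, 0.15), (0.85, 0.25), (0.75, 0.1), (0.8, 0.2)])
        assert select_flip_eligible(stats) == ["s0", "s3"]

    def test_perfect_constant_trace_all_eligible(self):
        trace = TrainingTrace(
            sample_ids=["a", "b"], labels=["coding", "coding"],
            probs=np.ones((2, 3)),
        )
        stats = compute_confidence_variability(trace)
        assert select_flip_eligible(stats) == ["a", "b"]

    def test_empty_pool_is_error(self):
        stats = stats_from([(0.5, 0.3), (0.2, 0.1)])
        with pytest.raises(ValueError, match="eligible"):
            select_flip_eligible(stats)


def _dataset(n=20):
    return [
        LabeledSequence(f"t{i}", "ATG" + "AAA" * 80, "coding" if i % 2 else "noncoding")
        for i in range(n)
    ]


class TestFlipLabels:
    def test_zero_fraction_changes_nothing(self):
        seqs = _dataset()
        flipped_seqs, flipped = flip_labels(
            seqs, [s.id for s in seqs], 0.0, np.random.default_rng(0)
        )
        assert flipped == set()
        assert flipped_seqs == seqs
        with pytest.raises(ValueError):
            FlipConfig(flip_fraction=0.0)  # config-level invariant

    def test_count_drawn_from_eligible_pool(self):
        seqs = _dataset(200)
        eligible = [s.id for s in seqs[:50]]
        flipped_seqs, flipped = flip_labels(seqs, eligible, 0.05, np.random.default_rng(1))
        assert len(flipped) == 10  # round(0.05 * 200)
        assert flipped <= set(eligible)
        for s, f in zip(seqs, flipped_seqs):
            if s.id in flipped:
                assert f.assigned_label != s.assigned_label
            else:
                assert f is s

    def test_labels_swap_both_directions(self):
        seqs = _dataset(4)
        _, flipped = flip_labels(seqs, [s.id for s in seqs], 0.5, np.random.default_rng(3))
        assert len(flipped) == 2

    def test_same_seed_same_flips(self):
        seqs = _dataset(100)
        eligible = [s.id for s in seqs]
        _, f1 = flip_labels(seqs, eligible, 0.1, np.random.default_rng(7))
        _, f2 = flip_labels(seqs, eligible, 0.1, np.random.default_rng(7))
        assert f1 == f2

    def test_request_exceeding_pool_is_error(self):
        seqs = _dataset(100)
        with pytest.raises(ValueError, match="eligible"):
            flip_labels(seqs, [seqs[0].id], 0.5, np.random.default_rng(0))


class TestRecoveryRate:
    @pytest.mark.parametrize(
        "flipped,detected,expected",
        [
            ({"a", "b"}, {"a", "b", "c"}, 1.0),
            ({"a", "b"}, {"c"}, 0.0),
            (set("abcdefghij"), set("abcdefghi"), 0.9),
        ],
    )
    def test_examples(self, flipped, detected, expected):
        assert recovery_rate(flipped, detected) == pytest.approx(expected)

    def test_empty_flipped_is_error(self):
        with pytest.raises(ValueError):
            recovery_rate(set(), {"a"})


@pytest.fixture(scope="module")
def tiny_result():
    cfg = SynthConfig(
        n_coding=12,
        n_noncoding=12,
        length_range_coding=(900, 1000),
        length_range_noncoding=(400, 700),
        seed=5,
    )
    seqs, _ = generate_dataset(cfg)
    train_cfg = TrainConfig(epochs=3, batch_size=8, seed=5)
    # vacuous detector so eligibility/bookkeeping can be tested without
    # waiting for real convergence on this tiny training budget
    flip_cfg = FlipConfig(
        flip_fraction=0.25,
        eligibility_mu_min=0.0,
        eligibility_sigma_max=1.0,
        detection=RegionThresholds(
            hard_mu_max=0.79, hard_sigma_max=1.0, easy_mu_min=0.8
        ),
        n_repeats=2,
        scheme_grid=(WeightingScheme.base(), WeightingScheme.weighted()),
        seed=5,
    )
    return run_flip_experiment(seqs, "cnn", train_cfg, flip_cfg)


class TestRunFlipExperiment:
    def test_recovery_table_shape(self, tiny_result):
        df = tiny_result.recovery
        assert set(df["scheme"]) == {"base", "weighted"}
        assert sorted(df["repeat"].unique()) == [0, 1]
        assert df["recovery"].between(0, 1).all()

    def test_flipped_sets_sized_and_distinct_per_repeat(self, tiny_result):
        f0, f1 = tiny_result.flipped_ids[0], tiny_result.flipped_ids[1]
        assert len(f0) == len(f1) == 6  # round(0.25 * 24)
        assert f0 != f1  # independently re-seeded repeats

    def test_scheme_ranking_orders_by_missed_fraction(self, tiny_result):
        ranking = tiny_result.scheme_ranking
        missed = [m for _, m in ranking]
        assert missed == sorted(missed)

    def test_json_export(self, tiny_result, tmp_path):
        import json

        tiny_result.to_json(tmp_path / "flip.json")
        payload = json.loads((tmp_path / "flip.json").read_text())
        assert payload["config"]["n_repeats"] == 2
        assert len(payload["recovery"]) == 4


class TestDetectorEdgeCases:
    def _trace_and_flipped(self):
        rng = np.random.default_rng(0)
        probs = rng.random((30, 4))
        trace = TrainingTrace(
            sample_ids=[f"s{i}" for i in range(30)],
            labels=["noncoding"] * 30,
            probs=probs,
        )
        flipped = {f"s{i}" for i in range(10)}
        return trace, flipped

    def test_vacuous_detector_recovers_everything(self):
        trace, flipped = self._trace_and_flipped()
        loose = RegionThresholds(hard_mu_max=1.0, hard_sigma_max=1.0, easy_mu_min=1.1)
        stats = assign_region(compute_confidence_variability(trace), loose)
        detected = set(stats.region_ids("hard"))
        assert recovery_rate(flipped, detected) == 1.0

    def test_empty_detector_recovers_nothing(self):
        trace, flipped = self._trace_and_flipped()
        strict = RegionThresholds(hard_mu_max=0.0, hard_sigma_max=0.0, easy_mu_min=0.5)
        stats = assign_region(compute_confidence_variability(trace), strict)
        detected = set(stats.region_ids("hard"))
        assert recovery_rate(flipped, detected) == 0.0

    def test_widening_detection_never_decreases_recovery(self):
        trace, flipped = self._trace_and_flipped()
        last = -1.0
        for mu_max in (0.2, 0.4, 0.6, 0.7):
            t = RegionThresholds(hard_mu_max=mu_max, hard_sigma_max=0.4,
                                 easy_mu_min=0.95)
            stats = assign_region(compute_confidence_variability(trace), t)
            r = recovery_rate(flipped, set(stats.region_ids("hard")))
            assert r >= last
            last = r
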