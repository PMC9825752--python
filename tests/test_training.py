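"""Class weights, encoded datasets, trace recording and evaluation."""

import numpy as np
import pytest

from lnccarto.classifiers import build_classifier
from lnccarto.encoding import KmerEmbeddingTable
from lnccarto.io import LabeledSequence
from lnccarto.synthetic import SynthConfig, generate_dataset
from lnccarto.training import (
    EncodedDataset,
    TrainConfig,
    TrainingTrace,
    compute_class_weights,
    evaluate_classifier,
    train_with_recording,
)


class TestClassWeights:
    def test_balanced_unit_penalty(self):
        w = compute_class_weights(["coding", "noncoding"] * 5, coding_penalty=1)
        assert w == {"coding": 1.0, "noncoding": 1.0}

    def test_balanced_with_penalty_five(self):
        w = compute_class_weights(["coding", "noncoding"] * 5)
        assert w["coding"] == pytest.approx(5.0)
        assert w["noncoding"] == pytest.approx(1.0)

    def test_curated_human_dataset_sizes(self):
        """38,051 coding / 19,472 non-coding, penalty 5: hand-computed
        N/(2 Nc) gives 3.77934 (coding) and 1.47707 (non-coding)."""
        labels = ["coding"] * 38051 + ["noncoding"] * 19472
        w = compute_class_weights(labels)
        assert w["coding"] == pytest.approx(57523 / (2 * 38051) * 5, rel=1e-12)
        assert w["coding"] == pytest.approx(3.77934, abs=1e-5)
        assert w["noncoding"] == pytest.approx(1.47707, abs=1e-5)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            compute_class_weights(["coding"] * 4)


class TestEncodedDataset:
    def test_from_sequences_alignment(self, small_dataset):
        seqs, _ = small_dataset
        data = EncodedDataset.from_sequences(seqs)
        assert data.ids == [s.id for s in seqs]
        assert all(
            n == len(s.seq) - 2 for n, s in zip(data.lengths, seqs)
        )

    def test_with_labels_view_shares_tokens(self, small_dataset):
        seqs, _ = small_dataset
        data = EncodedDataset.from_sequences(seqs)
        flipped = data.with_labels({seqs[0].id: "noncoding", seqs[-1].id: "coding"})
        assert flipped.tokens is data.tokens
        assert flipped.labels[0] == 0 and flipped.labels[-1] == 1
        assert data.labels[0] == 1  # original untouched

    def test_batches_cover_every_sample_once(self, small_dataset):
        seqs, _ = small_dataset
        data = EncodedDataset.from_sequences(seqs)
        got = np.concatenate([b.idx for b in data.batches(5, min_len=10)])
        assert sorted(got) == list(range(len(seqs)))

    def test_step_groups_mix_classes_and_cover_dataset(self, small_dataset):
        seqs, _ = small_dataset
        data = EncodedDataset.from_sequences(seqs)
        groups = data.step_groups(8, min_len=10)
        all_idx = np.concatenate([b.idx for g in groups for b in g])
        assert sorted(all_idx) == list(range(len(seqs)))
        for g in groups:
            labels = np.concatenate([data.labels[b.idx] for b in g])
            assert len(set(labels.tolist())) == 2  # both classes in every step

    def test_padding_uses_pad_id(self, small_dataset):
        seqs, _ = small_dataset
        data = EncodedDataset.from_sequences(seqs)
        batch = data.batches(len(seqs), min_len=1)[0]
        row = np.argmin(batch.lengths)
        n = data.lengths[batch.idx[row]]
        assert np.all(batch.tok[row, n:] == data.pad_id)


@pytest.fixture(scope="module")
def trained():
    cfg = SynthConfig(
        n_coding=16,
        n_noncoding=16,
        length_range_coding=(900, 1000),
        length_range_noncoding=(400, 700),
        seed=3,
    )
    seqs, _ = generate_dataset(cfg)
    table = KmerEmbeddingTable.random(3, 16, seed=0)
    data = EncodedDataset.from_sequences(seqs)
    tc = TrainConfig(epochs=3, batch_size=8, seed=1)
    handle = build_classifier("cnn", table, seed=1)
    trace = train_with_recording(handle, data, tc)
    return handle, data, trace, tc, table


class TestTrainWithRecording:
    def test_trace_shape_and_bounds(self, trained):
        _, data, trace, tc, _ = trained
        assert trace.probs.shape == (len(data), tc.epochs)
        assert trace.probs.min() >= 0 and trace.probs.max() <= 1

    def test_trace_records_assigned_label_probability(self, trained):
        handle, data, trace, tc, _ = trained
        p = handle.predict_proba(data, batch_size=tc.batch_size)
        np.testing.assert_allclose(
            trace.probs[:, -1], p[np.arange(len(data)), data.labels], atol=1e-12
        )

    def test_recording_is_inference_mode(self, trained):
        """Scoring the same post-epoch model twice yields identical columns."""
        handle, data, _, tc, _ = trained
        a = handle.predict_proba(data, batch_size=tc.batch_size)
        b = handle.predict_proba(data, batch_size=tc.batch_size)
        np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_traces(self, trained):
        _, data, trace, tc, table = trained
        handle2 = build_classifier("cnn", table, seed=1)
        trace2 = train_with_recording(handle2, data, tc)
        np.testing.assert_array_equal(trace.probs, trace2.probs)

    def test_trace_tsv_round_trip(self, trained, tmp_path):
        _, _, trace, _, _ = trained
        trace.to_tsv(tmp_path / "trace.tsv")
        back = TrainingTrace.from_tsv(tmp_path / "trace.tsv")
        assert back.sample_ids == trace.sample_ids
        assert back.labels == trace.labels
        np.testing.assert_allclose(back.probs, trace.probs, atol=1e-12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            TrainConfig(coding_penalty=0)


class TestEvaluate:
    def test_perfect_and_inverted_scores(self, trained):
        handle, data, _, _, _ = trained

        class Fake:
            def __init__(self, probs):
                self._p = probs

            def predict_proba(self, d, batch_size=64):
                return self._p

        y = data.labels
        perfect = np.stack([1.0 - y, y.astype(float)], axis=1)
        m = evaluate_classifier(Fake(perfect), data)
        assert m.auroc == 1.0 and m.aupr == 1.0 and m.f1_coding == 1.0
        inverted = perfect[:, ::-1]
        m2 = evaluate_classifier(Fake(inverted), data)
        assert m2.auroc == 0.0

    def test_all_equal_scores_give_half_auroc(self, trained):
        _, data, _, _, _ = trained

        class Fake:
            def predict_proba(self, d, batch_size=64):
                return np.full((len(d), 2), 0.5)

        m = evaluate_classifier(Fake(), data)
        assert m.auroc == pytest.approx(0.5)

    def test_single_class_test_set_is_error(self, trained):
        handle, data, _, _, _ = trained
        sub = data.subset(np.flatnonzero(data.labels == 1))
        with pytest.raises(ValueError):
            evaluate_classifier(handle, sub)


def test_separable_smoke_training_reaches_high_confidence():
    """On a small separable dataset the classifier ends confidently right.

    Smoke-check of the whole optimization loop: after enough updates the
    final-epoch mean assigned-label probability is high.  Small batches
    give the desk-scale dataset enough optimizer steps per epoch.
    """
    cfg = SynthConfig(n_coding=240, n_noncoding=160, seed=21)
    seqs, _ = generate_dataset(cfg)
    table = KmerEmbeddingTable.random(seed=21)
    data = EncodedDataset.from_sequences(seqs)
    tc = TrainConfig(epochs=10, batch_size=8, learning_rate=3e-3, seed=21)
    handle = build_classifier("cnn", table, seed=21)
    trace = train_with_recording(handle, data, tc)
    assert trace.probs[:, -1].mean() >= 0.9
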