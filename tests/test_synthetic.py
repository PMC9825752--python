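"""Synthetic generator: construction guarantees, determinism, truth table."""

import dataclasses

import numpy as np
import pytest

from lnccarto.features import find_orfs, longest_orf_length
from lnccarto.io import CODING, NONCODING, read_labeled_fasta
from lnccarto.synthetic import (
    SynthConfig,
    generate_coding_transcript,
    generate_dataset,
    generate_noncoding_transcript,
    misannotation_count,
    write_dataset,
)


@pytest.fixture()
def cfg(small_config):
    return small_config


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SynthConfig()

    @pytest.mark.parametrize(
        "kw",
        [
            {"length_range_noncoding": (150, 500)},          # below lncRNA bound
            {"orf_length_range": (301, 900)},                # not a codon multiple
            {"orf_length_range": (150, 900)},                # no separability gap
            {"length_range_coding": (700, 800)},             # cannot hold max ORF
            {"gc_content": 0.0},
            {"misannotation_fraction": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SynthConfig(**kw)


class TestCodingTranscript:
    def test_longest_orf_is_exactly_the_drawn_length(self, cfg):
        fixed = dataclasses.replace(cfg, orf_length_range=(300, 300))
        rng = np.random.default_rng(0)
        for _ in range(5):
            seq = generate_coding_transcript(fixed, rng)
            assert longest_orf_length(seq.seq) == 300
            assert seq.assigned_label == CODING

    def test_same_seed_reproduces_sequence(self, cfg):
        s1 = generate_coding_transcript(cfg, np.random.default_rng(42))
        s2 = generate_coding_transcript(cfg, np.random.default_rng(42))
        assert s1.seq == s2.seq

    def test_orf_structure(self, cfg):
        seq = generate_coding_transcript(cfg, np.random.default_rng(3))
        orf = max(find_orfs(seq.seq), key=lambda o: o.length)
        s = orf.extract(seq.seq)
        assert s[:3] == "ATG" and s[-3:] in ("TAA", "TAG", "TGA")
        # no internal in-frame stop
        assert all(s[i : i + 3] not in ("TAA", "TAG", "TGA") for i in range(3, len(s) - 3, 3))

    def test_utr_gc_matches_configuration(self, cfg):
        """UTR nucleotides are i.i.d. at the configured GC content.

        Binomial oracle: over ~n UTR bases, the mean GC fraction should lie
        within a few standard errors of the target.
        """
        rng = np.random.default_rng(8)
        fixed = dataclasses.replace(
            cfg, orf_length_range=(300, 300), length_range_coding=(1300, 1300)
        )
        gc_bases = 0
        utr_bases = 0
        for _ in range(30):
            seq = generate_coding_transcript(fixed, rng)
            orf = max(find_orfs(seq.seq), key=lambda o: o.length)
            utr = seq.seq[: orf.start] + seq.seq[orf.end :]
            gc_bases += sum(1 for c in utr if c in "GC")
            utr_bases += len(utr)
        p = gc_bases / utr_bases
        se = np.sqrt(0.5 * 0.5 / utr_bases)
        assert abs(p - 0.5) < 5 * se


class TestNoncodingTranscript:
    def test_longest_orf_capped(self, cfg):
        rng = np.random.default_rng(1)
        for _ in range(5):
            seq = generate_noncoding_transcript(cfg, rng)
            assert longest_orf_length(seq.seq) <= cfg.max_noncoding_orf
            assert seq.assigned_label == NONCODING

    def test_exact_length_config(self, cfg):
        fixed = dataclasses.replace(cfg, length_range_noncoding=(200, 200))
        seq = generate_noncoding_transcript(fixed, np.random.default_rng(2))
        assert len(seq.seq) == 200

    def test_rejection_rate_matches_monte_carlo_oracle(self):
        """The generator's acceptance rate matches a brute-force estimate.

        Oracle: draw i.i.d. 1000-nt sequences directly and measure how often
        the longest ORF is <= 150 nt; the generator's attempts-per-output
        must be statistically compatible (within ~3 combined standard
        errors of the acceptance probability).
        """
        cfg = SynthConfig(
            n_coding=1,
            n_noncoding=1,
            length_range_noncoding=(1000, 1000),
            max_noncoding_orf=150,
            seed=0,
        )
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGT"))
        n_trials = 250
        accept = sum(
            longest_orf_length("".join(bases[rng.integers(0, 4, size=1000)])) <= 150
            for _ in range(n_trials)
        )
        p_oracle = accept / n_trials
        se_oracle = np.sqrt(p_oracle * (1 - p_oracle) / n_trials)

        gen_rng = np.random.default_rng(88)
        stats: dict = {}
        produced = 100
        for _ in range(produced):
            seq = generate_noncoding_transcript(cfg, gen_rng, stats=stats)
            assert longest_orf_length(seq.seq) <= 150
        p_gen = produced / stats["attempts"]
        se_gen = np.sqrt(p_gen * (1 - p_gen) / stats["attempts"])
        assert abs(p_gen - p_oracle) < 3 * (se_oracle + se_gen)

    def test_infeasible_configuration_fails_fast(self):
        cfg = SynthConfig(
            n_coding=1,
            n_noncoding=1,
            length_range_noncoding=(1500, 1500),
            max_noncoding_orf=9,
            orf_length_range=(300, 900),
            seed=0,
        )
        with pytest.raises(RuntimeError, match="infeasible"):
            generate_noncoding_transcript(cfg, np.random.default_rng(0))


class TestDataset:
    def test_counts_and_no_misannotation_by_default(self, small_dataset):
        seqs, truth = small_dataset
        assert len(seqs) == 24
        assert truth.misannotated_ids == []
        assert all(truth.records[s.id][0] == s.assigned_label for s in seqs)

    def test_misannotation_count_is_rounded_fraction(self, cfg):
        noisy = dataclasses.replace(cfg, misannotation_fraction=0.1)
        seqs, truth = generate_dataset(noisy)
        expected = misannotation_count(0.1, len(seqs))
        assert len(truth.misannotated_ids) == expected == 2
        for tid in truth.misannotated_ids:
            assigned, true = truth.records[tid]
            assert assigned != true

    @pytest.mark.parametrize(
        "fraction,n,expected", [(0.0, 200, 0), (0.1, 200, 20), (0.05, 30, 2), (0.125, 20, 3)]
    )
    def test_rounding_rule_half_away_from_zero(self, fraction, n, expected):
        assert misannotation_count(fraction, n) == expected

    def test_class_separability_by_longest_orf(self, small_dataset, small_config):
        """The rule 'longest ORF >= orf_min' recovers true labels exactly."""
        seqs, truth = small_dataset
        for s in seqs:
            rule = (
                CODING
                if longest_orf_length(s.seq) >= small_config.orf_length_range[0]
                else NONCODING
            )
            assert rule == truth.true_label(s.id)

    def test_same_seed_byte_identical_outputs(self, cfg, tmp_path):
        for sub in ("a", "b"):
            seqs, truth = generate_dataset(cfg)
            write_dataset(seqs, truth, tmp_path / sub)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (
            (tmp_path / "a.labels.tsv").read_bytes()
            == (tmp_path / "b.labels.tsv").read_bytes()
        )

    def test_write_read_round_trip(self, small_dataset, tmp_path):
        seqs, truth = small_dataset
        fasta, manifest = write_dataset(seqs, truth, tmp_path / "ds")
        back = read_labeled_fasta(fasta, manifest)
        assert [(s.id, s.seq, s.assigned_label) for s in back] == [
            (s.id, s.seq, s.assigned_label) for s in seqs
        ]
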