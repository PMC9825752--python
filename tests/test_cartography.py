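"""Confidence/variability statistics, regions, candidates and consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnccarto.cartography import (
    AMBIGUOUS,
    EASY,
    HARD,
    RegionThresholds,
    WeightingScheme,
    assign_region,
    compute_confidence_variability,
    consensus_candidates,
    epoch_weights,
    select_misannotation_candidates,
)
from lnccarto.training import TrainingTrace


def make_trace(rows, labels=None, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[0]
    return TrainingTrace(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        labels=labels or ["noncoding"] * n,
        probs=rows,
    )


def oracle_mu_sigma(p, w):
    """Independent two-pass oracle for the weighted mean / population std."""
    w = np.asarray(w, dtype=float)
    mu = sum(wi * pi for wi, pi in zip(w, p)) / w.sum()
    var = sum(wi * (pi - mu) ** 2 for wi, pi in zip(w, p)) / w.sum()
    return mu, np.sqrt(var)


class TestConfidenceVariability:
    def test_constant_trace(self):
        stats = compute_confidence_variability(make_trace([[0.9, 0.9, 0.9]]))
        assert stats.frame["mu"].iloc[0] == pytest.approx(0.9)
        assert stats.frame["sigma"].iloc[0] == pytest.approx(0.0)

    def test_base_hand_example(self):
        stats = compute_confidence_variability(make_trace([[0.2, 0.4, 0.6, 0.8]]))
        assert stats.frame["mu"].iloc[0] == pytest.approx(0.5)
        assert stats.frame["sigma"].iloc[0] == pytest.approx(np.sqrt(0.05))

    def test_weighted_hand_example(self):
        stats = compute_confidence_variability(
            make_trace([[0.0, 1.0]]), WeightingScheme.weighted()
        )
        assert stats.frame["mu"].iloc[0] == pytest.approx(2 / 3)
        assert stats.frame["sigma"].iloc[0] == pytest.approx(np.sqrt(2) / 3)

    def test_ignore_first_drops_floor_fraction(self):
        p = [0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
        stats = compute_confidence_variability(
            make_trace([p]), WeightingScheme.ignore_first(0.20)
        )
        assert stats.frame["mu"].iloc[0] == pytest.approx(1.0)
        assert stats.frame["sigma"].iloc[0] == pytest.approx(0.0)

    def test_fewer_than_two_retained_epochs_is_error(self):
        with pytest.raises(ValueError):
            compute_confidence_variability(
                make_trace([[0.1, 0.2]]), WeightingScheme.ignore_first(0.6)
            )

    def test_base_equals_weighted_with_equal_weights_and_ignore0(self):
        rng = np.random.default_rng(5)
        P = rng.random((20, 12))
        base = compute_confidence_variability(make_trace(P))
        w = epoch_weights(WeightingScheme.base(), 12)
        for i in range(20):
            mu, sg = oracle_mu_sigma(P[i], w)
            assert base.frame["mu"].iloc[i] == pytest.approx(mu, abs=1e-12)
            assert base.frame["sigma"].iloc[i] == pytest.approx(sg, abs=1e-12)

    @pytest.mark.parametrize(
        "scheme",
        [
            WeightingScheme.base(),
            WeightingScheme.weighted(),
            WeightingScheme.ignore_first(0.05),
            WeightingScheme.ignore_first(0.20),
            WeightingScheme.ignore_first(0.80),
        ],
        ids=lambda s: s.name,
    )
    def test_all_schemes_match_two_pass_oracle(self, scheme):
        """100 random traces (N <= 100, E <= 50) vs the oracle, 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 101))
            e = int(rng.integers(10, 51))
            P = rng.random((n, e))
            stats = compute_confidence_variability(make_trace(P), scheme)
            w = epoch_weights(scheme, e)
            mask = w > 0
            for i in rng.choice(n, size=min(n, 5), replace=False):
                mu, sg = oracle_mu_sigma(P[i][mask], w[mask])
                assert abs(stats.frame["mu"].iloc[i] - mu) < 1e-12
                assert abs(stats.frame["sigma"].iloc[i] - sg) < 1e-12

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
    )
    @settings(max_examples=60, deadline=None)
    def test_sigma_bounded_by_half(self, probs):
        stats = compute_confidence_variability(make_trace([probs]))
        assert 0.0 <= stats.frame["sigma"].iloc[0] <= 0.5 + 1e-12
        assert 0.0 <= stats.frame["mu"].iloc[0] <= 1.0


class TestRegions:
    @pytest.mark.parametrize(
        "mu,sigma,region",
        [
            (0.5, 0.2, HARD),
            (0.9, 0.1, EASY),
            (0.7, 0.3, AMBIGUOUS),
            (0.6, 0.4, HARD),      # printed cutoffs classify inclusively
            (0.8, 0.2, EASY),
            (0.6, 0.41, AMBIGUOUS),
            (0.61, 0.1, AMBIGUOUS),
            (0.0, 0.0, HARD),
            (1.0, 0.0, EASY),
        ],
    )
    def test_printed_cutoffs(self, mu, sigma, region):
        trace = make_trace([[mu, mu]])
        stats = compute_confidence_variability(trace)
        stats.frame.loc[:, "sigma"] = sigma
        stats.frame.loc[:, "mu"] = mu
        assert assign_region(stats).frame["region"].iloc[0] == region

    def test_hard_and_easy_disjoint_on_grid(self):
        """Sweep (mu, sigma) over [0,1] x [0,0.5]: no point is both."""
        mus = np.linspace(0, 1, 51)
        sigmas = np.linspace(0, 0.5, 26)
        t = RegionThresholds()
        for mu in mus:
            for sg in sigmas:
                hard = mu <= t.hard_mu_max and sg <= t.hard_sigma_max
                easy = mu >= t.easy_mu_min and sg <= t.easy_sigma_max
                assert not (hard and easy)

    def test_overlapping_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RegionThresholds(hard_mu_max=0.8, easy_mu_min=0.8)


class TestCandidates:
    def _stats(self):
        trace = TrainingTrace(
            sample_ids=["a", "b", "c", "d"],
            labels=["coding", "noncoding", "noncoding", "noncoding"],
            probs=np.array(
                [[0.1, 0.1], [0.2, 0.2], [0.05, 0.05], [0.95, 0.95]]
            ),
            biotypes=["protein_coding", "lncRNA", "misc_RNA", "lncRNA"],
        )
        return assign_region(compute_confidence_variability(trace))

    def test_hard_coding_excluded_hard_noncoding_included(self):
        cands = select_misannotation_candidates(self._stats())
        assert cands == ["c", "b"]  # ascending mu

    def test_biotype_filter(self):
        cands = select_misannotation_candidates(self._stats(), biotype="lncRNA")
        assert cands == ["b"]

    def test_empty_hard_region(self):
        trace = make_trace([[0.9, 0.9]], labels=["noncoding"])
        stats = assign_region(compute_confidence_variability(trace))
        assert select_misannotation_candidates(stats) == []


class TestConsensus:
    def test_two_lists(self):
        res = consensus_candidates({"m1": ["a", "b"], "m2": ["b", "c"]})
        assert res.intersection == {"b"}
        assert res.union == {"a", "b", "c"}
        assert res.count("m1") == 1 and res.count("m2") == 1
        assert res.count("m1", "m2") == 1

    def test_three_identical_lists(self):
        ids = ["x", "y", "z"]
        res = consensus_candidates({"a": ids, "b": ids, "c": ids})
        assert res.count("a", "b", "c") == 3
        assert res.count("a") == 0

    def test_random_lists_match_set_enumeration(self, rng):
        pool = [f"id{i}" for i in range(200)]
        lists = {
            name: list(rng.choice(pool, size=size, replace=False))
            for name, size in (("cnn", 50), ("lstm", 60), ("transformer", 70))
        }
        res = consensus_candidates(lists)
        sets = {k: set(v) for k, v in lists.items()}
        names = list(sets)
        total = 0
        for mask in range(1, 8):
            combo = [names[i] for i in range(3) if mask >> i & 1]
            inside = set.intersection(*(sets[m] for m in combo))
            outside = set.union(*(sets[m] for m in names if m not in combo), set())
            cell = inside - outside
            assert res.count(*combo) == len(cell)
            total += len(cell)
        assert total == len(res.union)

    def test_single_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_candidates({"only": ["a"]})
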