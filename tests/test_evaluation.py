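"""Similarity score, KL machinery, thresholds, maps, periodicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sctrnnpb import (desk_spec, generate_behavior_template, kl_divergence,
                      similarity_score, state_histogram, success_threshold,
                      weight_distribution_stats)
from sctrnnpb.evaluation import (N_BINS_DEFAULT, SMOOTHING,
                                 context_periodicity, pb_error_map)


class TestHistogram:
    def test_constant_series_concentrates_in_one_bin(self):
        hist = state_histogram(np.zeros(200), n_bins=50)
        assert hist.probs.shape == (1, 50)
        peak = np.argmax(hist.probs[0])
        assert hist.probs[0, peak] > 0.999
        assert hist.edges[peak] <= 0.0 < hist.edges[peak + 1]

    def test_uniform_fill_gives_equal_mass(self):
        # one sample exactly inside each of the 50 bins
        centers = np.linspace(-1, 1, 51)[:-1] + 0.02
        hist = state_histogram(centers, n_bins=50)
        assert np.allclose(hist.probs[0], 1 / 50)

    def test_normalization_is_exact(self):
        rng = np.random.default_rng(0)
        values = np.clip(rng.normal(0, 0.3, (1000, 4)), -0.99, 0.99)
        hist = state_histogram(values)
        assert np.allclose(hist.probs.sum(axis=1), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            state_histogram(np.array([0.0, 1.0]))


class TestKL:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_closed_form_ln2(self):
        assert kl_divergence(np.array([1.0, 0.0]),
                             np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(50))
        q = rng.dirichlet(np.ones(50))
        direct = sum(pb * np.log(pb / qb) for pb, qb in zip(p, q) if pb > 0)
        assert abs(kl_divergence(p, q) - direct) < 1e-12

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones(3) / 3, np.ones(4) / 4)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_nonnegative_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-0.9, 0.9, 300)
        b = rng.uniform(-0.9, 0.9, 300)
        ha, hb = state_histogram(a), state_histogram(b)
        assert kl_divergence(ha.probs[0], hb.probs[0]) >= 0.0


class TestSimilarityScore:
    def test_self_similarity_is_zero(self):
        seq = generate_behavior_template(desk_spec())
        res = similarity_score(seq.values, seq.values)
        assert res.score == 0.0 and res.score_all_dims == 0.0

    def test_left_right_templates_distinguishable(self):
        left = generate_behavior_template(desk_spec("left"))
        right = generate_behavior_template(desk_spec("right"))
        res = similarity_score(left.values, right.values, left.proprio_idx)
        assert res.score > 0.0

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(1)
        gen = rng.uniform(-0.9, 0.9, (150, 5))
        tgt = rng.uniform(-0.9, 0.9, (150, 5))
        res = similarity_score(gen, tgt)
        edges = np.linspace(-1, 1, N_BINS_DEFAULT + 1)
        brute = 0.0
        for d in range(5):
            cp, _ = np.histogram(gen[:, d], bins=edges)
            cq, _ = np.histogram(tgt[:, d], bins=edges)
            p = (cp + SMOOTHING) / (cp + SMOOTHING).sum()
            q = (cq + SMOOTHING) / (cq + SMOOTHING).sum()
            brute += np.sum(p[p > 0] * np.log(p[p > 0] / q[p > 0]))
        assert abs(res.score_all_dims - brute) < 1e-12

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            similarity_score(np.zeros((0, 2)), np.zeros((5, 2)))


class TestSuccessThreshold:
    def test_min_then_halve(self):
        """xi equals half the minimum ordered cross-behavior score."""
        ds = _desk_dataset()
        xi = success_threshold(ds)
        dims = np.array([i for i, r in enumerate(ds.channel_roles)
                         if r == "proprio"])
        scores = []
        for a in ds.train("left"):
            for b in ds.train("right"):
                scores.append(similarity_score(a.values, b.values, dims).score)
                scores.append(similarity_score(b.values, a.values, dims).score)
        assert xi == pytest.approx(0.5 * min(scores))
        assert xi > 0.0

    def test_single_behavior_rejected(self):
        ds = _desk_dataset()
        ds.sequences = [s for s in ds.sequences if s.behavior == "left"]
        with pytest.raises(ValueError):
            success_threshold(ds)

    def test_duplicate_training_sets_give_zero_flagged(self):
        ds = _desk_dataset()
        left = ds.train("left")[0]
        for seq in ds.train("right"):
            seq.values = left.values.copy()
        assert success_threshold(ds) == pytest.approx(0.0, abs=1e-9)

    def test_every_training_sequence_beats_threshold_within_behavior(self):
        """Threshold consistency: same-behavior SS < xi for all pairs."""
        ds = _desk_dataset()
        xi = success_threshold(ds)
        dims = np.array([i for i, r in enumerate(ds.channel_roles)
                         if r == "proprio"])
        for behavior in ("left", "right"):
            seqs = ds.train(behavior)
            for a in seqs:
                best = min(similarity_score(a.values, b.values, dims).score
                           for b in seqs if b is not a)
                assert best < xi


def _desk_dataset():
    from sctrnnpb import build_dataset
    return build_dataset(desk_spec(), 2, 2, rng=123)


class TestWeightStats:
    def test_initial_distributions_identical_across_k(self):
        """Before learning, the context-weight histogram does not depend on
        the bias heterogeneity (weights come from the same uniform law)."""
        from sctrnnpb import desk_config, init_parameters
        stats = {}
        for k in (0.1, 10.0):
            models = [init_parameters(desk_config(k=k), seed, 4)
                      for seed in range(4)]
            stats[k] = weight_distribution_stats(models, bound=1.0)
        bound = 1 / np.sqrt(30)
        for k, st_ in stats.items():
            assert st_.std == pytest.approx(bound / np.sqrt(3), rel=0.05)
        assert stats[0.1].frac_weak == pytest.approx(stats[10.0].frac_weak,
                                                     abs=0.01)


class TestPeriodicity:
    def test_pure_sinusoid_scores_near_one(self):
        period = 40
        t = np.arange(5 * period)
        c = np.sin(2 * np.pi * t / period)[:, None]
        idx = context_periodicity(c, period)
        assert idx[0] > 0.99

    def test_white_noise_scores_near_uniform_share(self):
        rng = np.random.default_rng(0)
        T = 400
        c = rng.normal(size=(T, 8))
        idx = context_periodicity(c, 40)
        n_bins = T // 2
        assert np.mean(idx) < 10 * 3 / n_bins

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            context_periodicity(np.zeros((50, 2)), 40)


class TestPBMapGeometry:
    def test_grid_counting_excludes_atanh_boundary(self):
        """A 41 x 41 activity grid evaluates 39 x 39 interior cells."""
        from sctrnnpb import desk_config, init_parameters
        ds = _desk_dataset()
        params = init_parameters(desk_config(k=1.0), 0, n_sequences=4)
        pbmap = pb_error_map(params, ds, "left", grid_resolution=41)
        assert pbmap.errors.shape == (41, 41)
        assert np.isfinite(pbmap.errors).sum() == 39 * 39
        assert np.isnan(pbmap.errors[0]).all()
        assert np.isnan(pbmap.errors[:, -1]).all()

    def test_resolution_floor(self):
        from sctrnnpb import desk_config, init_parameters
        params = init_parameters(desk_config(), 0, n_sequences=4)
        with pytest.raises(ValueError):
            pb_error_map(params, _desk_dataset(), "left", grid_resolution=5)
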