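import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trimorf as tm


def process_oracle(scores: np.ndarray, w: int) -> np.ndarray:
    """Brute-force sliding-window (max + median) / 2."""
    n = scores.size
    out = np.empty(n)
    for j in range(n):
        window = scores[max(0, j - w):min(n, j + w + 1)]
        out[j] = (window.max() + np.median(window)) / 2
    return out


def track(scores, seq_id="s", stage="raw"):
    return tm.ScoreTrack(seq_id, np.asarray(scores, float), stage)


class TestProcessTrack:
    def test_hand_computed_example(self):
        out = tm.process_track(track([0, 1, 0, 0, 0]), tm.PostprocessConfig(1))
        # j=2: window (0,1,0) -> (1 + 0)/2
        assert out.scores[1] == 0.5
        np.testing.assert_allclose(out.scores,
                                   process_oracle(np.array([0, 1, 0, 0, 0.]), 1))
        assert out.stage == "processed"

    def test_constant_track_is_fixed_point(self):
        out = tm.process_track(track([0.3] * 12), tm.PostprocessConfig(5))
        np.testing.assert_array_equal(out.scores, [0.3] * 12)

    def test_single_residue_track(self):
        out = tm.process_track(track([0.7]), tm.PostprocessConfig(15))
        assert out.scores[0] == 0.7

    @pytest.mark.parametrize("n,w,seed", [(1, 1, 0), (5, 2, 1), (50, 12, 2),
                                          (200, 30, 3), (31, 30, 4)])
    def test_matches_oracle(self, n, w, seed):
        scores = np.random.default_rng(seed).uniform(size=n)
        got = tm.process_track(track(scores), tm.PostprocessConfig(w)).scores
        np.testing.assert_allclose(got, process_oracle(scores, w), atol=1e-12)

    @given(n=st.integers(1, 80), w=st.integers(1, 20),
           lam=st.floats(0.01, 10, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_positive_homogeneity_and_bounds(self, n, w, lam):
        scores = np.random.default_rng(n * 31 + w).uniform(size=n)
        cfg = tm.PostprocessConfig(w)
        base = tm.process_track(track(scores), cfg).scores
        scaled = tm.process_track(track(lam * scores), cfg).scores
        np.testing.assert_allclose(scaled, lam * base, atol=1e-9)
        assert base.min() >= scores.min() - 1e-12
        assert base.max() <= scores.max() + 1e-12

    def test_rejects_flank_below_one(self):
        with pytest.raises(ValueError):
            tm.PostprocessConfig(0)


class TestCombineTracks:
    def test_elementwise_mean(self):
        out = tm.combine_tracks([track([0.2, 0.4]), track([0.6, 0.8])])
        np.testing.assert_allclose(out.scores, [0.4, 0.6])
        assert out.stage == "combined"

    def test_idempotent_and_permutation_invariant(self):
        a, b, c = track([0.1, 0.9, 0.5]), track([0.2, 0.3, 0.4]), track([1, 0, 1])
        np.testing.assert_allclose(
            tm.combine_tracks([a, a, a]).scores, a.scores, atol=1e-15)
        np.testing.assert_allclose(
            tm.combine_tracks([a, b, c]).scores,
            tm.combine_tracks([c, a, b]).scores, atol=1e-15)

    def test_mismatches_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tm.combine_tracks([track([1] * 5), track([1] * 6)])
        with pytest.raises(ValueError, match="seq_id"):
            tm.combine_tracks([track([1, 2]), track([1, 2], seq_id="other")])
        with pytest.raises(ValueError):
            tm.combine_tracks([])


class TestCombinedPipeline:
    def test_degenerate_ensemble_equals_own_processed(self, stub_bundle,
                                                      trace_factory):
        trace = trace_factory("q", 60)
        own_cfg, comb_cfg = tm.PostprocessConfig(12), tm.PostprocessConfig(8)
        got = tm.run_combined_pipeline(stub_bundle, "A" * 60, trace,
                                       own_config=own_cfg,
                                       combined_config=comb_cfg)
        raw = tm.score_sequence(stub_bundle, "A" * 60, trace)
        expected = tm.process_track(tm.process_track(raw, own_cfg), comb_cfg)
        np.testing.assert_allclose(got.scores, expected.scores, atol=1e-15)
        assert got.stage == "combined"

    def test_constant_tracks_are_fixed_point(self, trace_factory):
        # stub scoring 0.4 everywhere plus a constant external track
        class Const:
            def normalized_scores(self, x):
                return np.full(len(x), 0.4)

        bundle = tm.ModelBundle(Const(), Const(), tm.FeatureConfig(),
                                tm.SvmConfig(), 20)
        trace = trace_factory("q", 50)
        ext = tm.ScoreTrack("q", np.full(50, 0.4))
        out = tm.run_combined_pipeline(
            bundle, "A" * 50, trace,
            external_tracks=[(ext, tm.PostprocessConfig(4))])
        np.testing.assert_allclose(out.scores, 0.4, atol=1e-12)

    def test_external_order_irrelevant(self, stub_bundle, trace_factory):
        trace = trace_factory("q", 70, seed=9)
        rng = np.random.default_rng(1)
        exts = [(tm.ScoreTrack("q", rng.uniform(size=70)),
                 tm.PostprocessConfig(f)) for f in (4, 15)]
        a = tm.run_combined_pipeline(stub_bundle, "A" * 70, trace,
                                     external_tracks=exts)
        b = tm.run_combined_pipeline(stub_bundle, "A" * 70, trace,
                                     external_tracks=exts[::-1])
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-15)
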