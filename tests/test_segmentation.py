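import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trimorf as tm
from trimorf.segmentation import extract_training_segments, run_zones
from trimorf.types import Polarity, Zone


def window_bounds_oracle(j: int, length: int, flank: int) -> tuple[int, int]:
    """Literal transcription of the three-branch query-window rule."""
    if j <= flank:
        return 1, min(length, j + flank)
    if j > length - flank:
        return j - flank, length
    return j - flank, j + flank


class TestZoneOf:
    @pytest.mark.parametrize("position,length,expected", [
        (1, 100, Zone.TERMINAL),
        (20, 100, Zone.TERMINAL),    # last residue of the left terminal zone
        (21, 100, Zone.MIDDLE),      # first middle residue
        (80, 100, Zone.MIDDLE),
        (81, 100, Zone.TERMINAL),
        (25, 40, Zone.TERMINAL),     # length <= 2*flank: no middle zone
    ])
    def test_trisection_boundaries(self, position, length, expected):
        assert tm.zone_of(position, length) is expected

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            tm.zone_of(0, 10)
        with pytest.raises(ValueError):
            tm.zone_of(11, 10)


class TestQuerySamples:
    @pytest.mark.parametrize("length", [1, 5, 40, 41, 100, 500])
    def test_matches_three_branch_oracle(self, length):
        flank = 20
        samples = tm.enumerate_query_samples(length, flank)
        assert len(samples) == length
        for j, s in enumerate(samples, start=1):
            assert s.position == j
            assert (s.start, s.end) == window_bounds_oracle(j, length, flank)
            assert s.zone is tm.zone_of(j, length, flank)

    def test_full_width_window_at_length_41(self):
        samples = tm.enumerate_query_samples(41, 20)
        widths = [s.end - s.start + 1 for s in samples]
        assert widths[20] == 41 and max(widths) == 41
        assert widths.count(41) == 1

    @given(length=st.integers(1, 300), flank=st.integers(1, 40))
    @settings(max_examples=60, derandomize=True)
    def test_terminal_sample_count(self, length, flank):
        samples = tm.enumerate_query_samples(length, flank)
        n_term = sum(s.zone is Zone.TERMINAL for s in samples)
        assert n_term == min(2 * flank, length)
        for s in samples:
            assert s.end - s.start + 1 == (
                min(length, s.position + flank) - max(1, s.position - flank) + 1
            )


def annotated(length: int, runs: list[tuple[int, int]]) -> tm.AnnotatedSequence:
    labels = np.zeros(length, dtype=bool)
    for a, b in runs:
        labels[a - 1:b] = True
    return tm.AnnotatedSequence("t", "A" * length, labels)


class TestTrainingSegments:
    def test_middle_morf_gets_flanked_middle_segment(self):
        segs = extract_training_segments(annotated(100, [(40, 50)]), rng=0)
        pos = [s for s in segs if s.polarity is Polarity.POSITIVE]
        assert len(pos) == 1
        assert (pos[0].start, pos[0].end, pos[0].zone) == (20, 70, Zone.MIDDLE)

    def test_terminal_morf_clipped_upstream(self):
        segs = extract_training_segments(annotated(100, [(3, 10)]), rng=0)
        pos = [s for s in segs if s.polarity is Polarity.POSITIVE]
        assert len(pos) == 1
        assert (pos[0].start, pos[0].end, pos[0].zone) == (1, 30, Zone.TERMINAL)

    def test_no_morf_yields_no_segments(self):
        assert extract_training_segments(annotated(100, []), rng=0) == []

    def test_straddling_run_feeds_both_zones(self):
        # run 15-25 has residues in both the terminal and middle zone
        segs = extract_training_segments(annotated(200, [(15, 25)]), rng=0)
        pos_zones = {s.zone for s in segs if s.polarity is Polarity.POSITIVE}
        assert pos_zones == {Zone.TERMINAL, Zone.MIDDLE}

    def test_negatives_match_length_and_zone_and_avoid_flanked_extent(self):
        seq = annotated(300, [(100, 115)])
        rng = np.random.default_rng(5)
        segs = extract_training_segments(seq, rng=rng)
        pos = [s for s in segs if s.polarity is Polarity.POSITIVE]
        neg = [s for s in segs if s.polarity is Polarity.NEGATIVE]
        assert len(pos) == len(neg) == 1
        assert neg[0].length == pos[0].length
        assert neg[0].zone is pos[0].zone
        # disjoint from the flanked extent [80, 135]
        assert neg[0].end < 80 or neg[0].start > 135

    def test_deterministic_given_seed(self):
        seq = annotated(400, [(50, 60), (200, 210)])
        a = extract_training_segments(seq, rng=7)
        b = extract_training_segments(seq, rng=7)
        assert a == b

    @given(
        length=st.integers(50, 400),
        run_start=st.integers(1, 300),
        run_len=st.integers(5, 25),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=60, derandomize=True)
    def test_negatives_never_intersect_morf_runs(self, length, run_start,
                                                 run_len, seed):
        run_start = min(run_start, length - run_len + 1)
        seq = annotated(length, [(run_start, run_start + run_len - 1)])
        segs = extract_training_segments(seq, rng=seed)
        for s in segs:
            covered = seq.labels[s.start - 1:s.end]
            if s.polarity is Polarity.NEGATIVE:
                assert not covered.any()
            else:
                assert covered.any()
        # zone bookkeeping: every positive zone matches the run's zones
        zones = run_zones(run_start, run_start + run_len - 1, length, 20)
        assert {s.zone for s in segs if s.polarity is Polarity.POSITIVE} == zones
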