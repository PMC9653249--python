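"""Segmentation, completeness filtering and summary tables.

The segmentation oracle is an exhaustive scan partitioner written
independently of the implementation; hypothesis drives random streams
through both.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gesturelaws import (
    GestureToken,
    TokenParseError,
    composition_by_size,
    filter_complete,
    length_composition_table,
    read_tokens,
    repertoire_summary,
    segment_sequences,
    write_tokens_csv,
)


def tok(start, end="auto", sig="S01", video="V1", gtype="A", cat="manual",
        form="loose"):
    if end == "auto":
        end = start + 0.40
    return GestureToken(
        signaller=sig, recipient="F01", date="2010-01-01", video_id=video,
        gesture_type=gtype, category=cat, duration_form=form,
        start_s=start, end_s=end,
    )


def stream_with_gaps(gaps, dur=0.40):
    """Tokens of fixed duration with the given end-to-start gaps."""
    out, t = [], 0.0
    for g in [None] + list(gaps):
        if g is not None:
            t += g
        out.append(tok(round(t, 4), round(t + dur, 4)))
        t += dur
    return out


class TestSegmentation:
    def test_sub_threshold_gaps_join_one_sequence(self):
        seqs = segment_sequences(stream_with_gaps([0.5, 0.5]))
        assert [s.size_n for s in seqs] == [3]

    def test_threshold_boundary_is_exclusive(self):
        # 0.99 s joins; a gap of exactly 1.00 s does NOT (strict "< 1 s")
        seqs = segment_sequences(stream_with_gaps([0.99, 1.00]))
        assert [s.size_n for s in seqs] == [2, 1]

    def test_overlapping_tokens_share_a_sequence(self):
        seqs = segment_sequences(stream_with_gaps([-0.2]))
        assert [s.size_n for s in seqs] == [2]

    def test_signaller_and_video_boundaries_split(self):
        toks = [
            tok(0.0, 0.4, sig="S01"),
            tok(0.5, 0.9, sig="S02"),  # close in time, different signaller
            tok(1.0, 1.4, sig="S02", video="V2"),  # different video
        ]
        seqs = segment_sequences(toks)
        assert [s.size_n for s in seqs] == [1, 1, 1]

    def test_missing_end_time_closes_sequence(self):
        toks = [tok(0.0, None), tok(0.5, 0.9)]
        seqs = segment_sequences(toks)
        assert [s.size_n for s in seqs] == [1, 1]
        assert not seqs[0].complete

    def test_start_to_start_gap_mode(self):
        # 0.4 s tokens with 0.8 s end-to-start gaps: start-to-start gap is
        # 1.2 s >= 1, so the start-to-start convention splits what the
        # end-to-start convention joins
        toks = stream_with_gaps([0.8, 0.8])
        assert [s.size_n for s in segment_sequences(toks)] == [3]
        split = segment_sequences(toks, gap_mode="start_to_start")
        assert [s.size_n for s in split] == [1, 1, 1]


@st.composite
def random_streams(draw):
    n = draw(st.integers(min_value=1, max_value=50))
    sigs = draw(st.lists(st.sampled_from(["S01", "S02"]), min_size=n, max_size=n))
    out, t = [], {}
    for i in range(n):
        sig = sigs[i]
        gap = draw(st.floats(min_value=0.0, max_value=2.5))
        start = t.get(sig, 0.0) + gap
        dur = draw(st.sampled_from([0.04, 0.40, 1.00]))
        out.append(tok(round(start, 3), round(start + dur, 3), sig=sig))
        t[sig] = start + dur
    return out


def brute_force_partition(tokens, threshold=1.0):
    """Exhaustive scan partitioner: grouped by (signaller, video), a new
    sequence begins whenever the end-to-start gap is >= threshold."""
    groups = {}
    for token in sorted(tokens, key=lambda x: (x.signaller, x.video_id, x.start_s)):
        groups.setdefault((token.signaller, token.video_id), []).append(token)
    partition = []
    for toks in groups.values():
        runs = [[toks[0]]]
        for prev, cur in zip(toks, toks[1:]):
            if prev.end_s is not None and cur.start_s - prev.end_s < threshold:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        partition.extend(runs)
    return sorted(
        tuple((t.signaller, t.start_s) for t in run) for run in partition
    )


class TestSegmentationProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_streams())
    def test_matches_brute_force_partitioner(self, tokens):
        seqs = segment_sequences(tokens)
        got = sorted(
            tuple((t.signaller, t.start_s) for t in s.tokens) for s in seqs
        )
        assert got == brute_force_partition(tokens)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(random_streams())
    def test_partition_conserves_tokens(self, tokens):
        seqs = segment_sequences(tokens)
        assert sum(s.size_n for s in seqs) == len(tokens)
        flat = sorted((t.signaller, t.start_s) for s in seqs for t in s.tokens)
        assert flat == sorted((t.signaller, t.start_s) for t in tokens)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(random_streams(), st.sampled_from([(0.5, 1.0), (1.0, 2.0), (0.2, 2.5)]))
    def test_raising_threshold_never_increases_sequence_count(self, tokens, th):
        lo, hi = th
        assert len(segment_sequences(tokens, hi)) <= len(segment_sequences(tokens, lo))


class TestFilterComplete:
    def test_all_complete_identity(self):
        toks = stream_with_gaps([0.5, 2.0])
        seqs = segment_sequences(toks)
        kept, n = filter_complete(seqs)
        assert kept == seqs and n == 0

    def test_one_missing_duration_drops_whole_sequence(self):
        toks = [tok(0.0, 0.4), tok(0.8, None)]  # joined, second incomplete
        seqs = segment_sequences(toks)
        assert [s.size_n for s in seqs] == [2]
        kept, n = filter_complete(seqs)
        assert kept == [] and n == 1

    def test_empty_input(self):
        assert filter_complete([]) == ([], 0)


class TestLengthComposition:
    def test_single_mixed_sequence(self):
        toks = [tok(0.0, 0.4, gtype="A"), tok(0.8, 1.2, gtype="A"),
                tok(1.6, 2.0, gtype="B")]
        table = length_composition_table(segment_sequences(toks))
        row = table.rows[-1]
        assert (row.length, row.n_same_type, row.n_different_type, row.n_total) \
            == (3, 0, 1, 1)

    def test_length_one_has_no_composition(self):
        table = length_composition_table(segment_sequences([tok(0.0)]))
        assert table.rows[0].n_same_type is None

    def test_totals_consistency(self, study_sequences):
        table = length_composition_table(study_sequences)
        assert table.n_sequences == len(study_sequences)
        for r in table.rows:
            if r.length >= 2:
                assert r.n_same_type + r.n_different_type == r.n_total


class TestRepertoire:
    def test_counts_proportions_and_means(self):
        toks = [tok(i * 10.0, i * 10.0 + 1.0, gtype="A") for i in range(3)]
        toks.append(tok(100.0, 102.0, gtype="B"))
        rep = repertoire_summary(toks)
        assert [e.gesture_type for e in rep] == ["A", "B"]
        assert rep[0].proportion_p == pytest.approx(0.75)
        assert rep[1].proportion_p == pytest.approx(0.25)
        assert rep[0].mean_duration_s == pytest.approx(1.0)
        assert rep[1].mean_duration_s == pytest.approx(2.0)

    def test_proportions_sum_to_one(self, study_sequences):
        rep = repertoire_summary([t for s in study_sequences for t in s.tokens])
        assert sum(e.proportion_p for e in rep) == pytest.approx(1.0)
        assert len(rep) == 26
        cats = {"manual": 0, "whole_body": 0}
        for e in rep:
            cats[e.category] += 1
        assert cats["manual"] <= 21 and cats["whole_body"] <= 5

    def test_missing_duration_rejected(self):
        with pytest.raises(ValueError, match="unknown duration"):
            repertoire_summary([tok(0.0, None)])


class TestCompositionBySize:
    def test_all_loose(self):
        toks = stream_with_gaps([0.5, 2.0])
        out = composition_by_size(segment_sequences(toks))
        assert all(v["all_loose"] == 1.0 for v in out.values())

    def test_mixed_pair(self):
        toks = [tok(0.0, 0.4, form="fixed"), tok(0.8, 1.2, form="loose")]
        out = composition_by_size(segment_sequences(toks))
        assert out[2] == {"all_loose": 0.0, "all_fixed": 0.0, "mixed": 1.0}

    def test_fractions_sum_to_one(self, study_sequences):
        for size, fr in composition_by_size(study_sequences).items():
            assert sum(fr.values()) == pytest.approx(1.0)


class TestReadTokens:
    def test_round_trip(self, tmp_path, study_tokens):
        path = tmp_path / "tokens.csv"
        write_tokens_csv(study_tokens, path)
        back = read_tokens(path)
        assert len(back) == len(study_tokens)
        assert back[0].gesture_type == study_tokens[0].gesture_type
        assert back[0].duration_s == pytest.approx(study_tokens[0].duration_s)

    def test_blank_end_keeps_token_with_missing_duration(self, tmp_path):
        path = tmp_path / "t.csv"
        write_tokens_csv([tok(0.0, 0.4), tok(2.0, None)], path)
        toks = read_tokens(path)
        assert len(toks) == 2
        assert toks[1].duration_s is None

    def test_end_before_start_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        write_tokens_csv([tok(0.0, 0.4)], path)
        text = path.read_text().replace("0.400000", "-1.000000")
        path.write_text(text)
        with pytest.raises(TokenParseError, match="row 1"):
            read_tokens(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("signaller,start_s\nS01,0.0\n")
        with pytest.raises(TokenParseError, match="missing required column"):
            read_tokens(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_tokens(tmp_path / "nope.csv")

    def test_non_numeric_time_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        write_tokens_csv([tok(0.0, 0.4)], path)
        path.write_text(path.read_text().replace("0.000000", "abc"))
        with pytest.raises(TokenParseError, match="row 1"):
            read_tokens(path)
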