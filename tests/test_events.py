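"""Event-log reading, dash-sequence derivation, truncation and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import brute_force_rle, hunt_from_ids
from huntdiv.events import (
    Hunt,
    HuntFormatError,
    derive_dash_sequences,
    read_hunt,
    summarize,
    truncate,
    write_hunt,
)

id_lists = st.lists(st.sampled_from("ABCDE"), min_size=1, max_size=60)


def test_read_hunt_toy_file(tmp_path):
    p = tmp_path / "hunt.csv"
    p.write_text("time_s,individual,capture\n1,A,0\n2,A,1\n3,B,0\n")
    hunt = read_hunt(p)
    assert hunt.n_events == 3
    assert hunt.individuals == ["A", "B"]
    assert list(hunt.capture) == [False, True, False]


def test_read_hunt_roundtrip(tmp_path):
    p = tmp_path / "hunt.csv"
    p.write_text("time_s,individual,capture\n0.5,A,0\n2.25,B,1\n2.25,A,0\n7,C,0\n")
    hunt = read_hunt(p)
    q = tmp_path / "copy.csv"
    write_hunt(hunt, q)
    again = read_hunt(q)
    assert np.array_equal(hunt.time_s, again.time_s)
    assert list(hunt.individual_id) == list(again.individual_id)
    assert np.array_equal(hunt.capture, again.capture)


def test_read_hunt_shuffled_rows_equal_sorted(tmp_path):
    sorted_file = tmp_path / "sorted.csv"
    shuffled = tmp_path / "shuffled.csv"
    sorted_file.write_text("time_s,individual,capture\n1,A,0\n2,B,1\n3,A,0\n")
    shuffled.write_text("time_s,individual,capture\n3,A,0\n1,A,0\n2,B,1\n")
    a, b = read_hunt(sorted_file), read_hunt(shuffled)
    assert np.array_equal(a.time_s, b.time_s)
    assert list(a.individual_id) == list(b.individual_id)
    assert np.array_equal(a.capture, b.capture)


@pytest.mark.parametrize(
    "content, message",
    [
        ("time_s,individual,capture\n", "no events"),
        ("time_s,who,capture\n1,A,0\n", "individual"),
        ("time_s,individual,capture\n1,A,0\nx,B,0\n", "line 3"),
        ("time_s,individual,capture\n1,A,2\n", "capture"),
    ],
)
def test_read_hunt_format_errors(tmp_path, content, message):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(HuntFormatError, match=message):
        read_hunt(p)


def test_simultaneous_timestamps_keep_file_order(tmp_path):
    p = tmp_path / "ties.csv"
    p.write_text("time_s,individual,capture\n1,A,0\n1,B,0\n1,C,0\n")
    assert list(read_hunt(p).individual_id) == ["A", "B", "C"]


@pytest.mark.parametrize(
    "ids, expected",
    [
        (["A", "A", "B", "A"], [("A", 2), ("B", 1), ("A", 1)]),
        (["A", "A", "A"], [("A", 3)]),
        (["A"], [("A", 1)]),
    ],
)
def test_derive_sequences_examples(make_hunt, ids, expected):
    seqs = derive_dash_sequences(make_hunt(ids))
    assert [(s.individual_id, s.length) for s in seqs] == expected


@given(ids=id_lists)
def test_derive_sequences_matches_rle_oracle(ids):
    hunt = hunt_from_ids(ids)
    seqs = derive_dash_sequences(hunt)
    assert [(s.individual_id, s.length) for s in seqs] == brute_force_rle(ids)
    # the sequences partition the event list
    assert seqs[0].start_index == 0
    assert seqs[-1].end_index == hunt.n_events - 1
    for a, b in zip(seqs, seqs[1:]):
        assert b.start_index == a.end_index + 1
        assert a.individual_id != b.individual_id
    assert sum(s.length for s in seqs) == hunt.n_events


@given(ids=id_lists, caps=st.data())
def test_sequence_capture_conservation(ids, caps):
    captures = caps.draw(
        st.lists(st.booleans(), min_size=len(ids), max_size=len(ids))
    )
    hunt = hunt_from_ids(ids, captures=captures)
    seqs = derive_dash_sequences(hunt)
    assert sum(s.captures for s in seqs) == sum(captures)


def test_max_gap_splitter(make_hunt):
    hunt = make_hunt(["A", "A", "A"], times=[0.0, 1.0, 50.0])
    assert len(derive_dash_sequences(hunt)) == 1
    assert len(derive_dash_sequences(hunt, max_gap_s=10.0)) == 2


def test_truncate_beyond_duration_is_identity(make_hunt):
    hunt = make_hunt(["A", "B", "A"], times=[1.0, 2.0, 3.0])
    out = truncate(hunt, 99.0)
    assert out.n_events == 3
    assert list(out.individual_id) == ["A", "B", "A"]


def test_truncate_mid_sequence_rederives(make_hunt):
    # A A | B B B | A ; cutoff inside B's run keeps B truncated at last dash
    hunt = make_hunt(list("AABBBA"), times=[0, 1, 2, 3, 4, 5])
    out = truncate(hunt, 3.5)
    seqs = derive_dash_sequences(out)
    assert [(s.individual_id, s.length) for s in seqs] == [("A", 2), ("B", 2)]
    assert brute_force_rle(out.individual_id) == [("A", 2), ("B", 2)]


def test_truncate_errors(make_hunt):
    hunt = make_hunt(["A", "B"], times=[10.0, 20.0])
    with pytest.raises(ValueError, match="empty truncation"):
        truncate(hunt, 5.0)
    with pytest.raises(ValueError):
        truncate(hunt, 0.0)


def _hunt_with_totals(n_dashes: int, n_sequences: int) -> Hunt:
    """Alternating two-individual hunt with exact dash/sequence totals."""
    base, extra = divmod(n_dashes, n_sequences)
    lengths = [base + 1] * extra + [base] * (n_sequences - extra)
    ids = []
    for k, ln in enumerate(lengths):
        ids.extend(["A" if k % 2 == 0 else "B"] * ln)
    return hunt_from_ids(ids)


@pytest.mark.parametrize(
    "n_dashes, n_sequences, printed_mean",
    [(711, 297, 2.4), (350, 186, 1.9)],
)
def test_summarize_reproduces_printed_mean_lengths(n_dashes, n_sequences, printed_mean):
    s = summarize(_hunt_with_totals(n_dashes, n_sequences))
    assert s.n_dashes == n_dashes and s.n_sequences == n_sequences
    assert s.mean_sequence_length == pytest.approx(n_dashes / n_sequences)
    assert round(s.mean_sequence_length, 1) == printed_mean


def test_summarize_single_sequence_flags_undefined_se(make_hunt):
    s = summarize(make_hunt(["A"]))
    assert s.mean_sequence_length == 1.0
    assert s.se_sequence_length == 0.0
    assert not s.se_defined


def test_hunt_rejects_unsorted_times():
    with pytest.raises(ValueError):
        Hunt(
            time_s=np.array([2.0, 1.0]),
            individual_id=np.array(["A", "B"], dtype=object),
            capture=np.array([False, False]),
            duration_s=2.0,
        )
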