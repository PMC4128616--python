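"""ABIF and FASTA+QUAL round-trips, error handling, third-party readability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracepure import (AbifError, Read, TraceRecord, read_abif,
                       read_fasta_qual, to_read, write_abif, write_fasta_qual)


def random_record(rng: np.random.Generator, n_bases=None) -> TraceRecord:
    n = int(rng.integers(0, 40)) if n_bases is None else n_bases
    n_scans = 10 * n + 20
    channels = {b: rng.integers(0, 4000, n_scans) for b in "ACGT"}
    pos = np.sort(rng.choice(n_scans, size=n, replace=False)) if n else np.array([], int)
    return TraceRecord(
        channels=channels,
        channel_order="".join(rng.permutation(list("ACGT"))),
        peak_positions=pos,
        basecalls="".join(rng.choice(list("ACGTN"), n)),
        qualities=rng.integers(0, 94, n),
        name="rec-%d" % rng.integers(1000),
        instrument="unit test",
    )


def assert_records_equal(a: TraceRecord, b: TraceRecord):
    assert a.basecalls == b.basecalls
    assert np.array_equal(a.qualities, b.qualities)
    assert np.array_equal(a.peak_positions, b.peak_positions)
    for base in "ACGT":
        assert np.array_equal(a.channels[base], b.channels[base])
    assert a.channel_order == b.channel_order
    assert a.name == b.name and a.instrument == b.instrument


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_abif_round_trip(tmp_path, seed):
    rng = np.random.default_rng(seed)
    record = random_record(rng)
    path = tmp_path / "trace.ab1"
    write_abif(record, path)
    assert_records_equal(read_abif(path), record)


def test_abif_round_trip_empty_record(tmp_path):
    record = TraceRecord(channels={b: np.array([], int) for b in "ACGT"},
                         peak_positions=[], basecalls="", qualities=[])
    path = tmp_path / "empty.ab1"
    write_abif(record, path)
    back = read_abif(path)
    assert back.basecalls == "" and back.n_scans == 0


def test_biopython_reads_our_files(tmp_path):
    """Files we write are legible to an independent ABIF parser."""
    from Bio import SeqIO

    rng = np.random.default_rng(5)
    record = random_record(rng, n_bases=25)
    path = tmp_path / "trace.ab1"
    write_abif(record, path)
    bio = SeqIO.read(str(path), "abi")
    assert str(bio.seq) == record.basecalls
    assert bio.letter_annotations["phred_quality"] == list(record.qualities)


def test_bad_magic_rejected(tmp_path):
    path = tmp_path / "fake.ab1"
    path.write_bytes(b"FAKE" + b"\x00" * 200)
    with pytest.raises(AbifError, match="not an ABIF file"):
        read_abif(path)


def test_length_mismatch_rejected(tmp_path):
    """A file whose PCON is shorter than PBAS is reported corrupt."""
    rng = np.random.default_rng(6)
    record = random_record(rng, n_bases=10)
    path = tmp_path / "trace.ab1"
    write_abif(record, path)
    raw = bytearray(path.read_bytes())
    # shrink every PCON entry's element count and size by one byte
    idx = raw.find(b"PCON")
    while idx != -1:
        for field_off, delta in ((12, 1), (16, 1)):  # count, datasize
            off = idx + field_off
            val = int.from_bytes(raw[off:off + 4], "big") - delta
            raw[off:off + 4] = val.to_bytes(4, "big")
        idx = raw.find(b"PCON", idx + 4)
    path.write_bytes(bytes(raw))
    with pytest.raises(AbifError, match="corrupt trace"):
        read_abif(path)


def test_missing_mandatory_tag_rejected(tmp_path):
    rng = np.random.default_rng(7)
    record = random_record(rng, n_bases=5)
    path = tmp_path / "trace.ab1"
    write_abif(record, path)
    raw = path.read_bytes().replace(b"PLOC", b"XLOC")
    path.write_bytes(raw)
    with pytest.raises(AbifError, match="incomplete trace"):
        read_abif(path)


def test_invalid_record_rejected_before_writing(tmp_path):
    rng = np.random.default_rng(8)
    record = random_record(rng, n_bases=5)
    record.qualities[0] = 94  # above the printable Phred ceiling
    path = tmp_path / "trace.ab1"
    with pytest.raises(AbifError):
        write_abif(record, path)
    assert not path.exists()


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_round_trip_property(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    record = random_record(rng)
    path = tmp_path_factory.mktemp("abif") / "t.ab1"
    write_abif(record, path)
    assert_records_equal(read_abif(path), record)


# ---------------------------------------------------------------------------
# FASTA + QUAL

def test_fasta_qual_round_trip(tmp_path):
    reads = [Read("a", "ACGT", [40, 40, 40, 40]),
             Read("b", "GGNTA", [0, 10, 20, 30, 93])]
    fa, qu = tmp_path / "r.fasta", tmp_path / "r.qual"
    write_fasta_qual(reads, fa, qu)
    back = read_fasta_qual(fa, qu)
    assert [r.id for r in back] == ["a", "b"]
    assert back[0].sequence == "ACGT"
    assert np.array_equal(back[1].qualities, [0, 10, 20, 30, 93])


def test_fasta_qual_empty_files(tmp_path):
    fa, qu = tmp_path / "r.fasta", tmp_path / "r.qual"
    fa.write_text("")
    qu.write_text("")
    assert read_fasta_qual(fa, qu) == []


def test_fasta_qual_mismatch_rejected(tmp_path):
    reads = [Read("a", "ACGT", [40] * 4), Read("b", "GG", [10, 20])]
    fa, qu = tmp_path / "r.fasta", tmp_path / "r.qual"
    write_fasta_qual(reads, fa, tmp_path / "unused.qual")
    write_fasta_qual(reads[:1], tmp_path / "unused.fasta", qu)  # qual lacks 'b'
    with pytest.raises(ValueError, match="paired file mismatch"):
        read_fasta_qual(fa, qu)


def test_to_read_preserves_ambiguity_codes(pure_trace):
    record, _ = pure_trace
    read = to_read(record)
    assert read.sequence == record.basecalls
    assert np.array_equal(read.qualities, record.qualities)
    ny = Read("amb", "ANYT", [30, 2, 2, 30])
    assert ny.sequence == "ANYT"
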