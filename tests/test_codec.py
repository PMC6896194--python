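"""Codec: single-line data-unit encoding must be a lossless, atomic bijection."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqpipe.codec import (
    DEFAULT_SPLITTER,
    EncodedUnit,
    FastqFormatError,
    FastqRecord,
    MalformedUnitError,
    PairingError,
    ReadPair,
    decode_unit,
    encode_pair,
    encode_single,
    mates_match,
    pair_streams,
    read_fastq,
    to_aligner_text,
    validate_splitter,
    write_fastq,
)
from fqpipe.synth import GenSpec, generate_records

# --- strategies -------------------------------------------------------------

# printable ASCII minus whitespace concerns; identifiers/plus may carry spaces
_printable = st.text(
    alphabet=st.characters(min_codepoint=33, max_codepoint=126), min_size=0, max_size=20
)
_bases = st.text(alphabet="ACGTN", min_size=1, max_size=50)


@st.composite
def fastq_records(draw):
    bases = draw(_bases)
    qualities = draw(
        st.text(
            alphabet=st.characters(min_codepoint=33, max_codepoint=73),
            min_size=len(bases),
            max_size=len(bases),
        )
    )
    return FastqRecord(
        identifier="@" + draw(_printable),
        bases=bases,
        plus_line="+" + draw(_printable),
        qualities=qualities,
    )


@st.composite
def read_pairs(draw):
    return ReadPair(draw(fastq_records()), draw(fastq_records()))


# --- round trip -------------------------------------------------------------


@settings(max_examples=200, derandomize=True)
@given(read_pairs())
def test_pair_round_trip_property(pair):
    """decode(encode(pair)) reproduces the pair exactly for arbitrary content."""
    unit = encode_pair(pair)
    assert decode_unit(unit) == pair


@settings(max_examples=200, derandomize=True)
@given(fastq_records())
def test_single_round_trip_property(record):
    unit = encode_single(record)
    assert decode_unit(unit) == record


def test_round_trip_bulk_generated():
    """1,000 generated pairs survive encode/decode byte-exactly."""
    pairs = [ReadPair(a, b) for a, b in generate_records(GenSpec(n_pairs=1000, read_length=30, seed=3))]
    for pair in pairs:
        assert decode_unit(encode_pair(pair)) == pair


@pytest.mark.parametrize("id_style", ["slash", "casava"])
def test_encoded_shape(id_style):
    """Paired units carry exactly 7 splitters, single units 3, no line breaks."""
    (r1, r2), = generate_records(GenSpec(n_pairs=1, read_length=10, seed=4, id_style=id_style))
    paired = encode_pair(ReadPair(r1, r2))
    single = encode_single(r1)
    assert paired.line.count(DEFAULT_SPLITTER) == 7
    assert single.line.count(DEFAULT_SPLITTER) == 3
    assert "\n" not in paired.line and "\n" not in single.line
    fields = paired.line.split(DEFAULT_SPLITTER)
    assert fields == list(r1.lines() + r2.lines())


def test_encode_rejects_splitter_in_content():
    bad = FastqRecord("@r\x01x", "ACGT", "+", "IIII")
    with pytest.raises(FastqFormatError, match="splitter"):
        encode_single(bad)


@pytest.mark.parametrize("count", [0, 2, 5, 6, 8])
def test_decode_wrong_splitter_count(count):
    """Malformed units fail loudly, naming the observed splitter count."""
    line = DEFAULT_SPLITTER.join(["@a"] + ["x"] * count)
    with pytest.raises(MalformedUnitError, match=f"observed {count}"):
        decode_unit(line)


# --- atomicity under contiguous partitioning --------------------------------


def _all_compositions(n):
    """Every way to cut n lines into contiguous non-empty groups."""
    if n == 0:
        yield []
        return
    for mask in range(2 ** (n - 1)):
        cuts = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        yield [(cuts[j], cuts[j + 1]) for j in range(len(cuts) - 1)]


def test_atomicity_under_all_partitions():
    """Any contiguous grouping of encoded lines decodes to whole pairs whose
    union is the input.

    All compositions are enumerated exhaustively for n <= 10; for n = 20 every
    contiguous interval is checked instead, which covers every group any
    composition can produce.
    """
    for n in (1, 4, 10):
        pairs = [ReadPair(a, b) for a, b in generate_records(GenSpec(n_pairs=n, read_length=8, seed=n))]
        lines = [encode_pair(p).line for p in pairs]
        for groups in _all_compositions(n):
            decoded = []
            for lo, hi in groups:
                decoded.extend(decode_unit(line) for line in lines[lo:hi])
            assert decoded == pairs

    n = 20
    pairs = [ReadPair(a, b) for a, b in generate_records(GenSpec(n_pairs=n, read_length=8, seed=99))]
    lines = [encode_pair(p).line for p in pairs]
    for lo in range(n):
        for hi in range(lo + 1, n + 1):
            assert [decode_unit(line) for line in lines[lo:hi]] == pairs[lo:hi]


def test_line_conservation():
    """n input pairs yield exactly n encoded lines (independent line scan)."""
    pairs = [ReadPair(a, b) for a, b in generate_records(GenSpec(n_pairs=500, read_length=10, seed=7))]
    blob = "".join(encode_pair(p).line + "\n" for p in pairs)
    assert blob.count("\n") == 500
    assert len(blob.splitlines()) == 500


# --- splitter validation ----------------------------------------------------


def test_validate_splitter_on_generated_records():
    """Control byte 0x01 is safe on 1,000 generated records; 'A' is not."""
    records = [r for a, b in generate_records(GenSpec(n_pairs=500, read_length=20, seed=5)) for r in (a, b)]
    assert validate_splitter(records, "\x01") is None
    violation = validate_splitter(records, "A")
    assert violation is not None
    assert violation.field in ("identifier", "bases")


def test_validate_splitter_reports_first_offender():
    records = [
        FastqRecord("@ok", "ACGT", "+", "IIII"),
        FastqRecord("@bad\x01", "ACGT", "+", "IIII"),
    ]
    violation = validate_splitter(records, "\x01")
    assert violation.record_index == 1
    assert violation.field == "identifier"


def test_validate_splitter_rejects_newline():
    with pytest.raises(ValueError):
        validate_splitter([], "\n")


# --- pairing ----------------------------------------------------------------


def _rec(identifier):
    return FastqRecord(identifier, "ACGT", "+", "IIII")


def test_pair_streams_in_order():
    r1s = [_rec(f"@r{i}/1") for i in range(3)]
    r2s = [_rec(f"@r{i}/2") for i in range(3)]
    pairs = list(pair_streams(r1s, r2s, "strict"))
    assert [(p.r1.identifier, p.r2.identifier) for p in pairs] == [
        (f"@r{i}/1", f"@r{i}/2") for i in range(3)
    ]


def test_pair_streams_truncation():
    r1s = [_rec(f"@r{i}/1") for i in range(3)]
    r2s = [_rec(f"@r{i}/2") for i in range(2)]
    with pytest.raises(PairingError, match="r2 ran out of records at pair index 2"):
        list(pair_streams(r1s, r2s, "off"))


def test_pair_streams_casava_ids_accepted_strict():
    """Casava-style ids share the first token; strict mode accepts them."""
    pairs = list(
        pair_streams([_rec("@x 1:N:0:AC")], [_rec("@x 2:N:0:AC")], "strict")
    )
    assert len(pairs) == 1


def test_pair_streams_strict_vs_lenient_mismatch():
    r1s, r2s = [_rec("@a/1")], [_rec("@b/2")]
    with pytest.raises(PairingError, match="pair index 0"):
        list(pair_streams(r1s, r2s, "strict"))
    warnings_seen = []
    assert len(list(pair_streams(r1s, r2s, "lenient", warn=warnings_seen.append))) == 1
    assert len(warnings_seen) == 1
    assert list(pair_streams(r1s, r2s, "off", warn=warnings_seen.append)) and len(warnings_seen) == 1


@pytest.mark.parametrize(
    "id1,id2,expected",
    [
        ("@r/1", "@r/2", True),
        ("@x 1:N:0:AC", "@x 2:N:0:AC", True),
        ("@a/1", "@b/2", False),
        ("@same", "@same", True),
    ],
)
def test_mates_match_token_rule(id1, id2, expected):
    assert mates_match(_rec(id1), _rec(id2)) is expected


# --- interleaved output -----------------------------------------------------


def test_to_aligner_text_layout():
    (r1, r2), = generate_records(GenSpec(n_pairs=1, read_length=12, seed=8))
    unit = encode_pair(ReadPair(r1, r2))
    lines = list(to_aligner_text([unit]))
    assert len(lines) == 8
    assert lines[0] == r1.identifier and lines[4] == r2.identifier
    assert list(to_aligner_text([])) == []


def test_to_aligner_text_reparses_with_independent_reader():
    """Interleaved output is valid FASTQ with mates adjacent (Biopython oracle)."""
    from Bio import SeqIO

    n = 50
    pairs = [ReadPair(a, b) for a, b in generate_records(GenSpec(n_pairs=n, read_length=25, seed=9))]
    units = [encode_pair(p) for p in pairs]
    text = "".join(line + "\n" for line in to_aligner_text(units))
    parsed = list(SeqIO.parse(io.StringIO(text), "fastq"))
    assert len(parsed) == 2 * n
    for i, pair in enumerate(pairs):
        assert str(parsed[2 * i].seq) == pair.r1.bases
        assert str(parsed[2 * i + 1].seq) == pair.r2.bases
        # mates adjacent, sharing an identifier stem
        assert parsed[2 * i].id.split("/")[0] == parsed[2 * i + 1].id.split("/")[0]
        assert parsed[2 * i].id.endswith("/1") and parsed[2 * i + 1].id.endswith("/2")


# --- file I/O ---------------------------------------------------------------


def test_read_fastq_round_trip(tmp_path):
    records = [r for a, b in generate_records(GenSpec(n_pairs=20, read_length=15, seed=10)) for r in (a, b)]
    path = tmp_path / "x.fastq"
    assert write_fastq(records, path) == 40
    assert list(read_fastq(path)) == records


def test_read_fastq_gzip(tmp_path):
    records = [a for a, _ in generate_records(GenSpec(n_pairs=5, read_length=15, seed=10))]
    path = tmp_path / "x.fastq.gz"
    write_fastq(records, path)
    assert list(read_fastq(path)) == records


def test_read_fastq_rejects_truncation(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r\nACGT\n+\n")
    with pytest.raises(FastqFormatError, match="truncated"):
        list(read_fastq(path))


def test_read_fastq_rejects_wrapped_sequence(tmp_path):
    # multi-line ("wrapped") FASTQ is rejected, not re-flowed
    path = tmp_path / "wrapped.fastq"
    path.write_text("@r\nACGT\nACGT\n+\nIIIIIIII\n@s\nAC\n+\nII\n")
    with pytest.raises(FastqFormatError):
        list(read_fastq(path))
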