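"""Record-atomic single-line encoding of FASTQ reads and mate pairs.

A 4-line FASTQ read (identifier, bases, "+" line, qualities) — or the two
mates of a paired-end read, eight lines in total — is merged into one text
line by replacing the internal line breaks with a *splitter* byte that does
not occur in well-formed FASTQ.  Because the whole data unit occupies a
single line, any line-based partitioning of the encoded file keeps reads
intact and mates together; decoding simply replaces the splitter with line
breaks again.

The default splitter is the control byte ``0x01``: Phred+33 quality strings
and sane identifiers only contain printable ASCII (33-126), so a control
byte cannot occur in valid input.  ``validate_splitter`` scans for it anyway
when the caller wants a guarantee.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Union

#: Control byte outside the printable ASCII range used by FASTQ content.
DEFAULT_SPLITTER = "\x01"

PairCheckMode = Literal["strict", "lenient", "off"]


class FastqFormatError(ValueError):
    """A record violates the 4-line FASTQ dialect."""


class MalformedUnitError(ValueError):
    """An encoded line does not contain the expected number of splitters."""


class PairingError(ValueError):
    """Mate streams disagree: identity mismatch or unequal lengths."""


@dataclass(frozen=True, slots=True)
class FastqRecord:
    """One sequencing read: the four lines of a FASTQ record, newline-stripped."""

    identifier: str
    bases: str
    plus_line: str
    qualities: str

    def validate(self, splitter: str | None = None) -> None:
        if not self.identifier.startswith("@"):
            raise FastqFormatError(f"identifier must start with '@': {self.identifier!r}")
        if not self.plus_line.startswith("+"):
            raise FastqFormatError(f"plus line must start with '+': {self.plus_line!r}")
        if len(self.bases) != len(self.qualities):
            raise FastqFormatError(
                f"bases/qualities length mismatch ({len(self.bases)} != {len(self.qualities)}) "
                f"for {self.identifier!r}"
            )
        for name, field in self.fields():
            if "\n" in field or "\r" in field:
                raise FastqFormatError(f"line break inside field {name!r} of {self.identifier!r}")
            if splitter is not None and splitter in field:
                raise FastqFormatError(
                    f"splitter byte {splitter!r} inside field {name!r} of {self.identifier!r}"
                )

    def fields(self) -> tuple[tuple[str, str], ...]:
        return (
            ("identifier", self.identifier),
            ("bases", self.bases),
            ("plus_line", self.plus_line),
            ("qualities", self.qualities),
        )

    def lines(self) -> tuple[str, str, str, str]:
        return (self.identifier, self.bases, self.plus_line, self.qualities)


@dataclass(frozen=True, slots=True)
class ReadPair:
    """Two mate records forming one atomic data unit."""

    r1: FastqRecord
    r2: FastqRecord


@dataclass(frozen=True, slots=True)
class EncodedUnit:
    """One text line holding a whole data unit.

    ``line`` contains exactly 7 splitter occurrences in paired mode
    (8 fields) or 3 in single mode (4 fields) and no line breaks.
    """

    line: str
    mode: Literal["paired", "single"]


@dataclass(frozen=True, slots=True)
class SplitterViolation:
    """First occurrence of the splitter byte inside record content."""

    record_index: int
    field: str
    identifier: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"splitter byte found in field {self.field!r} of record "
            f"{self.record_index} ({self.identifier!r})"
        )


def _open_text(path: Union[str, Path], mode: str = "rt") -> io.TextIOBase:
    """Open plain or gzip text transparently, preserving exact characters."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8", newline="\n")  # type: ignore[return-value]
    return open(path, mode, encoding="utf-8", newline="\n")


def read_fastq(path: Union[str, Path]) -> Iterator[FastqRecord]:
    """Stream 4-line FASTQ records from a plain or gzipped file.

    The 4-line dialect is enforced: records with wrapped sequence lines are
    rejected rather than re-flowed, and a trailing partial record raises
    :class:`FastqFormatError`.  Field text is preserved byte-for-byte
    (identifier and plus-line comments included), which generic FASTQ
    parsers that normalise records do not guarantee.
    """
    with _open_text(path) as handle:
        index = 0
        while True:
            head = handle.readline()
            if head == "":
                return
            rest = [handle.readline() for _ in range(3)]
            if any(line == "" for line in rest):
                raise FastqFormatError(f"truncated record at index {index} in {path}")
            record = FastqRecord(
                identifier=head.rstrip("\n"),
                bases=rest[0].rstrip("\n"),
                plus_line=rest[1].rstrip("\n"),
                qualities=rest[2].rstrip("\n"),
            )
            try:
                record.validate()
            except FastqFormatError as exc:
                raise FastqFormatError(f"record {index} in {path}: {exc}") from exc
            yield record
            index += 1


def write_fastq(records: Iterable[FastqRecord], path: Union[str, Path]) -> int:
    """Write records as 4-line FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for record in records:
            handle.write("\n".join(record.lines()) + "\n")
            n += 1
    return n


def validate_splitter(
    records: Iterable[FastqRecord], splitter: str = DEFAULT_SPLITTER
) -> SplitterViolation | None:
    """Scan record content for the splitter byte.

    Returns ``None`` when the splitter is safe, otherwise a
    :class:`SplitterViolation` naming the first offending record and field.
    A report (not an exception) lets callers pick a different splitter.
    """
    _check_splitter_byte(splitter)
    for index, record in enumerate(records):
        for name, field in record.fields():
            if splitter in field:
                return SplitterViolation(record_index=index, field=name, identifier=record.identifier)
    return None


def _check_splitter_byte(splitter: str) -> None:
    if len(splitter) != 1:
        raise ValueError(f"splitter must be a single character, got {splitter!r}")
    if splitter in ("\n", "\r"):
        raise ValueError("splitter must not be a line break")


def encode_pair(pair: ReadPair, splitter: str = DEFAULT_SPLITTER) -> EncodedUnit:
    """Merge a mate pair into one line: r1's four fields then r2's four.

    The field order yields smart-pairing (mates adjacent, R1 first) when the
    unit is decoded back to interleaved FASTQ.
    """
    _check_splitter_byte(splitter)
    pair.r1.validate(splitter)
    pair.r2.validate(splitter)
    line = splitter.join(pair.r1.lines() + pair.r2.lines())
    return EncodedUnit(line=line, mode="paired")


def encode_single(record: FastqRecord, splitter: str = DEFAULT_SPLITTER) -> EncodedUnit:
    """Merge a single-end read into one line with 3 splitter occurrences."""
    _check_splitter_byte(splitter)
    record.validate(splitter)
    return EncodedUnit(line=splitter.join(record.lines()), mode="single")


def decode_unit(
    unit: Union[EncodedUnit, str], splitter: str = DEFAULT_SPLITTER
) -> Union[ReadPair, FastqRecord]:
    """Exact inverse of :func:`encode_pair` / :func:`encode_single`.

    Accepts an :class:`EncodedUnit` or a raw line.  The splitter count
    decides the mode: 7 occurrences decode to a :class:`ReadPair`, 3 to a
    :class:`FastqRecord`; anything else raises :class:`MalformedUnitError`
    naming the observed count.
    """
    _check_splitter_byte(splitter)
    line = unit.line if isinstance(unit, EncodedUnit) else unit
    fields = line.split(splitter)
    count = len(fields) - 1
    if count == 7:
        r1 = FastqRecord(*fields[:4])
        r2 = FastqRecord(*fields[4:])
        r1.validate()
        r2.validate()
        return ReadPair(r1=r1, r2=r2)
    if count == 3:
        record = FastqRecord(*fields)
        record.validate()
        return record
    raise MalformedUnitError(
        f"expected 7 (paired) or 3 (single) splitter occurrences, observed {count}"
    )


def _id_token(identifier: str) -> str:
    """Mate-comparison key: first whitespace token, trailing /1 or /2 stripped."""
    token = identifier.split(None, 1)[0] if identifier.split() else identifier
    if token.endswith(("/1", "/2")):
        token = token[:-2]
    return token


def mates_match(r1: FastqRecord, r2: FastqRecord) -> bool:
    """True when the mate identifiers agree up to the mate-distinguishing part.

    Covers the legacy ``/1``/``/2`` suffix style and the Casava-1.8 style
    where the first token is identical and the comment differs.
    """
    return _id_token(r1.identifier) == _id_token(r2.identifier)


def pair_streams(
    r1_source: Iterable[FastqRecord],
    r2_source: Iterable[FastqRecord],
    check_mode: PairCheckMode = "lenient",
    warn: "callable | None" = None,
) -> Iterator[ReadPair]:
    """Zip two mate streams positionally into :class:`ReadPair` values.

    The i-th pair is (i-th record of r1, i-th record of r2).  Identity
    checking per ``check_mode``: ``strict`` raises :class:`PairingError` on a
    mismatch, ``lenient`` reports it through ``warn`` (default: a module
    logger) and continues, ``off`` skips the check.  Unequal stream lengths
    always raise, naming the side that ran short.
    """
    if check_mode not in ("strict", "lenient", "off"):
        raise ValueError(f"unknown check_mode {check_mode!r}")
    if warn is None:
        import logging

        warn = logging.getLogger(__name__).warning
    it1, it2 = iter(r1_source), iter(r2_source)
    index = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            short = "r1" if rec1 is None else "r2"
            raise PairingError(f"stream {short} ran out of records at pair index {index}")
        if check_mode != "off" and not mates_match(rec1, rec2):
            message = (
                f"mate identifiers disagree at pair index {index}: "
                f"{rec1.identifier!r} vs {rec2.identifier!r}"
            )
            if check_mode == "strict":
                raise PairingError(message)
            warn(message)
        yield ReadPair(r1=rec1, r2=rec2)
        index += 1


def to_aligner_text(
    units: Iterable[Union[EncodedUnit, str]], splitter: str = DEFAULT_SPLITTER
) -> Iterator[str]:
    """Decode units to interleaved FASTQ lines (no trailing newlines).

    Each paired unit emits r1's four lines then r2's four — the smart-pairing
    convention expected by ``bwa mem -p`` — and each single unit emits four
    lines.  The concatenation is valid FASTQ.
    """
    for unit in units:
        decoded = decode_unit(unit, splitter)
        if isinstance(decoded, ReadPair):
            yield from decoded.r1.lines()
            yield from decoded.r2.lines()
        else:
            yield from decoded.lines()


def read_units(path: Union[str, Path], mode: Literal["paired", "single"] = "paired") -> Iterator[EncodedUnit]:
    """Stream encoded units from a one-unit-per-line file."""
    with _open_text(path) as handle:
        for line in handle:
            yield EncodedUnit(line=line.rstrip("\n"), mode=mode)
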