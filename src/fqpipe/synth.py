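"""Seeded synthetic paired-end FASTQ generators and defect injection.

The generator stands in for real short-read extracts so every other module
is testable offline: 4-line records, uniform random ACGT bases, Phred+33
quality strings, and mate identifiers that agree up to the mate-
distinguishing part, in either the legacy ``/1``/``/2`` suffix style or the
Casava-1.8 comment style.  It emulates the *shape* of sequencing data (read
count, read length, identifier dialects), not error models or genome
content.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Union

from fqpipe.codec import FastqRecord, _open_text

IdStyle = Literal["slash", "casava"]
QualitySpan = Literal["uniform_I", "full_printable"]

Defect = Literal["id_mismatch", "truncated_record", "splitter_in_quality"]


@dataclass(slots=True)
class GenSpec:
    """Shape of the synthetic dataset.

    Defaults mirror a small short-read extract: 100 bp reads with uniform
    high quality.  ``full_printable`` draws qualities across the whole
    printable Phred+33 span instead.
    """

    n_pairs: int = 1000
    read_length: int = 100
    seed: int = 0
    id_style: IdStyle = "slash"
    quality_span: QualitySpan = "uniform_I"

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError(f"n_pairs must be >= 0, got {self.n_pairs}")
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")


@dataclass(slots=True)
class DefectInfo:
    """Machine-checkable location of an injected defect."""

    kind: Defect
    pair_index: int
    file: Literal["r1", "r2"]


_BASES = "ACGT"
# Printable Phred+33 quality range actually emitted by instruments ('!'..'I').
_QUAL_LO, _QUAL_HI = 33, 73


def _identifiers(spec: GenSpec, index: int) -> tuple[str, str]:
    stem = f"@sim.{spec.seed}.{index}"
    if spec.id_style == "slash":
        return f"{stem}/1", f"{stem}/2"
    return f"{stem} 1:N:0:ACGTACGT", f"{stem} 2:N:0:ACGTACGT"


def _make_record(rng: random.Random, identifier: str, spec: GenSpec) -> FastqRecord:
    bases = "".join(rng.choice(_BASES) for _ in range(spec.read_length))
    if spec.quality_span == "uniform_I":
        qualities = "I" * spec.read_length
    else:
        qualities = "".join(chr(rng.randint(_QUAL_LO, _QUAL_HI)) for _ in range(spec.read_length))
    return FastqRecord(identifier, bases, "+", qualities)


def generate_records(spec: GenSpec) -> list[tuple[FastqRecord, FastqRecord]]:
    """Deterministic in-memory mate pairs for the given spec."""
    rng = random.Random(spec.seed)
    pairs = []
    for i in range(spec.n_pairs):
        id1, id2 = _identifiers(spec, i)
        pairs.append((_make_record(rng, id1, spec), _make_record(rng, id2, spec)))
    return pairs


def generate_pairs(spec: GenSpec, out_prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Write ``<prefix>_1.fastq`` and ``<prefix>_2.fastq``; deterministic per seed."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    path1 = out_prefix.with_name(out_prefix.name + "_1.fastq")
    path2 = out_prefix.with_name(out_prefix.name + "_2.fastq")
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for rec1, rec2 in generate_records(spec):
            f1.write("\n".join(rec1.lines()) + "\n")
            f2.write("\n".join(rec2.lines()) + "\n")
    return path1, path2


def generate_corrupt(
    spec: GenSpec, defect: Defect, out_prefix: Union[str, Path]
) -> tuple[Path, Path, DefectInfo]:
    """Generate a pair of files carrying exactly one seeded defect.

    * ``id_mismatch`` — one r2 identifier stem is altered, so strict pairing
      fails at the recorded index.
    * ``truncated_record`` — the last record of r2 loses its quality line.
    * ``splitter_in_quality`` — one quality character of r2 is replaced by
      the 0x01 control byte, so splitter validation reports that record.
    """
    if spec.n_pairs < 1:
        raise ValueError("need at least one pair to corrupt")
    rng = random.Random(spec.seed ^ 0x5EED)
    target = rng.randrange(spec.n_pairs) if defect != "truncated_record" else spec.n_pairs - 1
    info = DefectInfo(kind=defect, pair_index=target, file="r2")

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    path1 = out_prefix.with_name(out_prefix.name + "_1.fastq")
    path2 = out_prefix.with_name(out_prefix.name + "_2.fastq")
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for i, (rec1, rec2) in enumerate(generate_records(spec)):
            f1.write("\n".join(rec1.lines()) + "\n")
            if i != target:
                f2.write("\n".join(rec2.lines()) + "\n")
                continue
            if defect == "id_mismatch":
                broken = FastqRecord(
                    rec2.identifier.replace("@sim", "@MISMATCH", 1),
                    rec2.bases,
                    rec2.plus_line,
                    rec2.qualities,
                )
                f2.write("\n".join(broken.lines()) + "\n")
            elif defect == "truncated_record":
                f2.write("\n".join(rec2.lines()[:3]) + "\n")
            elif defect == "splitter_in_quality":
                qualities = "\x01" + rec2.qualities[1:]
                f2.write("\n".join((rec2.identifier, rec2.bases, rec2.plus_line, qualities)) + "\n")
            else:
                raise ValueError(f"unknown defect {defect!r}")
    return path1, path2, info
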