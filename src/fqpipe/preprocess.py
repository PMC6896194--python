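"""Pre-processing: raw paired-end FASTQ -> encoded-unit file.

Two execution paths produce byte-identical output:

* ``run_serial`` — read, encode and write one chunk at a time in a single
  thread; the baseline.
* ``run_pipelined`` — the 3-stage pipeline (load -> transform -> write)
  realised as four concurrently-executing workers in paired-end mode (two
  loaders, one per file, because loading both files shares the same disk
  channel and so counts as a single pipeline stage), or three workers in
  single-end mode.  Workers are connected by bounded queues carrying chunks
  of records, so memory stays O(chunk_size) under backpressure.

With the pipeline's 3 stages bound to independent hardware channels (disk
read, CPU, write/upload), the ideal speedup is the pipeline depth: at most
3x.  ``measure_pipeline_speedup`` measures the realised ratio; per-stage
delay injection (``stage_delays``) lets tests emulate stage-balanced I/O
cost deterministically.
"""

from __future__ import annotations

import os
import queue
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterator, Literal, Optional, Union

from fqpipe.codec import (
    DEFAULT_SPLITTER,
    FastqRecord,
    PairCheckMode,
    PairingError,
    ReadPair,
    _open_text,
    encode_pair,
    encode_single,
    mates_match,
    read_fastq,
)

ENCODED_FILENAME = "encoded.units"

#: In-flight chunks per queue link; bounds memory while keeping stages busy.
_BUFFER_CHUNKS = 4


@dataclass(slots=True)
class StageDelays:
    """Injected per-chunk sleep (seconds) emulating stage work in each channel."""

    load: float = 0.0
    transform: float = 0.0
    write: float = 0.0


@dataclass(slots=True)
class PreprocessConfig:
    splitter: str = DEFAULT_SPLITTER
    chunk_size: int = 10_000
    pair_check: PairCheckMode = "lenient"
    stage_delays: StageDelays = field(default_factory=StageDelays)
    output_name: str = ENCODED_FILENAME


@dataclass(slots=True)
class StageTiming:
    """Busy time of one pipeline stage, excluding waits on queue hand-offs."""

    stage_name: Literal["load", "transform", "write"]
    busy_time: float
    items_processed: int


@dataclass(slots=True)
class PreprocessResult:
    units_written: int
    wall_time: float
    mode: Literal["serial", "pipelined"]
    stage_timings: list[StageTiming]
    output_path: Path

    def to_dict(self) -> dict:
        return {
            "units_written": self.units_written,
            "wall_time": self.wall_time,
            "mode": self.mode,
            "output_path": str(self.output_path),
            "stage_timings": [
                {
                    "stage_name": t.stage_name,
                    "busy_time": t.busy_time,
                    "items_processed": t.items_processed,
                }
                for t in self.stage_timings
            ],
        }


class PreprocessError(RuntimeError):
    """A worker failed; carries the originating stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pre-processing failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _chunked(records: Iterator[FastqRecord], size: int) -> Iterator[list[FastqRecord]]:
    chunk: list[FastqRecord] = []
    for record in records:
        chunk.append(record)
        if len(chunk) == size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def _encode_chunk(
    chunk1: list[FastqRecord],
    chunk2: Optional[list[FastqRecord]],
    config: PreprocessConfig,
    base_index: int,
) -> list[str]:
    """Encode one chunk of records (paired when chunk2 is given) to unit lines."""
    if chunk2 is None:
        return [encode_single(rec, config.splitter).line for rec in chunk1]
    if len(chunk1) != len(chunk2):
        short = "r2" if len(chunk2) < len(chunk1) else "r1"
        raise PairingError(
            f"stream {short} ran out of records at pair index {base_index + min(len(chunk1), len(chunk2))}"
        )
    lines = []
    for offset, (rec1, rec2) in enumerate(zip(chunk1, chunk2)):
        if config.pair_check != "off" and not mates_match(rec1, rec2):
            message = (
                f"mate identifiers disagree at pair index {base_index + offset}: "
                f"{rec1.identifier!r} vs {rec2.identifier!r}"
            )
            if config.pair_check == "strict":
                raise PairingError(message)
            import logging

            logging.getLogger(__name__).warning(message)
        lines.append(encode_pair(ReadPair(rec1, rec2), config.splitter).line)
    return lines


def _prepare_sink(sink: Union[str, Path], config: PreprocessConfig) -> tuple[Path, Path]:
    sink = Path(sink)
    sink.mkdir(parents=True, exist_ok=True)
    out_path = sink / config.output_name
    tmp_path = sink / f".{config.output_name}.inprogress"
    return out_path, tmp_path


def run_serial(
    r1_path: Union[str, Path],
    r2_path: Optional[Union[str, Path]],
    sink: Union[str, Path],
    config: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Baseline single-threaded pre-processing.

    Writes the canonical encoding of the input pairs, in order, to
    ``sink/encoded.units`` (written under a temporary name and renamed on
    success, so a complete file is an atomic signal).
    """
    config = config or PreprocessConfig()
    out_path, tmp_path = _prepare_sink(sink, config)
    delays = config.stage_delays
    busy = {"load": 0.0, "transform": 0.0, "write": 0.0}
    loaded = transformed = written = 0

    start = time.perf_counter()
    try:
        with _open_text(tmp_path, "wt") as out:
            reader1 = _chunked(read_fastq(r1_path), config.chunk_size)
            reader2 = _chunked(read_fastq(r2_path), config.chunk_size) if r2_path else None
            base_index = 0
            while True:
                t0 = time.perf_counter()
                chunk1 = next(reader1, None)
                chunk2 = next(reader2, None) if reader2 is not None else None
                if chunk1 is None and chunk2 is None:
                    break
                if chunk1 is None or (reader2 is not None and chunk2 is None):
                    short = "r1" if chunk1 is None else "r2"
                    raise PairingError(f"stream {short} ran out of records at pair index {base_index}")
                if delays.load:
                    time.sleep(delays.load)
                loaded += len(chunk1) + (len(chunk2) if chunk2 else 0)
                busy["load"] += time.perf_counter() - t0

                t0 = time.perf_counter()
                lines = _encode_chunk(chunk1, chunk2, config, base_index)
                if delays.transform:
                    time.sleep(delays.transform)
                transformed += len(lines)
                busy["transform"] += time.perf_counter() - t0

                t0 = time.perf_counter()
                out.write("".join(line + "\n" for line in lines))
                if delays.write:
                    time.sleep(delays.write)
                written += len(lines)
                busy["write"] += time.perf_counter() - t0
                base_index += len(lines)
        os.replace(tmp_path, out_path)
    except BaseException:
        tmp_path.unlink(missing_ok=True)
        raise
    wall = max(time.perf_counter() - start, 1e-9)
    timings = [
        StageTiming("load", busy["load"], loaded),
        StageTiming("transform", busy["transform"], transformed),
        StageTiming("write", busy["write"], written),
    ]
    return PreprocessResult(written, wall, "serial", timings, out_path)


class _Abort(Exception):
    """Internal: another worker failed, unwind quietly."""


class _Pipeline:
    """Shared failure flag plus abort-aware bounded queue hand-offs."""

    def __init__(self) -> None:
        self.failed = threading.Event()
        self.error: tuple[str, BaseException] | None = None
        self.lock = threading.Lock()

    def fail(self, stage: str, exc: BaseException) -> None:
        with self.lock:
            if self.error is None:
                self.error = (stage, exc)
        self.failed.set()

    def put(self, q: queue.Queue, item) -> None:
        while True:
            if self.failed.is_set():
                raise _Abort
            try:
                q.put(item, timeout=0.05)
                return
            except queue.Full:
                continue

    def get(self, q: queue.Queue):
        while True:
            if self.failed.is_set():
                raise _Abort
            try:
                return q.get(timeout=0.05)
            except queue.Empty:
                continue


def run_pipelined(
    r1_path: Union[str, Path],
    r2_path: Optional[Union[str, Path]],
    sink: Union[str, Path],
    config: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Pipelined pre-processing; output byte-identical to :func:`run_serial`.

    Topology (paired-end): two loader workers, one per input file, feed one
    transformer which feeds one writer — four workers realising three
    pipeline stages.  Single-end drops the second loader.  A failure in any
    worker aborts the whole run and re-raises the originating stage's error;
    no partially-written file is left under the final name.
    """
    config = config or PreprocessConfig()
    out_path, tmp_path = _prepare_sink(sink, config)
    delays = config.stage_delays
    paired = r2_path is not None
    pipe = _Pipeline()

    q1: queue.Queue = queue.Queue(maxsize=_BUFFER_CHUNKS)
    q2: queue.Queue = queue.Queue(maxsize=_BUFFER_CHUNKS) if paired else None  # type: ignore[assignment]
    q_out: queue.Queue = queue.Queue(maxsize=_BUFFER_CHUNKS)

    busy = {"load": 0.0, "transform": 0.0, "write": 0.0}
    counts = {"load": 0, "transform": 0, "write": 0}
    busy_lock = threading.Lock()

    def account(stage: str, seconds: float, items: int) -> None:
        with busy_lock:
            busy[stage] += seconds
            counts[stage] += items

    def loader(path, out_q: queue.Queue) -> None:
        try:
            for chunk in _chunked(read_fastq(path), config.chunk_size):
                t0 = time.perf_counter()
                if delays.load:
                    time.sleep(delays.load)
                account("load", time.perf_counter() - t0, len(chunk))
                pipe.put(out_q, chunk)
            pipe.put(out_q, None)
        except _Abort:
            pass
        except BaseException as exc:
            pipe.fail("load", exc)

    def transformer() -> None:
        base_index = 0
        try:
            while True:
                chunk1 = pipe.get(q1)
                chunk2 = pipe.get(q2) if paired else None
                if chunk1 is None and (not paired or chunk2 is None):
                    pipe.put(q_out, None)
                    return
                if chunk1 is None or (paired and chunk2 is None):
                    short = "r1" if chunk1 is None else "r2"
                    raise PairingError(
                        f"stream {short} ran out of records at pair index {base_index}"
                    )
                t0 = time.perf_counter()
                lines = _encode_chunk(chunk1, chunk2, config, base_index)
                if delays.transform:
                    time.sleep(delays.transform)
                account("transform", time.perf_counter() - t0, len(lines))
                base_index += len(lines)
                pipe.put(q_out, lines)
        except _Abort:
            pass
        except BaseException as exc:
            pipe.fail("transform", exc)

    def writer() -> None:
        try:
            with _open_text(tmp_path, "wt") as out:
                while True:
                    lines = pipe.get(q_out)
                    if lines is None:
                        return
                    t0 = time.perf_counter()
                    out.write("".join(line + "\n" for line in lines))
                    if delays.write:
                        time.sleep(delays.write)
                    account("write", time.perf_counter() - t0, len(lines))
        except _Abort:
            pass
        except BaseException as exc:
            pipe.fail("write", exc)

    workers = [threading.Thread(target=loader, args=(r1_path, q1), name="fqpipe-load-r1")]
    if paired:
        workers.append(threading.Thread(target=loader, args=(r2_path, q2), name="fqpipe-load-r2"))
    workers.append(threading.Thread(target=transformer, name="fqpipe-transform"))
    workers.append(threading.Thread(target=writer, name="fqpipe-write"))

    start = time.perf_counter()
    for worker in workers:
        worker.start()
    for worker in workers:
        worker.join()
    wall = max(time.perf_counter() - start, 1e-9)

    if pipe.error is not None:
        tmp_path.unlink(missing_ok=True)
        stage, cause = pipe.error
        raise PreprocessError(stage, cause) from cause
    os.replace(tmp_path, out_path)

    timings = [
        StageTiming("load", busy["load"], counts["load"]),
        StageTiming("transform", busy["transform"], counts["transform"]),
        StageTiming("write", busy["write"], counts["write"]),
    ]
    return PreprocessResult(counts["write"], wall, "pipelined", timings, out_path)


def measure_pipeline_speedup(
    r1_path: Union[str, Path],
    r2_path: Optional[Union[str, Path]],
    config: PreprocessConfig | None = None,
    repetitions: int = 5,
    workdir: Optional[Union[str, Path]] = None,
) -> float:
    """Median over repetitions of wall_serial / wall_pipelined.

    Each repetition runs both paths on the same input into throwaway sinks.
    The ideal pipeline bound caps the expectation at the stage count (3).
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    import tempfile

    config = config or PreprocessConfig()
    ratios = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for rep in range(repetitions):
            serial = run_serial(r1_path, r2_path, Path(tmp) / f"serial-{rep}", config)
            pipelined = run_pipelined(r1_path, r2_path, Path(tmp) / f"pipe-{rep}", config)
            ratios.append(serial.wall_time / pipelined.wall_time)
    return median(ratios)
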