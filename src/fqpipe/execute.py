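"""Main computation: partition encoded units and pipe them through an aligner.

The encoded-unit file is split into ``tasks`` contiguous, balanced line
blocks (sizes differ by at most one).  Because every line is a whole data
unit, no block boundary can break a read or separate mates.  Each block is
decoded on the fly to interleaved FASTQ and streamed into an external
command's standard input; the command's standard output is streamed into a
per-partition ``part-NNNNN.sam`` file in the sink.  Read data never touches
an intermediate file — decoding happens in memory, feeding the child's pipe.

The executor is aligner-agnostic: the command template gets a ``{threads}``
placeholder substituted and nothing else is parsed, so it runs real
``bwa mem -p -t {threads} ref.fa -`` as readily as the bundled mock aligner
or any other single-node map-pattern program.  Part outputs are never
merged; downstream consumers take the partitioned files as-is.
"""

from __future__ import annotations

import shlex
import subprocess
import sys
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

from fqpipe.codec import DEFAULT_SPLITTER, EncodedUnit, read_units, to_aligner_text
from fqpipe.metrics import PerfReport, throughput

SUCCESS_MARKER = "_SUCCESS"

#: Mock-aligner invocation resolved through the running interpreter, so the
#: default works without relying on console-script PATH placement.
DEFAULT_COMMAND = f"{shlex.quote(sys.executable)} -m fqpipe.mock_aligner --threads {{threads}}"


@dataclass(slots=True)
class RunConfig:
    """Executor configuration; defaults follow the best-performing grid cell
    on a 32-logical-core node: 4 concurrent tasks of 8 aligner threads."""

    tasks: int = 4
    threads: int = 8
    command_template: str = DEFAULT_COMMAND
    splitter: str = DEFAULT_SPLITTER
    sink: Union[str, Path] = "."
    mode: Literal["paired", "single"] = "paired"

    def __post_init__(self) -> None:
        if self.tasks < 1:
            raise ValueError(f"tasks must be >= 1, got {self.tasks}")
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")
        if not self.command_template.strip():
            raise ValueError("command template must be non-empty")

    def render_command(self) -> list[str]:
        rendered = self.command_template.format(threads=self.threads)
        argv = shlex.split(rendered)
        if not argv:
            raise ValueError("command template rendered to an empty command")
        return argv


@dataclass(slots=True)
class Partition:
    """One contiguous block of encoded units, 0-indexed in input order."""

    index: int
    units: list[EncodedUnit]


@dataclass(slots=True)
class TaskResult:
    partition_index: int
    records_in: int
    output_lines: int
    exit_status: int
    wall_time: float
    output_path: Path | None = None
    stderr_tail: str = ""

    @property
    def ok(self) -> bool:
        return self.exit_status == 0


class TaskFailure(RuntimeError):
    """A child command failed; carries its exit status and stderr tail."""

    def __init__(self, result: TaskResult):
        super().__init__(
            f"task {result.partition_index} exited with status {result.exit_status}"
            + (f"; stderr tail:\n{result.stderr_tail}" if result.stderr_tail else "")
        )
        self.result = result


def partition_lines(
    encoded_path: Union[str, Path],
    tasks: int,
    mode: Literal["paired", "single"] = "paired",
) -> list[Partition]:
    """Split the encoded file into ``tasks`` contiguous balanced blocks.

    Block sizes differ by at most 1 and their concatenation reproduces the
    input line sequence.  When ``tasks`` exceeds the line count the surplus
    partitions are simply empty.
    """
    if tasks < 1:
        raise ValueError(f"tasks must be >= 1, got {tasks}")
    units = list(read_units(encoded_path, mode))
    n = len(units)
    base, extra = divmod(n, tasks)
    partitions = []
    start = 0
    for index in range(tasks):
        size = base + (1 if index < extra else 0)
        partitions.append(Partition(index=index, units=units[start : start + size]))
        start += size
    return partitions


def _part_name(index: int) -> str:
    return f"part-{index:05d}.sam"


def run_task(partition: Partition, config: RunConfig) -> TaskResult:
    """Stream one partition through the external command.

    The child receives the partition's interleaved FASTQ on stdin; its stdout
    is streamed to ``part-NNNNN.sam`` in the sink (written under a hidden
    temporary name, renamed only on a zero exit, so a visible part file is
    always complete).  On a non-zero exit a :class:`TaskResult` with the
    child's stderr tail is returned and no part file appears.
    """
    sink = Path(config.sink)
    sink.mkdir(parents=True, exist_ok=True)
    final_path = sink / _part_name(partition.index)
    tmp_path = sink / f".{_part_name(partition.index)}.inprogress"
    argv = config.render_command()

    reads_per_unit = 2 if config.mode == "paired" else 1
    feed_error: list[BaseException] = []
    start = time.perf_counter()
    with open(tmp_path, "wb") as out:
        proc = subprocess.Popen(argv, stdin=subprocess.PIPE, stdout=out, stderr=subprocess.PIPE)

        def feed() -> None:
            try:
                assert proc.stdin is not None
                for line in to_aligner_text(partition.units, config.splitter):
                    proc.stdin.write(line.encode() + b"\n")
                proc.stdin.close()
            except BrokenPipeError:
                pass  # child exited early; its status tells the story
            except BaseException as exc:  # malformed unit etc.
                feed_error.append(exc)
                proc.kill()

        feeder = threading.Thread(target=feed, name=f"fqpipe-feed-{partition.index}")
        feeder.start()
        assert proc.stderr is not None
        stderr = proc.stderr.read()
        status = proc.wait()
        feeder.join()
    wall = max(time.perf_counter() - start, 1e-9)

    if feed_error:
        tmp_path.unlink(missing_ok=True)
        raise feed_error[0]

    if status != 0:
        tmp_path.unlink(missing_ok=True)
        return TaskResult(
            partition_index=partition.index,
            records_in=len(partition.units) * reads_per_unit,
            output_lines=0,
            exit_status=status,
            wall_time=wall,
            output_path=None,
            stderr_tail=stderr.decode(errors="replace")[-2000:],
        )

    with open(tmp_path, "rb") as handle:
        output_lines = sum(1 for _ in handle)
    tmp_path.replace(final_path)
    return TaskResult(
        partition_index=partition.index,
        records_in=len(partition.units) * reads_per_unit,
        output_lines=output_lines,
        exit_status=0,
        wall_time=wall,
        output_path=final_path,
    )


def run_main(
    encoded_path: Union[str, Path], config: RunConfig
) -> tuple[list[TaskResult], PerfReport]:
    """Run all partitions, up to ``config.tasks`` child commands at once.

    On success the sink holds ``part-00000.sam`` .. ``part-<tasks-1>.sam``
    plus a ``_SUCCESS`` marker; part files are deliberately not merged.
    Raises :class:`TaskFailure` for the first failing task (completed part
    results are attached to the exception's ``completed`` attribute).
    """
    partitions = partition_lines(encoded_path, config.tasks, config.mode)
    sink = Path(config.sink)
    sink.mkdir(parents=True, exist_ok=True)
    marker = sink / SUCCESS_MARKER
    marker.unlink(missing_ok=True)

    start = time.perf_counter()
    with ThreadPoolExecutor(max_workers=config.tasks) as pool:
        results = list(pool.map(lambda p: run_task(p, config), partitions))
    wall = max(time.perf_counter() - start, 1e-9)

    failures = [r for r in results if not r.ok]
    if failures:
        error = TaskFailure(failures[0])
        error.completed = [r for r in results if r.ok]  # type: ignore[attr-defined]
        raise error

    marker.touch()
    reads = sum(r.records_in for r in results)
    report = PerfReport(
        wall_time=wall,
        reads=reads,
        throughput=throughput(reads, wall),
        extra={"tasks": config.tasks, "threads": config.threads},
    )
    return results, report
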