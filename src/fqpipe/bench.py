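"""Parameter-grid benchmarking of the executor.

Sweeps every (task count, thread count) cell, running the main computation
once per repetition into a throwaway sink, and summarises each cell by its
median wall time and throughput.  Failing cells are recorded and the sweep
continues.  The grid search is how the default 4 tasks x 8 threads setting
was chosen on a 32-logical-core node; desk-scale sweeps with the mock
aligner exercise the same machinery.
"""

from __future__ import annotations

import dataclasses
import tempfile
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Union

from fqpipe.execute import RunConfig, TaskFailure, run_main
from fqpipe.metrics import round2


@dataclass(slots=True)
class BenchGrid:
    task_counts: list[int]
    thread_counts: list[int]
    repetitions: int = 1

    def __post_init__(self) -> None:
        if not self.task_counts or not self.thread_counts:
            raise ValueError("grid axes must be non-empty")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def run_bench(
    encoded_path: Union[str, Path], grid: BenchGrid, base_config: RunConfig
) -> list[dict]:
    """One summary row per grid cell plus a trailing ``best`` row.

    Each cell reports the median over repetitions; ``best`` is the cell with
    the highest median throughput.
    """
    rows: list[dict] = []
    with tempfile.TemporaryDirectory() as tmp:
        cell = 0
        for tasks in grid.task_counts:
            for threads in grid.thread_counts:
                walls, rates = [], []
                status = "ok"
                for rep in range(grid.repetitions):
                    config = dataclasses.replace(
                        base_config, tasks=tasks, threads=threads, sink=Path(tmp) / f"cell-{cell}-{rep}"
                    )
                    try:
                        _, perf = run_main(encoded_path, config)
                    except TaskFailure:
                        status = "failed"
                        break
                    walls.append(perf.wall_time)
                    rates.append(perf.throughput)
                rows.append(
                    {
                        "tasks": tasks,
                        "threads": threads,
                        "wall_time": round2(median(walls)) if walls else "",
                        "throughput": round2(median(rates)) if rates else "",
                        "status": status,
                    }
                )
                cell += 1
    ok_rows = [r for r in rows if r["status"] == "ok"]
    if ok_rows:
        best = max(ok_rows, key=lambda r: r["throughput"])
        rows.append({**best, "status": "best"})
    return rows
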