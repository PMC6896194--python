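"""Performance metrics for pipelined pre-processing and map-pattern execution.

Four quantities characterise the framework:

* theoretical pipeline speedup ``C / (1 + overhead)`` — bounded by the
  stage count ``C`` of the pipeline (3 here: load, transform, write);
* measured speedup ``t_baseline / t_optimized``;
* throughput ``N / T`` in reads per unit time;
* framework overhead ``1 - T_tool / T_framework`` — the fraction of wall
  time not spent in the wrapped tool itself;
* scale efficiency ``T_1 / (P * T_P)`` — 1 means perfect linear scaling.

Tabulated values are rounded half-up to 2 decimals; raw return values keep
full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence


def round2(value: float) -> float:
    """Half-up rounding to 2 decimals, as used in tabulated reports."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def theoretical_speedup(C: int, pipeline_overhead: float = 0.0) -> float:
    """Ideal pipeline speedup ``C / (1 + overhead)``.

    ``C`` is the pipeline depth (number of stages).  With zero overhead the
    speedup equals the depth, so a 3-stage pre-processing pipeline can gain
    at most 3x.
    """
    if C < 1:
        raise ValueError(f"stage count must be >= 1, got {C}")
    if pipeline_overhead < 0:
        raise ValueError(f"pipeline overhead must be >= 0, got {pipeline_overhead}")
    return C / (1.0 + pipeline_overhead)


def measured_speedup(t_baseline: float, t_optimized: float) -> float:
    """Wall-time ratio baseline / optimized; > 1 means the optimization won."""
    if t_baseline <= 0 or t_optimized <= 0:
        raise ValueError("times must be positive")
    return t_baseline / t_optimized


def throughput(N: int, T: float) -> float:
    """Reads processed per unit time, ``N / T``."""
    if N < 0:
        raise ValueError(f"read count must be >= 0, got {N}")
    if T <= 0:
        raise ValueError(f"time must be positive, got {T}")
    return N / T


def overhead(T_tool: float, T_framework: float) -> float:
    """Fraction of framework time not spent in the wrapped tool.

    ``1 - T_tool / T_framework`` lies in [0, 1) when the framework is at
    least as slow as the bare tool.  When the framework beats the bare tool
    (possible under hyper-threading) the value is negative; it is reported
    as-is with a warning rather than clamped, to preserve information.
    """
    if T_tool <= 0 or T_framework <= 0:
        raise ValueError("times must be positive")
    value = 1.0 - T_tool / T_framework
    if value < 0:
        warnings.warn(
            f"framework time ({T_framework}) is below bare-tool time ({T_tool}); "
            "overhead is negative",
            stacklevel=2,
        )
    return value


def scale_efficiency(T_1: float, P: int, T_P: float) -> float:
    """Scaling efficiency ``T_1 / (P * T_P)``; 1 is perfect linear scaling."""
    if T_1 <= 0 or T_P <= 0:
        raise ValueError("times must be positive")
    if P < 1:
        raise ValueError(f"node count must be >= 1, got {P}")
    return T_1 / (P * T_P)


def mean_differential(times_a: Sequence[float], times_b: Sequence[float]) -> float:
    """Mean of elementwise ``a_i - b_i``, rounded half-up to 2 decimals.

    Used to summarise the per-node-count gain of one configuration over
    another across a scaling sweep.
    """
    if len(times_a) != len(times_b):
        raise ValueError(f"length mismatch: {len(times_a)} vs {len(times_b)}")
    if not times_a:
        raise ValueError("inputs must be non-empty")
    diffs = [a - b for a, b in zip(times_a, times_b)]
    return round2(sum(diffs) / len(diffs))


@dataclass(slots=True)
class PerfReport:
    """End-to-end timing plus derived statistics for one run."""

    wall_time: float
    reads: int
    throughput: float
    speedup: float | None = None
    overhead_fraction: float | None = None
    efficiency: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "wall_time": self.wall_time,
            "reads": self.reads,
            "throughput": self.throughput,
        }
        if self.speedup is not None:
            out["speedup"] = self.speedup
        if self.overhead_fraction is not None:
            out["overhead_fraction"] = self.overhead_fraction
        if self.efficiency is not None:
            out["efficiency"] = self.efficiency
        out.update(self.extra)
        return out
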