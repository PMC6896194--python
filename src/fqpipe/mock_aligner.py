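"""Deterministic mock aligner: a drop-in child process for the executor.

Reads interleaved FASTQ on standard input and writes one tab-separated line
per read — identifier (without the leading ``@``), mate flag, read length,
and an MD5 digest of the bases — in input order.  Output is a pure function
of the input stream, which makes completeness and determinism assertions
sharp in tests.  ``--sam`` switches to minimal unmapped SAM records for
interoperability checks; either way the framework treats the output as
opaque pass-through text.

Flags accepted for command-template compatibility with real aligners:
``--threads`` (ignored), ``--delay-ms`` (sleep per 100-read block, to
emulate compute cost), ``--fail-at K`` (exit non-zero after K reads, for
error-path tests).
"""

from __future__ import annotations

import argparse
import hashlib
import sys
import time

_BLOCK = 100  # reads per --delay-ms sleep


def _mate_flag(identifier: str, read_index: int) -> int:
    if identifier.endswith("/1"):
        return 1
    if identifier.endswith("/2"):
        return 2
    token = identifier.split(None, 1)
    if len(token) == 2 and token[1][:2] in ("1:", "2:"):
        return int(token[1][0])
    return 1 + (read_index % 2)


def _sam_line(name: str, mate: int, bases: str, qualities: str) -> str:
    # unmapped, paired flags: 77 = first in pair, 141 = second in pair
    flag = 77 if mate == 1 else 141
    return f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{bases}\t{qualities}"


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(prog="fqpipe-mock-aligner", description=__doc__)
    parser.add_argument("--threads", type=int, default=1, help="accepted and ignored")
    parser.add_argument("--delay-ms", type=float, default=0.0, help="sleep per 100-read block")
    parser.add_argument("--fail-at", type=int, default=None, help="exit non-zero after K reads")
    parser.add_argument("--sam", action="store_true", help="emit minimal unmapped SAM records")
    args = parser.parse_args(argv)

    stdin = sys.stdin
    stdout = sys.stdout
    read_index = 0
    while True:
        head = stdin.readline()
        if head == "":
            break
        rest = [stdin.readline() for _ in range(3)]
        if any(line == "" for line in rest):
            print(f"mock-aligner: truncated record at read {read_index}", file=sys.stderr)
            return 2
        identifier = head.rstrip("\n")
        bases = rest[0].rstrip("\n")
        plus = rest[1].rstrip("\n")
        qualities = rest[2].rstrip("\n")
        if not identifier.startswith("@") or not plus.startswith("+"):
            print(f"mock-aligner: malformed record at read {read_index}", file=sys.stderr)
            return 2
        if len(bases) != len(qualities):
            print(f"mock-aligner: length mismatch at read {read_index}", file=sys.stderr)
            return 2

        if args.fail_at is not None and read_index >= args.fail_at:
            print(f"mock-aligner: injected failure after {args.fail_at} reads", file=sys.stderr)
            stdout.flush()
            return 3

        name = identifier[1:]
        mate = _mate_flag(identifier, read_index)
        if args.sam:
            stdout.write(_sam_line(name, mate, bases, qualities) + "\n")
        else:
            digest = hashlib.md5(bases.encode()).hexdigest()
            stdout.write(f"{name}\t{mate}\t{len(bases)}\t{digest}\n")
        read_index += 1
        if args.delay_ms and read_index % _BLOCK == 0:
            time.sleep(args.delay_ms / 1000.0)
    stdout.flush()
    return 0


if __name__ == "__main__":
    sys.exit(main())
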