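# Methods

## The data-unit encoding

A 4-line FASTQ record is atomic, and in paired-end data the atom is the
mate pair: eight lines across two files. Line-oriented partitioners know
nothing about this, so fqpipe makes the atom *be* a line. Encoding joins
r1's four fields and r2's four fields (in that order) with a splitter byte;
decoding splits on the byte and rebuilds the records. The field order —
r1 identifier, bases, plus line, qualities, then the same for r2 — means a
decoded unit is already in smart-pairing layout (mates adjacent, R1 first),
which is exactly what `bwa mem -p` consumes from a single stream.

Correctness rests on one precondition: the splitter byte must not occur in
record content. The default, `0x01`, is a control byte; Phred+33 quality
strings are confined to printable ASCII 33–126 and identifiers/bases in
well-formed FASTQ are printable too, so the default cannot collide with
valid input. `validate_splitter` scans for collisions anyway and returns a
*report* (first offending record and field) rather than raising, so a
caller can pick another byte; encoding itself hard-rejects any field
containing the splitter or a line break, so a corrupted unit can never be
written silently.

Two properties follow and are tested directly: round-trip identity
(`decode(encode(x)) == x` for arbitrary printable content, property-based)
and atomicity (any contiguous grouping of encoded lines decodes to whole
pairs whose concatenation is the input — enumerated exhaustively for small
n, and via all-intervals coverage for n = 20, since every group any
contiguous partition can form is an interval).

Multi-line ("wrapped") FASTQ is rejected, not re-flowed: silently rewriting
records would change bytes the user never asked us to touch. The reader is
deliberately byte-preserving — identifier and plus-line text round-trip
exactly — which is why it is a small in-house reader rather than a generic
FASTQ parser that normalises records; a generic parser (Biopython) is used
in the tests as the independent oracle for the interleaved output.

### Mate-identity rule

Identifier dialects vary: legacy mates end in `/1` and `/2`; Casava-1.8
mates share the first whitespace-delimited token and differ in the comment.
The pairing check therefore compares the first token after stripping a
trailing `/1`/`/2`. Modes: `strict` (raise on mismatch), `lenient` (log and
continue; the default, since real-world ids are messy and the check is a
guard, not a contract) and `off`. Unequal file lengths always fail, naming
the file that ran short and the pair index.

## The pre-processing pipeline

Pre-processing has three tasks: load raw FASTQ from disk, transform it to
encoded units, write the encoded file. The three map to distinct hardware
channels (disk read / CPU / write or upload), which is the textbook setting
for pipeline parallelism: with C stages and relative pipeline overhead *o*,
ideal speedup is C / (1 + o) — at most 3 here. Paired-end input uses four
workers for the three stages (one loader per input file; both loaders share
the disk channel and jointly form stage one), single-end uses three.

Implementation choices:

- **Workers are threads, not processes.** The stage work is dominated by
  I/O and hand-offs; threads release the GIL on file I/O and sleeps, keep
  the hand-off zero-copy, and make failure propagation simple. The
  equivalence and bound tests pass identically under this choice.
- **Chunked hand-off, bounded queues.** Records move in chunks
  (default 10 000 units) through queues bounded to 4 in-flight chunks, so
  memory is O(chunk_size) under backpressure regardless of file size.
- **Determinism contract.** Pipelined output is byte-identical to serial
  output for every input; the pipeline reorders *work*, never data.
- **Atomic completion.** Output is written under a hidden temporary name
  and renamed only on success, so the presence of `encoded.units` is a
  completion signal; any worker failure aborts the run, removes the
  temporary, and re-raises the originating stage's error.
- **Timing.** Wall time comes from a monotonic clock; per-stage busy time
  covers chunk processing (including injected delays) and excludes queue
  waits, matching the hardware-channel framing.
- **Delay injection.** `StageDelays` sleeps a configurable time per chunk
  in each stage. This exists so tests can pose a stage-balanced workload
  deterministically: with equal delays the measured serial/pipelined ratio
  must land in (1, 3], which the suite asserts with a 0.15 scheduling
  tolerance. Real throughput of the pure-Python transform is explicitly not
  a performance surface.

## The executor

The encoded file is split into `tasks` contiguous, balanced partitions
(sizes differ by at most one; surplus partitions are empty rather than an
error). Contiguous blocks rather than round-robin: reproducible, locality
preserving, and identical to how line-count splits of text files behave.
Each partition is decoded on the fly and streamed into the external
command's stdin by a feeder thread; stdout streams straight into
`part-NNNNN.sam` (temporary name, renamed on zero exit). No intermediate
file ever holds read data — the tests watch a scratch cwd/tempdir and
assert it stays empty. At most `tasks` children run concurrently; the
multi-node distribution of the original setting is emulated on one host
with partitions == tasks.

On success the sink gains a `_SUCCESS` marker next to the part files; on
any child failure the run raises, carrying the child's stderr tail, and no
part file or marker appears for the failed task. Part outputs are passed
through verbatim (SAM headers per part are left alone) and never merged:
downstream distributed processing re-partitions anyway.

Defaults `tasks=4, threads=8` reflect the best cell of a task×thread grid
sweep on a 32-logical-core node; both are plain configuration, with
`fqpipe bench` available to re-sweep on other hardware.

## Metrics

- theoretical speedup `C / (1 + o)` — monotone in C, equals C at o = 0;
- measured speedup `t_baseline / t_optimized`;
- throughput `N / T` (reads per second);
- overhead `1 − T_tool / T_framework` — in [0, 1) when the framework is no
  faster than the bare tool; a *negative* value (framework beat the bare
  tool, possible under hyper-threading) is reported with a warning rather
  than clamped, preserving information. `T_tool` is defined as the bare
  aligner command on identical input with the same thread count.
- scale efficiency `T_1 / (P · T_P)` — exactly 1 at P = 1.

Tabulated values round half-up to 2 decimals (matching how such tables are
conventionally printed); raw returns keep full precision.

## Synthetic data and the mock aligner

The generator emulates the *shape* of short-read data: n pairs of fixed
read length, uniform random ACGT bases, qualities either uniform `I`
(Q40, typical of modern instruments) or drawn across the printable Phred+33
span `!`..`I`, and mate identifiers in slash or Casava style. Defaults
(1000 pairs × 100 bp) are a desk-scale stand-in for real whole-genome
extracts. It does **not** model sequencing error profiles, duplicate rates,
adapter content or genome structure — so green tests establish the
framework's *plumbing* invariants (losslessness, atomicity, conservation,
determinism, bounds), not alignment quality, and say nothing about
cluster-scale wall times.

`generate_corrupt` plants exactly one seeded defect (mate-id mismatch,
truncated record, or a splitter byte inside a quality string) at a recorded
position, making every error path machine-checkable.

The mock aligner is a separate child process (also a console script) whose
output is a pure function of its input: one tab-separated line per read
with the identifier, mate flag, length, and an MD5 of the bases. That makes
completeness (identifier multiset equality), determinism (byte-identical
reruns) and failure handling (`--fail-at`) sharply assertable. `--sam`
emits minimal unmapped SAM records (flags 77/141) for interoperability
checks; either way the executor treats child output as opaque text.

## Known limitations

- Single-host emulation only: the sink is a local directory; a distributed
  filesystem adapter is an extension point, not a feature.
- The pure-Python transform stage is not optimised for raw throughput.
- FASTA, quality re-encoding, trimming/filtering and multi-line FASTQ are
  out of scope by design.
- The pipeline-speedup measurement is scheduling-sensitive; it is specified
  against injected stage-balanced delays, not against real disk behaviour.
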