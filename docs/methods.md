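# Methods

## The storage model

`genokv` stores *position-specific genomic records*: fixed-size key-value
pairs `R = (K, V)` whose key is a tuple of genome coordinates. The design
rests on three assumptions about this data class:

1. the key is unique and totally ordered (records sort by coordinate);
2. every record of a schema occupies the same number of bytes;
3. reads are dominated by range scans over coordinates, with occasional
   single lookups, and value fields are only ever post-filters.

Under these assumptions a log-structured layout beats per-record B-tree
indexing: inserts are buffered in RAM and amortised into large sequential
writes, and reads need only a *sparse* index (one entry per chunk of
records, not per record), which stays small enough to hold in memory even
for billions of records.

### Order-preserving codec

All sorting, merging, routing and searching operate on raw encoded bytes.
The codec guarantees `memcmp(encode(k1), encode(k2))` has the same sign as
comparing the decoded key tuples:

* unsigned integers: big-endian;
* signed integers: big-endian after adding a bias of `2^(8w−1)` (raw
  two's-complement bytes would order negatives after positives);
* fixed-width ASCII: raw bytes (latin-1 on the Python side so that every
  byte value round-trips losslessly).

Floats (IEEE-754 big-endian) are permitted in value parts only; float
bit-patterns do not memcmp-order, so they are excluded from key parts at
schema validation.

### Bucket files

A disk bucket is: 48-byte header (magic `PSDRDBKT`, format version, schema
digest, record size, chunk size, record count, index entry count), a sparse
index of `(first_key, ordinal)` per chunk, then the records in fixed-count
chunks. Opening a bucket reads exactly header + index; chunks are read on
demand. The chunk is the unit of both indexing and I/O: a lookup costs one
binary search over the in-memory index, one chunk read, and one in-chunk
binary search (possible only because records are equally sized).

Files are replaced atomically (temp file + `os.replace`), so an interrupted
synchronisation leaves the previous bucket intact; the write path validates
strict key ascent and record width, so a bucket file on disk is sorted and
key-unique by construction.

### Write path

Records are routed to `n` memory buckets by a **range partition** of the
encoded key space (an even split on the leading key bytes). Hashing would
balance load better but would scatter genomic intervals across buckets;
range partitioning is what lets a range select cross bucket boundaries as
one sequential read, and it is therefore forced by the query model.

A synchronisation is triggered when a bucket reaches its fill level, when
any bucket exceeds its age bound, or when the global buffer cap is hit;
among eligible buckets the fullest is synchronised first (ties to the
lowest id). The chosen bucket is swapped for an empty one — inserts never
wait on I/O — then sorted (stable, so insertion order is preserved within a
key), deduplicated by the update rule, and merged with the disk bucket by a
two-pointer streaming mergesort that holds at most one chunk per side.

Update rules resolve key collisions: `replace` (newest wins, the default),
`keep_first`, or `reduce(f)` where `f(old_bytes, new_bytes)` must return a
value of the schema's exact value width (checked; a violation aborts the
sync with the disk bucket untouched). A typical `reduce` keeps the minimum
E-value ever seen for a hit key.

### Read path and visibility

Queries see **flushed data only**: the select path walks disk buckets, and
callers needing read-your-writes call `flush()` first. This keeps reads
free of memtable locking and matches the engine's batch-oriented use.
Range selects are closed intervals `[K_S, K_E]`; a single lookup is the
degenerate case `K_S = K_E`. Genomic coordinates are stored exactly as
imported (1-based, inclusive); the store is coordinate-convention-agnostic.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `chunk_size` | 4096 records | unit of indexing and I/O; optimal value is hardware-dependent and must be tuned empirically, so it is a per-store knob recorded in the metadata file |
| `n_buckets` | 8 | key-range partitions; more buckets = smaller merges but more files |
| `fill_level` | 100 000 records | per-bucket sync trigger |
| `max_age_s` | 60 s | age-based sync trigger, bounds staleness of rarely-hit buckets |
| `global_buffer_bytes` | 256 MiB | cap on total buffered memory; hitting it syncs the fullest bucket |
| `update_rule` | `replace` | key-collision semantics (see above) |
| `max_parallel_syncs` | 2 | threaded mode only: concurrent merges, distinct buckets |

Deterministic mode (syncs inline at their trigger points) is the default
and is what every test uses; threaded mode exercises the non-blocking
contract (inserts proceed while a merge is in flight).

## Synthetic data

The generators make the engine fully testable without external downloads.

* `gen_snps` models a plant resequencing panel: 251 accessions, 5
  chromosomes, positions uniform on 1..30 Mb, random non-identical
  ref/alt bases, and a configurable duplicate-key rate (default 10 %) in
  which a row re-emits an earlier row's key with a new value — exactly the
  event the update rule exists for.
* `gen_herv` models homology hits of ~7000 retroviral fragments on a
  human-scale genome: 24 chromosomes up to 250 Mb, hit lengths 50 bp–10 kb,
  strand ∈ {0, 1}, and E-values log-uniform on 1e-60..1e-20, bracketing
  the conventional acceptance cutoff (1e-20) and the filter grid
  (1e-20 … 1e-50) used in the benchmarks.

What the generators do **not** emulate: linkage structure between nearby
SNPs, chromosome-length heterogeneity, clustering of hits in repeat-rich
regions, or realistic E-value/length correlation. Green tests therefore
establish storage-engine correctness (ordering, durability, query
equivalence) under realistic key *densities*, not biological realism of
the record contents.

## Numerical choices

* **E-values as float32.** The hit schema allots 4 bytes to the E-value,
  i.e. ~7 significant digits and underflow below ≈1.4e-45 (1e-50 stores as
  a subnormal or 0.0). Filtering is defined on the *stored* value, and the
  reference maps in tests and benchmarks filter the same decoded float32
  values, so cutoff comparisons are exact with respect to what the store
  holds. Callers needing full double precision should declare a `float64`
  value part.
* **NaN payloads.** Arbitrary bytes in a float32 field decode/re-encode
  bit-identically except non-canonical NaN payloads, which Python floats
  canonicalise; key bytes (never floats) always round-trip exactly.
* **Strict-ascent enforcement.** `write_bucket` rejects unsorted or
  duplicate-key input rather than fixing it silently; deduplication is the
  memtable's and merge's job, and a violation reaching the writer is a bug.
* **Boundary conventions.** Bucket ranges are half-open `[lo, hi)`; a key
  equal to a cut-point belongs to the bucket starting there. Query ranges
  are closed on both ends. A boundary equal to the minimal key is dropped
  from the bucket map (it would create a permanently empty bucket).
* **Minus-strand BLAST hits** arrive with subject start > end; the importer
  swaps them to ascending coordinates and sets `strand = 1` (strand is
  encoded {0, 1}).

## Benchmarks

`genokv.bench` reproduces the shape of the classic three-experiment
evaluation at desk scale — bulk insert with throughput checkpoints, random
single lookups (half present, half absent), and random closed ranges with
an E-value cutoff drawn from the 1e-20…1e-50 grid — with every answer
checked against an in-memory sorted map built from the same stream.
Defaults are 10⁶ inserts, 10⁴ lookups, 10³ ranges: the original experiments
ran up to 8·10⁸ records and 10⁶ ranges on dedicated hardware; the harness
keeps the generative shape at roughly 100–1000× smaller size. Timing
columns are informational only; absolute throughput is hardware-bound and
never part of a pass/fail decision.

## Known limitations

* No write-ahead log: a crash loses the unflushed memtable (by design; the
  disk state is always a consistent prefix of the workload).
* No variable-length values, nullable fields, or compression.
* Value predicates are post-filters; there is no secondary index, and no
  interval-overlap queries beyond key-order ranges.
* Single-process writers only; threaded mode parallelises syncs, not
  clients.
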