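# genokv

An embedded, bulk-insert-optimised key-value store for **position-specific
genomic records**: fixed-size records keyed by genome coordinates (a SNP per
accession/chromosome/position, a BLAST hit interval per chromosome), written
in the hundreds of millions during resequencing or homology-screening
pipelines, then queried by single position or by genomic range.

General-purpose relational databases handle this workload badly at desk
scale: their per-record indexes outgrow RAM and both insert and range-read
throughput collapse. `genokv` instead exploits the three properties such
data always has — a unique sortable key, a fixed record size, and queries
that are overwhelmingly range scans — with a log-structured design:

* **Order-preserving fixed-width codec.** Each record encodes to a constant
  number of bytes whose leading key bytes compare bytewise exactly like the
  decoded key tuple (big-endian unsigned ints, bias-shifted signed ints,
  fixed-width ASCII). Sorting, merging and binary search all run on raw
  `memcmp` order.
* **Key-range buckets.** A monotone map `M(K) → Bᵢ` routes each record to
  one of *n* contiguous key ranges. Every bucket exists twice: an
  append-only memory buffer and a sorted file on disk.
* **Mergesort synchronisation.** When a memory bucket reaches its fill
  level or age, it is swapped for an empty one (inserts never block),
  sorted, deduplicated under a state-dependent *update rule* (`replace`,
  `keep_first`, or a custom `reduce`), and merged chunk-wise with its disk
  bucket; the file is replaced atomically.
* **Sparse-indexed chunked bucket files.** Each bucket file is a header, a
  sparse index (one key per chunk), and fixed-count chunks of sorted
  records. Lookups binary-search the in-memory index, read one chunk, and
  binary-search inside it; range selects then stream sequentially across
  chunk and bucket boundaries, optionally post-filtering on value fields
  (e.g. BLAST E-value).

Built-in record schemas cover the two canonical inputs — five-column SNP
tables (accession, chromosome, position, ref, alt; 9-byte records) and
BLAST tabular hits of retroviral fragments (7 key parts + float32 E-value;
20-byte records) — and arbitrary user schemas can be declared from the same
fixed-width field kinds.

## Worked example

```python
from genokv import Store, builtin_snp_schema
from genokv.io_adapters import gen_snps

store = Store.create("demo_store", builtin_snp_schema(), n_buckets=8)
for row in gen_snps(100_000, seed=0, dup_rate=0.1):   # synthetic SNP panel
    store.insert_values(row.as_record())
store.flush()                                         # queries see disk only

print("records on disk:", store.stats()["records_on_disk"])
print("lookup:", store.lookup((7, 2, 2722)))
hits = list(store.range_select((7, 2, 1), (7, 2, 5_000_000)))
print("SNPs for accession 7, chr2, first 5 Mb:", len(hits))
store.close()
```

prints

```
records on disk: 89897
lookup: (7, 2, 2722, 'T', 'C')
SNPs for accession 7, chr2, first 5 Mb: 13
```

100 000 generated rows with a 10 % duplicate-key rate collapse to 89 897
unique keys under the default `replace` rule; the lookup returns the full
decoded record (T→C substitution at position 2722), and the range select
streams the 13 stored SNPs of that accession in the first 5 Mb of
chromosome 2 in ascending key order.

The same operations are available from the shell:

```bash
genokv create demo --schema snp
genokv import demo snps.tsv --format snp-tsv
genokv get demo 7,2,2722
genokv range demo 7,2,1 7,2,5000000
genokv verify demo
```

`genokv bench <config.yaml>` runs the insert / random-lookup / random-range
benchmark harness described in `docs/methods.md`; every benchmark is
simultaneously a correctness test against an in-memory reference map, and
timing columns are reporting only.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full desk-scale workload from scratch for both built-in
schemas — seeded synthetic data generation, bulk insert through the
buffering/sync path, random lookups, and random range selects with the
E-value filter grid — verifying every answer against an independent
in-memory map, and writes the results JSON to `--out`.

## Layout

| module | contents |
|---|---|
| `genokv.schema` | field specs, record schemas, order-preserving codec |
| `genokv.bucket_file` | on-disk bucket format: header, sparse index, chunks |
| `genokv.memtable` | bucket map `M(K)→Bᵢ`, memory buckets, swap-out |
| `genokv.sync` | update rules, sync selection policy, streaming mergesort |
| `genokv.query` | single lookup, range select, full scan |
| `genokv.store` | the `Store` facade: directory layout, config, flush |
| `genokv.io_adapters` | SNP-TSV / BLAST-tab / VCF importers, seeded generators |
| `genokv.bench`, `genokv.cli` | benchmark harness and the `genokv` CLI |
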