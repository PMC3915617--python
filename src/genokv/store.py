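"""The store facade: a directory of bucket files plus an in-RAM memtable.

A store lives in one directory::

    store.meta        text metadata: format version, schema, chunk_size,
                      bucket boundaries, thresholds, update rule name
    names.tsv         optional name -> id dictionaries (importers)
    bucket_00000.db   one file per non-empty disk bucket

Writes are buffered per key-range bucket and merged to disk when a bucket
reaches its fill level or age, when the global buffer cap is hit, or on
:meth:`Store.flush`.  Reads see flushed data only.

Two execution modes:

* deterministic (default): synchronisations run inline at their trigger
  points — mandatory for reproducible tests;
* threaded: up to ``max_parallel_syncs`` buckets merge concurrently in a
  thread pool; the memtable swap happens synchronously so inserts never
  block on a merge, and per-bucket locks serialise merges of the same
  bucket.
"""

from __future__ import annotations

import os
import threading
from concurrent.futures import ThreadPoolExecutor
from typing import Dict, Iterator, List, Optional, Sequence

from . import bucket_file as bf
from . import query as q
from .errors import StoreStateError
from .memtable import BucketContainer, BucketMap, default_bucket_map
from .schema import BUILTIN_SCHEMAS, RecordSchema
from .sync import SyncPlan, UpdateRule, merge_runs, select_bucket_for_sync

META_NAME = "store.meta"
META_FORMAT_VERSION = 1

DEFAULT_CHUNK_SIZE = 4096          # records per chunk
DEFAULT_N_BUCKETS = 8
DEFAULT_FILL_LEVEL = 100_000       # records per memory bucket before sync
DEFAULT_MAX_AGE_S = 60.0
DEFAULT_GLOBAL_BUFFER_BYTES = 256 * 1024 * 1024


class Store:
    """An open store. Use :meth:`create` or :meth:`open`, or as a context
    manager; always :meth:`close` (closing flushes)."""

    def __init__(self, path: str, schema: RecordSchema, bucket_map: BucketMap,
                 *, chunk_size: int, fill_level: int, max_age_s: float,
                 global_buffer_bytes: int, update_rule: UpdateRule,
                 deterministic: bool, max_parallel_syncs: int):
        self.path = os.fspath(path)
        self.schema = schema
        self.bucket_map = bucket_map
        self.chunk_size = chunk_size
        self.fill_level = fill_level
        self.max_age_s = max_age_s
        self.global_buffer_bytes = global_buffer_bytes
        self.update_rule = update_rule.bind(schema)
        self.deterministic = deterministic
        self.max_parallel_syncs = max_parallel_syncs

        self.container = BucketContainer(schema, bucket_map)
        self._handles: Dict[int, bf.BucketFile] = {}
        self._closed = False
        self._bucket_locks = [threading.Lock() for _ in range(bucket_map.n_buckets)]
        self._handle_lock = threading.Lock()
        self._executor: Optional[ThreadPoolExecutor] = None
        self._pending = []
        if not deterministic:
            self._executor = ThreadPoolExecutor(max_workers=max_parallel_syncs)

    # ------------------------------------------------------------------
    # lifecycle
    # ------------------------------------------------------------------
    @classmethod
    def create(cls, path, schema: RecordSchema, *,
               n_buckets: int = DEFAULT_N_BUCKETS,
               chunk_size: int = DEFAULT_CHUNK_SIZE,
               fill_level: int = DEFAULT_FILL_LEVEL,
               max_age_s: float = DEFAULT_MAX_AGE_S,
               global_buffer_bytes: int = DEFAULT_GLOBAL_BUFFER_BYTES,
               update_rule: Optional[UpdateRule] = None,
               deterministic: bool = True,
               max_parallel_syncs: int = 2) -> "Store":
        path = os.fspath(path)
        meta = os.path.join(path, META_NAME)
        if os.path.exists(meta):
            raise StoreStateError(f"store already exists at {path}")
        os.makedirs(path, exist_ok=True)
        bucket_map = default_bucket_map(schema, n_buckets)
        rule = update_rule or UpdateRule.replace()
        store = cls(path, schema, bucket_map, chunk_size=chunk_size,
                    fill_level=fill_level, max_age_s=max_age_s,
                    global_buffer_bytes=global_buffer_bytes,
                    update_rule=rule, deterministic=deterministic,
                    max_parallel_syncs=max_parallel_syncs)
        store._write_meta()
        return store

    @classmethod
    def open(cls, path, *, update_rule: Optional[UpdateRule] = None,
             deterministic: bool = True,
             max_parallel_syncs: int = 2) -> "Store":
        """Open an existing store from its metadata file.

        ``update_rule`` must be supplied when the store was created with a
        ``reduce`` rule (the reducer function cannot be persisted).
        """
        path = os.fspath(path)
        meta = os.path.join(path, META_NAME)
        if not os.path.exists(meta):
            raise StoreStateError(f"no store at {path}")
        with open(meta, "r") as fh:
            text = fh.read()
        sections = _parse_meta(text)
        schema = RecordSchema.from_config_text(sections["schema"])
        cfg = dict(
            line.split("\t", 1) for line in sections["config"].splitlines() if line
        )
        boundaries = [
            bytes.fromhex(h) for h in sections.get("boundaries", "").split() if h
        ]
        bucket_map = BucketMap(schema.key_size, boundaries)
        rule_name = cfg["update_rule"]
        if update_rule is None:
            if rule_name == "reduce":
                raise StoreStateError(
                    "store uses a 'reduce' update rule; pass update_rule= "
                    "with the reducer when opening"
                )
            update_rule = UpdateRule(rule_name)
        return cls(path, schema, bucket_map,
                   chunk_size=int(cfg["chunk_size"]),
                   fill_level=int(cfg["bucket_fill_level"]),
                   max_age_s=float(cfg["bucket_max_age_s"]),
                   global_buffer_bytes=int(cfg["global_buffer_bytes"]),
                   update_rule=update_rule, deterministic=deterministic,
                   max_parallel_syncs=max_parallel_syncs)

    def _write_meta(self) -> None:
        lines = [
            "[config]",
            f"format_version\t{META_FORMAT_VERSION}",
            f"chunk_size\t{self.chunk_size}",
            f"n_buckets\t{self.bucket_map.n_buckets}",
            f"bucket_fill_level\t{self.fill_level}",
            f"bucket_max_age_s\t{self.max_age_s}",
            f"global_buffer_bytes\t{self.global_buffer_bytes}",
            f"update_rule\t{self.update_rule.name}",
            "[boundaries]",
            " ".join(b.hex() for b in self.bucket_map.boundaries),
            "[schema]",
            self.schema.to_config_text().rstrip("\n"),
        ]
        tmp = os.path.join(self.path, META_NAME + ".tmp")
        with open(tmp, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        os.replace(tmp, os.path.join(self.path, META_NAME))

    def close(self) -> None:
        if self._closed:
            return
        self.flush()
        if self._executor is not None:
            self._executor.shutdown(wait=True)
        with self._handle_lock:
            for h in self._handles.values():
                h.close()
            self._handles.clear()
        self._closed = True

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False

    def _check_open(self) -> None:
        if self._closed:
            raise StoreStateError("store is closed")

    # ------------------------------------------------------------------
    # write path
    # ------------------------------------------------------------------
    def bucket_path(self, bucket_id: int) -> str:
        return os.path.join(self.path, f"bucket_{bucket_id:05d}.db")

    def insert(self, *values) -> None:
        """Encode one record (one positional value per field) and buffer it."""
        self.insert_values(values)

    def insert_values(self, values: Sequence) -> None:
        self._check_open()
        rec = self.schema.encode(values)
        self.container.append(rec)
        self._maybe_sync()

    def insert_encoded(self, record: bytes) -> None:
        self._check_open()
        if len(record) != self.schema.record_size:
            raise StoreStateError("encoded record has wrong length")
        self.container.append(record)
        self._maybe_sync()

    def _maybe_sync(self) -> None:
        over_cap = self.container.buffered_bytes() >= self.global_buffer_bytes
        bid = select_bucket_for_sync(self.container, self.fill_level,
                                     self.max_age_s)
        if bid is None and over_cap:
            # cap reached but no bucket at its own threshold: largest wins
            sizes = [(b.size, -b.bucket_id) for b in self.container.buckets]
            best = max(sizes)
            if best[0] > 0:
                bid = -best[1]
        if bid is not None:
            self._sync_bucket(bid)

    def _sync_bucket(self, bucket_id: int) -> None:
        run = self.container.swap_out(bucket_id, self.update_rule)
        if not run:
            return
        if self.deterministic:
            self._merge(bucket_id, run)
        else:
            fut = self._executor.submit(self._merge, bucket_id, run)
            self._pending.append(fut)
            self._pending = [f for f in self._pending if not f.done()]

    def _merge(self, bucket_id: int, run: List[bytes]) -> None:
        plan = SyncPlan(bucket_id, run, self.bucket_path(bucket_id),
                        self.schema, self.chunk_size)
        with self._bucket_locks[bucket_id]:
            merge_runs(plan, self.update_rule)
            with self._handle_lock:
                h = self._handles.pop(bucket_id, None)
            if h is not None:
                h.close()

    def flush(self) -> None:
        """Persist every buffered record; idempotent."""
        self._check_open()
        for fut in list(self._pending):
            fut.result()
        self._pending = []
        for b in list(self.container.buckets):
            if b.size > 0:
                run = self.container.swap_out(b.bucket_id, self.update_rule)
                self._merge(b.bucket_id, run)

    # ------------------------------------------------------------------
    # read path
    # ------------------------------------------------------------------
    def _bucket_handle(self, bucket_id: int) -> Optional[bf.BucketFile]:
        with self._handle_lock:
            h = self._handles.get(bucket_id)
            if h is not None:
                return h
        path = self.bucket_path(bucket_id)
        if not os.path.exists(path):
            return None
        h = bf.open_bucket(path, self.schema)
        with self._handle_lock:
            self._handles[bucket_id] = h
        return h

    def lookup(self, key_values) -> Optional[tuple]:
        self._check_open()
        return q.lookup(self, key_values)

    def range_select(self, start_key_values, end_key_values,
                     predicate=None) -> Iterator[tuple]:
        self._check_open()
        req = q.RangeRequest(self.schema.encode_key(start_key_values),
                             self.schema.encode_key(end_key_values),
                             predicate)
        return q.range_select(self, req)

    def scan_all(self) -> Iterator[tuple]:
        self._check_open()
        return q.scan_all(self)

    # ------------------------------------------------------------------
    # maintenance
    # ------------------------------------------------------------------
    def stats(self) -> dict:
        self._check_open()
        buckets = {}
        total = 0
        for bid in range(self.bucket_map.n_buckets):
            h = self._bucket_handle(bid)
            if h is None:
                continue
            buckets[bid] = {
                "records": h.record_count,
                "chunks": h.n_chunks,
                "index_entries": h.index_entry_count,
                "file_bytes": os.path.getsize(h.path),
            }
            total += h.record_count
        return {
            "schema": self.schema.name,
            "record_size": self.schema.record_size,
            "key_size": self.schema.key_size,
            "chunk_size": self.chunk_size,
            "n_buckets": self.bucket_map.n_buckets,
            "records_on_disk": total,
            "records_buffered": self.container.buffered_records(),
            "buckets": buckets,
        }

    def verify(self) -> int:
        """Full-store audit; returns record count, raises on inconsistency."""
        self._check_open()
        total = 0
        last_key = None
        ks = self.schema.key_size
        for bid in range(self.bucket_map.n_buckets):
            h = self._bucket_handle(bid)
            if h is None:
                continue
            bf.audit_bucket(h)
            for rec in h.iter_records():
                key = rec[:ks]
                if last_key is not None and key <= last_key:
                    raise bf.CorruptionError(
                        f"keys not ascending across buckets at bucket {bid}"
                    )
                last_key = key
                total += 1
        return total


def _parse_meta(text: str) -> dict:
    sections: Dict[str, List[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return {k: "\n".join(v).strip("\n") for k, v in sections.items()}


def schema_by_name(name: str) -> RecordSchema:
    """Look up a built-in schema ('snp' or 'herv') by name."""
    try:
        return BUILTIN_SCHEMAS[name]()
    except KeyError:
        raise StoreStateError(f"no built-in schema named {name!r}") from None
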