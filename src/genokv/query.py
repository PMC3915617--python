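"""Read path: single lookups and streaming range selects.

Both follow the same route: identify the bucket by the monotone key map,
binary-search the bucket's sparse index for the chunk, binary-search inside
the chunk for the first record, then (for ranges) read sequentially across
chunk and bucket boundaries until the end key passes.  A single lookup is
the degenerate range with equal start and end keys.

Only flushed (on-disk) data is visible; callers needing read-your-writes
flush first.  Value predicates are applied per decoded record after key
filtering — there is no secondary index on value fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Optional

from .errors import SchemaError


@dataclass
class RangeRequest:
    """A closed key interval [k_start, k_end] plus an optional row filter."""

    k_start: bytes
    k_end: bytes
    predicate: Optional[Callable[[tuple], bool]] = None

    def __post_init__(self):
        if len(self.k_start) != len(self.k_end):
            raise SchemaError("range endpoints have different key lengths")
        if self.k_start > self.k_end:
            raise ValueError("range start key exceeds end key")


def _first_geq(chunk_raw: bytes, key: bytes, record_size: int, key_size: int
               ) -> int:
    """Index of the first record in the chunk with key >= ``key``."""
    lo, hi = 0, len(chunk_raw) // record_size
    while lo < hi:
        mid = (lo + hi) // 2
        off = mid * record_size
        if chunk_raw[off : off + key_size] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo


def lookup_encoded(store, key: bytes) -> Optional[bytes]:
    """The unique encoded record with this key, or ``None``."""
    schema = store.schema
    rs, ks = schema.record_size, schema.key_size
    bucket = store._bucket_handle(store.bucket_map.route(key))
    if bucket is None or bucket.record_count == 0:
        return None
    c = bucket.locate_chunk(key)
    raw = bucket.read_chunk_raw(c)
    i = _first_geq(raw, key, rs, ks)
    off = i * rs
    if off < len(raw) and raw[off : off + ks] == key:
        return raw[off : off + rs]
    return None


def lookup(store, key_values) -> Optional[tuple]:
    """Decode-level single select: full key tuple -> record tuple or None."""
    raw = lookup_encoded(store, store.schema.encode_key(key_values))
    return store.schema.decode(raw) if raw is not None else None


def range_select_encoded(store, request: RangeRequest) -> Iterator[bytes]:
    """Yield encoded records with k_start <= key <= k_end in key order."""
    schema = store.schema
    rs, ks = schema.record_size, schema.key_size
    k_start, k_end = request.k_start, request.k_end
    b_first = store.bucket_map.route(k_start)
    b_last = store.bucket_map.route(k_end)
    for bid in range(b_first, b_last + 1):
        bucket = store._bucket_handle(bid)
        if bucket is None or bucket.record_count == 0:
            continue
        c = bucket.locate_chunk(k_start) if bid == b_first else 0
        while c < bucket.n_chunks:
            raw = bucket.read_chunk_raw(c)
            i = _first_geq(raw, k_start, rs, ks) if (bid == b_first) else 0
            off = i * rs
            while off < len(raw):
                key = raw[off : off + ks]
                if key > k_end:
                    return
                yield raw[off : off + rs]
                off += rs
            c += 1


def range_select(store, request: RangeRequest) -> Iterator[tuple]:
    """Decoded, optionally predicate-filtered range select (streaming)."""
    decode = store.schema.decode
    pred = request.predicate
    for raw in range_select_encoded(store, request):
        rec = decode(raw)
        if pred is None or pred(rec):
            yield rec


def scan_all(store) -> Iterator[tuple]:
    """Full-store ordered scan == range select over the whole key space."""
    req = RangeRequest(store.schema.min_key(), store.schema.max_key())
    return range_select(store, req)
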