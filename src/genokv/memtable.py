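"""In-memory buffering: key-range bucket map and memory buckets.

Incoming records are routed to one of ``n`` memory buckets by a *monotone*
mapping over the encoded key: bucket ``i`` covers the half-open key range
``[boundary[i-1], boundary[i])``.  Range partitioning (rather than hashing)
keeps records that are close on the genome close on disk, which is what
makes sequential range scans across bucket boundaries possible.

A memory bucket is an append-order buffer; sorting and duplicate resolution
happen once, at swap-out time, so inserts stay O(1).
"""

from __future__ import annotations

import time
import warnings
from bisect import bisect_right
from typing import List, Optional, Sequence

from .schema import RecordSchema


class BucketMap:
    """Monotone partition of the key space into contiguous ranges.

    ``boundaries`` is a sorted list of n-1 encoded keys; bucket ``i`` covers
    ``[boundaries[i-1], boundaries[i])`` with the first range starting at
    the minimal key and the last ending at the maximal key.  A key equal to
    a boundary belongs to the bucket *starting* at that boundary.
    """

    def __init__(self, key_size: int, boundaries: Sequence[bytes]):
        boundaries = list(boundaries)
        for b in boundaries:
            if len(b) != key_size:
                raise ValueError(
                    f"boundary of {len(b)} bytes, key size is {key_size}"
                )
        if boundaries != sorted(set(boundaries)):
            raise ValueError("boundaries must be strictly ascending")
        self.key_size = key_size
        self.boundaries = boundaries

    @property
    def n_buckets(self) -> int:
        return len(self.boundaries) + 1

    def route(self, key: bytes) -> int:
        """Bucket id whose range contains ``key`` (binary search)."""
        return bisect_right(self.boundaries, key)

    def bucket_range(self, bucket_id: int):
        """(low, high) bounds of a bucket; low inclusive, high exclusive
        (``None`` means open end of the key space)."""
        lo = self.boundaries[bucket_id - 1] if bucket_id > 0 else None
        hi = (
            self.boundaries[bucket_id]
            if bucket_id < len(self.boundaries)
            else None
        )
        return lo, hi


def default_bucket_map(schema: RecordSchema, n_buckets: int) -> BucketMap:
    """Even split of the key space on the leading key bytes.

    Uses the leading ``min(key_size, 8)`` bytes as an integer and places
    boundaries at ``i * 2**(8p) // n_buckets``.  Deterministic given
    (schema, n_buckets).  If the leading bytes cannot distinguish
    ``n_buckets`` ranges, duplicate boundaries are dropped with a warning
    and the effective bucket count shrinks.
    """
    if n_buckets < 1:
        raise ValueError("n_buckets must be >= 1")
    ks = schema.key_size
    p = min(ks, 8)
    total = 1 << (8 * p)
    pad = b"\x00" * (ks - p)
    raw = [
        (i * total // n_buckets).to_bytes(p, "big") + pad
        for i in range(1, n_buckets)
    ]
    # dedupe, and drop a boundary at the minimal key (it would create an
    # always-empty first bucket)
    boundaries = sorted({b for b in raw if b != b"\x00" * ks})
    if len(boundaries) < len(raw):
        warnings.warn(
            f"key prefix supports only {len(boundaries) + 1} distinct "
            f"buckets, requested {n_buckets}",
            stacklevel=2,
        )
    return BucketMap(ks, boundaries)


class MemoryBucket:
    """Append-order buffer of encoded records awaiting synchronisation."""

    __slots__ = ("bucket_id", "records", "created_at")

    def __init__(self, bucket_id: int):
        self.bucket_id = bucket_id
        self.records: List[bytes] = []
        self.created_at: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.records)

    def append(self, record: bytes) -> None:
        if self.created_at is None:
            self.created_at = time.monotonic()
        self.records.append(record)

    def age_s(self) -> float:
        if self.created_at is None:
            return 0.0
        return time.monotonic() - self.created_at


class BucketContainer:
    """All memory buckets plus routing; the write-side RAM half of a store."""

    def __init__(self, schema: RecordSchema, bucket_map: BucketMap):
        self.schema = schema
        self.map = bucket_map
        self.buckets = [MemoryBucket(i) for i in range(bucket_map.n_buckets)]
        self.inserted = 0  # counters for the no-data-loss audit
        self.swapped_out = 0

    def route(self, key: bytes) -> int:
        return self.map.route(key)

    def append(self, record: bytes) -> int:
        bid = self.map.route(record[: self.schema.key_size])
        self.buckets[bid].append(record)
        self.inserted += 1
        return bid

    def buffered_records(self) -> int:
        return sum(b.size for b in self.buckets)

    def buffered_bytes(self) -> int:
        return self.buffered_records() * self.schema.record_size

    def swap_out(self, bucket_id: int, update_rule) -> List[bytes]:
        """Detach bucket ``bucket_id`` and return its sorted, unique run.

        The live container immediately holds a fresh empty bucket, so
        buffering continues while the run is merged to disk.  Duplicate keys
        inside the buffer are collapsed with ``update_rule`` in insertion
        order (earlier record = existing, later = incoming).
        """
        old = self.buckets[bucket_id]
        self.buckets[bucket_id] = MemoryBucket(bucket_id)
        ks = self.schema.key_size
        recs = old.records
        recs.sort(key=lambda r: r[:ks])  # stable: insertion order kept per key
        out: List[bytes] = []
        for rec in recs:
            if out and out[-1][:ks] == rec[:ks]:
                merged_value = update_rule.resolve(out[-1][ks:], rec[ks:])
                out[-1] = out[-1][:ks] + merged_value
            else:
                out.append(rec)
        self.swapped_out += len(recs)
        return out
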