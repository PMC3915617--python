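"""Synchronisation: merge sorted in-memory runs into disk buckets.

A sync takes the sorted, key-unique run produced by swapping out a memory
bucket and merges it with the corresponding bucket file using a streaming
mergesort.  Key collisions are resolved by a state-dependent *update rule*:

* ``replace``    — the incoming (memory) value wins;
* ``keep_first`` — the existing (disk) value wins;
* ``reduce``     — an associative reducer combines old and new value bytes
  (e.g. keep the minimum E-value seen for a hit).

The merge streams chunk-wise from disk and writes chunk-wise through
:func:`~genokv.bucket_file.write_bucket`, so peak memory stays
O(chunk_size * record_size) regardless of bucket size, and the disk bucket
is replaced atomically only after the whole merged file is on disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Iterator, List, Optional, Sequence

from . import bucket_file as bf
from .errors import IntegrityError
from .schema import RecordSchema

Reducer = Callable[[bytes, bytes], bytes]


class UpdateRule:
    """Resolution of a key collision between a stored and an incoming value."""

    def __init__(self, name: str, reducer: Optional[Reducer] = None,
                 value_size: Optional[int] = None):
        if name not in ("replace", "keep_first", "reduce"):
            raise ValueError(f"unknown update rule {name!r}")
        if name == "reduce" and reducer is None:
            raise ValueError("rule 'reduce' needs a reducer function")
        self.name = name
        self.reducer = reducer
        self.value_size = value_size

    @classmethod
    def replace(cls) -> "UpdateRule":
        """Newest value wins (the default)."""
        return cls("replace")

    @classmethod
    def keep_first(cls) -> "UpdateRule":
        """First stored value wins; later inserts of the key are ignored."""
        return cls("keep_first")

    @classmethod
    def reduce(cls, reducer: Reducer, value_size: Optional[int] = None
               ) -> "UpdateRule":
        """Combine old and new value bytes with an associative reducer."""
        return cls("reduce", reducer, value_size)

    def bind(self, schema: RecordSchema) -> "UpdateRule":
        """Attach the schema's value width so resolve() can enforce it."""
        self.value_size = schema.value_size
        return self

    def resolve(self, old_value: bytes, new_value: bytes) -> bytes:
        if self.name == "replace":
            return new_value
        if self.name == "keep_first":
            return old_value
        out = self.reducer(old_value, new_value)
        if self.value_size is not None and len(out) != self.value_size:
            raise IntegrityError(
                f"reducer returned {len(out)} bytes, value width is "
                f"{self.value_size}"
            )
        return out


@dataclass
class SyncPlan:
    """One bucket's pending merge: sorted unique run + its disk counterpart."""

    bucket_id: int
    run: Sequence[bytes]           # sorted, key-unique encoded records
    path: str                      # destination bucket file
    schema: RecordSchema
    chunk_size: int


def select_bucket_for_sync(container, fill_level: int, max_age_s: float
                           ) -> Optional[int]:
    """Pick the bucket to synchronise next, or ``None``.

    Among buckets meeting the fill-level or age condition, the one with the
    most buffered records wins; ties break to the lowest bucket id.
    """
    best: Optional[int] = None
    best_size = -1
    for b in container.buckets:
        if b.size == 0:
            continue
        if b.size >= fill_level or b.age_s() >= max_age_s:
            if b.size > best_size:
                best, best_size = b.bucket_id, b.size
    return best


def _merged_stream(plan: SyncPlan, rule: UpdateRule,
                   disk: Optional[bf.BucketFile]) -> Iterator[bytes]:
    """Two-pointer merge of the disk bucket (chunk-wise) with the run."""
    ks = plan.schema.key_size
    run = plan.run
    ri, rn = 0, len(run)

    disk_iter = disk.iter_chunks() if disk is not None else iter(())
    chunk: List[bytes] = []
    ci = 0

    def next_disk():
        nonlocal chunk, ci
        while True:
            if ci < len(chunk):
                rec = chunk[ci]
                ci += 1
                return rec
            chunk = next(disk_iter, None)
            ci = 0
            if chunk is None:
                return None

    d = next_disk()
    while d is not None and ri < rn:
        dk = d[:ks]
        mk = run[ri][:ks]
        if dk < mk:
            yield d
            d = next_disk()
        elif dk > mk:
            yield run[ri]
            ri += 1
        else:
            yield dk + rule.resolve(d[ks:], run[ri][ks:])
            d = next_disk()
            ri += 1
    while d is not None:
        yield d
        d = next_disk()
    while ri < rn:
        yield run[ri]
        ri += 1


def merge_runs(plan: SyncPlan, rule: UpdateRule) -> None:
    """Merge ``plan.run`` with the disk bucket and atomically replace it.

    With an empty run and an existing bucket the output is bit-identical to
    the input file.  Any failure (reducer width violation, I/O error) leaves
    the original bucket file untouched.
    """
    rule.bind(plan.schema)
    disk = None
    if os.path.exists(plan.path):
        disk = bf.open_bucket(plan.path, plan.schema)
    try:
        stream = _merged_stream(plan, rule, disk)
        bf.write_bucket(plan.path, plan.schema, stream, plan.chunk_size)
    finally:
        if disk is not None:
            disk.close()
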