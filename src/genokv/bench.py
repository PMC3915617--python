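"""Desk-scale benchmark harness: insert, random lookup, random range select.

Every benchmark doubles as a correctness test: the store's answers are
compared record-for-record against an in-memory sorted map built from the
same generated stream under the same update rule.  A mismatch is a hard
failure (a correctness bug), while timing numbers are reporting only —
absolute throughput depends on hardware and is never asserted.

The three workloads mirror the classic evaluation shape for this kind of
engine: bulk insert with periodic throughput checkpoints, random single
lookups (half present, half absent keys), and random closed ranges with an
optional E-value post-filter drawn from a cutoff grid.
"""

from __future__ import annotations

import csv
import json
import os
import time
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_adapters import gen_herv, gen_snps
from .schema import RecordSchema, builtin_herv_schema, builtin_snp_schema
from .store import Store
from .sync import UpdateRule


class OracleMap:
    """Brute-force reference: a dict of encoded key -> value bytes."""

    def __init__(self, schema: RecordSchema, rule: UpdateRule):
        self.schema = schema
        self.rule = rule.bind(schema)
        self.d: Dict[bytes, bytes] = {}
        self._sorted: Optional[List[bytes]] = None

    def put_values(self, values: Sequence) -> None:
        rec = self.schema.encode(values)
        ks = self.schema.key_size
        key, val = rec[:ks], rec[ks:]
        old = self.d.get(key)
        self.d[key] = val if old is None else self.rule.resolve(old, val)
        self._sorted = None

    def sorted_keys(self) -> List[bytes]:
        if self._sorted is None:
            self._sorted = sorted(self.d)
        return self._sorted

    def lookup(self, key: bytes) -> Optional[bytes]:
        return self.d.get(key)

    def range(self, k_start: bytes, k_end: bytes) -> List[bytes]:
        keys = self.sorted_keys()
        lo = bisect_left(keys, k_start)
        hi = bisect_right(keys, k_end)
        return [keys[i] + self.d[keys[i]] for i in range(lo, hi)]

    def __len__(self):
        return len(self.d)


@dataclass
class BenchConfig:
    """Workload description for one benchmark run."""

    schema: str = "snp"             # 'snp' or 'herv'
    n_records: int = 1_000_000
    n_lookups: int = 10_000
    n_ranges: int = 1_000
    range_len_min: int = 1_000     # in key (position) units
    range_len_max: int = 10_000
    evalue_cutoffs: Sequence[float] = dfield(
        default_factory=lambda: [10.0 ** -e for e in range(20, 55, 5)]
    )
    seed: int = 0
    n_buckets: int = 8
    chunk_size: int = 4096
    fill_level: int = 100_000
    dup_rate: float = 0.1
    report_dir: Optional[str] = None
    checkpoint_every: int = 50_000

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.range_len_min > self.range_len_max:
            raise ValueError("range_len_min exceeds range_len_max")

    @classmethod
    def from_mapping(cls, d: dict) -> "BenchConfig":
        return cls(**d)


def _builtin(name: str) -> RecordSchema:
    if name == "snp":
        return builtin_snp_schema()
    if name == "herv":
        return builtin_herv_schema()
    raise ValueError(f"bench schema must be 'snp' or 'herv', got {name!r}")


def _generate(cfg: BenchConfig):
    if cfg.schema == "snp":
        rows = gen_snps(cfg.n_records, cfg.seed, dup_rate=cfg.dup_rate)
    else:
        rows = gen_herv(cfg.n_records, cfg.seed, dup_rate=cfg.dup_rate)
    for row in rows:
        yield row.as_record()


def run_insert_bench(store: Store, oracle: OracleMap, cfg: BenchConfig
                     ) -> List[dict]:
    """Bulk insert with throughput checkpoints; verify by full scan."""
    rows = []
    t0 = time.perf_counter()
    n = 0
    for values in _generate(cfg):
        store.insert_values(values)
        oracle.put_values(values)
        n += 1
        if n % cfg.checkpoint_every == 0 or n == cfg.n_records:
            dt = time.perf_counter() - t0
            rows.append({
                "records_inserted": n,
                "elapsed_s": round(dt, 4),
                "throughput_rps": round(n / dt, 1) if dt > 0 else float("inf"),
            })
    store.flush()
    # correctness: the store's full scan equals the oracle exactly
    scan = store.scan_all()
    for key in oracle.sorted_keys():
        rec = next(scan, None)
        expect = store.schema.decode(key + oracle.d[key])
        if rec != expect:
            raise AssertionError(
                f"insert bench: record mismatch at key {key.hex()}"
            )
    if next(scan, None) is not None:
        raise AssertionError("insert bench: store holds extra records")
    return rows


def run_lookup_bench(store: Store, oracle: OracleMap, cfg: BenchConfig
                     ) -> List[dict]:
    """Random single lookups, half present and half absent keys."""
    rng = np.random.default_rng(cfg.seed + 1)
    keys = oracle.sorted_keys()
    schema = store.schema
    ks = schema.key_size
    n_present = cfg.n_lookups // 2
    present_idx = rng.integers(0, len(keys), n_present)
    queries = [keys[i] for i in present_idx]
    # absent keys: random bytes re-drawn on accidental hits
    n_absent = cfg.n_lookups - n_present
    raw = rng.integers(0, 256, (n_absent, ks), dtype=np.uint8)
    queries += [bytes(raw[i]) for i in range(n_absent)]

    from .query import lookup_encoded

    t0 = time.perf_counter()
    hits = 0
    for key in queries:
        got = lookup_encoded(store, key)
        expect = oracle.lookup(key)
        expect_rec = (key + expect) if expect is not None else None
        if got != expect_rec:
            raise AssertionError(f"lookup bench: mismatch at key {key.hex()}")
        if got is not None:
            hits += 1
    dt = time.perf_counter() - t0
    return [{
        "n_lookups": len(queries),
        "hits": hits,
        "elapsed_s": round(dt, 4),
        "mean_latency_us": round(1e6 * dt / max(len(queries), 1), 2),
    }]


def _random_ranges(cfg: BenchConfig, rng) -> List[Tuple[bytes, bytes, Optional[float]]]:
    schema = _builtin(cfg.schema)
    out = []
    cutoffs = list(cfg.evalue_cutoffs)
    for _ in range(cfg.n_ranges):
        length = int(rng.integers(cfg.range_len_min, cfg.range_len_max + 1))
        if cfg.schema == "snp":
            acc = int(rng.integers(0, 251))
            chrom = int(rng.integers(1, 6))
            pos = int(rng.integers(1, 30_000_000))
            k0 = schema.encode_key((acc, chrom, pos))
            k1 = schema.encode_key((acc, chrom, min(pos + length, 2**32 - 1)))
            cutoff = None
        else:
            chrom = int(rng.integers(1, 25))
            pos = int(rng.integers(1, 250_000_000))
            k0 = schema.partial_key((chrom, pos), 0x00)
            k1 = schema.partial_key((chrom, min(pos + length, 2**32 - 1)), 0xFF)
            cutoff = cutoffs[int(rng.integers(0, len(cutoffs)))] if cutoffs else None
        out.append((k0, k1, cutoff))
    return out


def run_range_bench(store: Store, oracle: OracleMap, cfg: BenchConfig
                    ) -> List[dict]:
    """Random closed ranges, optionally E-value-filtered, oracle-checked."""
    from .query import RangeRequest, range_select

    rng = np.random.default_rng(cfg.seed + 2)
    schema = store.schema
    ks = schema.key_size
    ranges = _random_ranges(cfg, rng)
    ev_index = None
    if cfg.schema == "herv":
        ev_index = [f.name for f in schema.fields].index("evalue")

    rows = []
    t0 = time.perf_counter()
    for i, (k0, k1, cutoff) in enumerate(ranges):
        pred = None
        if cutoff is not None:
            pred = (lambda rec, _c=cutoff, _j=ev_index: rec[_j] < _c)
        got = list(range_select(store, RangeRequest(k0, k1, pred)))
        expect = [schema.decode(r) for r in oracle.range(k0, k1)]
        if cutoff is not None:
            expect = [r for r in expect if r[ev_index] < cutoff]
        if got != expect:
            raise AssertionError(f"range bench: mismatch in range {i}")
        rows.append({
            "range_id": i,
            "n_records": len(got),
            "evalue_cutoff": cutoff if cutoff is not None else "",
        })
    dt = time.perf_counter() - t0
    rows.append({
        "range_id": "total",
        "n_records": sum(r["n_records"] for r in rows),
        "evalue_cutoff": f"elapsed_s={round(dt, 4)}",
    })
    return rows


def run_bench(cfg: BenchConfig, store_dir: str) -> Dict[str, List[dict]]:
    """Full benchmark: create a store, run all three workloads, write CSVs."""
    schema = _builtin(cfg.schema)
    rule = UpdateRule.replace()
    store = Store.create(store_dir, schema, n_buckets=cfg.n_buckets,
                         chunk_size=cfg.chunk_size, fill_level=cfg.fill_level,
                         update_rule=rule)
    oracle = OracleMap(schema, UpdateRule.replace())
    try:
        results = {
            "insert": run_insert_bench(store, oracle, cfg),
            "lookup": run_lookup_bench(store, oracle, cfg),
            "range": run_range_bench(store, oracle, cfg),
        }
    finally:
        store.close()
    if cfg.report_dir:
        os.makedirs(cfg.report_dir, exist_ok=True)
        for name, rows in results.items():
            if rows:
                path = os.path.join(cfg.report_dir, f"bench_{name}.csv")
                with open(path, "w", newline="") as fh:
                    w = csv.DictWriter(fh, fieldnames=list(rows[0]))
                    w.writeheader()
                    w.writerows(rows)
    return results


def plot_insert_throughput(rows: List[dict], out_png: str) -> None:
    """Optional throughput-vs-inserted plot for the insert benchmark."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = [r["records_inserted"] for r in rows]
    y = [r["throughput_rps"] for r in rows]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, y, marker="o")
    ax.set_xlabel("records inserted")
    ax.set_ylabel("cumulative throughput (records/s)")
    ax.set_title("insert benchmark")
    fig.tight_layout()
    fig.savefig(out_png, dpi=100)
    plt.close(fig)
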