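"""Importers for SNP tables and BLAST tabular hits, plus seeded generators.

The two record families the store ships schemas for:

* **SNP rows** — one substituted base per (accession, chromosome, position),
  as distributed by resequencing projects: five tab-separated columns
  (accession name, chromosome, position, reference base, mutated base).
* **Retroviral-fragment hits** — BLAST tabular hits of known fragments
  against a genome: query id, subject id, query start/end, subject
  start/end, E-value.  Hits are kept only below an E-value cutoff; hits on
  the minus strand arrive with subject start > end and are normalised to
  ascending coordinates with strand = 1.

Text identifiers (accession names, chromosome tokens like ``Chr1``/``X``,
fragment ids) are interned to dense unsigned integers through a persisted
name registry, since the fixed-width schemas store compact ids.

The synthetic generators emulate both families with configurable sizes,
duplicate-key rates and E-value ranges, deterministically per seed, so the
whole engine is testable without any external download.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

import numpy as np

from .errors import GenoKVError

NUCLEOTIDES = frozenset("ACGTN")


class ImportError_(GenoKVError):
    """A malformed input line (strict mode)."""


@dataclass
class SnpRow:
    accession_id: int
    chromosome: int
    position: int
    ref: str
    alt: str

    def as_record(self) -> tuple:
        return (self.accession_id, self.chromosome, self.position,
                self.ref, self.alt)


@dataclass
class HervRow:
    chromosome: int
    chrom_start: int
    chrom_end: int
    herv_start: int
    herv_end: int
    herv_id: int
    strand: int
    evalue: float

    def as_record(self) -> tuple:
        return (self.chromosome, self.chrom_start, self.chrom_end,
                self.herv_start, self.herv_end, self.herv_id,
                self.strand, self.evalue)


class NameTable:
    """Dense name -> id interning for one namespace."""

    def __init__(self):
        self._ids: Dict[str, int] = {}
        self._names: List[str] = []

    def get_or_assign(self, name: str) -> int:
        i = self._ids.get(name)
        if i is None:
            i = len(self._names)
            self._ids[name] = i
            self._names.append(name)
        return i

    def name_of(self, i: int) -> str:
        return self._names[i]

    def __len__(self):
        return len(self._names)


class NameRegistry:
    """Per-namespace name tables, persisted as a 3-column TSV.

    Chromosome tokens (``Chr1``, ``1``, ``X``, ...) are interned like any
    other name rather than parsed numerically; numeric-looking chromosome
    tokens are special-cased to their integer value so that ``Chr1`` files
    and plain ``1`` files agree when both use the conventional names.
    """

    def __init__(self):
        self.tables: Dict[str, NameTable] = {}

    def table(self, namespace: str) -> NameTable:
        t = self.tables.get(namespace)
        if t is None:
            t = NameTable()
            self.tables[namespace] = t
        return t

    def intern(self, namespace: str, name: str) -> int:
        return self.table(namespace).get_or_assign(name)

    def chromosome_id(self, token: str) -> int:
        t = token[3:] if token.lower().startswith("chr") else token
        if t.isdigit():
            return int(t)
        return 100 + self.intern("chromosome_nonnumeric", t)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for ns in sorted(self.tables):
                t = self.tables[ns]
                for i, name in enumerate(t._names):
                    fh.write(f"{ns}\t{name}\t{i}\n")

    @classmethod
    def load(cls, path) -> "NameRegistry":
        reg = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                ns, name, i = line.split("\t")
                t = reg.table(ns)
                assigned = t.get_or_assign(name)
                if assigned != int(i):
                    raise GenoKVError(f"{path}: inconsistent id for {name!r}")
        return reg


@dataclass
class ImportStats:
    rows: int = 0
    skipped: int = 0
    errors: List[str] = field(default_factory=list)


def _open_text(source) -> Tuple[io.TextIOBase, bool]:
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r"), True


def parse_snp_tsv(source, *, names: Optional[NameRegistry] = None,
                  strict: bool = True,
                  columns: Tuple[int, int, int, int, int] = (0, 1, 2, 3, 4),
                  stats: Optional[ImportStats] = None) -> Iterator[SnpRow]:
    """Parse a five-column SNP table (accession, chrom, pos, ref, alt).

    Lines starting with ``#`` are skipped.  ``columns`` gives the indices of
    the five fields for dialects with a different column order.  In strict
    mode a malformed line raises with its line number; in lenient mode it is
    counted and skipped.
    """
    names = names or NameRegistry()
    stats = stats if stats is not None else ImportStats()
    fh, owned = _open_text(source)
    ai, ci, pi, ri, mi = columns
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                acc = names.intern("accession", parts[ai])
                chrom = names.chromosome_id(parts[ci])
                pos = int(parts[pi])
                ref = parts[ri].upper()
                alt = parts[mi].upper()
                if pos < 1:
                    raise ValueError(f"position {pos} < 1")
                if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                    raise ValueError(f"bad nucleotide {ref!r}/{alt!r}")
            except (ValueError, IndexError) as exc:
                msg = f"line {lineno}: {exc}"
                if strict:
                    raise ImportError_(msg) from None
                stats.skipped += 1
                stats.errors.append(msg)
                continue
            stats.rows += 1
            yield SnpRow(acc, chrom, pos, ref, alt)
    finally:
        if owned:
            fh.close()


def parse_blast_tab(source, evalue_cutoff: float = 1e-20, *,
                    names: Optional[NameRegistry] = None,
                    strict: bool = True,
                    stats: Optional[ImportStats] = None) -> Iterator[HervRow]:
    """Parse BLAST tabular hits; keep rows with E-value strictly below cutoff.

    Columns: query id, subject id, query start, query end, subject start,
    subject end, E-value.  The query is the retroviral fragment, the subject
    the chromosome.  Minus-strand hits (subject start > end) are normalised
    to ascending coordinates with ``strand = 1``.
    """
    names = names or NameRegistry()
    stats = stats if stats is not None else ImportStats()
    fh, owned = _open_text(source)
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                herv_id = names.intern("herv", parts[0])
                chrom = names.chromosome_id(parts[1])
                q_start, q_end = int(parts[2]), int(parts[3])
                s_start, s_end = int(parts[4]), int(parts[5])
                evalue = float(parts[6])
                if evalue < 0:
                    raise ValueError(f"negative E-value {evalue}")
            except (ValueError, IndexError) as exc:
                msg = f"line {lineno}: {exc}"
                if strict:
                    raise ImportError_(msg) from None
                stats.skipped += 1
                stats.errors.append(msg)
                continue
            if not (evalue < evalue_cutoff):
                stats.skipped += 1
                continue
            strand = 0
            if s_start > s_end:
                s_start, s_end = s_end, s_start
                strand = 1
            if q_start > q_end:
                q_start, q_end = q_end, q_start
            stats.rows += 1
            yield HervRow(chrom, s_start, s_end, q_start, q_end,
                          herv_id, strand, evalue)
    finally:
        if owned:
            fh.close()


def import_vcf(path, accession_name: str, *,
               names: Optional[NameRegistry] = None) -> Iterator[SnpRow]:
    """Convenience VCF import: biallelic SNP records to SnpRow.

    One VCF file is treated as one accession (``accession_name``);
    multi-allelic sites and non-SNP alleles are skipped.
    """
    import pysam  # optional dependency, imported lazily

    names = names or NameRegistry()
    acc = names.intern("accession", accession_name)
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            if ref.upper() not in NUCLEOTIDES or alt.upper() not in NUCLEOTIDES:
                continue
            chrom = names.chromosome_id(rec.chrom)
            yield SnpRow(acc, chrom, rec.pos, ref.upper(), alt.upper())


# ----------------------------------------------------------------------
# synthetic generators
# ----------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def gen_snps(n: int, seed: int, *, n_accessions: int = 251,
             n_chromosomes: int = 5, max_pos: int = 30_000_000,
             dup_rate: float = 0.1) -> Iterator[SnpRow]:
    """Deterministic synthetic SNP stream.

    Defaults model a plant resequencing panel: 251 accessions, 5
    chromosomes of ~30 Mb, positions uniform.  A ``dup_rate`` fraction of
    rows re-emit an earlier row's key with a fresh value, exercising the
    update rule on key collisions.
    """
    if n == 0:
        return
    rng = np.random.default_rng(seed)
    acc = rng.integers(0, n_accessions, n)
    chrom = rng.integers(1, n_chromosomes + 1, n)
    pos = rng.integers(1, max_pos + 1, n)
    ref_i = rng.integers(0, 4, n)
    # mutated base differs from the reference base
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    if dup_rate > 0 and n > 1:
        dup = rng.random(n) < dup_rate
        dup[0] = False
        src = (rng.random(n) * np.arange(n)).astype(np.int64)
        # sequential so chained copies resolve to keys actually emitted
        for i in np.nonzero(dup)[0]:
            j = src[i]
            acc[i], chrom[i], pos[i] = acc[j], chrom[j], pos[j]
    ref = _BASES[ref_i]
    alt = _BASES[alt_i]
    for i in range(n):
        yield SnpRow(int(acc[i]), int(chrom[i]), int(pos[i]),
                     str(ref[i]), str(alt[i]))


def gen_herv(n: int, seed: int, *, n_chromosomes: int = 24,
             max_pos: int = 250_000_000, n_hervs: int = 7000,
             max_fragment_len: int = 10_000, dup_rate: float = 0.0,
             evalue_log10_range: Tuple[float, float] = (-60.0, -20.0)
             ) -> Iterator[HervRow]:
    """Deterministic synthetic retroviral-fragment hit stream.

    Defaults model fragment hits on a human-scale genome: 24 chromosomes of
    up to 250 Mb, ~7000 distinct fragments, hit lengths up to 10 kb, and
    E-values log-uniform over ``evalue_log10_range`` (default 1e-60..1e-20,
    bracketing the usual acceptance cutoff and filter grid).
    """
    if n == 0:
        return
    rng = np.random.default_rng(seed)
    chrom = rng.integers(1, n_chromosomes + 1, n)
    length = rng.integers(50, max_fragment_len + 1, n)
    start = rng.integers(1, max_pos - max_fragment_len, n)
    end = start + length
    herv_id = rng.integers(0, n_hervs, n)
    h_start = rng.integers(1, 5000, n)
    h_end = h_start + rng.integers(1, 5000, n)
    strand = rng.integers(0, 2, n)
    lo, hi = evalue_log10_range
    evalue = 10.0 ** rng.uniform(lo, hi, n)
    if dup_rate > 0 and n > 1:
        dup = rng.random(n) < dup_rate
        dup[0] = False
        src = (rng.random(n) * np.arange(n)).astype(np.int64)
        for i in np.nonzero(dup)[0]:
            j = src[i]
            for arr in (chrom, start, end, herv_id, h_start, h_end, strand):
                arr[i] = arr[j]
    for i in range(n):
        yield HervRow(int(chrom[i]), int(start[i]), int(end[i]),
                      int(h_start[i]), int(h_end[i]), int(herv_id[i]),
                      int(strand[i]), float(evalue[i]))
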