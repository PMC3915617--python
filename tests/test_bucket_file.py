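"""Bucket file format: round trips, sparse index, lazy opens, corruption."""

import os
import random

import pytest

from genokv.bucket_file import (
    HEADER_LEN,
    audit_bucket,
    open_bucket,
    write_bucket,
)
from genokv.errors import CorruptionError, IncompatibleFileError, IntegrityError
from genokv.schema import builtin_herv_schema, builtin_snp_schema

from conftest import random_snp_values

CHUNK = 16


def make_records(schema, n, seed=0):
    """n strictly-ascending encoded SNP records."""
    rng = random.Random(seed)
    keys = set()
    while len(keys) < n:
        keys.add(random_snp_values(rng)[:3])
    return [schema.encode(k + ("A", "G")) for k in sorted(keys)]


@pytest.fixture
def snp_records(snp_schema):
    return make_records(snp_schema, 2 * CHUNK + 1)


class TestWriteOpen:
    def test_empty_stream_gives_valid_empty_file(self, tmp_path, snp_schema):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, [], CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.record_count == 0
            assert b.index_entry_count == 0
            assert b.first_keys == []
            assert b.locate_chunk(b"\x00" * 7) is None

    @pytest.mark.parametrize("n", [0, 1, CHUNK - 1, CHUNK, CHUNK + 1,
                                   2 * CHUNK + 1, 1000])
    def test_round_trip_and_chunk_arithmetic(self, tmp_path, snp_schema, n):
        recs = make_records(snp_schema, n)
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, recs, CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.record_count == n
            assert b.n_chunks == -(-n // CHUNK)
            assert b.read_all() == recs
            audit_bucket(b)

    def test_three_chunks_for_2n_plus_1(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.n_chunks == 3
            assert b.index_entry_count == 3
            assert b.records_in_chunk(2) == 1
            assert b.read_chunk(2) == snp_records[-1:]

    def test_header_fields_round_trip(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.record_size == snp_schema.record_size
            assert b.chunk_size == CHUNK
            assert b.record_count == len(snp_records)
            assert b.index_entry_count == 3

    def test_file_length_equation(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        index_len = 3 * (snp_schema.key_size + 4)
        expected = HEADER_LEN + index_len + len(snp_records) * 9
        assert os.path.getsize(p) == expected

    def test_open_lazy_reads_header_and_index_only(self, tmp_path, snp_schema,
                                                   snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.bytes_read == HEADER_LEN + 3 * (snp_schema.key_size + 4)
            b.read_chunk(0)
            assert b.bytes_read > HEADER_LEN  # payload read only on demand

    def test_wrong_schema_rejected(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with pytest.raises(IncompatibleFileError):
            open_bucket(p, builtin_herv_schema())

    def test_bad_magic_rejected(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        raw = p.read_bytes()
        p.write_bytes(b"NOTMAGIC" + raw[8:])
        with pytest.raises(IncompatibleFileError):
            open_bucket(p, snp_schema)

    def test_truncated_file_is_corruption(self, tmp_path, snp_schema,
                                          snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        raw = p.read_bytes()
        p.write_bytes(raw[:-5])
        with pytest.raises(CorruptionError):
            open_bucket(p, snp_schema)


class TestIntegrity:
    def test_unsorted_input_rejected_no_file_left(self, tmp_path, snp_schema,
                                                  snp_records):
        p = tmp_path / "b.db"
        bad = [snp_records[1], snp_records[0]]
        with pytest.raises(IntegrityError):
            write_bucket(p, snp_schema, bad, CHUNK)
        assert not p.exists()
        assert list(tmp_path.iterdir()) == []  # no temp litter either

    def test_duplicate_key_rejected(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        with pytest.raises(IntegrityError):
            write_bucket(p, snp_schema, [snp_records[0]] * 2, CHUNK)
        assert not p.exists()

    def test_failed_rewrite_keeps_original(self, tmp_path, snp_schema,
                                           snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        before = p.read_bytes()
        with pytest.raises(IntegrityError):
            write_bucket(p, snp_schema, [snp_records[1], snp_records[0]], CHUNK)
        assert p.read_bytes() == before

    def test_wrong_record_size_rejected(self, tmp_path, snp_schema):
        with pytest.raises(IntegrityError):
            write_bucket(tmp_path / "b.db", snp_schema, [b"\x00" * 8], CHUNK)

    def test_audit_detects_flipped_index_key(self, tmp_path, snp_schema,
                                             snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            b.first_keys[1] = bytes(7)  # simulate an index/payload mismatch
            with pytest.raises(CorruptionError):
                audit_bucket(b)


class TestLocateChunk:
    def test_first_key_of_chunk_maps_to_that_chunk(self, tmp_path, snp_schema):
        recs = make_records(snp_schema, 10 * CHUNK)
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, recs, CHUNK)
        with open_bucket(p, snp_schema) as b:
            for c in range(b.n_chunks):
                assert b.locate_chunk(b.first_keys[c]) == c
                assert b.read_chunk(c)[0][:7] == b.first_keys[c]

    def test_key_before_first_clamps_to_chunk_zero(self, tmp_path, snp_schema,
                                                   snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records[1:], CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.locate_chunk(b"\x00" * 7) == 0

    def test_key_past_last_clamps_to_last_chunk(self, tmp_path, snp_schema,
                                                snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            assert b.locate_chunk(b"\xff" * 7) == b.n_chunks - 1

    def test_matches_linear_scan_oracle(self, tmp_path, snp_schema):
        recs = make_records(snp_schema, 20 * CHUNK + 3, seed=5)
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, recs, CHUNK)
        rng = random.Random(6)
        with open_bucket(p, snp_schema) as b:
            for _ in range(10_000):
                key = snp_schema.encode_key(random_snp_values(rng)[:3])
                # linear scan: last chunk whose first_key <= key, else 0
                expect = 0
                for c, fk in enumerate(b.first_keys):
                    if fk <= key:
                        expect = c
                assert b.locate_chunk(key) == expect

    def test_read_chunk_out_of_range(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            with pytest.raises(IndexError):
                b.read_chunk(3)

    def test_chunks_partition_read_all(self, tmp_path, snp_schema, snp_records):
        p = tmp_path / "b.db"
        write_bucket(p, snp_schema, snp_records, CHUNK)
        with open_bucket(p, snp_schema) as b:
            concat = [r for chunk in b.iter_chunks() for r in chunk]
            assert concat == b.read_all()
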