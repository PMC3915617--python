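import random

import pytest

from genokv.schema import builtin_herv_schema, builtin_snp_schema


@pytest.fixture
def snp_schema():
    return builtin_snp_schema()


@pytest.fixture
def herv_schema():
    return builtin_herv_schema()


def random_snp_values(rng: random.Random, max_pos: int = 2**32 - 1):
    bases = "ACGTN"
    return (
        rng.randrange(256),
        rng.randrange(65536),
        rng.randrange(max_pos + 1),
        rng.choice(bases),
        rng.choice(bases),
    )


def random_herv_values(rng: random.Random):
    return (
        rng.randrange(256),
        rng.randrange(2**32),
        rng.randrange(2**32),
        rng.randrange(65536),
        rng.randrange(65536),
        rng.randrange(65536),
        rng.randrange(2),
        10.0 ** rng.uniform(-60, -20),
    )


class DictOracle:
    """Independent reference: plain dict keyed by the decoded key tuple.

    Applies the same collision semantics as the store's update rule but is
    implemented with none of the store's machinery.
    """

    def __init__(self, n_key_parts: int, rule: str = "replace", reducer=None):
        self.k = n_key_parts
        self.rule = rule
        self.reducer = reducer
        self.d = {}

    def put(self, values: tuple):
        key, val = values[: self.k], values[self.k :]
        if key in self.d:
            if self.rule == "replace":
                self.d[key] = val
            elif self.rule == "keep_first":
                pass
            else:
                self.d[key] = self.reducer(self.d[key], val)
        else:
            self.d[key] = val

    def lookup(self, key: tuple):
        v = self.d.get(key)
        return key + v if v is not None else None

    def sorted_records(self):
        return [k + self.d[k] for k in sorted(self.d)]

    def range(self, k_start: tuple, k_end: tuple):
        return [k + self.d[k] for k in sorted(self.d) if k_start <= k <= k_end]

    def __len__(self):
        return len(self.d)
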