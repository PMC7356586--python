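from __future__ import annotations

import random

import pytest

from adapterid.sequence_io import Read


def make_reads(seqs: list[str]) -> list[Read]:
    return [Read(id=f"r{i}", seq=s) for i, s in enumerate(seqs)]


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240601)
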