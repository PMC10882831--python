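from __future__ import annotations

import numpy as np
import pytest

from tmseq import MoleculeConsensus, ReadRecord, ReferenceSet


@pytest.fixture
def small_reference() -> ReferenceSet:
    return ReferenceSet.random(n_transcripts=3, length=200, gc=0.5, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_read(
    seq: str,
    cb: str = "AAAA",
    umi: str = "CCCC",
    tx: str = "tx000",
    start: int = 0,
    rid: str = "r0",
    qual: int = 37,
) -> ReadRecord:
    return ReadRecord(rid, cb, umi, tx, start, seq, chr(qual + 33) * len(seq))


def make_molecule(
    seq: str,
    cb: str = "AAAA",
    umi: str = "CCCC",
    tx: str = "tx000",
    start: int = 0,
    family_size: int = 3,
) -> MoleculeConsensus:
    support = np.stack(
        [
            np.full(len(seq), family_size, dtype=np.int64),
            np.full(len(seq), family_size, dtype=np.int64),
        ],
        axis=1,
    )
    return MoleculeConsensus(cb, umi, tx, start, seq, support, family_size)


@pytest.fixture
def make_read_fn():
    return make_read


@pytest.fixture
def make_molecule_fn():
    return make_molecule
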