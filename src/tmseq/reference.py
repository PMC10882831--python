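"""Reference transcript sets.

A :class:`ReferenceSet` holds the mRNA-sense transcript sequences against
which RNA-DNA discrepancies are defined. Transcripts are single-stranded:
no reverse-complement folding is ever applied downstream, which is what
lets a C→U transcription-error signal be distinguished from the G→A
signal a DNA-level mutation would also produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, decode, encode


@dataclass(frozen=True)
class ReferenceSet:
    """An ordered collection of uniquely named ACGT transcript sequences."""

    transcripts: tuple[tuple[str, str], ...]
    _codes: dict[str, np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __init__(self, transcripts):
        transcripts = tuple((str(i), str(s).upper()) for i, s in transcripts)
        ids = [i for i, _ in transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")
        if not transcripts:
            raise ValueError("reference must contain at least one transcript")
        codes = {}
        for tid, seq in transcripts:
            if not seq:
                raise ValueError(f"transcript {tid!r} has empty sequence")
            c = encode(seq)
            if (c > 3).any():
                raise ValueError(
                    f"transcript {tid!r} contains bases outside {{A,C,G,T}}"
                )
            codes[tid] = c
        object.__setattr__(self, "transcripts", transcripts)
        object.__setattr__(self, "_codes", codes)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.transcripts)

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self._codes

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tx_id: str) -> str:
        return decode(self._codes[tx_id])

    def codes(self, tx_id: str) -> np.ndarray:
        """uint8 codes of one transcript (do not mutate)."""
        return self._codes[tx_id]

    def length(self, tx_id: str) -> int:
        return len(self._codes[tx_id])

    @property
    def min_length(self) -> int:
        return min(len(c) for c in self._codes.values())

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self._codes.values())

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(seq), id=tid, description="")
            for tid, seq in self.transcripts
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def random(
        cls,
        n_transcripts: int,
        length: int,
        gc: float = 0.5,
        seed: int = 0,
        prefix: str = "tx",
    ) -> "ReferenceSet":
        """Generate i.i.d. random transcripts with the given GC content."""
        if not 0.0 <= gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        rng = np.random.default_rng(seed)
        # order A, C, G, T
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        out = []
        for i in range(n_transcripts):
            codes = rng.choice(4, size=length, p=p).astype(np.uint8)
            out.append((f"{prefix}{i:03d}", decode(codes)))
        return cls(out)

    def base_composition(self) -> dict[str, int]:
        """Total count of each reference base across all transcripts."""
        counts = np.zeros(4, dtype=np.int64)
        for c in self._codes.values():
            counts += np.bincount(c, minlength=4)
        return {b: int(counts[i]) for i, b in enumerate(BASES)}
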