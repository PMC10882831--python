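"""UMI-family grouping and consensus collapsing.

Reads sharing one (cell barcode, UMI, transcript) key derive from a
single original mRNA molecule. Collapsing each family to a consensus
removes independent per-read sequencing errors and late-PCR errors: two
reads carrying the same wrong base at the same position by chance occur
at roughly (e/3)^2 per base for per-read error rate e, far below the
transcription-error signal of interest. PCR errors from the very first
duplications, inherited by every sampled read, survive consensus and form
an irreducible artifact floor (quantified in the test suite against the
simulator's ground truth).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._seq import N_CODE, decode, encode

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(
    r"^(?P<rid>[^|]+)\|CB:(?P<cb>[^|]+)\|UMI:(?P<umi>[^|]+)"
    r"\|TX:(?P<tx>[^|]+)\|POS:(?P<pos>\d+)$"
)

FamilyKey = tuple[str, str, str]  # (cell_barcode, umi, transcript_id)


@dataclass
class ReadRecord:
    """One sequencing read with its molecular annotations."""

    read_id: str
    cell_barcode: str
    umi: str
    transcript_id: str
    start: int  # 0-based offset on the transcript
    sequence: str
    qualities: str  # Phred+33

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        if self.start < 0:
            raise ValueError("start must be >= 0")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class MoleculeConsensus:
    """One original mRNA molecule collapsed from its UMI family.

    ``consensus_sequence`` covers the intersection of the family's read
    extents; positions without the required agreement are masked as N and
    excluded from every downstream denominator. ``per_base_support`` holds
    (n_agree, n_total) per position.
    """

    cell_barcode: str
    umi: str
    transcript_id: str
    start: int
    consensus_sequence: str
    per_base_support: np.ndarray  # (L, 2) int
    family_size: int

    def __len__(self) -> int:
        return len(self.consensus_sequence)

    @property
    def end(self) -> int:
        return self.start + len(self.consensus_sequence)


@dataclass(frozen=True)
class Rejected:
    """Marker for a family that could not be collapsed."""

    reason: str
    key: FamilyKey | None = None
    family_size: int = 0


def parse_read_name(name: str):
    """Parse the tmseq read-name dialect; None if it does not match."""
    m = _NAME_RE.match(name)
    if m is None:
        return None
    return m["rid"], m["cb"], m["umi"], m["tx"], int(m["pos"])


def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse a FASTQ in the simulator dialect into ReadRecords.

    Reads whose names lack the CB/UMI/TX/POS annotations are dropped and
    tallied to the log.
    """
    dropped = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            parsed = parse_read_name(header[1:].rstrip("\n"))
            if parsed is None:
                dropped += 1
                continue
            rid, cb, umi, tx, pos = parsed
            if cb == "-" or umi == "-":
                dropped += 1
                continue
            yield ReadRecord(rid, cb, umi, tx, pos, seq, qual)
    if dropped:
        logger.warning("read_fastq: dropped %d reads without CB/UMI tags", dropped)


def read_sam(path, cb_tag: str = "CB", umi_tag: str = "UB") -> Iterator[ReadRecord]:
    """Parse an aligned SAM/BAM with cell-barcode and UMI tags.

    Tag names follow the 10x convention by default but are configurable.
    Unmapped reads and reads missing either tag are dropped and tallied.
    """
    import pysam

    dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or not aln.has_tag(cb_tag) or not aln.has_tag(umi_tag):
                dropped += 1
                continue
            qual = aln.query_qualities
            qstr = (
                "".join(chr(q + 33) for q in qual)
                if qual is not None
                else "I" * len(aln.query_sequence)
            )
            yield ReadRecord(
                aln.query_name,
                str(aln.get_tag(cb_tag)),
                str(aln.get_tag(umi_tag)),
                aln.reference_name,
                aln.reference_start,
                aln.query_sequence,
                qstr,
            )
    if dropped:
        logger.warning("read_sam: dropped %d unusable reads", dropped)


def group_families(reads: Iterable[ReadRecord]) -> dict[FamilyKey, list[ReadRecord]]:
    """Partition reads into UMI families by exact (CB, UMI, TX) match.

    Identical UMIs in different cells (or on different transcripts) form
    distinct families. No directional-adjacency collapsing of near-miss
    UMIs is attempted (logged once as a limitation).
    """
    families: dict[FamilyKey, list[ReadRecord]] = {}
    n = 0
    for read in reads:
        families.setdefault(
            (read.cell_barcode, read.umi, read.transcript_id), []
        ).append(read)
        n += 1
    logger.info("group_families: %d reads -> %d families", n, len(families))
    return families


def build_consensus(
    family: list[ReadRecord],
    min_reads: int = 2,
    min_agreement: float = 1.0,
) -> MoleculeConsensus | Rejected:
    """Collapse one UMI family to a molecule consensus.

    Per aligned column the majority base is taken; a column is masked N
    unless the top base reaches ``min_agreement`` of the family and beats
    the runner-up strictly (ties are always masked, never broken). The
    default (min_reads=2, unanimity) makes a surviving artifact require
    two independent reads with the same wrong base.

    Positions not covered by every read are trimmed (extent intersection),
    keeping n_total equal to the family size at every retained position.
    """
    if not family:
        return Rejected("empty_family")
    key = (family[0].cell_barcode, family[0].umi, family[0].transcript_id)
    if any(
        (r.cell_barcode, r.umi, r.transcript_id) != key for r in family[1:]
    ):
        return Rejected("chimeric_family", key, len(family))
    if len(family) < min_reads:
        return Rejected("small_family", key, len(family))
    lo = max(r.start for r in family)
    hi = min(r.end for r in family)
    if hi <= lo:
        return Rejected("no_overlap", key, len(family))
    k = len(family)
    mat = np.empty((k, hi - lo), dtype=np.uint8)
    for i, r in enumerate(family):
        mat[i] = encode(r.sequence)[lo - r.start : hi - r.start]
    # column-wise base counts
    counts = np.zeros((4, hi - lo), dtype=np.int64)
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    order = np.sort(counts, axis=0)
    top, runner = order[-1], order[-2]
    winner = counts.argmax(axis=0).astype(np.uint8)
    ok = (top >= min_agreement * k) & (top > runner)
    consensus = np.where(ok, winner, np.uint8(N_CODE))
    support = np.stack([top, np.full_like(top, k)], axis=1)
    return MoleculeConsensus(
        cell_barcode=key[0],
        umi=key[1],
        transcript_id=key[2],
        start=lo,
        consensus_sequence=decode(consensus),
        per_base_support=support,
        family_size=k,
    )


def collapse_families(
    families: dict[FamilyKey, list[ReadRecord]],
    min_reads: int = 2,
    min_agreement: float = 1.0,
) -> tuple[list[MoleculeConsensus], dict[str, int]]:
    """Collapse every family; return consensus molecules and a rejection tally."""
    molecules: list[MoleculeConsensus] = []
    tally: dict[str, int] = {}
    for key in sorted(families):
        result = build_consensus(families[key], min_reads, min_agreement)
        if isinstance(result, Rejected):
            tally[result.reason] = tally.get(result.reason, 0) + 1
        else:
            molecules.append(result)
    if tally:
        logger.info("collapse_families: rejections %s", tally)
    logger.info(
        "collapse_families: %d families -> %d consensus molecules",
        len(families),
        len(molecules),
    )
    return molecules, tally


def write_consensus_tsv(molecules: list[MoleculeConsensus], path) -> None:
    """Serialize consensus molecules (per-base support reduced to its minimum)."""
    rows = [
        {
            "cell_barcode": m.cell_barcode,
            "umi": m.umi,
            "transcript_id": m.transcript_id,
            "start": m.start,
            "family_size": m.family_size,
            "min_support": int(m.per_base_support[:, 0].min()) if len(m) else 0,
            "consensus_sequence": m.consensus_sequence,
        }
        for m in molecules
    ]
    with open(path, "w") as fh:
        fh.write("# tmseq consensus molecules; start 0-based; masked bases = N\n")
        pd.DataFrame(
            rows,
            columns=[
                "cell_barcode",
                "umi",
                "transcript_id",
                "start",
                "family_size",
                "min_support",
                "consensus_sequence",
            ],
        ).to_csv(fh, sep="\t", index=False)


def read_consensus_tsv(path) -> list[MoleculeConsensus]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in frame.itertuples(index=False):
        seq = str(row.consensus_sequence)
        support = np.stack(
            [
                np.full(len(seq), row.family_size, dtype=np.int64),
                np.full(len(seq), row.family_size, dtype=np.int64),
            ],
            axis=1,
        )
        out.append(
            MoleculeConsensus(
                cell_barcode=str(row.cell_barcode),
                umi=str(row.umi),
                transcript_id=str(row.transcript_id),
                start=int(row.start),
                consensus_sequence=seq,
                per_base_support=support,
                family_size=int(row.family_size),
            )
        )
    return out
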