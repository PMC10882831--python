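"""Rolling-circle consensus sequencing (CirSeq) analysis.

In CirSeq an RNA fragment is circularized and copied in tandem within a
single read, so errors made during transcription travel with the fragment
into *every* repeat, while sequencing errors hit individual copies.
Folding the tandem repeats into an intra-read consensus therefore
suppresses per-copy sequencing errors (residual O(e²) per column for
3 repeats) and preserves transcription errors — giving a bulk estimate of
the overall transcription error output (N→N) without cell barcodes.

Period detection is by self-offset mismatch minimization: transparent,
exhaustively checkable against a brute-force scan, and adequate at the
scales this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import BASES, N_CODE, SUB_TYPES, decode, encode
from .calling import ErrorSpectrum
from .consensus import Rejected, parse_read_name
from .reference import ReferenceSet

logger = logging.getLogger(__name__)


@dataclass
class RepeatConsensus:
    """One rolling-circle read folded to its repeat-unit consensus."""

    read_id: str
    period: int
    n_repeats: int
    consensus_sequence: str  # length = period; masked columns are N
    per_base_support: np.ndarray  # (period, 2): (n_agree, n_total)
    transcript_id: str | None = None
    start: int | None = None  # 0-based fragment origin on the transcript

    def __len__(self) -> int:
        return len(self.consensus_sequence)


def detect_period(
    read_sequence: str,
    min_period: int,
    max_period: int,
    max_mismatch_frac: float = 0.1,
    min_repeats: int = 3,
) -> int | None:
    """Find the tandem-repeat period of a rolling-circle read.

    Returns the period p minimizing the mismatch fraction between
    ``read[0:L-p]`` and ``read[p:L]``, among candidates with mismatch
    fraction <= ``max_mismatch_frac`` and at least ``min_repeats`` full
    repeats (``L // p``); ties go to the smallest p. None if no candidate
    qualifies. Appending fewer than ``period`` trailing bases does not
    change the result for a true tandem read.
    """
    codes = encode(read_sequence)
    L = len(codes)
    if min_period < 1:
        raise ValueError("min_period must be >= 1")
    if L < 2 * min_period:
        raise ValueError("read shorter than 2 x min_period")
    best_p, best_frac = None, None
    for p in range(min_period, min(max_period, L - 1) + 1):
        if L // p < min_repeats:
            continue
        mism = int((codes[: L - p] != codes[p:]).sum())
        frac = mism / (L - p)
        if frac > max_mismatch_frac:
            continue
        if best_frac is None or frac < best_frac:
            best_p, best_frac = p, frac
    return best_p


def fold_consensus(
    read_sequence: str,
    qualities: str,
    period: int,
    min_repeats: int = 3,
    max_masked_frac: float = 0.2,
    read_id: str = "",
    transcript_id: str | None = None,
    start: int | None = None,
) -> RepeatConsensus | Rejected:
    """Fold a rolling-circle read into its repeat-unit consensus.

    Column j takes the quality-weighted plurality over read[j],
    read[j+p], read[j+2p], ...; a column is masked N when the winning
    base's summed quality is less than twice the runner-up's (ties are
    always masked). Partial trailing repeats contribute to the columns
    they cover. REJECTED if more than ``max_masked_frac`` of columns are
    masked.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    codes = encode(read_sequence)
    L = len(codes)
    if len(qualities) != L:
        raise ValueError("sequence and qualities must have equal length")
    quals = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8).astype(
        np.int64
    ) - 33
    n_repeats = L // period
    col = np.arange(L) % period
    qsum = np.zeros((period, 4), dtype=np.int64)
    counts = np.zeros((period, 4), dtype=np.int64)
    np.add.at(qsum, (col, codes), quals)
    np.add.at(counts, (col, codes), 1)
    order = np.argsort(qsum, axis=1, kind="stable")
    win = order[:, -1]
    rows = np.arange(period)
    win_q = qsum[rows, win]
    run_q = qsum[rows, order[:, -2]]
    masked = win_q < 2 * run_q  # ties always masked
    consensus = np.where(masked, np.uint8(N_CODE), win.astype(np.uint8))
    support = np.stack(
        [counts[rows, win], np.bincount(col, minlength=period)], axis=1
    )
    masked_frac = float(masked.mean())
    if masked_frac > max_masked_frac:
        return Rejected("too_masked", None, n_repeats)
    return RepeatConsensus(
        read_id=read_id,
        period=period,
        n_repeats=n_repeats,
        consensus_sequence=decode(consensus),
        per_base_support=support,
        transcript_id=transcript_id,
        start=start,
    )


def fold_fastq(
    path,
    min_period: int,
    max_period: int,
    max_mismatch_frac: float = 0.1,
    min_repeats: int = 3,
    max_masked_frac: float = 0.2,
) -> tuple[list[RepeatConsensus], dict[str, int]]:
    """Detect periods and fold every read of a CirSeq FASTQ.

    Reads carry the simulator name dialect, whose TX/POS fields provide
    the reference mapping (external data would need an aligner, which is
    out of scope here). Returns folded consensi and a tally of reads
    dropped at each stage.
    """
    consensi: list[RepeatConsensus] = []
    tally = {"no_period": 0, "too_masked": 0, "unparsed_name": 0}
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            parsed = parse_read_name(header[1:].rstrip("\n"))
            if parsed is None:
                tally["unparsed_name"] += 1
                continue
            rid, _, _, tx, pos = parsed
            p = detect_period(seq, min_period, max_period, max_mismatch_frac, min_repeats)
            if p is None:
                tally["no_period"] += 1
                continue
            folded = fold_consensus(
                seq, qual, p, min_repeats, max_masked_frac, rid, tx, pos
            )
            if isinstance(folded, Rejected):
                tally["too_masked"] += 1
                continue
            consensi.append(folded)
    logger.info("fold_fastq: %d consensi, dropped %s", len(consensi), tally)
    return consensi, tally


def cirseq_error_rate(
    consensi: list[RepeatConsensus],
    reference: ReferenceSet,
    sample_id: str = "cirseq",
    mut_frac_threshold: float = 0.95,
    min_mut_coverage: int = 10,
) -> ErrorSpectrum:
    """Overall N→N error rate and 12-type breakdown of folded consensi.

    Bulk data has no cell structure, so the DNA-mutation exclusion uses a
    pooled per-site rule: a (transcript, position, alt) whose mutant
    fraction across consensi reaches ``mut_frac_threshold`` at coverage
    >= ``min_mut_coverage`` is removed from numerator and denominator.
    """
    # per-consensus sparse tallies: mismatch and masked positions only
    mism: dict[tuple[str, int, int], int] = {}
    masked_at: dict[tuple[str, int], int] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    surveyed = np.zeros(4, dtype=np.int64)
    per_cons = []
    for cons in consensi:
        if cons.transcript_id is None or cons.start is None:
            raise ValueError(f"consensus {cons.read_id!r} lacks a reference mapping")
        if cons.transcript_id not in reference:
            raise KeyError(f"transcript {cons.transcript_id!r} not in reference")
        ref = reference.codes(cons.transcript_id)
        if cons.start + len(cons) > len(ref):
            raise ValueError(
                f"consensus {cons.read_id!r} extends past end of "
                f"{cons.transcript_id}"
            )
        codes = encode(cons.consensus_sequence)
        refslice = ref[cons.start : cons.start + len(cons)]
        unmasked = codes != N_CODE
        surveyed += np.bincount(refslice[unmasked], minlength=4)
        intervals.setdefault(cons.transcript_id, []).append(
            (cons.start, cons.start + len(cons))
        )
        for rel in np.flatnonzero(~unmasked):
            key = (cons.transcript_id, cons.start + int(rel))
            masked_at[key] = masked_at.get(key, 0) + 1
        sites = []
        for rel in np.flatnonzero(unmasked & (codes != refslice)):
            pos = cons.start + int(rel)
            mkey = (cons.transcript_id, pos, int(codes[rel]))
            mism[mkey] = mism.get(mkey, 0) + 1
            sites.append((pos, int(codes[rel]), int(refslice[rel])))
        per_cons.append(sites)

    starts_ends = {
        tx: (
            np.sort(np.array([a for a, _ in iv], dtype=np.int64)),
            np.sort(np.array([b for _, b in iv], dtype=np.int64)),
        )
        for tx, iv in intervals.items()
    }

    def unmasked_cover(tx: str, pos: int) -> int:
        starts, ends = starts_ends[tx]
        n = int(
            np.searchsorted(starts, pos, side="right")
            - np.searchsorted(ends, pos, side="right")
        )
        return n - masked_at.get((tx, pos), 0)

    excluded: set[tuple[str, int]] = set()
    for (tx, pos, alt), n in mism.items():
        total = unmasked_cover(tx, pos)
        if total >= min_mut_coverage and n / total >= mut_frac_threshold:
            excluded.add((tx, pos))

    errors = {t: 0 for t in SUB_TYPES}
    for cons, sites in zip(consensi, per_cons):
        for pos, alt, refb in sites:
            if (cons.transcript_id, pos) in excluded:
                continue
            errors[(BASES[refb], BASES[alt])] += 1
    for tx, pos in excluded:
        refb = reference.codes(tx)[pos]
        surveyed[refb] -= unmasked_cover(tx, pos)

    spec = ErrorSpectrum(
        sample_id, errors, {b: int(surveyed[i]) for i, b in enumerate(BASES)}
    )
    logger.info(
        "cirseq_error_rate[%s]: %d consensi, %d errors / %d surveyed "
        "(%d sites excluded)",
        sample_id,
        len(consensi),
        spec.total_errors,
        spec.total_surveyed,
        len(excluded),
    )
    return spec
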