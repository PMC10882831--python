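"""Sparse consensus-and-calling engine for simulated libraries.

Large parameter-recovery experiments need tens of millions of surveyed
consensus bases. Because stochastic errors are sparse, the full
FASTQ → family grouping → column-vote consensus → per-site tally pipeline
is equivalent to bookkeeping over the simulator's event lists: a consensus
column can deviate from the reference (or be masked) only at a position
touched by at least one event. This module performs exactly that
bookkeeping — same unanimity rule, same masking, same call and spectrum
definitions as :mod:`tmseq.consensus` / :mod:`tmseq.calling` — and the
test suite asserts byte-exact agreement of calls and spectra between the
two routes on randomized configurations.

Only the default unanimity agreement rule (``min_agreement=1.0``) is
supported here; any other setting must use the record-based path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import BASES
from .calling import (
    CANDIDATE_DNA_MUTATION,
    TRANSCRIPTION_ERROR,
    DiscrepancyCall,
    ErrorSpectrum,
    classify_calls,
)
from .simulate import SimulatedCells

logger = logging.getLogger(__name__)


@dataclass
class EngineResult:
    """Outcome of collapsing and calling one simulated library."""

    calls: list[DiscrepancyCall]
    spectrum: ErrorSpectrum
    n_molecules: int  # consensus molecules kept
    n_rejected: int  # families below min_reads
    total_consensus_bases: int  # unmasked + masked (before site exclusion)
    masked_bases: int


def _prefix_counts(codes: np.ndarray) -> np.ndarray:
    """(4, L+1) prefix sums of base occurrence for one transcript."""
    out = np.zeros((4, len(codes) + 1), dtype=np.int64)
    for b in range(4):
        np.cumsum(codes == b, out=out[b, 1:])
    return out


class _Coverage:
    """Counts of kept molecules covering a transcript position, per cell."""

    def __init__(self, sim: SimulatedCells, keep: np.ndarray):
        self.sim = sim
        self.keep = keep
        self._cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def _group(self, cell: int, tx: int):
        key = (cell, tx)
        if key not in self._cache:
            lo, hi = self.sim.molecule_range(cell, tx)
            sel = np.flatnonzero(self.keep[lo:hi]) + lo
            starts = self.sim.mol_start[sel]
            ends = starts + self.sim.mol_len[sel]
            self._cache[key] = (np.sort(starts), np.sort(ends))
        return self._cache[key]

    def count(self, cell: int, tx: int, pos: int) -> int:
        starts, ends = self._group(cell, tx)
        return int(
            np.searchsorted(starts, pos, side="right")
            - np.searchsorted(ends, pos, side="right")
        )


def collapse_and_call(
    sim: SimulatedCells,
    min_reads: int = 2,
    min_agreement: float = 1.0,
    mut_frac_threshold: float = 0.95,
    min_mut_coverage: int = 10,
    sample_id: str = "sample",
    unit: str = "molecule",
) -> EngineResult:
    """Collapse UMI families and call discrepancies from simulator events."""
    if min_agreement != 1.0:
        raise NotImplementedError(
            "the sparse engine implements the unanimity rule only; "
            "use the record-based pipeline for min_agreement < 1"
        )
    if unit not in ("molecule", "site"):
        raise ValueError("unit must be 'molecule' or 'site'")
    cfg = sim.config
    ref = sim.reference
    n_tx = len(ref)
    n_mols = sim.n_molecules
    keep = sim.mol_reads >= min_reads
    n_rejected = int((~keep).sum())

    # ---- denominator: per-base reference composition over kept extents ----
    surveyed = np.zeros(4, dtype=np.int64)
    prefixes = {}
    for t, tid in enumerate(ref.ids):
        prefixes[t] = _prefix_counts(ref.codes(tid))
    for t in range(n_tx):
        sel = np.flatnonzero(keep & (sim.mol_tx == t))
        if len(sel) == 0:
            continue
        P = prefixes[t]
        s = sim.mol_start[sel]
        e = s + sim.mol_len[sel]
        for b in range(4):
            surveyed[b] += int((P[b, e] - P[b, s]).sum())
    total_consensus_bases = int(sim.mol_len[keep].sum())

    if n_mols == 0:
        spec = ErrorSpectrum(sample_id, {}, {b: 0 for b in BASES}, unit=unit)
        return EngineResult([], spec, 0, n_rejected, 0, 0)

    M = int(sim.mol_len.max()) + 1

    # ---- event pairs on kept molecules ----
    se_mol = sim.read_mol[sim.se_read] if len(sim.se_read) else np.array([], dtype=np.int64)
    se_keep = keep[se_mol] if len(se_mol) else np.array([], dtype=bool)
    k_seq = se_mol[se_keep] * M + sim.se_pos[se_keep]
    seq_delta = sim.se_delta[se_keep]
    seq_read = sim.se_read[se_keep]

    pe_keep = keep[sim.pe_mol] if len(sim.pe_mol) else np.array([], dtype=bool)
    k_pcr = sim.pe_mol[pe_keep] * M + sim.pe_pos[pe_keep]

    sub_keep = keep[sim.sub_mol] if len(sim.sub_mol) else np.array([], dtype=bool)
    k_sub = sim.sub_mol[sub_keep] * M + sim.sub_pos[sub_keep]
    sub_base_kept = sim.sub_base[sub_keep]

    order_seq = np.argsort(k_seq, kind="stable")
    k_seq_sorted = k_seq[order_seq]
    uniq_seq, first_seq, count_seq = (
        np.unique(k_seq_sorted, return_index=True, return_counts=True)
        if len(k_seq)
        else (np.array([], dtype=np.int64),) * 3
    )

    loop_keys = np.union1d(np.unique(k_pcr), uniq_seq[count_seq >= 2])
    single = np.setdiff1d(uniq_seq[count_seq == 1], loop_keys, assume_unique=True)

    sub_sorted_order = np.argsort(k_sub, kind="stable")
    k_sub_sorted = k_sub[sub_sorted_order]
    sub_base_sorted = sub_base_kept[sub_sorted_order]

    def mol_base_at(key: int) -> int:
        """Final molecule (transcription-level) base at an event position."""
        i = np.searchsorted(k_sub_sorted, key)
        if i < len(k_sub_sorted) and k_sub_sorted[i] == key:
            return int(sub_base_sorted[i])
        m, pos = divmod(key, M)
        return sim.ref_base_abs(sim.mol_tx[m], int(sim.mol_start[m] + pos))

    masked_keys: list[np.ndarray] = []
    mism_key: list[int] = []
    mism_alt: list[int] = []

    # ---- vectorized common case: exactly one sequencing error at a column ----
    if len(single):
        mols = single // M
        fam1 = sim.mol_reads[mols] == 1
        masked_keys.append(single[~fam1])
        if fam1.any():
            # single-read families adopt the errored read verbatim
            idx = first_seq[
                np.searchsorted(uniq_seq, single[fam1])
            ]  # position in sorted seq arrays
            deltas = seq_delta[order_seq][idx]
            for key, d in zip(single[fam1], deltas):
                base = (mol_base_at(int(key)) + int(d)) % 4
                m, pos = divmod(int(key), M)
                rb = sim.ref_base_abs(sim.mol_tx[m], int(sim.mol_start[m] + pos))
                if base != rb:
                    mism_key.append(int(key))
                    mism_alt.append(base)

    # ---- rare case: PCR-affected or multiply-hit columns ----
    D = cfg.pcr_cycles
    seq_read_sorted = seq_read[order_seq]
    seq_delta_sorted = seq_delta[order_seq]
    se_pos_kept = sim.se_pos[se_keep][order_seq]
    for key in loop_keys:
        key = int(key)
        m, pos = divmod(key, M)
        r0 = int(np.searchsorted(sim.read_mol, m, side="left"))
        r1 = int(np.searchsorted(sim.read_mol, m, side="right"))
        deltas = np.zeros(r1 - r0, dtype=np.int64)
        p0 = int(np.searchsorted(sim.pe_mol, m, side="left"))
        p1 = int(np.searchsorted(sim.pe_mol, m, side="right"))
        for j in range(p0, p1):
            if sim.pe_pos[j] != pos or not pe_keep[j]:
                continue
            anc = (sim.read_leaf[r0:r1] >> (D - sim.pe_level[j])) == sim.pe_node[j]
            deltas[anc] += sim.pe_delta[j]
        s0 = int(np.searchsorted(k_seq_sorted, key, side="left"))
        s1 = int(np.searchsorted(k_seq_sorted, key, side="right"))
        for j in range(s0, s1):
            deltas[int(seq_read_sorted[j]) - r0] += int(seq_delta_sorted[j])
        deltas %= 4
        if (deltas == deltas[0]).all():
            base = (mol_base_at(key) + int(deltas[0])) % 4
            rb = sim.ref_base_abs(sim.mol_tx[m], int(sim.mol_start[m] + pos))
            if base != rb:
                mism_key.append(key)
                mism_alt.append(base)
        else:
            masked_keys.append(np.array([key], dtype=np.int64))
    del se_pos_kept

    masked = (
        np.concatenate(masked_keys) if masked_keys else np.array([], dtype=np.int64)
    )

    # ---- molecule-level substitutions at untouched columns ----
    # (single ∪ loop_keys covers every column with a read-level event,
    # whatever its outcome; masked adds nothing but costs nothing)
    touched = np.union1d(np.union1d(masked, loop_keys), single)
    pure = ~np.isin(k_sub_sorted, touched)
    for key, base in zip(k_sub_sorted[pure], sub_base_sorted[pure]):
        m, pos = divmod(int(key), M)
        rb = sim.ref_base_abs(sim.mol_tx[m], int(sim.mol_start[m] + pos))
        if int(base) != rb:
            mism_key.append(int(key))
            mism_alt.append(int(base))

    # ---- masked bases leave the denominator ----
    if len(masked):
        mols = masked // M
        pos = masked % M
        refb = sim._ref_concat[
            sim._tx_offset[sim.mol_tx[mols]] + sim.mol_start[mols] + pos
        ]
        surveyed -= np.bincount(refb, minlength=4)

    # ---- aggregate mismatches into per-cell per-site calls ----
    coverage = _Coverage(sim, keep)
    mism_key_arr = np.array(mism_key, dtype=np.int64)
    mism_alt_arr = np.array(mism_alt, dtype=np.int64)
    calls: list[DiscrepancyCall] = []
    site_mism: dict[tuple[int, int, int], int] = {}  # (cell, tx, pos) -> any-alt count
    site_masked: dict[tuple[int, int], int] = {}  # (tx, abs pos) -> masked molecules
    cell_masked: dict[tuple[int, int, int], int] = {}
    if len(masked):
        mols = masked // M
        pos = masked % M
        for m, p in zip(mols, pos):
            tx = int(sim.mol_tx[m])
            ap = int(sim.mol_start[m] + p)
            site_masked[(tx, ap)] = site_masked.get((tx, ap), 0) + 1
            ck = (int(sim.mol_cell[m]), tx, ap)
            cell_masked[ck] = cell_masked.get(ck, 0) + 1
    if len(mism_key_arr):
        mols = mism_key_arr // M
        pos = mism_key_arr % M
        cells = sim.mol_cell[mols]
        txs = sim.mol_tx[mols]
        apos = sim.mol_start[mols] + pos
        for c, t, p in zip(cells, txs, apos):
            k = (int(c), int(t), int(p))
            site_mism[k] = site_mism.get(k, 0) + 1
        agg: dict[tuple[int, int, int, int], int] = {}
        for c, t, p, a in zip(cells, txs, apos, mism_alt_arr):
            k = (int(c), int(t), int(p), int(a))
            agg[k] = agg.get(k, 0) + 1
        for (c, t, p, a) in sorted(agg):
            n_mut = agg[(c, t, p, a)]
            cover = coverage.count(c, t, p)
            n_wt = (
                cover
                - cell_masked.get((c, t, p), 0)
                - site_mism[(c, t, p)]
            )
            calls.append(
                DiscrepancyCall(
                    cell_barcode=str(sim.barcodes[c]),
                    transcript_id=ref.ids[t],
                    position=p,
                    ref_base=BASES[sim.ref_base_abs(t, p)],
                    alt_base=BASES[a],
                    n_mut=n_mut,
                    n_wt=n_wt,
                )
            )

    classify_calls(calls, mut_frac_threshold, min_mut_coverage)

    # ---- spectrum ----
    tx_index = {tid: i for i, tid in enumerate(ref.ids)}
    excluded = {
        (c.transcript_id, c.position)
        for c in calls
        if c.classification == CANDIDATE_DNA_MUTATION
    }
    errors = {t: 0 for t in [(x, y) for x in BASES for y in BASES if x != y]}
    seen_sites: set[tuple[str, int, str]] = set()
    for c in calls:
        if c.classification != TRANSCRIPTION_ERROR:
            continue
        if (c.transcript_id, c.position) in excluded:
            continue
        if unit == "molecule":
            errors[(c.ref_base, c.alt_base)] += c.n_mut
        else:
            site = (c.transcript_id, c.position, c.alt_base)
            if site not in seen_sites:
                seen_sites.add(site)
                errors[(c.ref_base, c.alt_base)] += 1
    for tx, pos in excluded:
        t = tx_index[tx]
        cover = sum(coverage.count(c, t, pos) for c in range(cfg.n_cells))
        cover -= site_masked.get((t, pos), 0)
        surveyed[ref.codes(tx)[pos]] -= cover

    surveyed_d = {b: int(surveyed[i]) for i, b in enumerate(BASES)}
    spec = ErrorSpectrum(sample_id, errors, surveyed_d, unit=unit)
    logger.info(
        "engine[%s]: %d molecules (%d rejected), %d masked bases, "
        "%d calls, %d errors / %d surveyed",
        sample_id,
        int(keep.sum()),
        n_rejected,
        len(masked),
        len(calls),
        spec.total_errors,
        spec.total_surveyed,
    )
    return EngineResult(
        calls=calls,
        spectrum=spec,
        n_molecules=int(keep.sum()),
        n_rejected=n_rejected,
        total_consensus_bases=total_consensus_bases,
        masked_bases=int(len(masked)),
    )
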