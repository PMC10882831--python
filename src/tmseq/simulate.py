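"""Forward simulation of lesion-driven transcription errors.

The generator emulates the molecular biology that a UMI-based
transcriptional-mutagenesis (TM) analysis must disentangle, in quiescent
(non-replicating) cells:

* **Lesions** (O6-methylguanine-like) sit on one DNA allele of a site and
  cause a recurrent cognate miscoding (default C→T, i.e. C→U in RNA) in a
  fraction of the transcripts from that cell — the source of pseudo-alleles.
* **True DNA mutations** affect (essentially) 100% of a cell's transcripts
  covering the site.
* **Background transcription errors** are i.i.d. per molecule base.
* **PCR errors** occur per duplication on a binary amplification tree, so
  an early error is inherited by a *subset* of a UMI family's reads.
* **Sequencing errors** are i.i.d. per read base.

Internally the simulator draws an explicit sparse *event* representation.
Reads are materialized to FASTQ from those events; the high-throughput
consensus engine (:mod:`tmseq.engine`) consumes the same events directly,
so the two routes are exactly equivalent by construction (and by test).

Substitution alt bases for stochastic errors are drawn as a delta
``r ∈ {1,2,3}`` applied as ``(base + r) mod 4`` — uniform over the three
non-current bases; deltas are additive mod 4, so stacked errors compose
commutatively. Lesion and mutation events carry absolute alt bases.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import BASES, decode, encode
from .reference import ReferenceSet

TRUTH_COLUMNS = [
    "cell_id",
    "transcript_id",
    "position",
    "kind",
    "ref_base",
    "alt_base",
    "expected_mutant_fraction",
]


@dataclass
class TruthTable:
    """Ground truth of simulated lesion / DNA-mutation events.

    One row per event; ``position`` is 0-based on the transcript.
    ``expected_mutant_fraction`` is the per-molecule probability that a
    transcript covering the site carries the alt base: 1.0 for DNA
    mutations (quiescent cells, no subclonal replication), and
    ``lesioned_allele_fraction × lesion_miscoding_prob`` for lesions.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = set(TRUTH_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        kinds = set(self.frame["kind"].unique())
        if not kinds <= {"lesion", "dna_mutation"}:
            raise ValueError(f"unknown truth kinds: {kinds}")
        dna = self.frame[self.frame["kind"] == "dna_mutation"]
        if len(dna) and not (dna["expected_mutant_fraction"] == 1.0).all():
            raise ValueError("dna_mutation rows must have expected fraction 1.0")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def empty(cls) -> "TruthTable":
        return cls(pd.DataFrame(columns=TRUTH_COLUMNS))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# tmseq truth table; positions 0-based\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward simulation.

    Counts are means of (shifted) Poisson draws where noted; probabilities
    are per-base or per-event as documented on each field.
    """

    n_cells: int = 50
    #: mean molecules per (cell, transcript); Poisson
    molecules_per_cell_per_transcript: float = 4.0
    #: mean reads per molecule; shifted Poisson with minimum below
    reads_per_molecule: float = 3.0
    min_reads_per_molecule: int = 2
    #: None → molecules span the whole transcript
    fragment_length: int | None = None
    #: P(lesion on one allele) per eligible (ref == lesion_ref_base) base per cell
    lesion_site_rate: float = 0.0
    #: P(transcript from the lesioned allele carries the cognate error)
    lesion_miscoding_prob: float = 1.0
    lesion_ref_base: str = "C"
    lesion_alt_base: str = "T"
    #: fraction of a site's transcripts drawn from the lesioned allele
    lesioned_allele_fraction: float = 0.5
    #: explicit (cell_index, transcript_id, position, alt_base) DNA mutations
    dna_mutation_sites: tuple[tuple[int, str, int, str], ...] = ()
    background_tx_error_rate: float = 0.0
    #: per-base probability of error in each PCR duplication event
    pcr_error_rate: float = 0.0
    pcr_cycles: int = 12
    seq_error_rate: float = 0.0
    umi_length: int = 10
    barcode_length: int = 12
    #: constant Phred score written to FASTQ
    base_quality: int = 37
    #: fragments for CirSeq mode; None → n_cells × molecules × n_transcripts
    cirseq_fragments: int | None = None
    seed: int = 0

    def validate(self, reference: ReferenceSet | None = None) -> None:
        probs = {
            "lesion_site_rate": self.lesion_site_rate,
            "lesion_miscoding_prob": self.lesion_miscoding_prob,
            "lesioned_allele_fraction": self.lesioned_allele_fraction,
            "background_tx_error_rate": self.background_tx_error_rate,
            "pcr_error_rate": self.pcr_error_rate,
            "seq_error_rate": self.seq_error_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.molecules_per_cell_per_transcript <= 0:
            raise ValueError("molecules_per_cell_per_transcript must be > 0")
        if self.min_reads_per_molecule < 1:
            raise ValueError("min_reads_per_molecule must be >= 1")
        if self.reads_per_molecule < self.min_reads_per_molecule:
            raise ValueError(
                "reads_per_molecule mean must be >= min_reads_per_molecule"
            )
        if self.lesion_ref_base not in BASES or self.lesion_alt_base not in BASES:
            raise ValueError("lesion ref/alt bases must be in {A,C,G,T}")
        if self.lesion_ref_base == self.lesion_alt_base:
            raise ValueError("lesion ref and alt bases must differ")
        if self.umi_length < 1 or self.barcode_length < 1:
            raise ValueError("umi_length and barcode_length must be >= 1")
        if self.pcr_cycles < 1:
            raise ValueError("pcr_cycles must be >= 1")
        if not 2 <= self.base_quality <= 41:
            raise ValueError("base_quality must be in [2, 41]")
        if self.fragment_length is not None and self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if reference is not None:
            if (
                self.fragment_length is not None
                and self.fragment_length > reference.min_length
            ):
                raise ValueError("fragment_length exceeds shortest transcript")
            for cell, tx, pos, alt in self.dna_mutation_sites:
                if not 0 <= cell < self.n_cells:
                    raise ValueError(f"mutation cell index {cell} out of range")
                if tx not in reference:
                    raise ValueError(f"mutation transcript {tx!r} not in reference")
                if not 0 <= pos < reference.length(tx):
                    raise ValueError(f"mutation position {pos} out of bounds on {tx}")
                if alt not in BASES:
                    raise ValueError(f"mutation alt base {alt!r} invalid")
                if alt == reference[tx][pos]:
                    raise ValueError(
                        f"mutation alt equals reference base at {tx}:{pos}"
                    )

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from YAML (or flat ``key=value`` lines, one per line)."""
        text = Path(path).read_text()
        if "=" in text.splitlines()[0] and ":" not in text.splitlines()[0]:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = yaml.safe_load(val.strip())
        else:
            data = yaml.safe_load(text)
        if "dna_mutation_sites" in data:
            data["dna_mutation_sites"] = tuple(
                tuple(row) for row in data["dna_mutation_sites"]
            )
        return cls(**data)

    def evolve(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _random_tags(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n random ACGT strings of the given length, as an object array."""
    codes = rng.integers(0, 4, size=(n, length)).astype(np.uint8)
    return np.array([decode(row) for row in codes], dtype=object)


def _unique_tags(rng, n, length) -> np.ndarray:
    tags = _random_tags(rng, n, length)
    # redraw collisions until unique (deterministic; vanishing probability)
    while True:
        _, first = np.unique(tags, return_index=True)
        if len(first) == n:
            return tags
        dup = np.setdiff1d(np.arange(n), first)
        tags[dup] = _random_tags(rng, len(dup), length)


@dataclass
class SimulatedCells:
    """Event-level representation of one simulated scRNA-seq library."""

    config: SimulationConfig
    reference: ReferenceSet
    barcodes: np.ndarray  # (n_cells,) object
    # molecules, cell-major / transcript-minor ordering
    mol_cell: np.ndarray
    mol_tx: np.ndarray  # index into reference.ids
    mol_start: np.ndarray
    mol_len: np.ndarray
    mol_reads: np.ndarray
    umis: np.ndarray  # (n_mols,) object
    mol_offsets: np.ndarray  # (n_cells*n_tx + 1,) molecule index ranges
    # molecule-level final substitutions (pos molecule-relative)
    sub_mol: np.ndarray
    sub_pos: np.ndarray
    sub_base: np.ndarray
    # reads, molecule-major
    read_mol: np.ndarray
    read_leaf: np.ndarray
    # PCR duplication-tree errors: node (level, index), delta ∈ {1,2,3}
    pe_mol: np.ndarray
    pe_level: np.ndarray
    pe_node: np.ndarray
    pe_pos: np.ndarray
    pe_delta: np.ndarray
    # per-read sequencing errors
    se_read: np.ndarray
    se_pos: np.ndarray
    se_delta: np.ndarray
    truth: TruthTable
    _ref_concat: np.ndarray = field(repr=False)
    _tx_offset: np.ndarray = field(repr=False)

    # ------------------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.mol_cell)

    @property
    def n_reads(self) -> int:
        return len(self.read_mol)

    def molecule_range(self, cell: int, tx: int) -> tuple[int, int]:
        """Molecule index range [lo, hi) for one (cell, transcript)."""
        n_tx = len(self.reference)
        flat = cell * n_tx + tx
        return int(self.mol_offsets[flat]), int(self.mol_offsets[flat + 1])

    def ref_base_abs(self, tx: int, pos: int) -> int:
        return int(self._ref_concat[self._tx_offset[tx] + pos])

    # ------------------------------------------------------------------
    @classmethod
    def generate(
        cls, config: SimulationConfig, reference: ReferenceSet
    ) -> "SimulatedCells":
        config.validate(reference)
        rng = np.random.default_rng(config.seed)
        tx_ids = reference.ids
        n_tx = len(tx_ids)
        tx_codes = [reference.codes(t) for t in tx_ids]
        tx_len = np.array([len(c) for c in tx_codes], dtype=np.int64)
        ref_concat = np.concatenate(tx_codes)
        tx_offset = np.concatenate([[0], np.cumsum(tx_len)])[:-1]

        barcodes = _unique_tags(rng, config.n_cells, config.barcode_length)

        # --- lesion sites: per-cell Bernoulli over eligible bases ---------
        lesion_ref_code = BASES.index(config.lesion_ref_base)
        lesion_alt_code = BASES.index(config.lesion_alt_base)
        eligible = [np.flatnonzero(c == lesion_ref_code) for c in tx_codes]
        elig_counts = np.array([len(e) for e in eligible])
        elig_cum = np.concatenate([[0], np.cumsum(elig_counts)])
        lesion_sites: dict[tuple[int, int], np.ndarray] = {}
        truth_rows = []
        if config.lesion_site_rate > 0 and elig_cum[-1] > 0:
            expected = config.lesioned_allele_fraction * config.lesion_miscoding_prob
            total_per_cell = int(elig_cum[-1])
            for cell in range(config.n_cells):
                k = rng.binomial(total_per_cell, config.lesion_site_rate)
                if k == 0:
                    continue
                flat = np.sort(rng.choice(total_per_cell, size=k, replace=False))
                tx_of = np.searchsorted(elig_cum, flat, side="right") - 1
                for t in np.unique(tx_of):
                    pos = eligible[t][flat[tx_of == t] - elig_cum[t]]
                    lesion_sites[(cell, int(t))] = pos.astype(np.int64)
                    for p in pos:
                        truth_rows.append(
                            (
                                barcodes[cell],
                                tx_ids[t],
                                int(p),
                                "lesion",
                                config.lesion_ref_base,
                                config.lesion_alt_base,
                                expected,
                            )
                        )

        # --- explicit DNA mutations ---------------------------------------
        tx_index = {t: i for i, t in enumerate(tx_ids)}
        mutations: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for cell, tx, pos, alt in config.dna_mutation_sites:
            t = tx_index[tx]
            mutations.setdefault((cell, t), []).append((pos, BASES.index(alt)))
            truth_rows.append(
                (barcodes[cell], tx, pos, "dna_mutation", reference[tx][pos], alt, 1.0)
            )

        truth_frame = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
        if len(truth_frame):
            truth_frame = truth_frame.sort_values(
                ["cell_id", "transcript_id", "position", "kind"]
            ).reset_index(drop=True)
        truth = TruthTable(truth_frame)

        # --- molecules ----------------------------------------------------
        counts = rng.poisson(
            config.molecules_per_cell_per_transcript, size=config.n_cells * n_tx
        ).astype(np.int64)
        mol_offsets = np.concatenate([[0], np.cumsum(counts)])
        n_mols = int(mol_offsets[-1])
        mol_cell = np.repeat(np.arange(config.n_cells), counts.reshape(-1, n_tx).sum(1))
        mol_tx = np.repeat(np.tile(np.arange(n_tx), config.n_cells), counts)
        if config.fragment_length is None:
            mol_start = np.zeros(n_mols, dtype=np.int64)
            mol_len = tx_len[mol_tx]
        else:
            frag = config.fragment_length
            span = tx_len[mol_tx] - frag + 1
            mol_start = (rng.random(n_mols) * span).astype(np.int64)
            mol_len = np.full(n_mols, frag, dtype=np.int64)

        # enforce UMI uniqueness within (cell, transcript) so families never
        # merge; integer-packed keys keep the collision check cheap
        umi_codes = rng.integers(0, 4, size=(n_mols, config.umi_length)).astype(
            np.uint8
        )
        powers = 4 ** np.arange(config.umi_length, dtype=np.int64)
        while True:
            umi_int = umi_codes.astype(np.int64) @ powers
            keys = (mol_cell.astype(np.int64) * n_tx + mol_tx) * int(
                4**config.umi_length
            ) + umi_int
            _, first = np.unique(keys, return_index=True)
            if len(first) == n_mols:
                break
            dup = np.setdiff1d(np.arange(n_mols), first)
            umi_codes[dup] = rng.integers(
                0, 4, size=(len(dup), config.umi_length)
            ).astype(np.uint8)
        umis = np.array([decode(row) for row in umi_codes], dtype=object)

        mol_reads = config.min_reads_per_molecule + rng.poisson(
            config.reads_per_molecule - config.min_reads_per_molecule, size=n_mols
        ).astype(np.int64)

        # --- molecule-level substitution events ---------------------------
        # priority 0 = DNA mutation (absolute), 1 = lesion (absolute),
        # priority 2 = background transcription error (delta)
        ev_mol, ev_pos, ev_prio, ev_abs, ev_val = [], [], [], [], []

        for (cell, t), sites in sorted(mutations.items()):
            lo, hi = int(mol_offsets[cell * n_tx + t]), int(
                mol_offsets[cell * n_tx + t + 1]
            )
            for pos, alt in sites:
                for m in range(lo, hi):
                    rel = pos - mol_start[m]
                    if 0 <= rel < mol_len[m]:
                        ev_mol.append(m)
                        ev_pos.append(rel)
                        ev_prio.append(0)
                        ev_abs.append(True)
                        ev_val.append(alt)

        for (cell, t), sites in lesion_sites.items():
            lo, hi = int(mol_offsets[cell * n_tx + t]), int(
                mol_offsets[cell * n_tx + t + 1]
            )
            if hi == lo:
                continue
            mols = np.arange(lo, hi)
            rel = sites[None, :] - mol_start[mols, None]  # (n_mol, n_site)
            cover = (rel >= 0) & (rel < mol_len[mols, None])
            mm, ss = np.nonzero(cover)
            if len(mm) == 0:
                continue
            lesioned = rng.random(len(mm)) < config.lesioned_allele_fraction
            miscoded = rng.random(len(mm)) < config.lesion_miscoding_prob
            hit = lesioned & miscoded
            for m, s in zip(mols[mm[hit]], ss[hit]):
                ev_mol.append(int(m))
                ev_pos.append(int(sites[s] - mol_start[m]))
                ev_prio.append(1)
                ev_abs.append(True)
                ev_val.append(lesion_alt_code)

        if config.background_tx_error_rate > 0 and n_mols:
            total = int(mol_len.sum())
            k = rng.binomial(total, config.background_tx_error_rate)
            if k:
                flat = rng.integers(0, total, size=k)
                delta = rng.integers(1, 4, size=k)
                cum = np.concatenate([[0], np.cumsum(mol_len)])
                m = np.searchsorted(cum, flat, side="right") - 1
                ev_mol.extend(m.tolist())
                ev_pos.extend((flat - cum[m]).tolist())
                ev_prio.extend([2] * k)
                ev_abs.extend([False] * k)
                ev_val.extend(delta.tolist())

        sub_mol, sub_pos, sub_base = _resolve_molecule_events(
            np.array(ev_mol, dtype=np.int64),
            np.array(ev_pos, dtype=np.int64),
            np.array(ev_prio, dtype=np.int64),
            np.array(ev_abs, dtype=bool),
            np.array(ev_val, dtype=np.int64),
            mol_tx,
            mol_start,
            ref_concat,
            tx_offset,
        )

        # --- reads --------------------------------------------------------
        read_mol = np.repeat(np.arange(n_mols), mol_reads)
        n_reads = len(read_mol)
        do_pcr = config.pcr_error_rate > 0 and n_reads > 0
        if do_pcr:
            read_leaf = rng.integers(0, 2**config.pcr_cycles, size=n_reads)
        else:
            read_leaf = np.zeros(n_reads, dtype=np.int64)

        # --- PCR-tree errors (only nodes ancestral to a sampled read) -----
        pe_mol = pe_level = pe_node = pe_pos = pe_delta = np.array([], dtype=np.int64)
        if do_pcr:
            D = config.pcr_cycles
            levels = np.arange(1, D + 1)
            rl_mol = np.repeat(read_mol, D)
            rl_level = np.tile(levels, n_reads)
            rl_node = (read_leaf[:, None] >> (D - levels)[None, :]).reshape(-1)
            # pack (mol, level, node) into one int64 key for a fast unique
            span = 1 << D
            packed = np.sort((rl_mol * (D + 1) + rl_level) * span + rl_node)
            if len(packed):
                packed = packed[
                    np.concatenate([[True], packed[1:] != packed[:-1]])
                ]
            rel = np.empty((len(packed), 3), dtype=np.int64)
            rel[:, 2] = packed % span
            tmp = packed // span
            rel[:, 1] = tmp % (D + 1)
            rel[:, 0] = tmp // (D + 1)
            trials = int(mol_len[rel[:, 0]].sum())
            k = rng.binomial(trials, config.pcr_error_rate)
            if k:
                flat = rng.integers(0, trials, size=k)
                delta = rng.integers(1, 4, size=k)
                cum = np.concatenate([[0], np.cumsum(mol_len[rel[:, 0]])])
                idx = np.searchsorted(cum, flat, side="right") - 1
                pe_mol = rel[idx, 0]
                pe_level = rel[idx, 1]
                pe_node = rel[idx, 2]
                pe_pos = flat - cum[idx]
                pe_delta = delta
                order = np.lexsort((pe_level, pe_pos, pe_mol))
                pe_mol, pe_level, pe_node = pe_mol[order], pe_level[order], pe_node[order]
                pe_pos, pe_delta = pe_pos[order], pe_delta[order]

        # --- sequencing errors --------------------------------------------
        se_read = se_pos = se_delta = np.array([], dtype=np.int64)
        if config.seq_error_rate > 0 and n_reads:
            read_len = mol_len[read_mol]
            total = int(read_len.sum())
            k = rng.binomial(total, config.seq_error_rate)
            if k:
                flat = rng.integers(0, total, size=k)
                delta = rng.integers(1, 4, size=k)
                order = np.argsort(flat, kind="stable")
                flat, delta = flat[order], delta[order]
                cum = np.concatenate([[0], np.cumsum(read_len)])
                se_read = np.searchsorted(cum, flat, side="right") - 1
                se_pos = flat - cum[se_read]
                se_delta = delta

        return cls(
            config=config,
            reference=reference,
            barcodes=barcodes,
            mol_cell=mol_cell,
            mol_tx=mol_tx,
            mol_start=mol_start,
            mol_len=mol_len,
            mol_reads=mol_reads,
            umis=umis,
            mol_offsets=mol_offsets,
            sub_mol=sub_mol,
            sub_pos=sub_pos,
            sub_base=sub_base,
            read_mol=read_mol,
            read_leaf=read_leaf,
            pe_mol=pe_mol,
            pe_level=pe_level,
            pe_node=pe_node,
            pe_pos=pe_pos,
            pe_delta=pe_delta,
            se_read=se_read,
            se_pos=se_pos,
            se_delta=se_delta,
            truth=truth,
            _ref_concat=ref_concat,
            _tx_offset=tx_offset,
        )

    # ------------------------------------------------------------------
    def molecule_sequence(self, m: int) -> np.ndarray:
        """Final molecule codes (transcription-level) for molecule m."""
        lo = self._tx_offset[self.mol_tx[m]] + self.mol_start[m]
        seq = self._ref_concat[lo : lo + self.mol_len[m]].copy()
        s0 = np.searchsorted(self.sub_mol, m, side="left")
        s1 = np.searchsorted(self.sub_mol, m, side="right")
        if s1 > s0:
            seq[self.sub_pos[s0:s1]] = self.sub_base[s0:s1]
        return seq

    def read_sequences(self, m: int) -> list[np.ndarray]:
        """Codes of every read of molecule m, in read-index order."""
        base = self.molecule_sequence(m)
        r0 = int(np.searchsorted(self.read_mol, m, side="left"))
        r1 = int(np.searchsorted(self.read_mol, m, side="right"))
        p0 = int(np.searchsorted(self.pe_mol, m, side="left"))
        p1 = int(np.searchsorted(self.pe_mol, m, side="right"))
        D = self.config.pcr_cycles
        out = []
        for r in range(r0, r1):
            seq = base.copy()
            if p1 > p0:
                leaf = self.read_leaf[r]
                for j in range(p0, p1):
                    if (leaf >> (D - self.pe_level[j])) == self.pe_node[j]:
                        seq[self.pe_pos[j]] = (seq[self.pe_pos[j]] + self.pe_delta[j]) % 4
            q0 = int(np.searchsorted(self.se_read, r, side="left"))
            q1 = int(np.searchsorted(self.se_read, r, side="right"))
            for j in range(q0, q1):
                seq[self.se_pos[j]] = (seq[self.se_pos[j]] + self.se_delta[j]) % 4
            out.append(seq)
        return out

    def write_fastq(self, path) -> Path:
        """Materialize all reads to FASTQ using the tmseq name dialect."""
        path = Path(path)
        qchar = chr(self.config.base_quality + 33)
        tx_ids = self.reference.ids
        buf = io.StringIO()
        rid = 0
        for m in range(self.n_molecules):
            bc = self.barcodes[self.mol_cell[m]]
            umi = self.umis[m]
            tx = tx_ids[self.mol_tx[m]]
            start = self.mol_start[m]
            qual = qchar * int(self.mol_len[m])
            for seq in self.read_sequences(m):
                buf.write(
                    f"@r{rid}|CB:{bc}|UMI:{umi}|TX:{tx}|POS:{start}\n"
                    f"{decode(seq)}\n+\n{qual}\n"
                )
                rid += 1
        path.write_text(buf.getvalue())
        return path


def _resolve_molecule_events(
    ev_mol, ev_pos, ev_prio, ev_abs, ev_val, mol_tx, mol_start, ref_concat, tx_offset
):
    """Collapse stacked molecule-level events to one final base per (mol, pos).

    Events are applied in priority order (mutation, lesion, background);
    absolute events set the base, deltas add mod 4.
    """
    empty = np.array([], dtype=np.int64)
    if len(ev_mol) == 0:
        return empty, empty, np.array([], dtype=np.uint8)
    order = np.lexsort((np.arange(len(ev_mol)), ev_prio, ev_pos, ev_mol))
    ev_mol, ev_pos, ev_prio = ev_mol[order], ev_pos[order], ev_prio[order]
    ev_abs, ev_val = ev_abs[order], ev_val[order]
    key = ev_mol * (ev_pos.max() + 1) + ev_pos
    uniq, first, counts = np.unique(key, return_index=True, return_counts=True)
    out_mol = ev_mol[first]
    out_pos = ev_pos[first]
    ref_at = ref_concat[tx_offset[mol_tx[out_mol]] + mol_start[out_mol] + out_pos]
    out_base = np.empty(len(uniq), dtype=np.int64)
    single = counts == 1
    si = first[single]
    out_base[single] = np.where(
        ev_abs[si], ev_val[si], (ref_at[single] + ev_val[si]) % 4
    )
    for g in np.flatnonzero(~single):
        base = int(ref_at[g])
        for j in range(first[g], first[g] + counts[g]):
            base = int(ev_val[j]) if ev_abs[j] else (base + int(ev_val[j])) % 4
        out_base[g] = base
    o2 = np.lexsort((out_pos, out_mol))
    return out_mol[o2], out_pos[o2], out_base[o2].astype(np.uint8)


def simulate_cells(
    config: SimulationConfig, reference: ReferenceSet, out_fastq
) -> tuple[Path, TruthTable]:
    """Simulate a barcoded scRNA-seq library; write FASTQ, return truth."""
    sim = SimulatedCells.generate(config, reference)
    path = sim.write_fastq(out_fastq)
    return path, sim.truth


# ----------------------------------------------------------------------
# CirSeq (rolling-circle) simulation
# ----------------------------------------------------------------------


@dataclass
class SimulatedCirseq:
    """Event-level representation of a simulated CirSeq library.

    Each read is ``repeat_count`` tandem copies of one RNA fragment.
    Transcription-level errors are drawn once per fragment (shared by all
    repeats); sequencing errors are independent per repeat copy.
    """

    config: SimulationConfig
    reference: ReferenceSet
    repeat_count: int
    fragment_length: int
    frag_tx: np.ndarray
    frag_start: np.ndarray
    # transcription errors: per-fragment deltas at fragment-relative positions
    te_frag: np.ndarray
    te_pos: np.ndarray
    te_delta: np.ndarray
    # sequencing errors: per (fragment, copy, position)
    qe_frag: np.ndarray
    qe_copy: np.ndarray
    qe_pos: np.ndarray
    qe_delta: np.ndarray

    @property
    def n_fragments(self) -> int:
        return len(self.frag_tx)

    @classmethod
    def generate(
        cls,
        config: SimulationConfig,
        reference: ReferenceSet,
        repeat_count: int,
        fragment_length: int,
    ) -> "SimulatedCirseq":
        config.validate(reference)
        if repeat_count < 2:
            raise ValueError("repeat_count must be >= 2")
        if fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if fragment_length > reference.min_length:
            raise ValueError("fragment_length exceeds shortest transcript")
        rng = np.random.default_rng(config.seed)
        n_tx = len(reference)
        tx_len = np.array([reference.length(t) for t in reference.ids])
        n_frag = config.cirseq_fragments
        if n_frag is None:
            n_frag = int(
                round(config.n_cells * config.molecules_per_cell_per_transcript * n_tx)
            )
        if n_frag < 1:
            raise ValueError("number of fragments must be >= 1")
        weights = (tx_len - fragment_length + 1).astype(float)
        weights /= weights.sum()
        frag_tx = rng.choice(n_tx, size=n_frag, p=weights)
        span = tx_len[frag_tx] - fragment_length + 1
        frag_start = (rng.random(n_frag) * span).astype(np.int64)

        te_frag = te_pos = te_delta = np.array([], dtype=np.int64)
        if config.background_tx_error_rate > 0:
            total = n_frag * fragment_length
            k = rng.binomial(total, config.background_tx_error_rate)
            if k:
                flat = np.sort(rng.integers(0, total, size=k), kind="stable")
                te_frag = flat // fragment_length
                te_pos = flat % fragment_length
                te_delta = rng.integers(1, 4, size=k)

        qe_frag = qe_copy = qe_pos = qe_delta = np.array([], dtype=np.int64)
        if config.seq_error_rate > 0:
            total = n_frag * repeat_count * fragment_length
            k = rng.binomial(total, config.seq_error_rate)
            if k:
                flat = np.sort(rng.integers(0, total, size=k), kind="stable")
                qe_frag = flat // (repeat_count * fragment_length)
                rem = flat % (repeat_count * fragment_length)
                qe_copy = rem // fragment_length
                qe_pos = rem % fragment_length
                qe_delta = rng.integers(1, 4, size=k)

        return cls(
            config=config,
            reference=reference,
            repeat_count=repeat_count,
            fragment_length=fragment_length,
            frag_tx=frag_tx.astype(np.int64),
            frag_start=frag_start,
            te_frag=te_frag,
            te_pos=te_pos,
            te_delta=te_delta,
            qe_frag=qe_frag,
            qe_copy=qe_copy,
            qe_pos=qe_pos,
            qe_delta=qe_delta,
        )

    def fragment_sequence(self, i: int) -> np.ndarray:
        """Transcription-level fragment codes (shared by all repeats)."""
        tx = self.reference.ids[self.frag_tx[i]]
        s = int(self.frag_start[i])
        seq = self.reference.codes(tx)[s : s + self.fragment_length].copy()
        lo = np.searchsorted(self.te_frag, i, side="left")
        hi = np.searchsorted(self.te_frag, i, side="right")
        for j in range(lo, hi):
            seq[self.te_pos[j]] = (seq[self.te_pos[j]] + self.te_delta[j]) % 4
        return seq

    def read_sequence(self, i: int) -> np.ndarray:
        """Full rolling-circle read codes for fragment i."""
        unit = self.fragment_sequence(i)
        read = np.tile(unit, self.repeat_count)
        lo = np.searchsorted(self.qe_frag, i, side="left")
        hi = np.searchsorted(self.qe_frag, i, side="right")
        for j in range(lo, hi):
            p = self.qe_copy[j] * self.fragment_length + self.qe_pos[j]
            read[p] = (read[p] + self.qe_delta[j]) % 4
        return read

    def write_fastq(self, path) -> Path:
        path = Path(path)
        qchar = chr(self.config.base_quality + 33)
        tx_ids = self.reference.ids
        buf = io.StringIO()
        for i in range(self.n_fragments):
            seq = decode(self.read_sequence(i))
            buf.write(
                f"@cir{i}|CB:-|UMI:-|TX:{tx_ids[self.frag_tx[i]]}"
                f"|POS:{self.frag_start[i]}\n{seq}\n+\n{qchar * len(seq)}\n"
            )
        path.write_text(buf.getvalue())
        return path


def simulate_cirseq(
    config: SimulationConfig,
    reference: ReferenceSet,
    repeat_count: int,
    fragment_length: int,
    out_fastq,
) -> tuple[Path, TruthTable]:
    """Simulate a rolling-circle (CirSeq) library; write FASTQ.

    Bulk libraries pool many cells, so lesion sites are not fixed across
    fragments; transcription-level errors are i.i.d. per fragment at
    ``background_tx_error_rate`` and the returned truth table is empty —
    the injected rate itself is the recovery target.
    """
    sim = SimulatedCirseq.generate(config, reference, repeat_count, fragment_length)
    path = sim.write_fastq(out_fastq)
    return path, TruthTable.empty()
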