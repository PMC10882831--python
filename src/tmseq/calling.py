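"""RNA-DNA discrepancy calling and error-spectrum estimation.

A discrepancy call records, for one cell / transcript site / alt base,
how many consensus molecules carry the alt (``n_mut``) versus match the
reference (``n_wt``). Counts are always molecule (UMI-family) counts,
never raw reads. Sites whose pooled mutant fraction across cells reaches
~1 at adequate coverage are classified as candidate DNA mutations and
removed entirely from the spectrum — the single-stranded bookkeeping
(C→U is never folded with G→A) is what makes this exclusion informative:
a genuine DNA mutation would raise complementary substitution types,
a transcription lesion only its cognate one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import BASES, N_CODE, SUB_TYPES, encode, sub_label
from .consensus import MoleculeConsensus
from .reference import ReferenceSet

logger = logging.getLogger(__name__)

TRANSCRIPTION_ERROR = "transcription_error"
CANDIDATE_DNA_MUTATION = "candidate_dna_mutation"


@dataclass
class DiscrepancyCall:
    """Per-cell, per-site, per-substitution molecule tally."""

    cell_barcode: str
    transcript_id: str
    position: int  # 0-based on the transcript
    ref_base: str
    alt_base: str
    n_mut: int
    n_wt: int
    classification: str | None = None

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases must differ")
        if self.n_mut < 1:
            raise ValueError("a call requires n_mut >= 1")

    @property
    def mutant_fraction(self) -> float:
        return self.n_mut / (self.n_mut + self.n_wt)


def call_discrepancies(
    molecules: list[MoleculeConsensus], reference: ReferenceSet
) -> list[DiscrepancyCall]:
    """Compare consensus molecules to the reference, per cell.

    Masked (N) positions are skipped. ``n_wt`` counts co-located
    reference-matching molecules of the same cell; molecules from
    different cells are never merged. A molecule extending past its
    transcript end raises (it signals a coordinate bug upstream).
    """
    groups: dict[tuple[str, str], list[tuple[MoleculeConsensus, np.ndarray]]] = {}
    for mol in molecules:
        if mol.transcript_id not in reference:
            raise KeyError(f"transcript {mol.transcript_id!r} not in reference")
        if mol.end > reference.length(mol.transcript_id):
            raise ValueError(
                f"molecule extends past end of {mol.transcript_id} "
                f"({mol.end} > {reference.length(mol.transcript_id)})"
            )
        codes = encode(mol.consensus_sequence)
        groups.setdefault((mol.cell_barcode, mol.transcript_id), []).append(
            (mol, codes)
        )

    calls: list[DiscrepancyCall] = []
    for (cell, tx) in sorted(groups):
        members = groups[(cell, tx)]
        ref = reference.codes(tx)
        # tally mutant molecules per (position, alt)
        mut: dict[tuple[int, int], int] = {}
        for mol, codes in members:
            refslice = ref[mol.start : mol.end]
            mism = np.flatnonzero((codes != refslice) & (codes != N_CODE))
            for rel in mism:
                key = (mol.start + int(rel), int(codes[rel]))
                mut[key] = mut.get(key, 0) + 1
        for (pos, alt) in sorted(mut):
            n_wt = sum(
                1
                for mol, codes in members
                if mol.start <= pos < mol.end and codes[pos - mol.start] == ref[pos]
            )
            calls.append(
                DiscrepancyCall(
                    cell_barcode=cell,
                    transcript_id=tx,
                    position=pos,
                    ref_base=BASES[ref[pos]],
                    alt_base=BASES[alt],
                    n_mut=mut[(pos, alt)],
                    n_wt=n_wt,
                )
            )
    logger.info(
        "call_discrepancies: %d molecules -> %d calls", len(molecules), len(calls)
    )
    return calls


def classify_site(
    calls: list[DiscrepancyCall],
    mut_frac_threshold: float = 0.95,
    min_mut_coverage: int = 10,
) -> str:
    """Classify one (transcript, position, alt) site from its calls across cells.

    ``candidate_dna_mutation`` iff the pooled mutant fraction reaches the
    threshold at pooled coverage >= ``min_mut_coverage``; otherwise the
    discrepancy is a transcription error. A 50:50 pseudo-allele site stays
    a transcription error, as does a fully mutant site at low coverage
    (insufficient evidence of a mutation).
    """
    if not calls:
        raise ValueError("classify_site requires at least one call")
    key = (calls[0].transcript_id, calls[0].position, calls[0].alt_base)
    if any((c.transcript_id, c.position, c.alt_base) != key for c in calls):
        raise ValueError("classify_site calls must share (transcript, pos, alt)")
    n_mut = sum(c.n_mut for c in calls)
    n_tot = n_mut + sum(c.n_wt for c in calls)
    if n_tot >= min_mut_coverage and n_mut / n_tot >= mut_frac_threshold:
        return CANDIDATE_DNA_MUTATION
    return TRANSCRIPTION_ERROR


def classify_calls(
    calls: list[DiscrepancyCall],
    mut_frac_threshold: float = 0.95,
    min_mut_coverage: int = 10,
) -> list[DiscrepancyCall]:
    """Assign a classification to every call (in place; returns the list)."""
    groups: dict[tuple[str, int, str], list[DiscrepancyCall]] = {}
    for c in calls:
        groups.setdefault((c.transcript_id, c.position, c.alt_base), []).append(c)
    for group in groups.values():
        cls = classify_site(group, mut_frac_threshold, min_mut_coverage)
        for c in group:
            c.classification = cls
    return calls


@dataclass
class ErrorSpectrum:
    """Per-bp rates of the 12 ordered substitution types for one sample.

    ``errors[(X, Y)]`` counts erroneous molecule-bases of type X→Y;
    ``surveyed[X]`` counts unmasked consensus-molecule bases whose
    reference base is X (candidate-DNA-mutation and blacklisted sites
    excluded from both). Rates are exact ratios; a type with zero
    surveyed bases has an *undefined* (NaN) rate, distinct from 0.
    """

    sample_id: str
    errors: dict[tuple[str, str], int]
    surveyed: dict[str, int]
    unit: str = "molecule"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.errors = {t: int(self.errors.get(t, 0)) for t in SUB_TYPES}
        self.surveyed = {b: int(self.surveyed.get(b, 0)) for b in BASES}
        for (x, _), n in self.errors.items():
            if n < 0:
                raise ValueError("negative error count")
        for x in BASES:
            alts = sum(self.errors[(x, y)] for y in BASES if y != x)
            if self.unit == "molecule" and alts > self.surveyed[x] > 0:
                raise ValueError(
                    f"more {x} errors than surveyed {x} bases ({alts} > {self.surveyed[x]})"
                )

    def rate(self, ref: str, alt: str) -> float:
        denom = self.surveyed[ref]
        if denom == 0:
            warnings.warn(
                f"{self.sample_id}: no surveyed {ref} bases; "
                f"{sub_label(ref, alt)} rate undefined",
                stacklevel=2,
            )
            return float("nan")
        return self.errors[(ref, alt)] / denom

    @property
    def rates(self) -> dict[tuple[str, str], float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return {t: self.rate(*t) for t in SUB_TYPES}

    @property
    def total_errors(self) -> int:
        return sum(self.errors.values())

    @property
    def total_surveyed(self) -> int:
        return sum(self.surveyed.values())

    @property
    def overall_rate(self) -> float:
        """The overall N→N error rate: all errors over all surveyed bases."""
        if self.total_surveyed == 0:
            warnings.warn(f"{self.sample_id}: no surveyed bases", stacklevel=2)
            return float("nan")
        return self.total_errors / self.total_surveyed

    def to_frame(self) -> pd.DataFrame:
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for x, y in SUB_TYPES:
                rows.append(
                    {
                        "sample_id": self.sample_id,
                        "type": sub_label(x, y, rna=True),
                        "ref_base": x,
                        "alt_base": y,
                        "errors": self.errors[(x, y)],
                        "surveyed": self.surveyed[x],
                        "rate": self.rate(x, y),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# tmseq error spectrum; rate = errors / surveyed (bp^-1); "
                f"unit={self.unit}; overall N->N rate = {self.overall_rate:.6g}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "ErrorSpectrum":
        frame = pd.read_csv(path, sep="\t", comment="#")
        errors = {
            (r.ref_base, r.alt_base): int(r.errors) for r in frame.itertuples()
        }
        surveyed = {
            r.ref_base: int(r.surveyed) for r in frame.itertuples()
        }
        sid = sample_id if sample_id is not None else str(frame["sample_id"].iloc[0])
        return cls(sid, errors, surveyed)


def load_blacklist(path) -> dict[str, list[tuple[int, int]]]:
    """Load a BED (0-based, half-open) site blacklist on transcript coords."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tx, start, end = line.split("\t")[:3]
            intervals.setdefault(tx, []).append((int(start), int(end)))
    return intervals


def _in_blacklist(blacklist, tx: str, pos: int) -> bool:
    return any(a <= pos < b for a, b in blacklist.get(tx, ()))


def error_spectrum(
    calls: list[DiscrepancyCall],
    molecules: list[MoleculeConsensus],
    reference: ReferenceSet,
    sample_id: str = "sample",
    unit: str = "molecule",
    blacklist: dict[str, list[tuple[int, int]]] | None = None,
) -> ErrorSpectrum:
    """Estimate the 12-type per-bp error spectrum from classified calls.

    With ``unit='molecule'`` (default) the numerator counts erroneous
    molecules (each mutant UMI family is one transcription event); with
    ``unit='site'`` it counts distinct error sites. The denominator is the
    number of unmasked consensus-molecule bases per reference base, with
    candidate-DNA-mutation (and blacklisted) sites removed entirely.
    """
    if unit not in ("molecule", "site"):
        raise ValueError("unit must be 'molecule' or 'site'")
    if any(c.classification is None for c in calls):
        raise ValueError("calls must be classified before spectrum estimation")
    blacklist = blacklist or {}

    excluded: set[tuple[str, int]] = {
        (c.transcript_id, c.position)
        for c in calls
        if c.classification == CANDIDATE_DNA_MUTATION
    }

    errors: dict[tuple[str, str], int] = {t: 0 for t in SUB_TYPES}
    seen_sites: set[tuple[str, int, str]] = set()
    for c in calls:
        if c.classification != TRANSCRIPTION_ERROR:
            continue
        if (c.transcript_id, c.position) in excluded:
            continue
        if _in_blacklist(blacklist, c.transcript_id, c.position):
            continue
        if unit == "molecule":
            errors[(c.ref_base, c.alt_base)] += c.n_mut
        else:
            site = (c.transcript_id, c.position, c.alt_base)
            if site not in seen_sites:
                seen_sites.add(site)
                errors[(c.ref_base, c.alt_base)] += 1

    surveyed = np.zeros(4, dtype=np.int64)
    mol_codes = [encode(m.consensus_sequence) for m in molecules]
    for mol, codes in zip(molecules, mol_codes):
        refslice = reference.codes(mol.transcript_id)[mol.start : mol.end]
        surveyed += np.bincount(refslice[codes != N_CODE], minlength=4)

    # remove excluded / blacklisted site coverage from the denominator
    drop_sites: set[tuple[str, int]] = set(excluded)
    for tx, ivals in blacklist.items():
        if tx in reference:
            for a, b in ivals:
                for pos in range(max(a, 0), min(b, reference.length(tx))):
                    drop_sites.add((tx, pos))
    if drop_sites:
        for mol, codes in zip(molecules, mol_codes):
            for tx, pos in drop_sites:
                if tx == mol.transcript_id and mol.start <= pos < mol.end:
                    if codes[pos - mol.start] != N_CODE:
                        ref = reference.codes(tx)[pos]
                        surveyed[ref] -= 1

    surveyed_d = {b: int(surveyed[i]) for i, b in enumerate(BASES)}
    spec = ErrorSpectrum(sample_id, errors, surveyed_d, unit=unit)
    logger.info(
        "error_spectrum[%s]: %d errors over %d surveyed bases (overall %.3g)",
        sample_id,
        spec.total_errors,
        spec.total_surveyed,
        spec.overall_rate if spec.total_surveyed else float("nan"),
    )
    return spec


def write_calls_tsv(calls: list[DiscrepancyCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("# tmseq discrepancy calls; position 0-based; molecule counts\n")
        pd.DataFrame(
            [
                {
                    "cell_barcode": c.cell_barcode,
                    "transcript_id": c.transcript_id,
                    "position": c.position,
                    "ref_base": c.ref_base,
                    "alt_base": c.alt_base,
                    "n_mut": c.n_mut,
                    "n_wt": c.n_wt,
                    "classification": c.classification or "",
                }
                for c in calls
            ],
            columns=[
                "cell_barcode",
                "transcript_id",
                "position",
                "ref_base",
                "alt_base",
                "n_mut",
                "n_wt",
                "classification",
            ],
        ).to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path) -> list[DiscrepancyCall]:
    frame = pd.read_csv(
        path, sep="\t", comment="#", dtype={"classification": "string"}
    )
    out = []
    for r in frame.itertuples(index=False):
        cls = r.classification if isinstance(r.classification, str) and r.classification else None
        out.append(
            DiscrepancyCall(
                cell_barcode=str(r.cell_barcode),
                transcript_id=str(r.transcript_id),
                position=int(r.position),
                ref_base=str(r.ref_base),
                alt_base=str(r.alt_base),
                n_mut=int(r.n_mut),
                n_wt=int(r.n_wt),
                classification=cls,
            )
        )
    return out


def export_vcf_like(calls: list[DiscrepancyCall], path) -> None:
    """Write calls as a VCF-like TSV (positions 1-based, documented in header)."""
    with open(path, "w") as fh:
        fh.write(
            "## tmseq VCF-like export; POS is 1-based; counts are consensus "
            "molecules (UMI families)\n"
            "#CHROM\tPOS\tREF\tALT\tCELL\tN_MUT\tN_WT\tCLASS\n"
        )
        for c in calls:
            fh.write(
                f"{c.transcript_id}\t{c.position + 1}\t{c.ref_base}\t{c.alt_base}"
                f"\t{c.cell_barcode}\t{c.n_mut}\t{c.n_wt}\t{c.classification or '.'}\n"
            )
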