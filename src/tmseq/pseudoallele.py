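"""Pseudo-allele analysis.

A *pseudo-allele* is a site in one cell whose transcript pool contains
both wild-type and identically mutant molecules — the expected signature
of an unrepaired, miscoding DNA lesion on one allele: with full lesion
bypass on a diploid locus, roughly half of the site's transcripts carry
the cognate error, mimicking a heterozygous DNA mutation without any
change to the DNA sequence. Sites are reported when mutant mRNAs exceed
10% of the molecules (strictly more than 10%, with configurable
recurrence and coverage requirements on top).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import TRANSCRIPTION_ERROR, DiscrepancyCall

logger = logging.getLogger(__name__)


@dataclass
class PseudoAllele:
    """One per-cell site generating both WT and mutant transcripts."""

    cell_barcode: str
    transcript_id: str
    position: int
    ref_base: str
    alt_base: str
    n_mut: int
    n_wt: int

    @property
    def mutant_fraction(self) -> float:
        return self.n_mut / (self.n_mut + self.n_wt)

    @property
    def total_molecules(self) -> int:
        return self.n_mut + self.n_wt


def compute_pseudo_alleles(
    calls: list[DiscrepancyCall],
    min_fraction: float = 0.10,
    min_mut_molecules: int = 2,
    min_total_molecules: int = 10,
) -> list[PseudoAllele]:
    """Filter transcription-error calls down to reportable pseudo-alleles.

    A (cell, site, alt) is included iff its mutant fraction strictly
    exceeds ``min_fraction`` ("more than 10% mutant mRNAs"), it has at
    least ``min_mut_molecules`` mutant molecules (a lone molecule is not
    recurrence), and total coverage is at least ``min_total_molecules``
    (making the fraction filter meaningful). Output is sorted by mutant
    fraction, descending.

    Calls classified as candidate DNA mutations are ignored; unclassified
    calls are rejected.
    """
    if any(c.classification is None for c in calls):
        raise ValueError("calls must be classified before pseudo-allele analysis")
    out = []
    for c in calls:
        if c.classification != TRANSCRIPTION_ERROR:
            continue
        total = c.n_mut + c.n_wt
        if (
            c.mutant_fraction > min_fraction
            and c.n_mut >= min_mut_molecules
            and total >= min_total_molecules
        ):
            out.append(
                PseudoAllele(
                    cell_barcode=c.cell_barcode,
                    transcript_id=c.transcript_id,
                    position=c.position,
                    ref_base=c.ref_base,
                    alt_base=c.alt_base,
                    n_mut=c.n_mut,
                    n_wt=c.n_wt,
                )
            )
    out.sort(
        key=lambda p: (
            -p.mutant_fraction,
            p.cell_barcode,
            p.transcript_id,
            p.position,
            p.alt_base,
        )
    )
    logger.info(
        "compute_pseudo_alleles: %d calls -> %d pseudo-alleles", len(calls), len(out)
    )
    return out


def ratio_histogram(
    pseudo_alleles: list[PseudoAllele],
    bin_width: float = 0.05,
    lo: float = 0.10,
    hi: float = 1.00,
) -> pd.DataFrame:
    """Bin mutant:WT fractions into fixed (lo, hi] bins of width 0.05.

    Bins are right-inclusive — a 6:6 site (fraction 0.5) falls in
    (0.45, 0.50]. Counts sum to the number of pseudo-alleles.
    """
    n_bins = int(round((hi - lo) / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    for p in pseudo_alleles:
        f = p.mutant_fraction
        if not (lo < f <= hi):
            raise ValueError(f"mutant fraction {f} outside ({lo}, {hi}]")
        # right-inclusive bin index, robust to floating error on exact edges
        idx = int(np.ceil((f - lo) / bin_width - 1e-9)) - 1
        counts[min(max(idx, 0), n_bins - 1)] += 1
    lows = lo + bin_width * np.arange(n_bins)
    return pd.DataFrame(
        {
            "bin_low": np.round(lows, 10),
            "bin_high": np.round(lows + bin_width, 10),
            "count": counts,
        }
    )


def write_pseudo_alleles_tsv(pseudo_alleles: list[PseudoAllele], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# tmseq pseudo-alleles; position 0-based; "
            "mutant_fraction = n_mut/(n_mut+n_wt)\n"
        )
        pd.DataFrame(
            [
                {
                    "cell_barcode": p.cell_barcode,
                    "transcript_id": p.transcript_id,
                    "position": p.position,
                    "ref_base": p.ref_base,
                    "alt_base": p.alt_base,
                    "n_mut": p.n_mut,
                    "n_wt": p.n_wt,
                    "mutant_fraction": p.mutant_fraction,
                }
                for p in pseudo_alleles
            ],
            columns=[
                "cell_barcode",
                "transcript_id",
                "position",
                "ref_base",
                "alt_base",
                "n_mut",
                "n_wt",
                "mutant_fraction",
            ],
        ).to_csv(fh, sep="\t", index=False)
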