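"""Canned parameter-recovery experiments at the study's error rates.

The two simulated conditions mirror a genotoxin-exposure experiment in
quiescent neural stem cells:

* **vehicle** — only baseline stochastic transcription errors, injected
  uniformly over substitution types at a total per-base rate of
  ``3 × 6.7e-6``, so the C→U component alone is 6.7e-6 bp⁻¹.
* **treated** — the same background plus single-allele, fully miscoding
  C→T lesions at a site rate chosen so the *total* C→U molecule-error
  rate is 6.9e-5 bp⁻¹ (background third plus lesion-driven errors at
  ``lesion_site_rate × lesioned_allele_fraction × lesion_miscoding_prob``
  per C base).

Both conditions share realistic nuisance processes: per-read sequencing
errors at 1e-3, PCR errors at 1e-6 per duplication over a 12-cycle tree.
These helpers drive the sparse engine; scale is set by ``n_cells``
against a fixed 20-transcript × 1200 bp reference.
"""

from __future__ import annotations

import numpy as np

from .calling import ErrorSpectrum
from .engine import collapse_and_call
from .reference import ReferenceSet
from .simulate import SimulatedCells, SimulationConfig
from .stats import SampleGroup, compare_groups

#: injected C→U molecule-error rates (bp^-1) of the two conditions
TREATED_CU_RATE = 6.9e-5
VEHICLE_CU_RATE = 6.7e-6

_LESION_ALLELE_FRACTION = 0.5
_LESION_MISCODING_PROB = 1.0
#: uniform background such that its C→U component equals the vehicle rate
BACKGROUND_RATE = 3 * VEHICLE_CU_RATE
#: lesion site rate supplying the treated excess over the background
TREATED_LESION_SITE_RATE = (TREATED_CU_RATE - VEHICLE_CU_RATE) / (
    _LESION_ALLELE_FRACTION * _LESION_MISCODING_PROB
)


def recovery_reference(seed: int = 42) -> ReferenceSet:
    """The fixed transcriptome used by the recovery experiments."""
    return ReferenceSet.random(n_transcripts=20, length=1200, gc=0.5, seed=seed)


def condition_config(
    condition: str, n_cells: int, seed: int, **overrides
) -> SimulationConfig:
    """SimulationConfig for one replicate of 'treated' or 'vehicle'."""
    if condition == "treated":
        lesion_rate = TREATED_LESION_SITE_RATE
    elif condition == "vehicle":
        lesion_rate = 0.0
    else:
        raise ValueError(f"unknown condition {condition!r}")
    params = dict(
        n_cells=n_cells,
        molecules_per_cell_per_transcript=4.0,
        reads_per_molecule=3.0,
        min_reads_per_molecule=2,
        lesion_site_rate=lesion_rate,
        lesion_miscoding_prob=_LESION_MISCODING_PROB,
        lesioned_allele_fraction=_LESION_ALLELE_FRACTION,
        background_tx_error_rate=BACKGROUND_RATE,
        pcr_error_rate=1e-6,
        pcr_cycles=12,
        seq_error_rate=1e-3,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def recover_spectrum(
    condition: str,
    n_cells: int,
    seed: int,
    reference: ReferenceSet | None = None,
    **overrides,
) -> ErrorSpectrum:
    """Simulate one replicate and run consensus + calling on it."""
    reference = reference if reference is not None else recovery_reference()
    cfg = condition_config(condition, n_cells, seed, **overrides)
    sim = SimulatedCells.generate(cfg, reference)
    result = collapse_and_call(sim, sample_id=f"{condition}_s{seed}")
    return result.spectrum


def treated_vehicle_pvalue(
    seed: int,
    n_replicates: int = 3,
    treated_cells: int = 100,
    vehicle_cells: int = 750,
    reference: ReferenceSet | None = None,
) -> tuple[float, float]:
    """One 3-vs-3 treated/vehicle comparison of per-replicate C→U rates.

    Replicates are sized so each carries at least ~100 expected C→U error
    molecules. Returns (t, two-tailed p) from the pooled-variance test.
    """
    reference = reference if reference is not None else recovery_reference()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * n_replicates)]
    treated = SampleGroup(
        "treated",
        [
            recover_spectrum("treated", treated_cells, seeds[i], reference)
            for i in range(n_replicates)
        ],
    )
    vehicle = SampleGroup(
        "vehicle",
        [
            recover_spectrum("vehicle", vehicle_cells, seeds[n_replicates + i], reference)
            for i in range(n_replicates)
        ],
    )
    return compare_groups(treated, vehicle, ("C", "T"))
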