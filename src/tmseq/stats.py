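"""Replicate-level aggregation and group comparison.

Replicates of a condition (e.g. genotoxin-treated vs vehicle) each yield
one :class:`~tmseq.calling.ErrorSpectrum`; the group comparison for a
substitution type is an unpaired two-tailed t-test on the per-replicate
rates — pooled-variance Student's t by default, Welch behind a flag.
No multiple-testing correction is applied across the 12 types by default;
a Bonferroni option exists.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._seq import SUB_TYPES, parse_sub, sub_label
from .calling import ErrorSpectrum

logger = logging.getLogger(__name__)


@dataclass
class SampleGroup:
    """A labelled condition with one ErrorSpectrum per replicate."""

    label: str
    spectra: list[ErrorSpectrum] = field(default_factory=list)

    def __post_init__(self):
        if not self.spectra:
            raise ValueError(f"group {self.label!r} needs at least one replicate")

    @property
    def n_replicates(self) -> int:
        return len(self.spectra)

    def rates(self, sub: tuple[str, str] | str) -> np.ndarray:
        """Per-replicate rates for one substitution type (NaN = undefined)."""
        if isinstance(sub, str):
            sub = parse_sub(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.array([s.rate(*sub) for s in self.spectra])

    def overall_rates(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.array([s.overall_rate for s in self.spectra])


def group_mean_rates(group: SampleGroup) -> dict[tuple[str, str], float]:
    """Arithmetic mean rate per substitution type across replicates.

    Replicates with an undefined (NaN) rate for a type are excluded from
    that type's mean, with a warning.
    """
    out = {}
    for sub in SUB_TYPES:
        rates = group.rates(sub)
        bad = np.isnan(rates)
        if bad.any():
            warnings.warn(
                f"group {group.label!r}: {int(bad.sum())} replicate(s) with "
                f"undefined {sub_label(*sub)} rate excluded from the mean",
                stacklevel=2,
            )
        rates = rates[~bad]
        out[sub] = float(rates.mean()) if len(rates) else float("nan")
    return out


def compare_groups(
    a: SampleGroup,
    b: SampleGroup,
    sub: tuple[str, str] | str = ("C", "T"),
    welch: bool = False,
) -> tuple[float, float]:
    """Unpaired two-tailed t-test on per-replicate rates of one type.

    Returns (t statistic, two-tailed p). Pooled-variance Student's t by
    default; ``welch=True`` drops the equal-variance assumption. Groups
    with fewer than two usable replicates are refused (test undefined).
    """
    ra = a.rates(sub)
    rb = b.rates(sub)
    ra, rb = ra[~np.isnan(ra)], rb[~np.isnan(rb)]
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError(
            f"compare_groups needs >= 2 replicates per group with defined "
            f"rates; got {len(ra)} ({a.label}) and {len(rb)} ({b.label})"
        )
    t, p = sps.ttest_ind(ra, rb, equal_var=not welch)
    # identical samples: define t=0, p=1 rather than NaN from zero variance
    if math.isnan(t):
        if np.allclose(ra.mean(), rb.mean()):
            return 0.0, 1.0
        return math.inf if ra.mean() > rb.mean() else -math.inf, 0.0
    return float(t), float(p)


def bonferroni(p: float, n_tests: int = len(SUB_TYPES)) -> float:
    """Bonferroni-adjusted p-value (off by default in reports)."""
    return min(1.0, p * n_tests)
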