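"""Closed-form knockout-probability model and screen bookkeeping.

The F0 knockout strategy targets a gene at several loci simultaneously and
relies on frameshift mutations as a universal knockout mechanism.  Under the
simplifying assumptions that (i) mutation outcomes at different loci are
independent, (ii) each allele is hit independently, and (iii) any frameshift
anywhere in the targeted gene knocks the allele out (even if a downstream
indel restores the frame), the probability that one allele carries at least
one frameshift after targeting ``n`` loci is

    q = 1 - (1 - P_mutation * P_frameshift) ** n

and the biallelic knockout probability is ``P_KO = q ** 2``.

This module also implements the per-animal accumulation of the frameshift
allele fraction across sequenced loci (product of complements of per-locus
read fractions) and the control-adjusted unviability percentage used when
reporting injection toxicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "LocusEditSummary",
    "ViabilityCounts",
    "UnviabilityResult",
    "biallelic_ko_probability",
    "frameshift_allele_fraction",
    "adjusted_unviability",
]


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the biallelic knockout model.

    Attributes
    ----------
    p_mutation:
        Probability that a targeted locus is mutated on one allele.
    p_frameshift:
        Probability that a mutation causes a frameshift (the empirical value
        is close to 2/3, since one in three net indel lengths is a multiple
        of three).
    n_loci:
        Number of loci targeted on the gene.
    """

    p_mutation: float
    p_frameshift: float
    n_loci: int

    def __post_init__(self) -> None:
        _check_probability("p_mutation", self.p_mutation)
        _check_probability("p_frameshift", self.p_frameshift)
        if self.n_loci < 0 or int(self.n_loci) != self.n_loci:
            raise ValueError(f"n_loci must be a non-negative integer, got {self.n_loci!r}")


@dataclass(frozen=True)
class LocusEditSummary:
    """Per-locus editing outcome for one animal (the unit of accumulation)."""

    locus_id: str
    animal_id: str
    frac_mutated: float
    frac_frameshift: float
    n_reads: int = 0

    def __post_init__(self) -> None:
        _check_probability("frac_mutated", self.frac_mutated)
        _check_probability("frac_frameshift", self.frac_frameshift)
        if self.frac_frameshift > self.frac_mutated + 1e-12:
            raise ValueError(
                "frac_frameshift cannot exceed frac_mutated "
                f"({self.frac_frameshift} > {self.frac_mutated})"
            )
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


@dataclass(frozen=True)
class ViabilityCounts:
    """Embryo counts for the unviability computation (1 dpf basis)."""

    n_total_1dpf: int
    n_dead_or_dysmorphic: int
    group: str = "injected"

    def __post_init__(self) -> None:
        if self.n_total_1dpf <= 0:
            raise ValueError("n_total_1dpf must be positive")
        if not 0 <= self.n_dead_or_dysmorphic <= self.n_total_1dpf:
            raise ValueError("n_dead_or_dysmorphic must lie in [0, n_total_1dpf]")

    @property
    def percent(self) -> float:
        """Percentage of embryos dead or dysmorphic after 1 dpf."""
        return 100.0 * self.n_dead_or_dysmorphic / self.n_total_1dpf


@dataclass(frozen=True)
class UnviabilityResult:
    percent: float
    floored: bool = False


def biallelic_ko_probability(params: ModelParams) -> float:
    """Probability that both alleles of a gene carry a frameshift.

    ``P_KO = [1 - (1 - p_mutation * p_frameshift) ** n_loci] ** 2``,
    treating the two alleles as independent and frameshift as the sole
    knockout mechanism.  Monotone non-decreasing in every argument.
    """
    p_shift_per_locus = params.p_mutation * params.p_frameshift
    q = 1.0 - (1.0 - p_shift_per_locus) ** params.n_loci
    return q * q


def _as_fractions(per_locus: Iterable) -> list[float]:
    fractions: list[float] = []
    summaries: list[LocusEditSummary] = []
    for item in per_locus:
        if isinstance(item, LocusEditSummary):
            summaries.append(item)
        else:
            fractions.append(float(item))
    if summaries and fractions:
        raise TypeError("mix of LocusEditSummary and bare fractions is not supported")
    if summaries:
        animals = {s.animal_id for s in summaries}
        if len(animals) > 1:
            raise ValueError(f"summaries span several animals: {sorted(animals)}")
        # Default locus ordering: lexicographic by locus_id (the vendor
        # ranking used alphabetical locus names).
        summaries = sorted(summaries, key=lambda s: s.locus_id)
        fractions = [s.frac_frameshift for s in summaries]
    for f in fractions:
        _check_probability("frameshift fraction", f)
    return fractions


def frameshift_allele_fraction(per_locus: Sequence) -> np.ndarray:
    """Cumulative frameshift allele fraction across targeted loci.

    Accepts either bare per-locus frameshift read fractions (used in the
    caller-supplied order) or :class:`LocusEditSummary` records for a single
    animal (ordered lexicographically by ``locus_id``).  Returns the whole
    cumulative trajectory: element ``l`` is the fraction of alleles carrying
    at least one frameshift after targeting loci ``1..l+1``,

        pshift_{1->l} = 1 - prod_{i<=l} (1 - pshift_i),

    assuming genotypes at each locus of an allele are assigned independently.
    An empty input warns and returns an empty trajectory (cumulative
    fraction 0).
    """
    fractions = _as_fractions(per_locus)
    if not fractions:
        warnings.warn("no per-locus summaries supplied; cumulative fraction is 0", stacklevel=2)
        return np.zeros(0)
    not_shift = np.cumprod([1.0 - f for f in fractions])
    return 1.0 - not_shift


def adjusted_unviability(injected: ViabilityCounts, control: ViabilityCounts) -> UnviabilityResult:
    """Control-adjusted unviability percentage.

    Subtracts the control group's percentage of dead-or-dysmorphic embryos
    (counted after 1 dpf, over the 1-dpf total) from the injected group's, so
    only effects mediated by the mutagenic RNP injection are reported.  A
    negative difference floors at 0 and is flagged.
    """
    diff = injected.percent - control.percent
    if diff < 0.0:
        return UnviabilityResult(0.0, floored=True)
    return UnviabilityResult(diff, floored=False)
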