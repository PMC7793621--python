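"""Headloop suppression-PCR primer design, in-silico validation and scoring.

Headloop PCR suppresses amplification of the wild-type haplotype at a Cas9
target site: a 5' tag added to one PCR primer is reverse-complementary to
the wild-type target sequence, so after second-strand synthesis the tag
base-pairs with the target locus in the same strand and directs elongation
into a stable hairpin, removing the amplicon from the template pool.  Any
indel at the target site breaks tag complementarity and the mutant template
keeps amplifying exponentially, so a band on a gel reports mutagenic
activity without sequencing.

Tag selection rules: (1) the predicted Cas9 cut site falls within the
first 6 bp of the tag; (2) the tag window contains no SNP; (3) the tag
matches the GC-content and melting temperature of the base primers as
closely as possible.  When the tagged primer points the same way as the
guide, the reverse complement of the guide-binding sequence is the starting
candidate.

Practical caveat (documented, not simulated): effective suppression
requires a proofreading polymerase with 3'->5' exonuclease activity;
non-proofreading enzymes displace or degrade the hairpin and defeat
suppression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import reverse_complement
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .amplicon_indels import AmpliconReference

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSite",
    "PrimerPair",
    "HeadloopPrimer",
    "BandIntensities",
    "SuppressionResult",
    "HeadloopScore",
    "DesignError",
    "design_headloop_primer",
    "simulate_suppression",
    "headloop_score",
    "tm_gc",
]

MUTAGENIC_THRESHOLD = 0.6


class DesignError(ValueError):
    """No headloop tag satisfies the design rules; the message names the rule."""


@dataclass(frozen=True)
class TargetSite:
    """A Cas9 target site on an amplicon.

    ``predicted_cut`` is the blunt-cut boundary index 3 bp 5' of the PAM
    (between amplicon positions ``cut - 1`` and ``cut``), i.e. between
    positions 17 and 18 of the protospacer.
    """

    protospacer: str
    pam: str
    strand: str
    guide_start: int
    guide_end: int
    predicted_cut: int

    @classmethod
    def from_reference(cls, ref: AmpliconReference) -> "TargetSite":
        if ref.guide_strand == "+":
            proto = ref.sequence[ref.guide_start : ref.guide_end]
            pam = ref.sequence[ref.guide_end : ref.guide_end + 3]
        else:
            proto = reverse_complement(ref.sequence[ref.guide_start : ref.guide_end])
            pam = reverse_complement(ref.sequence[ref.guide_start - 3 : ref.guide_start])
        return cls(proto, pam, ref.guide_strand, ref.guide_start, ref.guide_end, ref.predicted_cut)


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str


@dataclass(frozen=True)
class HeadloopPrimer:
    """A base primer with its 5' headloop tag.

    ``tag_target_interval`` is the half-open plus-strand amplicon interval
    the tag is complementary to; the full oligo is ``tag + base_primer``.
    """

    base_primer: str
    tag: str
    tagged_side: str  # "forward" | "reverse"
    tag_target_interval: tuple[int, int]
    gc_fraction: float
    tm_celsius: float
    gc_tm_flag: bool = False

    @property
    def sequence(self) -> str:
        return self.tag + self.base_primer


@dataclass(frozen=True)
class BandIntensities:
    """Gel band intensities for one sample and its matched (uninjected) control."""

    sample_id: str
    standard_pcr: float
    headloop_pcr: float
    control_standard_pcr: float
    control_headloop_pcr: float

    def __post_init__(self) -> None:
        for name in ("standard_pcr", "headloop_pcr", "control_standard_pcr", "control_headloop_pcr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def tm_gc(sequence: str) -> tuple[float, float]:
    """Melting temperature (C) and GC fraction of an ACGT-only oligo.

    Tm uses nearest-neighbour thermodynamics (Biopython ``Tm_NN`` defaults:
    SantaLucia & Hicks unified parameters, 50 mM Na+, 25 nM primer each
    strand).  Ambiguity codes are rejected.
    """
    sequence = sequence.upper()
    if not sequence or set(sequence) - set("ACGT"):
        raise ValueError(f"sequence must be non-empty ACGT-only, got {sequence!r}")
    tm = float(MeltingTemp.Tm_NN(sequence))
    return tm, float(gc_fraction(sequence))


def _candidate_windows(cut: int, side: str, length: int, n_amplicon: int):
    """Tag target windows [a, b) honouring rule 1.

    The tag is read 5'->3' starting at the end of the window nearest the
    primer's elongation direction, so the cut boundary must lie strictly
    within the first six tag bases.
    """
    if side == "forward":
        # tag = revcomp(amplicon[a:b]); tag 5' end maps to position b - 1
        for b in range(cut + 1, cut + 6):
            a = b - length
            if 0 <= a and b <= n_amplicon:
                yield a, b
    else:
        # tag anneals to the minus strand; tag 5' end maps to position a
        for a in range(cut - 1, cut - 6, -1):
            b = a + length
            if 0 <= a and b <= n_amplicon:
                yield a, b


def design_headloop_primer(
    base_pair: PrimerPair,
    site: TargetSite,
    amplicon: str,
    snps: Sequence[int] = (),
    gc_tolerance: float = 0.15,
    tm_tolerance: float = 5.0,
    tag_length: int = 20,
    length_adjust: int = 4,
    tagged_side: str | None = None,
) -> HeadloopPrimer:
    """Design the headloop tag for one primer of a base pair.

    The tagged primer defaults to the one pointing the same way as the
    guide, for which the reverse complement of the guide-binding sequence
    is the natural first candidate.  Candidate windows (lengths
    ``tag_length +/- length_adjust``, preferring ``tag_length``) are screened
    against rules 1-2; among the survivors the tag minimising the combined
    GC/Tm mismatch with the base primers is returned, deterministically.
    A best candidate outside ``gc_tolerance``/``tm_tolerance`` is returned
    flagged, with a warning.

    Raises
    ------
    DesignError
        If no window satisfies rule 1 (geometry) or rule 2 (SNP-free),
        naming the violated rule.
    """
    amplicon = amplicon.upper()
    if tagged_side is None:
        tagged_side = "forward" if site.strand == "+" else "reverse"
    base = base_pair.forward if tagged_side == "forward" else base_pair.reverse
    tm_f, gc_f = tm_gc(base_pair.forward)
    tm_r, gc_r = tm_gc(base_pair.reverse)
    tm_base = 0.5 * (tm_f + tm_r)
    gc_base = 0.5 * (gc_f + gc_r)

    snpset = set(int(s) for s in snps)
    lengths = [tag_length]
    for d in range(1, length_adjust + 1):
        lengths += [tag_length - d, tag_length + d]

    any_geometry = False
    best = None
    for length in lengths:
        if length < 10:
            continue
        for a, b in _candidate_windows(site.predicted_cut, tagged_side, length, len(amplicon)):
            any_geometry = True
            if snpset & set(range(a, b)):
                continue
            target = amplicon[a:b]
            tag = reverse_complement(target) if tagged_side == "forward" else target
            tm, gc = tm_gc(tag)
            penalty = abs(gc - gc_base) / gc_tolerance + abs(tm - tm_base) / tm_tolerance
            key = (penalty, abs(length - tag_length), a)
            if best is None or key < best[0]:
                best = (key, tag, (a, b), gc, tm)
    if best is None:
        if not any_geometry:
            raise DesignError(
                "rule 1 violated: no tag window places the predicted cut site "
                "within its first 6 bp inside the amplicon"
            )
        raise DesignError("rule 2 violated: every candidate tag window contains a SNP")
    key, tag, interval, gc, tm = best
    flagged = abs(gc - gc_base) > gc_tolerance or abs(tm - tm_base) > tm_tolerance
    if flagged:
        logger.warning(
            "headloop tag GC/Tm outside tolerance of base primers "
            "(tag GC %.2f Tm %.1f vs base GC %.2f Tm %.1f); best candidate returned flagged",
            gc, tm, gc_base, tm_base,
        )
    return HeadloopPrimer(base, tag, tagged_side, interval, gc, tm, gc_tm_flag=flagged)


@dataclass(frozen=True)
class SuppressionResult:
    outcome: str  # "suppressed" | "amplified" | "no_amplification"
    detail: str = ""


def simulate_suppression(
    haplotype: str,
    base_pair: PrimerPair,
    primer: HeadloopPrimer,
    amplicon: str,
    max_mismatches: int = 1,
) -> SuppressionResult:
    """Predict the headloop PCR outcome for one haplotype.

    The haplotype is aligned to the wild-type amplicon and the tag-target
    interval is followed through the alignment.  It is *suppressed* iff the
    interval survives with no indel and at most ``max_mismatches``
    substitutions (the default of 1 tolerates a stray SNP; 0 is the
    strictest behaviour).  Any indel inside the interval breaks tag
    complementarity, so even a 1-bp deletion is enough to prevent hairpin
    formation and the template is *amplified*.  If a base primer's 3'
    binding site is absent from the haplotype, the result is
    *no_amplification*, which is distinct from suppression (failed PCR,
    flagged).
    """
    from .amplicon_indels import pairwise_ops

    haplotype = haplotype.upper()
    amplicon = amplicon.upper()
    fwd = base_pair.forward.upper()
    rev_site = reverse_complement(base_pair.reverse.upper())
    if fwd not in haplotype or rev_site not in haplotype:
        return SuppressionResult("no_amplification", "primer binding site disrupted")
    a, b = primer.tag_target_interval
    ops, tgt_blocks, qry_blocks, _ = pairwise_ops(amplicon, haplotype)
    for kind, start, end, ins in ops:
        if kind == "deletion" and start < b and end > a:
            return SuppressionResult("amplified", "deletion in tag target: no hairpin")
        if kind == "insertion" and a < start < b:
            return SuppressionResult("amplified", "insertion in tag target: no hairpin")
    mismatches = 0
    covered = 0
    for (t0, t1), (q0, q1) in zip(tgt_blocks, qry_blocks):
        lo, hi = max(t0, a), min(t1, b)
        for t in range(lo, hi):
            covered += 1
            if amplicon[t] != haplotype[q0 + (t - t0)]:
                mismatches += 1
    mismatches += (b - a) - covered  # interval bases lost to clipping
    if mismatches <= max_mismatches:
        return SuppressionResult("suppressed", "tag target intact: hairpin forms")
    return SuppressionResult("amplified", "tag target mutated: no hairpin")


@dataclass(frozen=True)
class HeadloopScore:
    sample_id: str
    score: float | None
    mutagenic: bool | None
    flag: str = ""


def headloop_score(
    bands: BandIntensities,
    epsilon: float = 1e-9,
    threshold: float = MUTAGENIC_THRESHOLD,
) -> HeadloopScore:
    """Score a sample from standard- and headloop-PCR band intensities.

    ``score = 1 - (HL/STD)_sample / max((HL/STD)_control, epsilon)``,
    clipped to [0, 1].  The control ratio is the matched uninjected
    reference, so a sample whose headloop-to-standard ratio is
    indistinguishable from the control scores 0 (wild-type-like) and a
    sample with no headloop-relative signal scores 1 (fully mutant under
    this orientation).  Samples at or above ``threshold`` (default 0.6) are
    classified mutagenic.  A zero standard-PCR band means the PCR failed:
    the score is undefined and flagged.
    """
    if bands.standard_pcr == 0:
        return HeadloopScore(bands.sample_id, None, None, flag="failed PCR: zero standard band")
    flag = ""
    if bands.control_standard_pcr == 0:
        return HeadloopScore(bands.sample_id, None, None, flag="failed PCR: zero control standard band")
    ratio_sample = bands.headloop_pcr / bands.standard_pcr
    ratio_control = bands.control_headloop_pcr / bands.control_standard_pcr
    score = 1.0 - ratio_sample / max(ratio_control, epsilon)
    score = min(1.0, max(0.0, score))
    return HeadloopScore(bands.sample_id, score, score >= threshold, flag=flag)
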