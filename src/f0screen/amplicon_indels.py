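"""Amplicon-sequencing indel caller and downstream spectrum statistics.

Quantifies Cas9-induced indels in amplicon deep-sequencing reads: reads are
aligned to the reference amplicon with an affine-gap pairwise aligner (free
end gaps emulate soft-clipping), quality-filtered, and every alignment gap
inside the reporting window becomes an indel call with PAM-relative
coordinates.  Downstream statistics mirror a standard F0-screen analysis:
per-sample mutated / frameshift read fractions (control-normalised, with a
sequencing-error frequency floor), top-10 indel sharing between samples,
and the pooled unique-indel length and deletion-position spectra.

Coordinate convention: the PAM nucleotide adjacent to the guide binding
site is position 0.  For a guide on the + strand, negative positions are
5' of the first PAM nucleotide; for a guide on the - strand the axis is
mirrored, so negative positions are 3' of the first PAM nucleotide on the
amplicon's plus strand.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "AmpliconReference",
    "ReadRecord",
    "IndelCall",
    "AlignedRead",
    "SampleEditProfile",
    "Scoring",
    "SpectrumResult",
    "align_read",
    "align_and_call",
    "filter_reads",
    "classify_frameshift",
    "summarize_sample",
    "top10_sharing",
    "unique_indel_spectrum",
    "merge_pairs",
    "read_fastq",
]

# Read-quality filters: thresholds as used on MiSeq amplicon data.  A read
# is discarded iff length < 140 bp, or mean Phred < 40, or more than 20% of
# its length soft-clipped (all strict inequalities).
MIN_READ_LENGTH = 140
MIN_MEAN_QUALITY = 40.0
MAX_CLIP_FRACTION = 0.20
DEFAULT_MIN_FREQ = 0.005
DEFAULT_WINDOW = 60


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AmpliconReference:
    """Reference amplicon with guide / PAM annotation.

    ``guide_start``/``guide_end`` are 0-based half-open coordinates of the
    20-nt protospacer on the amplicon plus strand; ``pam_position`` is the
    plus-strand coordinate of the PAM nucleotide adjacent to the guide
    binding site (origin of the PAM-relative axis).
    """

    locus_id: str
    sequence: str
    guide_start: int
    guide_end: int
    guide_strand: str
    pam_position: int

    def __post_init__(self) -> None:
        if self.guide_strand not in "+-":
            raise ValueError("guide_strand must be '+' or '-'")
        if not (0 <= self.guide_start < self.guide_end <= len(self.sequence)):
            raise ValueError("guide interval must lie within the amplicon")
        expected_pam = self.guide_end if self.guide_strand == "+" else self.guide_start - 1
        if self.pam_position != expected_pam:
            raise ValueError(
                f"PAM position {self.pam_position} not adjacent to guide on the "
                f"{self.guide_strand} strand (expected {expected_pam})"
            )

    @classmethod
    def from_guide(cls, locus_id: str, sequence: str, guide_seq: str) -> "AmpliconReference":
        """Locate a 20-nt protospacer on either strand and annotate the PAM."""
        sequence = sequence.upper()
        guide_seq = guide_seq.upper()
        pos = sequence.find(guide_seq)
        if pos >= 0:
            return cls(locus_id, sequence, pos, pos + len(guide_seq), "+", pos + len(guide_seq))
        rc = reverse_complement(guide_seq)
        pos = sequence.find(rc)
        if pos >= 0:
            return cls(locus_id, sequence, pos, pos + len(rc), "-", pos - 1)
        raise ValueError(f"guide {guide_seq!r} not found in amplicon {locus_id!r}")

    @property
    def predicted_cut(self) -> int:
        """Blunt-cut boundary index, 3 bp 5' of the PAM (SpCas9 convention).

        The cut falls between amplicon positions ``cut - 1`` and ``cut``.
        """
        if self.guide_strand == "+":
            return self.guide_end - 3
        return self.guide_start + 3

    def to_pam_relative(self, pos: int) -> int:
        return pos - self.pam_position if self.guide_strand == "+" else self.pam_position - pos

    def from_pam_relative(self, rel: int) -> int:
        return rel + self.pam_position if self.guide_strand == "+" else self.pam_position - rel


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    mate: str = "single"

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("sequence and quality lengths differ")

    @property
    def mean_quality(self) -> float | None:
        if self.qualities is None or len(self.qualities) == 0:
            return None
        return float(np.mean(self.qualities))


@dataclass(frozen=True)
class IndelCall:
    """One insertion or deletion in PAM-relative coordinates.

    ``start``/``end`` are the PAM-relative positions of the first and last
    affected reference nucleotide (inclusive; equal for insertions, which
    sit immediately before position ``start`` on the guide-oriented axis).
    Identity of an indel = (type, start, end, inserted sequence).
    """

    type: str  # "deletion" | "insertion"
    start: int
    end: int
    length: int
    inserted_sequence: str = ""
    frequency: float = float("nan")

    def __post_init__(self) -> None:
        if self.type not in ("deletion", "insertion"):
            raise ValueError("type must be 'deletion' or 'insertion'")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.type == "deletion":
            if self.inserted_sequence:
                raise ValueError("deletions carry no inserted sequence")
            if self.end < self.start:
                raise ValueError("deletion end must be >= start")
        else:
            if len(self.inserted_sequence) != self.length:
                raise ValueError("insertion length must match inserted sequence")

    @property
    def identity(self) -> tuple:
        return (self.type, self.start, self.end, self.inserted_sequence)

    @property
    def signed_length(self) -> int:
        return self.length if self.type == "insertion" else -self.length


@dataclass
class AlignedRead:
    """Alignment of one read to the amplicon, with raw gap operations.

    ``ops`` are left-aligned gaps in amplicon plus-strand coordinates:
    ``("deletion", start, end_exclusive, "")`` or
    ``("insertion", pos, pos, inserted_seq)``.
    """

    read: ReadRecord
    score: float
    ops: list[tuple]
    clipped_fraction: float
    alignable: bool = True


@dataclass
class SampleEditProfile:
    """Per-sample editing summary at one locus."""

    locus_id: str
    animal_id: str
    reads_kept: int
    reads_discarded: int
    frac_mutated: float
    frac_frameshift: float
    indels: list[IndelCall] = field(default_factory=list)
    excluded: bool = False
    control_normalised: bool = True

    def indel_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": self.locus_id,
                "animal_id": self.animal_id,
                "type": c.type,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "inserted_sequence": c.inserted_sequence,
                "frequency": c.frequency,
            }
            for c in self.indels
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "locus_id",
                "animal_id",
                "type",
                "start",
                "end",
                "length",
                "inserted_sequence",
                "frequency",
            ],
        )


@dataclass(frozen=True)
class Scoring:
    """Affine-gap alignment scoring (free end gaps emulate soft-clipping)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -24.0
    gap_extend: float = -1.0
    min_score_per_base: float = 1.0


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps on both sequences: the read may sit inside the amplicon
    # and read ends extending past the amplicon are left unaligned
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


# ---------------------------------------------------------------------------
# alignment and calling


def _left_align_ops(ops: list[tuple], ref: str) -> list[tuple]:
    """Shift each gap maximally to the left in amplicon coordinates."""
    out = []
    for kind, start, end, ins in ops:
        if kind == "deletion":
            while start > 0 and ref[start - 1] == ref[end - 1]:
                start -= 1
                end -= 1
        else:
            while start > 0 and ref[start - 1] == ins[-1]:
                ins = ref[start - 1] + ins[:-1]
                start -= 1
                end -= 1
        out.append((kind, start, end, ins))
    return sorted(out, key=lambda o: (o[1], o[0]))


def pairwise_ops(
    ref_seq: str,
    query_seq: str,
    scoring: Scoring = Scoring(),
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[tuple], np.ndarray, np.ndarray, float]:
    """Align query to reference; return left-aligned gap ops and aligned blocks.

    Returns ``(ops, target_blocks, query_blocks, score)`` where ops are in
    reference coordinates and blocks are the Biopython aligned-segment
    arrays (end gaps excluded, i.e. soft-clipped query ends fall outside
    the blocks).
    """
    if aligner is None:
        aligner = _make_aligner(scoring)
    aln = aligner.align(ref_seq, query_seq)[0]
    tgt_blocks, qry_blocks = aln.aligned
    ops: list[tuple] = []
    for i in range(1, len(tgt_blocks)):
        t_gap = tgt_blocks[i][0] - tgt_blocks[i - 1][1]
        q_gap = qry_blocks[i][0] - qry_blocks[i - 1][1]
        if t_gap > 0:
            ops.append(("deletion", int(tgt_blocks[i - 1][1]), int(tgt_blocks[i][0]), ""))
        if q_gap > 0:
            ins = query_seq[qry_blocks[i - 1][1] : qry_blocks[i][0]]
            ops.append(("insertion", int(tgt_blocks[i][0]), int(tgt_blocks[i][0]), ins))
    return _left_align_ops(ops, ref_seq), tgt_blocks, qry_blocks, float(aln.score)


def align_read(
    read: ReadRecord,
    ref: AmpliconReference,
    scoring: Scoring = Scoring(),
    aligner: Align.PairwiseAligner | None = None,
) -> AlignedRead:
    """Align one read to the amplicon and extract gap operations.

    The unaligned read ends (free end gaps) define the soft-clipped
    fraction used by :func:`filter_reads`.  Reads scoring below
    ``min_score_per_base * len(read)`` are flagged unalignable and excluded
    from all denominators.
    """
    ops, tgt_blocks, qry_blocks, score = pairwise_ops(
        ref.sequence, read.sequence.upper(), scoring, aligner
    )
    if len(tgt_blocks) == 0:
        return AlignedRead(read, score, [], 1.0, alignable=False)
    clipped = qry_blocks[0][0] + (len(read.sequence) - qry_blocks[-1][1])
    clipped_fraction = clipped / len(read.sequence) if read.sequence else 1.0
    alignable = score >= scoring.min_score_per_base * len(read.sequence)
    return AlignedRead(read, score, ops, clipped_fraction, alignable)


def _op_to_call(op: tuple, ref: AmpliconReference) -> IndelCall:
    kind, start, end, ins = op
    if kind == "deletion":
        a = ref.to_pam_relative(start)
        b = ref.to_pam_relative(end - 1)
        return IndelCall("deletion", min(a, b), max(a, b), end - start)
    rel = ref.to_pam_relative(start)
    seq = ins if ref.guide_strand == "+" else reverse_complement(ins)
    return IndelCall("insertion", rel, rel, len(ins), seq)


def call_from_ops(
    ops: Iterable[tuple], ref: AmpliconReference, window: int | None = DEFAULT_WINDOW
) -> list[IndelCall]:
    """Convert amplicon-coordinate gap operations into PAM-relative calls.

    Only gaps overlapping ``predicted_cut +/- window`` are reported, bounding
    spurious end-of-read gaps.
    """
    cut = ref.predicted_cut
    calls = []
    for op in ops:
        kind, start, end, _ = op
        hi = end if kind == "deletion" else start
        if window is not None and (hi < cut - window or start > cut + window):
            continue
        calls.append(_op_to_call(op, ref))
    return calls


def call_to_amplicon_coords(call: IndelCall, ref: AmpliconReference) -> tuple:
    """Invert the PAM-relative transform back to plus-strand amplicon coordinates."""
    a = ref.from_pam_relative(call.start)
    b = ref.from_pam_relative(call.end)
    lo, hi = min(a, b), max(a, b)
    if call.type == "deletion":
        return ("deletion", lo, hi + 1, "")
    ins = call.inserted_sequence if ref.guide_strand == "+" else reverse_complement(call.inserted_sequence)
    return ("insertion", lo, hi, ins)


def align_and_call(
    read: ReadRecord,
    ref: AmpliconReference,
    scoring: Scoring = Scoring(),
    window: int | None = DEFAULT_WINDOW,
    aligner: Align.PairwiseAligner | None = None,
) -> list[IndelCall]:
    """Align one read and return its PAM-relative indel calls.

    Substitutions never create calls; an unalignable read raises
    ``ValueError`` (pipelines should exclude it instead via
    :func:`align_read`).
    """
    aligned = align_read(read, ref, scoring, aligner=aligner)
    if not aligned.alignable:
        raise ValueError(f"read {read.read_id!r} is unalignable at {ref.locus_id!r}")
    return call_from_ops(aligned.ops, ref, window)


# ---------------------------------------------------------------------------
# filtering and per-read classification


def filter_reads(
    aligned: Sequence[AlignedRead],
    min_length: int = MIN_READ_LENGTH,
    min_mean_quality: float = MIN_MEAN_QUALITY,
    max_clip_fraction: float = MAX_CLIP_FRACTION,
) -> tuple[list[AlignedRead], list[tuple[AlignedRead, str]]]:
    """Partition aligned reads into kept and (read, reason) discarded.

    A read is discarded iff its length is *strictly below* ``min_length``,
    its mean Phred quality is *strictly below* ``min_mean_quality``, or
    *strictly more* than ``max_clip_fraction`` of its length is
    soft-clipped.  Missing qualities fail the quality rule (logged).
    """
    kept: list[AlignedRead] = []
    discarded: list[tuple[AlignedRead, str]] = []
    for ar in aligned:
        if len(ar.read.sequence) < min_length:
            discarded.append((ar, "short"))
            continue
        mq = ar.read.mean_quality
        if mq is None:
            logger.warning("read %s has no qualities; failing quality rule", ar.read.read_id)
            discarded.append((ar, "quality"))
            continue
        if mq < min_mean_quality:
            discarded.append((ar, "quality"))
            continue
        if ar.clipped_fraction > max_clip_fraction:
            discarded.append((ar, "soft-clipped"))
            continue
        kept.append(ar)
    return kept, discarded


def classify_frameshift(calls: Iterable[IndelCall]) -> bool:
    """True iff the net indel length of one read is not a multiple of 3."""
    net = sum(c.signed_length for c in calls)
    return net % 3 != 0


# ---------------------------------------------------------------------------
# paired-end handling


def merge_pairs(r1: ReadRecord, r2: ReadRecord, min_overlap: int = 10) -> ReadRecord:
    """Merge a read pair by exact 3' overlap; fall back to R1 otherwise."""
    rc2 = reverse_complement(r2.sequence)
    q2 = r2.qualities[::-1] if r2.qualities is not None else None
    max_ov = min(len(r1.sequence), len(rc2))
    for ov in range(max_ov, min_overlap - 1, -1):
        if r1.sequence[-ov:] == rc2[:ov]:
            seq = r1.sequence + rc2[ov:]
            if r1.qualities is not None and q2 is not None:
                quals = tuple(r1.qualities) + tuple(q2[ov:])
            else:
                quals = None
            return ReadRecord(r1.read_id, seq, quals, mate="merged")
    return replace(r1, mate="R1")


# ---------------------------------------------------------------------------
# per-sample summary


def summarize_sample(
    reads: Sequence,
    ref: AmpliconReference,
    control_profile: SampleEditProfile | None = None,
    min_freq: float = DEFAULT_MIN_FREQ,
    coverage_floor: int | None = None,
    animal_id: str = "",
    window: int | None = DEFAULT_WINDOW,
    scoring: Scoring = Scoring(),
    is_control: bool = False,
) -> SampleEditProfile:
    """Full per-sample pipeline: align, filter, call, normalise, summarise.

    ``reads`` may be single reads or (R1, R2) tuples (pairs are merged by
    overlap, or R1 is used; coverage is counted in pairs).  Indels below
    ``min_freq`` are dropped as sequencing error; indels present in the
    matched control are not counted as Cas9-induced.  Samples under the
    coverage floor (default 30x for pairs, 60x for single reads) are marked
    excluded.  ``frac_mutated`` / ``frac_frameshift`` are computed over kept
    reads.
    """
    paired = bool(reads) and isinstance(reads[0], tuple)
    if coverage_floor is None:
        coverage_floor = 30 if paired else 60
    merged = [merge_pairs(*pair) for pair in reads] if paired else list(reads)

    aligner = _make_aligner(scoring)
    aligned = [align_read(r, ref, scoring, aligner=aligner) for r in merged]
    unalignable = [a for a in aligned if not a.alignable]
    for a in unalignable:
        logger.warning("read %s unalignable at %s; excluded", a.read.read_id, ref.locus_id)
    kept, discarded = filter_reads([a for a in aligned if a.alignable])

    per_read_calls = [call_from_ops(a.ops, ref, window) for a in kept]
    counts: Counter = Counter()
    exemplar: dict[tuple, IndelCall] = {}
    for calls in per_read_calls:
        for c in set(c.identity for c in calls):
            counts[c] += 1
        for c in calls:
            exemplar.setdefault(c.identity, c)

    n_kept = len(kept)
    surviving: set[tuple] = set()
    control_ids = (
        {c.identity for c in control_profile.indels} if control_profile is not None else set()
    )
    if control_profile is None and not is_control:
        warnings.warn(
            f"no control profile for {ref.locus_id!r}/{animal_id!r}: mutation counts "
            "are NOT control-normalised",
            stacklevel=2,
        )
    for ident, n in counts.items():
        freq = n / n_kept if n_kept else 0.0
        if freq < min_freq:
            continue  # sequencing error
        if ident in control_ids:
            continue  # present in control: not Cas9-induced
        surviving.add(ident)

    n_mut = 0
    n_shift = 0
    for calls in per_read_calls:
        real = [c for c in calls if c.identity in surviving]
        if real:
            n_mut += 1
            if classify_frameshift(real):
                n_shift += 1

    indels = sorted(
        (replace(exemplar[i], frequency=counts[i] / n_kept) for i in surviving),
        key=lambda c: (-c.frequency, c.identity),
    )
    return SampleEditProfile(
        locus_id=ref.locus_id,
        animal_id=animal_id,
        reads_kept=n_kept,
        reads_discarded=len(discarded) + len(unalignable),
        frac_mutated=n_mut / n_kept if n_kept else 0.0,
        frac_frameshift=n_shift / n_kept if n_kept else 0.0,
        indels=indels,
        excluded=n_kept < coverage_floor,
        control_normalised=control_profile is not None,
    )


# ---------------------------------------------------------------------------
# cross-sample statistics


def _top10(profile: SampleEditProfile) -> set[tuple]:
    if len(profile.indels) < 10:
        raise ValueError(
            f"sample {profile.locus_id}/{profile.animal_id} has fewer than 10 indels "
            "and is discarded from the sharing analysis"
        )
    ranked = sorted(profile.indels, key=lambda c: (-c.frequency, c.identity))
    return {c.identity for c in ranked[:10]}


def top10_sharing(a: SampleEditProfile, b: SampleEditProfile) -> int:
    """Number of indels common to the two samples' top-10 most frequent indels.

    Identity: same start and end positions, same type, and for insertions
    the same inserted sequence.
    """
    return len(_top10(a) & _top10(b))


@dataclass
class SpectrumResult:
    """Pooled unique-indel length histogram and deletion-position profile."""

    length_counts: pd.Series  # index: signed length (deletions negative)
    deletion_positions: pd.Series  # index: PAM-relative position of deleted nt
    n_unique: int

    @property
    def deletion_fraction(self) -> float:
        if self.n_unique == 0:
            return float("nan")
        return float(self.length_counts[self.length_counts.index < 0].sum()) / self.n_unique


def unique_indel_spectrum(samples: Iterable[SampleEditProfile]) -> SpectrumResult:
    """Pooled spectrum over per-sample *unique* indels (control samples excluded
    by the caller).  Each distinct indel contributes once per sample whatever
    its read frequency, approximating the per-repair-event outcome law."""
    lengths: Counter = Counter()
    positions: Counter = Counter()
    n_unique = 0
    for profile in samples:
        seen = {c.identity: c for c in profile.indels}
        for c in seen.values():
            n_unique += 1
            lengths[c.signed_length] += 1
            if c.type == "deletion":
                for pos in range(c.start, c.end + 1):
                    positions[pos] += 1
    length_counts = pd.Series(dict(sorted(lengths.items())), dtype=int)
    deletion_positions = pd.Series(dict(sorted(positions.items())), dtype=int)
    return SpectrumResult(length_counts, deletion_positions, n_unique)


# ---------------------------------------------------------------------------
# I/O helpers


def read_fastq(path: str | Path, mate: str = "single") -> list[ReadRecord]:
    """Read a plain or gzipped FASTQ file into ReadRecords."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [
            ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
                mate=mate,
            )
            for rec in SeqIO.parse(handle, "fastq")
        ]


def profiles_to_frame(profiles: Iterable[SampleEditProfile]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": p.locus_id,
            "animal_id": p.animal_id,
            "reads_kept": p.reads_kept,
            "reads_discarded": p.reads_discarded,
            "frac_mutated": p.frac_mutated,
            "frac_frameshift": p.frac_frameshift,
            "n_indels": len(p.indels),
            "excluded": p.excluded,
            "control_normalised": p.control_normalised,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
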