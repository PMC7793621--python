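"""Seeded generators for every input type, with machine-readable ground truth.

Everything downstream of a wet-lab instrument in this toolkit can be
exercised on synthetic data drawn from the regimes the method was designed
for: Cas9-edited amplicon reads (87% mutated reads per locus, a 57:43
deletion:insertion mix, short-biased indel lengths, deletion positions
normally distributed around 4 bp 5' of the PAM), bout-structured
delta-pixel activity traces on a 14 h:10 h light:dark schedule, and
trended cosine luminescence plates sampled every 9.92 min.  Every
generator takes a seed (or numpy Generator) and emits a truth table;
downstream tests read truth only from those tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_indels import AmpliconReference, ReadRecord
from .behaviour_fingerprint import Epoch, LightSchedule, build_epochs

__all__ = [
    "EditModel",
    "BehaviourModel",
    "AmpliconCohort",
    "BehaviourCohort",
    "random_amplicon",
    "generate_amplicon_cohort",
    "generate_allele_population",
    "generate_behaviour_cohort",
    "generate_luminescence_plate",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def random_amplicon(
    rng: np.random.Generator | int | None,
    length: int = 250,
    locus_id: str = "locus",
    strand: str = "+",
) -> AmpliconReference:
    """Random amplicon with a 20-nt protospacer and NGG PAM near its middle."""
    rng = np.random.default_rng(rng)
    seq = list(_random_seq(rng, length))
    guide_start = length // 2 - 10
    guide_end = guide_start + 20
    if strand == "+":
        seq[guide_end + 1] = "G"
        seq[guide_end + 2] = "G"
        pam = guide_end
    else:
        seq[guide_start - 2] = "C"
        seq[guide_start - 3] = "C"
        pam = guide_start - 1
    return AmpliconReference(locus_id, "".join(seq), guide_start, guide_end, strand, pam)


# ---------------------------------------------------------------------------
# amplicon read cohorts


@dataclass(frozen=True)
class EditModel:
    """Editing-outcome law for one screen.

    Defaults emulate the characterised regime: ~87% of reads mutated per
    locus, 57% deletions vs 43% insertions, geometric indel lengths over
    1..30 (mean ~4), deletion positions centred 4 bp 5' of the PAM, and a
    per-base substitution error rate consistent with Q40 base quality.
    """

    p_mutation: float = 0.87
    deletion_fraction: float = 0.57
    length_geometric_p: float = 0.25
    max_indel_length: int = 30
    deletion_center: float = -4.0
    deletion_sd: float = 3.0
    sequencing_error_rate: float = 1e-4
    base_quality: int = 40
    repertoire_size: int = 20
    animal_weight_concentration: float = 5.0

    def __post_init__(self) -> None:
        for name in ("p_mutation", "deletion_fraction", "length_geometric_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _draw_length(model: EditModel, rng: np.random.Generator) -> int:
    while True:
        length = int(rng.geometric(model.length_geometric_p))
        if length <= model.max_indel_length:
            return length


def _locus_repertoire(
    ref: AmpliconReference, model: EditModel, rng: np.random.Generator
) -> tuple[list[tuple], np.ndarray]:
    """Locus-specific repertoire of candidate repair outcomes.

    Real Cas9 repair outcomes depend on the sequence context, so the same
    RNP produces the same indels in different animals far more often than
    chance; each locus therefore draws its own discrete repertoire, shared
    by all animals injected at that locus.  Operations are in amplicon
    plus-strand coordinates.
    """
    cut = ref.predicted_cut
    ops: list[tuple] = []
    seen = set()
    margin = 15
    while len(ops) < model.repertoire_size:
        # type first, then rejection-sample within the type, so uniqueness
        # rejections cannot skew the deletion:insertion mix
        is_deletion = rng.random() < model.deletion_fraction
        attempts = 0
        while True:
            attempts += 1
            length = _draw_length(model, rng)
            if is_deletion:
                sd_pos = model.deletion_sd * (1 + attempts // 25)
                center_rel = model.deletion_center + sd_pos * rng.standard_normal()
                center = ref.from_pam_relative(int(round(center_rel)))
                start = center - length // 2
                start = max(margin, min(start, len(ref.sequence) - margin - length))
                op = ("deletion", start, start + length, "")
            else:
                ins = _random_seq(rng, length)
                op = ("insertion", cut, cut, ins)
            if op not in seen:
                break
        seen.add(op)
        ops.append(op)
    base_weights = rng.dirichlet(np.full(len(ops), 2.0))
    return ops, base_weights


def _apply_op(sequence: str, op: tuple) -> str:
    kind, start, end, ins = op
    if kind == "deletion":
        return sequence[:start] + sequence[end:]
    return sequence[:start] + ins + sequence[start:]


def _sequencing_noise(seq: str, model: EditModel, rng: np.random.Generator) -> str:
    errors = np.flatnonzero(rng.random(len(seq)) < model.sequencing_error_rate)
    if errors.size == 0:
        return seq
    chars = list(seq)
    for i in errors:
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


@dataclass
class AmpliconCohort:
    """Synthetic amplicon sequencing cohort with ground truth.

    ``reads`` maps (locus_id, animal_id) to reads of an injected animal;
    ``controls`` maps locus_id to error-only reads of the uninjected
    control.  ``truth`` holds the realised per-sample mutated / frameshift
    read fractions and ``true_indels`` the injected indel identities.
    """

    references: list[AmpliconReference]
    reads: dict[tuple[str, str], list[ReadRecord]]
    controls: dict[str, list[ReadRecord]]
    truth: pd.DataFrame
    true_indels: pd.DataFrame


def generate_amplicon_cohort(
    references: Sequence[AmpliconReference],
    model: EditModel = EditModel(),
    n_animals: int = 4,
    reads_per_sample: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> AmpliconCohort:
    """Simulate an amplicon MiSeq run over loci x animals, plus controls."""
    rng = np.random.default_rng(rng)
    reads: dict[tuple[str, str], list[ReadRecord]] = {}
    controls: dict[str, list[ReadRecord]] = {}
    truth_rows = []
    indel_rows = []
    for ref in references:
        ops, base_weights = _locus_repertoire(ref, model, rng)
        net = {i: (len(op[3]) if op[0] == "insertion" else -(op[2] - op[1])) for i, op in enumerate(ops)}
        for i, op in enumerate(ops):
            indel_rows.append(
                {
                    "locus_id": ref.locus_id,
                    "type": op[0],
                    "amplicon_start": op[1],
                    "amplicon_end": op[2],
                    "inserted_sequence": op[3],
                    "net_length": net[i],
                }
            )
        for a in range(1, n_animals + 1):
            animal_id = f"fish{a}"
            conc = model.animal_weight_concentration
            weights = rng.dirichlet(conc * len(ops) * base_weights + 1e-3)
            sample: list[ReadRecord] = []
            n_mut = 0
            n_shift = 0
            for r in range(reads_per_sample):
                seq = ref.sequence
                if rng.random() < model.p_mutation:
                    k = int(rng.choice(len(ops), p=weights))
                    seq = _apply_op(seq, ops[k])
                    n_mut += 1
                    if net[k] % 3 != 0:
                        n_shift += 1
                seq = _sequencing_noise(seq, model, rng)
                quals = tuple([model.base_quality] * len(seq))
                sample.append(ReadRecord(f"{ref.locus_id}_{animal_id}_r{r}", seq, quals))
            reads[(ref.locus_id, animal_id)] = sample
            truth_rows.append(
                {
                    "locus_id": ref.locus_id,
                    "animal_id": animal_id,
                    "n_reads": reads_per_sample,
                    "true_frac_mutated": n_mut / reads_per_sample,
                    "true_frac_frameshift": n_shift / reads_per_sample,
                }
            )
        controls[ref.locus_id] = [
            ReadRecord(
                f"{ref.locus_id}_control_r{r}",
                _sequencing_noise(ref.sequence, model, rng),
                tuple([model.base_quality] * len(ref.sequence)),
            )
            for r in range(reads_per_sample)
        ]
    return AmpliconCohort(
        references=list(references),
        reads=reads,
        controls=controls,
        truth=pd.DataFrame(truth_rows),
        true_indels=pd.DataFrame(indel_rows),
    )


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Deterministic plain-text FASTQ writer (Phred+33)."""
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [2] * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")


def generate_allele_population(
    pshift: Sequence[float],
    n_alleles: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alleles with independent per-locus frameshift states.

    Returns ``(states, measured_fractions, true_trajectory)``: the boolean
    allele x locus frameshift matrix, the per-locus frameshift fractions an
    amplicon assay would measure, and the true cumulative fraction of
    alleles carrying at least one frameshift among the first 1, 2, ... loci.
    """
    rng = np.random.default_rng(rng)
    pshift = np.asarray(pshift, dtype=float)
    states = rng.random((n_alleles, pshift.size)) < pshift
    measured = states.mean(axis=0)
    true_trajectory = np.maximum.accumulate(states, axis=1).mean(axis=0)
    return states, measured, true_trajectory


# ---------------------------------------------------------------------------
# behaviour cohorts


@dataclass(frozen=True)
class BehaviourModel:
    """Two-state (bout/pause) activity model with day/night modulation.

    Per larva, the fraction of time active and the movement intensity are
    drawn from normal across-animal distributions per epoch class; frames
    then follow a two-state Markov process whose stationary active
    fraction matches the draw.  ``shift`` moves the mutant group's mean of
    a generator parameter ("active_fraction" or "intensity") by the stated
    number of across-animal SDs for one epoch class, defining the expected
    fingerprint Z-score on the corresponding measured parameter.
    """

    frame_rate: float = 25.0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    n_epochs: int = 6  # day, night, ... (first day + night are habituation)
    mean_active_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"day": 0.25, "night": 0.08}
    )
    sd_active_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"day": 0.08, "night": 0.03}
    )
    mean_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"day": 10.0, "night": 8.0}
    )
    sd_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"day": 2.0, "night": 2.0}
    )
    mean_active_bout_seconds: float = 0.24
    shift: Mapping[tuple[str, str], float] = field(default_factory=dict)

    #: measured fingerprint parameter carrying each generator parameter
    SHIFT_TARGETS = {
        "active_fraction": "total_time_active_pct",
        "intensity": "active_bout_mean",
    }


@dataclass
class BehaviourCohort:
    traces: pd.DataFrame  # frames x wells (delta pixels)
    metadata: pd.DataFrame  # well, group
    epochs: list[Epoch]
    frame_rate: float
    truth: pd.DataFrame  # parameter, epoch, expected_z


def _two_state_trace(
    n_frames: int,
    p_active: float,
    mean_active_frames: float,
    intensity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternating geometric active/inactive runs with the target stationary
    active fraction; active frames carry gamma-distributed delta pixels."""
    if p_active <= 0.0:
        return np.zeros(n_frames, dtype=np.int32)
    q_exit_active = min(1.0, 1.0 / max(mean_active_frames, 1.0))
    q_enter_active = min(1.0, p_active * q_exit_active / max(1.0 - p_active, 1e-9))
    state = bool(rng.random() < p_active)
    chunks: list[np.ndarray] = []
    total = 0
    while total < n_frames:
        n_runs = int(2 * n_frames * max(q_exit_active * p_active, q_enter_active * (1 - p_active))) + 16
        lens = np.empty(2 * n_runs, dtype=np.int64)
        lens_a = rng.geometric(q_exit_active, n_runs)
        lens_i = rng.geometric(q_enter_active, n_runs)
        if state:
            lens[0::2], lens[1::2] = lens_a, lens_i
        else:
            lens[0::2], lens[1::2] = lens_i, lens_a
        states = np.empty(2 * n_runs, dtype=bool)
        states[0::2], states[1::2] = state, not state
        chunk = np.repeat(states, lens)
        chunks.append(chunk)
        total += chunk.size
        state = not states[-1]
    mask = np.concatenate(chunks)[:n_frames]
    values = np.zeros(n_frames, dtype=np.int32)
    n_active = int(mask.sum())
    if n_active:
        draws = np.maximum(1, np.round(rng.gamma(2.0, intensity / 2.0, n_active)))
        values[mask] = draws.astype(np.int32)
    return values


def generate_behaviour_cohort(
    model: BehaviourModel = BehaviourModel(),
    n_per_group: int = 40,
    groups: Sequence[str] = ("wildtype", "mutant"),
    rng: np.random.Generator | int | None = None,
) -> BehaviourCohort:
    """Delta-pixel traces for a wild-type and a (shifted) mutant group.

    The wild-type group never receives the shift; every other group does.
    The truth table states the expected fingerprint Z for the measured
    parameter mapped to each shifted generator parameter (0 for the other
    directly modelled parameters; collaterally affected parameters are
    left unspecified, NaN).
    """
    rng = np.random.default_rng(rng)
    hours = []
    label = "day"
    for _ in range(model.n_epochs):
        hours.append(model.schedule.day_hours if label == "day" else model.schedule.night_hours)
        label = "night" if label == "day" else "day"
    n_frames = int(round(sum(hours) * 3600 * model.frame_rate))
    epochs = build_epochs(n_frames, model.frame_rate, model.schedule)
    mean_active_frames = model.mean_active_bout_seconds * model.frame_rate

    traces: dict[str, np.ndarray] = {}
    meta_rows = []
    for group in groups:
        shifted = group != "wildtype"
        for i in range(n_per_group):
            well = f"{group}_{i:02d}"
            # each larva carries one stable trait per epoch class: redrawing
            # per epoch would shrink the between-larva SD of multi-epoch
            # parameter averages below the model's stated SD
            traits: dict[str, tuple[float, float]] = {}
            for cls in ("day", "night"):
                mu_p = model.mean_active_fraction[cls]
                sd_p = model.sd_active_fraction[cls]
                mu_i = model.mean_intensity[cls]
                sd_i = model.sd_intensity[cls]
                if shifted:
                    mu_p += model.shift.get(("active_fraction", cls), 0.0) * sd_p
                    mu_i += model.shift.get(("intensity", cls), 0.0) * sd_i
                # traits are truncated to [0.01, 0.95] so bout statistics
                # stay defined for every larva; a strictly silent model
                # (zero mean and SD) still yields all-zero traces
                if mu_p == 0.0 and sd_p == 0.0:
                    p = 0.0
                else:
                    p = float(np.clip(rng.normal(mu_p, sd_p), 0.01, 0.95))
                intensity = float(np.clip(rng.normal(mu_i, sd_i), 1.0, None))
                traits[cls] = (p, intensity)
            trace = np.zeros(n_frames, dtype=np.int32)
            for ep in epochs:
                p, intensity = traits[ep.label]
                seg = _two_state_trace(
                    ep.end_frame - ep.start_frame, p, mean_active_frames, intensity, rng
                )
                trace[ep.start_frame : ep.end_frame] = seg
            traces[well] = trace
            meta_rows.append({"well": well, "group": group})

    truth_rows = []
    for cls in ("day", "night"):
        for gen_param, measured in BehaviourModel.SHIFT_TARGETS.items():
            truth_rows.append(
                {
                    "parameter": measured,
                    "epoch": cls,
                    "expected_z": model.shift.get((gen_param, cls), 0.0),
                }
            )
    return BehaviourCohort(
        traces=pd.DataFrame(traces),
        metadata=pd.DataFrame(meta_rows),
        epochs=epochs,
        frame_rate=model.frame_rate,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# luminescence plates


def generate_luminescence_plate(
    periods: Mapping[str, float],
    interval_minutes: float = 9.92,
    duration_hours: float = 123.0,
    amplitude: float = 100.0,
    snr: float = 5.0,
    background_level: float = 50.0,
    trend_slope: float = -0.5,
    n_blanks: int = 8,
    ct_start: float = 3.0,
    conditions: Mapping[str, str] | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Cosine luminescence plate with a shared baseline trend and blanks.

    ``periods`` maps well id -> true period (hours).  Each well carries
    ``amplitude * cos`` at its own period and random phase, a shared slow
    background, a linear amplitude/baseline trend and Gaussian noise with
    ``sd = amplitude / snr``; blank wells carry background and noise only.
    Returns ``(plate, truth)`` with truth rows (well, true_period_hours).
    """
    from .circadian_period import LuminescencePlate

    rng = np.random.default_rng(rng)
    n = int(round(duration_hours * 60.0 / interval_minutes))
    t = ct_start + np.arange(n) * interval_minutes / 60.0
    background = background_level * (1.0 + 0.2 * np.sin(2 * np.pi * t / 70.0))
    noise_sd = amplitude / snr
    data = {}
    truth_rows = []
    for well, period in periods.items():
        phase = rng.uniform(0, 2 * np.pi)
        signal = (
            background
            + trend_slope * t
            + amplitude * np.cos(2 * np.pi * t / period + phase)
            + rng.normal(0.0, noise_sd, n)
        )
        data[well] = signal
        truth_rows.append({"well": well, "true_period_hours": period})
    blanks = []
    for b in range(n_blanks):
        well = f"blank{b:02d}"
        blanks.append(well)
        data[well] = background + rng.normal(0.0, noise_sd * 0.1, n)
    plate = LuminescencePlate(
        data=pd.DataFrame(data),
        interval_minutes=interval_minutes,
        blank_wells=tuple(blanks),
        conditions=dict(conditions or {}),
        ct_start=ct_start,
    )
    return plate, pd.DataFrame(truth_rows)
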