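# Methods

This note documents the models and numerical choices behind `f0screen`, the
assumptions they rest on, and what the synthetic-data generators do and do
not emulate.

## Knockout-probability model

A gene is targeted at `n` loci with Cas9 ribonucleoproteins. Writing
`P_mutation` for the per-locus probability that an allele is mutated and
`P_frameshift` for the probability that a mutation shifts the reading frame
(empirically close to 2/3, because one net indel length in three is a
multiple of 3), the per-allele frameshift probability is

    q = 1 − (1 − P_mutation · P_frameshift)^n

and the biallelic knockout probability is `P_KO = q²`.

Assumptions: (i) outcomes at different loci are independent, on each allele
and between alleles; (ii) frameshift is the sole knockout mechanism — an
indel that mutates essential residues without shifting the frame is not
counted, so the model is conservative; (iii) an allele carrying any
frameshift is null even if a downstream indel restores the frame. At
`P_mutation = 1.00, P_frameshift = 0.66` the model gives 92.3% at three
loci; at `P_mutation = 0.80` it gives 90.3% at four loci — the basis of the
three-to-four-guide design rule. The closed form is verified in the tests
against exhaustive enumeration over all per-locus (mutated?, frameshift?)
states of two alleles.

### Frameshift accumulation from sequencing data

For one animal, sequencing locus `l` yields the fraction of reads with a
frameshift, `pshift_l`. Under the same independence assumption, the
fraction of alleles carrying at least one frameshift after targeting loci
1..L accumulates as the product of complements:

    pshift_{1→L} = 1 − Π_{l≤L} (1 − pshift_l)

The function returns the whole cumulative trajectory. The default locus
order is lexicographic by locus id (the order in which guides are usually
ranked by the vendor); callers may pass bare fractions in any explicit
order. The caveat inherited from the data: reads at each locus are assumed
to be a random sample of the allele pool, which cell-lineage effects can
violate.

### Adjusted unviability

Unviability is the fraction of embryos dead or dysmorphic after 1 day
post-fertilisation, counted over the 1-dpf total (0-dpf losses are
unfertilised or needle-damaged eggs and are excluded). The control group's
percentage is subtracted so only RNP-mediated effects are reported; a
negative difference floors at zero and is flagged.

## Amplicon indel quantification

Reads are aligned to the reference amplicon with an affine-gap pairwise
aligner (Biopython `PairwiseAligner`; match +5, mismatch −4, gap open −24,
gap extend −1, both sequences' end gaps free). Free end gaps let read ends
that do not belong to the amplicon stay unaligned; the unaligned end
fraction stands in for the soft-clip fraction of a mapping aligner. Gap
placement is normalised by shifting every indel maximally left in amplicon
coordinates, which makes indel identity comparisons deterministic. A read
scoring below 1 point per base is flagged unalignable and excluded from
all denominators.

Filters (all strict inequalities): length < 140 bp, mean Phred < 40, or
> 20% soft-clipped. The quality statistic is the read mean; a per-base
minimum of Q40 would discard essentially all real reads. Samples under
30× paired-end (60× single-read) coverage are marked excluded.

Indel calls are reported in PAM-relative coordinates: the PAM nucleotide
adjacent to the guide-binding site is position 0; for a plus-strand guide
negative positions lie 5′ of the PAM, and for a minus-strand guide the
axis is mirrored. Only gaps within ±60 bp of the predicted cut site
(3 bp 5′ of the PAM, the standard SpCas9 blunt cut) are reported, which
bounds spurious end-of-read gaps. Substitutions never produce calls.
Indel identity is (type, start, end, inserted sequence).

Per sample: indels below a frequency of 0.005 are treated as sequencing
error; indels present in the matched uninjected/scrambled control are not
counted as Cas9-induced; a read is mutated if it carries at least one
surviving call, and frameshifted if its net indel length is not a multiple
of 3 (intron/exon-boundary effects are deliberately ignored). Mates of a
pair are merged by exact 3′ overlap when possible, otherwise R1 is used,
and coverage is counted in pairs.

Cross-sample statistics follow the screen conventions: top-10 sharing
intersects the ten most frequent indels of two samples under the identity
rule; the unique-indel spectrum de-duplicates per sample before pooling
(so a clonally amplified early mutation counts once), tallies signed
lengths (deletions negative), and accumulates per-nucleotide deletion
positions on the PAM-relative axis.

## Headloop suppression PCR

A 5′ tag reverse-complementary to the wild-type target sequence is added
to one PCR primer. After second-strand synthesis the tag anneals to its
target in the same strand and elongation forms a stable hairpin, removing
wild-type amplicons from the template pool; an indel at the target breaks
complementarity and the mutant template amplifies exponentially.

Design rules: (1) the predicted cut site must fall within the first 6 bp
of the tag; (2) the tag window must contain no SNP; (3) GC content and
melting temperature should match the base primers as closely as possible.
The tagged primer defaults to the one pointing the same way as the guide,
for which the reverse complement of the guide-binding sequence is the
natural first candidate; windows of 20 ± 4 nt are screened and the
GC/Tm-closest valid window wins (ties broken toward the canonical length
and the leftmost window, so the design is deterministic). An unsatisfiable
rule raises an error naming the rule; a best-effort tag outside the GC/Tm
tolerance (defaults: 0.15 GC fraction, 5 °C) is returned flagged. Tm is
nearest-neighbour thermodynamics (Biopython `Tm_NN` defaults: 50 mM Na⁺,
25 nM each strand).

In-silico validation aligns a haplotype to the wild-type amplicon and
follows the tag-target interval through the alignment: the haplotype is
suppressed iff the interval survives with no indel and at most `m`
substitutions (default 1, tolerating a stray SNP; 0 is strictest). Any
indel inside the interval — including a single deleted base — predicts
amplification. A disrupted primer binding site yields a distinct
no-amplification outcome. Note that an indel in a sequence repeat whose
left-aligned placement falls outside the interval leaves the target
sequence literally intact, and is therefore (correctly) suppressed.

The gel score compares the sample's headloop-to-standard band ratio with
the matched control ratio: `score = 1 − (HL/STD)_sample /
max((HL/STD)_control, ε)`, clipped to [0, 1]. A sample indistinguishable
from its control scores 0; a sample with no headloop-relative signal
scores 1; samples at or above 0.6 are classified mutagenic. The formula
and its orientation are this package's explicit convention — the assay's
published description does not print one — and the 0.6 threshold is
tentative: loci are known where a mutagenic guide repeatedly scores low
(false negatives), so scores should gate sequencing, not replace it. A
documentation warning, not a simulation: effective suppression requires a
proofreading polymerase (3′→5′ exonuclease activity).

## Power simulation

Control and knockout phenotypes are modelled as normal distributions
(fitted from real data with optional outlier trimming; synthetic draws are
never trimmed). For each injection success rate s = 0, 1, …, 100%, the
simulated F0 group of n = 100 animals contains `round(n·s)` knockout draws
and control draws for the remainder, against a fresh control group of 100.
Cohen's d (pooled SD) is converted to the smallest per-group n achieving
0.8 power for a two-sided two-sample t-test at α = 0.05, by iterating n
upward through the noncentral-t power function (cross-checked in tests
against `statsmodels`). Effects needing more than a configurable ceiling
(default 1000) per group report an "undetectable" sentinel, as does d = 0.
The 101-rate sweep is repeated (default 10 iterations) for error bars; the
full default sweep runs in well under a minute on one CPU.

The stimulus-response reduction used for chemical assays (e.g. mustard
oil) is the total activity in the first 3 min of exposure minus the total
activity in the 3 min immediately before transfer.

## Behavioural fingerprints

The activity signal is Δ pixels: the per-frame count of pixels changing
intensity in a well. A trace decomposes exactly into alternating maximal
runs — active bouts (strictly positive frames) and inactive bouts (zeros).
Ten parameters are computed per larva and per epoch class (day, night):
active bout length, mean, SD, total, minimum, maximum (all averaged across
bouts of the class), number of active bouts, total time active (%), total
activity, and inactive bout length. The first day and night are treated as
habituation and cropped; remaining epochs are pooled by class (pooling all
bouts of a class was chosen over averaging per-epoch summaries). The
active-bout SD is the within-bout SD averaged across bouts. A class with
no active bouts yields missing bout-level parameters, excluded pairwise
downstream. One-second binning with a 15-min rolling average exists for
display only; statistics always use unbinned bouts.

A fingerprint is the vector of Z-scores of the 20 (parameter × class)
values against the paired wild-type siblings' mean and SD (sample SD,
≥ 2 wild types required; zero-SD parameters are flagged missing). Groups
are compared by Pearson correlation of mean fingerprints
(pairwise-complete) and by each larva's Euclidean distance to the paired
wild-type mean fingerprint — the origin in Z space — with missing entries
excluded and the distance rescaled by √(k_full/k_used). Group tests:
one-way ANOVA then pairwise Welch's t-tests with Holm adjustment; two-way
ANOVA with a condition × day/night interaction for activity; and a
meta-analysis Z-test for comparing two Cohen's d values, with
`se(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`.

## Circadian period estimation

Plate-reader luminescence (counts per second, one sample every 9.92 min by
default) is background-subtracted using the mean of blank wells, then
detrended: a centred moving-average baseline is subtracted and the result
divided by a moving-average envelope of its absolute value, making the
estimate invariant to rescaling the raw counts; the series is then mean
centred. Both windows default to 48 h: a moving average shorter than the
rhythm partially tracks the oscillation and biases the period fit (with
24 h windows the median recovery error on the synthetic benchmark tripled).
Moving averages use reflected ends, as a shrinking edge window bends the
baseline at the record boundaries. Analysis is restricted to free-running
conditions by cropping the series at a stated circadian time (24 h after
the last partial light-dark cycle in the reference protocol).

The period is estimated per well by nonlinear least squares on
`A·cos(2πt/T + φ)` plus an offset and an optional residual linear term.
The fit is seeded from the dominant spectral peak inside a user-defined
window of plausible periods, evaluated on a fine period grid because the
record is short relative to circadian periods; `T` is bounded to the
window. Group-specific windows are supported (e.g. 18–32 h untreated,
28–42 h under a period-lengthening drug). Flags: *failed* when no
in-window peak exists or the fit does not converge; *equivocal* — manual
review — when the relative period standard error exceeds 10%, the cosine
explains under 20% of the variance, or the period sticks to a window
boundary (the signature of a true period outside the window); *ok*
estimates always lie strictly inside their window. A single cosine
component is a deliberate simplification of multi-component fitting;
one rhythm is assumed per well. Detrending a strongly trended record
costs roughly 0.1 h of accuracy near the record edges, visible in the
noiseless synthetic benchmark.

## Synthetic data generators

All generators are seeded (`numpy.random.Generator`) and bit-reproducible,
and every one emits a machine-readable truth table; tests read truth only
from those tables.

**Amplicon reads.** Each locus draws a repertoire of candidate repair
outcomes (default 20) because real repair outcomes are sequence-dependent:
the same guide produces overlapping indel sets in different animals, which
is what the top-10 sharing statistic measures. The outcome law mirrors the
characterised regime: 87% of reads mutated per locus, 57% deletions vs 43%
insertions (the type is drawn before uniqueness rejection so the mix is
unbiased), geometric lengths on 1..30 with mean ≈ 4, deletion centres
normal around 4 bp 5′ of the PAM (SD 3), insertions at the cut site.
Animals share the locus repertoire with Dirichlet-jittered weights. Base
qualities are constant Q40 with a consistent 10⁻⁴ substitution error rate;
controls carry errors only. Not emulated: quality-by-cycle profiles,
chimeras, microhomology-aware repair prediction, large multi-locus
deletions — so passing tests validate the calling pipeline's arithmetic,
not robustness to every MiSeq artefact.

**Behaviour.** A two-state (bout/pause) Markov process per larva with
geometric run lengths; the per-larva fraction of time active and movement
intensity are drawn once per epoch class from normal across-animal
distributions (day mean 0.25, SD 0.08; night mean 0.08, SD 0.03; intensity
10 ± 2 and 8 ± 2 Δpx) truncated to keep bout statistics defined, with mean
active bouts of 0.24 s. Defaults follow the reference recording regime
(25 frames/s, 14 h:10 h light:dark); tests run a reduced geometry —
5 frames/s with 1 h day / 1 h night epochs, one habituation cycle plus two
analysed — so an 80-larva cohort generates and analyses in well under a
minute. A mutant shift vector moves the group mean of a generator trait by
a stated number of across-animal SDs, which defines the expected
fingerprint Z on the mapped measured parameter (active fraction → total
time active; intensity → active bout mean); collaterally affected
parameters (bout counts, inactive bout length, total activity) are left
unspecified in the truth table. Not emulated: circadian drift within an
epoch, water-change artefacts, startle responses, or inter-larva
correlation.

**Luminescence plates.** Per-well cosines with user-specified true
periods, random phases, a shared slowly varying background, a linear
baseline trend and Gaussian noise with SD = amplitude/SNR; blank wells
carry background and reduced noise only. No damping is simulated.

## Problem sizes used in the automated checks

Enumeration oracle up to 4 loci on a 5 × 5 probability grid; 10⁴ alleles ×
3 loci for the accumulation recursion; 3 loci × 4 animals × 1000 reads
(plus 1000-read controls) for the amplicon round trip; 50 randomized
headloop designs with 1–3 bp indels; the full 101-rate × 10-iteration
power sweep at n = 100; two replicate behaviour clutches of 40 + 40
larvae; 100 luminescence wells spanning 20–40 h at SNR 5 over 123 h.
These sizes are the package's own benchmark choices; generator defaults
remain at the reference regimes described above.

## Known limitations

- The knockout model ignores in-frame deleterious mutations, exon
  skipping, maternal protein perdurance, and large inter-locus deletions;
  all push in the conservative direction except perdurance.
- The aligner is glocal and will not recover indels larger than roughly
  the reporting window or reads whose ends both lie outside the amplicon.
- The headloop score's mapping to mutant allele fraction is monotone only
  under the stated band-ratio convention and is known to produce false
  negatives at some loci.
- Minimum sample sizes assume normal phenotypes and independent animals;
  within-clutch correlation would inflate them.
- The circadian fit assumes a single stationary rhythm; damping or
  multi-component rhythms bias the estimate and typically surface as
  equivocal flags.
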