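# Methods

## Scope and model

`rloopmap` analyzes co-transcriptional R-loop formation at a CGG-repeat
locus through three computational lenses: sequence-level propensity,
population-level enrichment (DRIP-qPCR), and single-molecule structure
(non-denaturing bisulfite footprints). All sequence work is done on the
sense (mRNA-synonymous, CGG-bearing) strand with 0-based half-open
coordinates; positive GC skew on that strand marks the R-loop-favoring
orientation, because the displaced strand of the R-loop is the G-rich
non-template strand.

## Sequence signatures (`seqsig`)

Per window of length L (default 100 nt, step 1 nt for maximal resolution;
both configurable): GC% = 100·(G+C)/L; GC skew = (G−C)/(G+C); CpG O/E =
(#CpG·L)/(#C·#G) in the Gardiner-Garden & Frommer form, with the
length-corrected variant (#CpG·L²)/(#C·#G·(L−1)) available as
`cpg_oe_form="length-corrected"`. CpG dinucleotides are counted within the
window only. Windows with G+C = 0 (skew) or C·G = 0 (O/E), and any window
containing N, are reported as NaN — never as 0 — and break CpG-island runs.

CpG islands are maximal runs of consecutive windows with O/E > 0.6 and
GC% > 50, merged to the base-space union of the passing windows' spans and
retained when the span reaches 200 nt. Reporting the union of full window
spans (rather than window centers) makes the island boundary a
deterministic function of the profile. G-clusters are maximal runs of ≥ 4
consecutive G. The CGG-tract annotator scans all three codon frames for
the longest run of CGG units in which AGG units are tolerated when flanked
by CGG on both sides; AGG units count toward the unit total, so tract
length is always 3 × unit count.

## DRIP-qPCR quantification (`dripq`)

Quantities assume perfect per-cycle doubling (efficiency 2.0; standard-curve
calibration is out of scope): Q_well = 2^(−mean Ct), replicate Cts averaged
before transformation. Well quantities are scaled to whole-fraction
quantities by Q_prep = Q_well · dilution / assayed_fraction, where
`assayed_fraction` is the well volume over the fraction's prep volume
*before* dilution and `dilution` separately corrects concentration; the
input prep is further scaled by 1/input_share to the total starting
material. Percent of input is 100 · Q_prep(DRIP)/Q_total(input); fold
enrichment is the percent-of-input ratio of target over a
non-R-loop-forming reference locus and algebraically equals 2^(−ΔΔCt) when
correction constants match. Defaults mirror a standard protocol — input
diluted 1:100 with a 5-of-10 µL assayed-equivalent, 5 of 80 µL of
undiluted DRIP output assayed, 10 of 460 µL reserved as input — but which
corrections enter a published enrichment varies between labs, so all four
constants are explicit per-record configuration, and the simulator
populates them so the corrections invert its construction exactly.

RNase-H sensitivity uses an unpaired two-sample t-test on natural-log
enrichments (pooled variance by default, Welch by flag). When both groups
have zero log-scale variance the statistic is degenerate and flagged
(t = 0, p = 1 for equal means; ±∞, p = 0 otherwise) rather than returned
as NaN. Washout series are normalized to 100 × percent_input /
percent_input(peak timepoint).

## Bisulfite footprint mapping (`footprint`)

Bisulfite deaminates cytosine efficiently only in ssDNA, so in a
non-denaturing reaction the converted cytosines of a clone trace the
displaced strand of the R-loop. Clones are aligned to the *unconverted*
reference by a global affine-gap dynamic program with bisulfite-asymmetric
substitution scoring: reference C vs clone T scores as a full match
(conversion is signal), the reverse direction is a mismatch; N is neutral.
Inside the annotated CGG tract, gaps are restricted to unit-aligned 3-nt
multiples with a fixed per-unit cost, so length-polymorphic repeat alleles
align unit-wise instead of smearing gaps through the tract. The DP is
banded (band = length difference + 25, widened automatically if the
optimum escapes); traceback preference (diagonal, unit jump, deletion,
insertion) makes gap placement deterministic and leftmost. Clone
orientation is auto-detected by aligning both the clone and its reverse
complement and keeping the better score, since clones are sequenced from
either vector end. Clones scoring below half the perfect score
(configurable) are rejected as unalignable. This parameterized aligner
replaces general-purpose multiple alignment for reproducibility and
repeat-awareness.

Per reference cytosine: clone T → converted, clone C → unconverted, gap/N/
other → missing. Missing never counts toward protected runs (a sequencing
gap is not evidence of protection). Protected runs are maximal stretches of
≥ 3 consecutive unconverted cytosines (default chosen to exceed sporadic
single-site conversion failure; configurable), annotated inside/outside
the tract and flagged symmetric about an AGG interruption when the
interruption lies within one cytosine column of the run midpoint — the
hairpin-stem signature, in which only a short loop at the tract center
stays convertible.

A clone's footprint summary lists maximal converted runs; the initiation
site is the start of the first run of ≥ 3 converted cytosines
(`min_ss_run`). Using a run rather than the literal first converted
position is deliberate: with any nonzero dsDNA conversion rate, isolated
background conversions would otherwise dominate the minimum. Initiation is
assigned to the nearest G-cluster at or upstream, with a 12-nt downstream
tolerance absorbing boundary scatter around the nucleating cluster; if
only more-downstream clusters exist the nearest is assigned and flagged.
Configuration classification compares converted fractions in three regions
— the 150 nt immediately upstream of the tract, the tract, and 150 nt
immediately downstream (tract-proximal windows, so distal never-displaced
sequence cannot dilute the signal) — against a 0.5 threshold midway
between realistic ss and ds conversion rates: ss tract → regular; ds tract
with both flanks ss → hairpin; only the downstream flank ss → collapsed;
none → no R-loop.

## Synthetic data (`simgen`)

`make_allele` builds a GC-rich (72%) FMR1-like construct: a 600-nt
promoter-proximal flank carrying three TSS positions and four planted
G-clusters between the downstream-most TSS and the repeat, the (CGG)n
tract with AGG interruptions after every 10th unit by default (explicit
unit indices for expanded alleles, which in carriers retain interruptions
only near the 5′ end), and a 200-nt downstream flank with one more planted
G-cluster 20 nt past the tract — five clusters in all, mirroring the
locus schematic. Background flanks are scrubbed of accidental G-runs ≥ 4
and accidental 3-unit repeat stretches, planted clusters are padded with
non-G so they stay maximal, and the tract junctions are guarded so flank
sequence cannot extend the repeat frame; every planted feature is returned
as ground truth.

`simulate_clones` draws, per clone, one of four configurations (defaults:
regular 0.45, hairpin 0.20, collapsed 0.15, none 0.20 — putting 0.35 mass
on the hairpin/collapsed states whose tract escapes conversion, inside the
~25–50% of molecules expected to show that pattern). Regular: ssDNA from
the first upstream G-cluster through the tract and 250 nt beyond (past the
amplicon's 3′ end, as real footprints run off the sequenced region).
Collapsed: ssDNA only from the downstream G-cluster. Hairpin: as regular
but the tract is protected except `hairpin_loop_size` (default 1)
cytosines centered on the middle AGG interruption, reproducing the single
exposed central CpG adjacent to the AGG. Boundaries are jittered by
N(0, 1) cytosine columns; each cytosine converts with p_ss = 0.9 in ssDNA
and p_ds = 0.05 in dsDNA — placeholders, as the assay's true non-denaturing
conversion efficiencies are not quantified — followed by a 0.001/base
sequencing-error process. `simulate_ct_table` draws Ct =
baseline − log2(Q_well) + N(0, σ_Ct) with the volume/dilution fields set
so the quantification inverts the construction exactly at σ = 0.

What the simulator does *not* emulate: PCR slippage spectra in the repeat
(unit indels are an alignment capability, not a default noise source),
bacterial deletions and chimeric clones, methylation effects on
conversion, per-locus amplification-efficiency differences, and
between-subject biological variance structure beyond lognormal spread.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to every
artifact of real clone libraries.

## Group-level statistics (`pipeline`)

Repeated DRIP experiments on one subject are correlated, so experiments
are first aggregated to per-subject means; groups are then compared by an
unpaired pooled-variance t-test on log subject means together with a
permutation test over subject-to-group assignments (exact enumeration up
to 20 000 assignments, else Monte-Carlo with the identity assignment
included), statistic = |difference of group means of log subject means|.
This is a deliberately simple surrogate for a mixed-effects model and is
labeled as such in its output; group means, SDs and ranges are reported on
the raw scale. Permutation p-values are discrete (atoms = half the number
of assignments, since complementary assignments tie under the two-sided
statistic), which matters when checking calibration against a continuous
uniform.

## Numerical choices and problem sizes

Window metrics are computed with cumulative sums (exact integer counts);
NaN propagation is explicit. Alignment scores use floats with a single
deterministic traceback preference order. Permutation tests compare with a
1e-12 slack so float ties count as exceedances. Seeds flow through
`numpy.random.default_rng` / `SeedSequence` everywhere; all generators are
bit-deterministic given their seed. The test and acceptance runs size
simulations for single-CPU desk scale: 100–200 Monte-Carlo replicates for
qPCR recovery, 200 clones for conversion-rate/boundary recovery, 400–500
clones for configuration-fraction recovery on a compact 20-unit allele
(250/120-nt flanks), and 500 null datasets of 5+5 subjects for permutation
calibration — the 5+5 design gives 126 p-value atoms, fine enough for a
valid Kolmogorov–Smirnov uniformity check.

## Known limitations

- The expanded-allele GC% saturation (100% windows) requires a pure CGG
  stretch ≥ window length; alleles with periodic AGG interruptions
  throughout the tract plateau slightly below 100%.
- The aligner's unit-gap constraint assumes the tract annotation is
  correct; a mis-annotated tract frame degrades alignments inside it.
- Configuration classification with its fixed 0.5 threshold assumes
  p_ss and p_ds are well separated; it will blur for conversion rates
  closer than ~0.3 apart.
- The group comparison is not a mixed model: with few subjects its
  permutation p has a coarse lower bound and the t-test leans on
  approximate log-normality of subject means.
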