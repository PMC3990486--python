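"""Synthetic FMR1-like data with known ground truth.

Three generators with the statistical structure the analysis assumes:

* :func:`make_allele` — a GC-rich 5'UTR-like sequence: promoter flank with
  multiple transcription start sites, planted G-clusters, a (CGG)n tract
  with optional AGG interruptions, and a downstream flank carrying one more
  G-cluster.  All planted features are returned as ground truth.
* :func:`simulate_clones` — non-denaturing bisulfite clones drawn from a
  four-configuration R-loop model: a *regular* R-loop (displaced strand
  single-stranded from an upstream G-cluster through the repeat and
  beyond), a *collapsed* R-loop (the tract re-paired as dsDNA, ssDNA only
  downstream, nucleated at the downstream G-cluster), a *hairpin* R-loop
  (ss flanks, tract protected by a hairpin stem except a short exposed
  loop centered on an AGG interruption), or *no R-loop*.  Cytosines convert
  with probability ``p_convert_ss`` in ssDNA and ``p_convert_ds`` in
  dsDNA.
* :func:`simulate_ct_table` — DRIP-qPCR cycle-threshold tables constructed
  as the exact inverse of the comparative-Ct quantification, with Gaussian
  noise on the Ct scale and a controllable true enrichment.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dripq
from .dripq import CtRecord
from .footprint import CloneSequence
from .seqsig import GCluster, GenomicSequence, RepeatAnnotation

__all__ = [
    "AlleleSpec",
    "AlleleTruth",
    "FootprintModel",
    "CloneTruth",
    "QpcrModel",
    "make_allele",
    "simulate_clones",
    "simulate_ct_table",
]


@dataclass
class AlleleSpec:
    """Parameters of one synthetic allele.

    ``agg_units`` gives explicit unit indices carrying an AGG interruption;
    if None, one AGG is placed after every ``agg_every`` CGG units (the
    common human pattern of AGG every 9-10 units), skipping first and last
    units so interruptions stay internally flanked by CGG.
    """

    n_units: int = 30
    agg_every: int | None = 10
    agg_units: list[int] | None = None
    flank_5_len: int = 600
    flank_3_len: int = 200
    gc_fraction: float = 0.72
    seed: int = 0

    def interruption_units(self) -> list[int]:
        if self.agg_units is not None:
            units = sorted(self.agg_units)
        elif self.agg_every:
            units = list(range(self.agg_every - 1, max(self.n_units - 1, 0), self.agg_every))
        else:
            units = []
        for u in units:
            if not (0 < u < self.n_units - 1):
                raise ValueError(f"interruption unit {u} not internal to the tract")
        for a, b in zip(units, units[1:]):
            if b == a + 1:
                raise ValueError("adjacent AGG interruptions are not allowed")
        return units


@dataclass
class AlleleTruth:
    """Planted ground truth for a synthetic allele."""

    sequence: GenomicSequence
    repeat: RepeatAnnotation
    g_clusters: list[GCluster]
    tss_positions: list[int]

    @property
    def upstream_g_clusters(self) -> list[GCluster]:
        if not self.repeat:
            return self.g_clusters
        return [g for g in self.g_clusters if g.end <= self.repeat.start]

    @property
    def downstream_g_clusters(self) -> list[GCluster]:
        if not self.repeat:
            return []
        return [g for g in self.g_clusters if g.start >= self.repeat.end]


def _random_flank(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    """GC-rich background with no G-run >= 4 and no 3+-unit CGG/AGG tract."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    s = list(rng.choice(list("ACGT"), size=length, p=p))
    for i in range(3, length):  # break accidental G-clusters
        if s[i] == "G" and s[i - 1] == "G" and s[i - 2] == "G" and s[i - 3] == "G":
            s[i] = "C" if rng.random() < 0.5 else "T"
    seq = "".join(s)
    for frame in range(3):  # break accidental repeat tracts
        run = 0
        for pos in range(frame, length - 2, 3):
            if seq[pos : pos + 3] in ("CGG", "AGG"):
                run += 1
                if run >= 3:
                    s[pos + 1] = "T"
                    seq = "".join(s)
                    run = 0
            else:
                run = 0
    return s


def _plant_gcluster(s: list[str], start: int, length: int) -> None:
    # non-G padding keeps the planted run maximal
    if start > 0:
        s[start - 1] = "A"
    for k in range(length):
        s[start + k] = "G"
    if start + length < len(s):
        s[start + length] = "A"


def make_allele(spec: AlleleSpec) -> AlleleTruth:
    """Construct an FMR1-like allele with planted, returned ground truth.

    Default layout mirrors the 5' end of the locus: three TSSs in the
    promoter-proximal flank, four G-clusters between the downstream-most
    TSS and the repeat, the (CGG)n tract, and one more G-cluster in the
    downstream flank — five planted clusters in all.
    """
    rng = np.random.default_rng(spec.seed)
    interruptions = spec.interruption_units()

    f5 = _random_flank(rng, spec.flank_5_len, spec.gc_fraction)
    f3 = _random_flank(rng, spec.flank_3_len, spec.gc_fraction)

    tss_positions = [
        int(spec.flank_5_len * f) for f in (0.15, 0.25, 0.38)
    ]
    # four upstream clusters between the last TSS and the tract
    last_tss = tss_positions[-1]
    room = spec.flank_5_len - last_tss - 40
    up_starts = [last_tss + 30 + int(room * f) for f in (0.0, 0.28, 0.55, 0.8)]
    up_lengths = [5, 4, 6, 4]
    clusters: list[GCluster] = []
    for start, length in zip(up_starts, up_lengths):
        _plant_gcluster(f5, start, length)
        clusters.append(GCluster(start=start, end=start + length))
    # junction guards: flanking partial units must not extend the tract
    f5[-1] = "T"
    f3[0] = "T"

    units = ["AGG" if u in interruptions else "CGG" for u in range(spec.n_units)]
    tract = "".join(units)
    tract_start = spec.flank_5_len
    tract_end = tract_start + 3 * spec.n_units

    down_start_rel = 20
    _plant_gcluster(f3, down_start_rel, 5)
    clusters.append(GCluster(start=tract_end + down_start_rel, end=tract_end + down_start_rel + 5))

    seq = "".join(f5) + tract + "".join(f3)
    repeat = (
        RepeatAnnotation(
            start=tract_start,
            end=tract_end,
            unit_count=spec.n_units,
            interruptions=[tract_start + 3 * u for u in interruptions],
        )
        if spec.n_units > 0
        else RepeatAnnotation()
    )
    gseq = GenomicSequence(id=f"synthetic_allele_cgg{spec.n_units}", seq=seq)
    return AlleleTruth(
        sequence=gseq, repeat=repeat, g_clusters=clusters, tss_positions=tss_positions
    )


@dataclass
class FootprintModel:
    """Generative model for non-denaturing bisulfite clones.

    ``config_probs`` gives the mixture over R-loop configurations; the
    default puts 0.35 mass on collapsed+hairpin, inside the ~25-50% of
    molecules whose repeat tract escapes conversion.  ``p_convert_ss`` and
    ``p_convert_ds`` are per-cytosine conversion probabilities in single-
    vs double-stranded DNA (placeholders — the assay's true efficiencies
    are not quantified); ``hairpin_loop_size`` is the number of exposed
    loop cytosines at the hairpin center; ``boundary_jitter`` blurs ssDNA
    boundaries, in cytosine columns; ``ss_3p_extent`` is how far (nt) the
    displaced region runs past its 3' anchor.
    """

    config_probs: dict[str, float] = field(
        default_factory=lambda: {
            "regular": 0.45,
            "collapsed": 0.15,
            "hairpin": 0.20,
            "no_rloop": 0.20,
        }
    )
    p_convert_ss: float = 0.9
    p_convert_ds: float = 0.05
    hairpin_loop_size: int = 1
    boundary_jitter: float = 1.0
    seq_error_rate: float = 0.001
    ss_3p_extent: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.config_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"config_probs sum to {total}, not 1")
        if not all(0 <= v <= 1 for v in self.config_probs.values()):
            raise ValueError("config_probs must be probabilities")
        if not (0 <= self.p_convert_ds < self.p_convert_ss <= 1):
            raise ValueError("need 0 <= p_convert_ds < p_convert_ss <= 1")


@dataclass
class CloneTruth:
    clone_id: str
    configuration: str
    ss_interval: tuple[int, int] | None  # base coordinates, half-open
    protected_interval: tuple[int, int] | None = None  # hairpin stem
    loop_positions: tuple[int, ...] = ()


def _jitter_boundary(pos: int, c_positions: np.ndarray, sd: float, rng) -> int:
    """Shift a base-coordinate boundary by ~N(0, sd) cytosine columns."""
    if sd <= 0 or len(c_positions) == 0:
        return pos
    idx = int(np.searchsorted(c_positions, pos))
    idx = int(np.clip(idx + round(rng.normal(0.0, sd)), 0, len(c_positions) - 1))
    return int(c_positions[idx])


def simulate_clones(
    allele: AlleleTruth,
    model: FootprintModel,
    n_clones: int,
    allele_label: str | None = None,
) -> tuple[list[CloneSequence], list[CloneTruth]]:
    """Draw bisulfite clones from the R-loop configuration model.

    Per clone: draw a configuration, lay out its single-stranded interval
    (and, for hairpins, the protected stem with an exposed loop centered on
    the AGG interruption), jitter the boundaries, convert each sense-strand
    cytosine with the region's probability, then apply sequencing errors.
    """
    rng = np.random.default_rng(model.seed)
    seq = allele.sequence.seq
    n = len(seq)
    c_positions = np.array([i for i, b in enumerate(seq) if b == "C"], dtype=int)
    repeat = allele.repeat
    label = allele_label if allele_label is not None else str(repeat.unit_count)

    configs = list(model.config_probs)
    probs = np.array([model.config_probs[c] for c in configs])

    up = allele.upstream_g_clusters
    down = allele.downstream_g_clusters
    if repeat and not up:
        raise ValueError("allele has no upstream G-cluster to nucleate at")

    clones: list[CloneSequence] = []
    truths: list[CloneTruth] = []
    for k in range(n_clones):
        cfg = configs[int(rng.choice(len(configs), p=probs))]
        ss: tuple[int, int] | None = None
        protected: tuple[int, int] | None = None
        loop: tuple[int, ...] = ()
        if cfg in ("regular", "hairpin"):
            start = up[0].start if repeat else (allele.g_clusters[0].start if allele.g_clusters else 0)
            end3 = (repeat.end if repeat else start) + model.ss_3p_extent
            ss = (
                _jitter_boundary(start, c_positions, model.boundary_jitter, rng),
                min(n, _jitter_boundary(end3, c_positions, model.boundary_jitter, rng) + 1),
            )
            if cfg == "hairpin" and repeat:
                protected = (repeat.start, repeat.end)
                if repeat.interruptions:
                    center = repeat.interruptions[len(repeat.interruptions) // 2]
                else:
                    center = (repeat.start + repeat.end) // 2
                in_tract = c_positions[
                    (c_positions >= repeat.start) & (c_positions < repeat.end)
                ]
                if len(in_tract) and model.hairpin_loop_size > 0:
                    order = np.argsort(np.abs(in_tract - center), kind="stable")
                    loop = tuple(int(p) for p in in_tract[order[: model.hairpin_loop_size]])
        elif cfg == "collapsed":
            anchor = down[0].start if down else (repeat.end if repeat else n)
            end3 = anchor + model.ss_3p_extent
            ss = (
                _jitter_boundary(anchor, c_positions, model.boundary_jitter, rng),
                min(n, _jitter_boundary(end3, c_positions, model.boundary_jitter, rng) + 1),
            )

        bases = list(seq)
        for pos in c_positions:
            in_ss = ss is not None and ss[0] <= pos < ss[1]
            if protected is not None and protected[0] <= pos < protected[1]:
                in_ss = int(pos) in loop
            p = model.p_convert_ss if in_ss else model.p_convert_ds
            if rng.random() < p:
                bases[pos] = "T"
        if model.seq_error_rate > 0:
            n_err = rng.binomial(n, model.seq_error_rate)
            for pos in rng.choice(n, size=n_err, replace=False):
                choices = [b for b in "ACGT" if b != bases[pos]]
                bases[pos] = choices[int(rng.integers(3))]

        cid = f"{allele.sequence.id}|clone{k:04d}"
        clones.append(CloneSequence(clone_id=cid, seq="".join(bases), allele_label=label))
        truths.append(
            CloneTruth(
                clone_id=cid,
                configuration=cfg,
                ss_interval=ss,
                protected_interval=protected,
                loop_positions=loop,
            )
        )
    return clones, truths


@dataclass
class QpcrModel:
    """Forward model for DRIP-qPCR cycle thresholds.

    ``true_percent_input`` maps each locus to the true share (%) of
    starting material recovered by the immunoprecipitation; fold enrichment
    of locus A over B is their ratio.  Cts are drawn as
    ``baseline_ct - log2(well quantity) + Normal(0, ct_noise_sd)`` with the
    dilution and volume-share fields populated so the comparative-Ct
    corrections invert the construction exactly at zero noise.
    """

    true_percent_input: dict[str, float] = field(
        default_factory=lambda: {"FMR1": 0.38, "ZNF554": 0.10}
    )
    ct_noise_sd: float = 0.0
    baseline_ct: float = 10.0
    replicate_count: int = 3
    input_dilution: float = dripq.DEFAULT_INPUT_DILUTION
    drip_assayed_fraction: float = dripq.DEFAULT_DRIP_ASSAYED_FRACTION
    input_assayed_fraction: float = dripq.DEFAULT_INPUT_ASSAYED_FRACTION
    input_share: float = dripq.DEFAULT_INPUT_SHARE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if any(v <= 0 for v in self.true_percent_input.values()):
            raise ValueError("true percent input values must be positive")


def simulate_ct_table(
    model: QpcrModel, loci: list[str] | None = None, sample_id: str = "sim"
) -> tuple[list[CtRecord], dict[str, float]]:
    """Generate one sample's Ct records plus the planted truth.

    Returns (records, truth) where truth maps locus -> true percent input.
    The total input quantity per locus is fixed at 1 (arbitrary units); the
    scale cancels in every ratio the quantification forms.
    """
    rng = np.random.default_rng(model.seed)
    loci = loci if loci is not None else list(model.true_percent_input)
    records: list[CtRecord] = []
    for locus in loci:
        pi = model.true_percent_input[locus]
        q_total = 1.0
        q_input_well = (
            q_total * model.input_share * model.input_assayed_fraction / model.input_dilution
        )
        q_drip_well = (pi / 100.0) * q_total * model.drip_assayed_fraction
        for fraction, q_well, assayed, dilution in (
            ("input", q_input_well, model.input_assayed_fraction, model.input_dilution),
            ("drip", q_drip_well, model.drip_assayed_fraction, 1.0),
        ):
            cts = [
                model.baseline_ct - np.log2(q_well) + rng.normal(0.0, model.ct_noise_sd)
                for _ in range(model.replicate_count)
            ]
            records.append(
                CtRecord(
                    sample_id=sample_id,
                    fraction=fraction,
                    locus=locus,
                    ct_replicates=[float(c) for c in cts],
                    input_dilution=dilution,
                    assayed_fraction=assayed,
                    input_share=model.input_share if fraction == "input" else 1.0,
                )
            )
    return records, dict(model.true_percent_input)
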