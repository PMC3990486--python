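"""DRIP-qPCR quantification by the comparative-Ct method.

DRIP (DNA:RNA immunoprecipitation) pulls down R-loop-containing fragments
with the S9.6 anti-hybrid antibody; enrichment at a locus is then read out
by qPCR against the reserved input material.  Assuming perfect per-cycle
doubling, a cycle threshold Ct corresponds to a relative template quantity
Q = 2**(-Ct).  Because the input is diluted before assay and only a share
of each fraction is loaded per reaction, the measured well quantities must
be scaled back to whole-fraction quantities before forming the
percent-of-input ratio:

    Q_prep  = Q_well * dilution / assayed_fraction
    %input  = 100 * Q_prep(DRIP) / (Q_prep(input) / input_share)

where ``assayed_fraction`` is well volume over the fraction's prep volume
before dilution, and ``input_share`` is the share of starting material that
was reserved as input.  Fold enrichment is the ratio of percent-of-input at
the target locus over a non-R-loop-forming reference locus (ZNF554 for
genomic DNA, the episome backbone for episomal constructs).

Defaults mirror a standard protocol: input diluted 1:100 with 5 of 10 uL
assayed-equivalent, 5 of 80 uL of undiluted DRIP output assayed, 10 of
460 uL reserved as input.  Which corrections enter a published enrichment
varies between labs, so every constant is explicit configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CtRecord",
    "EnrichmentResult",
    "WashoutSeries",
    "RnaseHSummary",
    "percent_input",
    "fold_enrichment",
    "rnaseh_sensitivity",
    "normalize_washout",
    "DEFAULT_INPUT_DILUTION",
    "DEFAULT_DRIP_ASSAYED_FRACTION",
    "DEFAULT_INPUT_ASSAYED_FRACTION",
    "DEFAULT_INPUT_SHARE",
]

DEFAULT_INPUT_DILUTION = 100.0
DEFAULT_DRIP_ASSAYED_FRACTION = 5.0 / 80.0
DEFAULT_INPUT_ASSAYED_FRACTION = 5.0 / 10.0
DEFAULT_INPUT_SHARE = 10.0 / 460.0

#: assumed amplification efficiency (perfect doubling per cycle)
EFFICIENCY = 2.0


@dataclass
class CtRecord:
    """One sample x fraction x locus row of a qPCR table."""

    sample_id: str
    fraction: str  # "input" | "drip"
    locus: str
    ct_replicates: list[float]
    input_dilution: float = 1.0
    assayed_fraction: float = 1.0
    input_share: float = 1.0

    def __post_init__(self) -> None:
        if self.fraction not in ("input", "drip"):
            raise ValueError(f"fraction must be 'input' or 'drip', got {self.fraction!r}")
        if not self.ct_replicates:
            raise ValueError("ct_replicates must be non-empty")
        if any(ct <= 0 for ct in self.ct_replicates):
            raise ValueError("all Ct values must be positive")
        if self.input_dilution < 1:
            raise ValueError("input_dilution must be >= 1")
        if not (0 < self.assayed_fraction <= 1) or not (0 < self.input_share <= 1):
            raise ValueError("assayed_fraction and input_share must be in (0, 1]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))

    def quantity(self) -> float:
        """Whole-prep relative quantity, corrected for dilution and loading."""
        q_well = EFFICIENCY ** (-self.mean_ct)
        return q_well * self.input_dilution / self.assayed_fraction


@dataclass
class EnrichmentResult:
    sample_id: str
    locus: str
    percent_input: float
    reference_locus: str | None = None
    fold_enrichment: float | None = None


@dataclass
class WashoutSeries:
    """A DRIP washout time course, normalized to recovery at the peak."""

    timepoints: list[float]
    percent_input: list[float]
    peak_timepoint: float
    normalized_recovery: list[float] = field(default_factory=list)


def percent_input(drip: CtRecord, input_rec: CtRecord) -> float:
    """Percent of input recovered in the DRIP fraction at one locus.

    Both records are corrected to whole-prep quantities; the input prep is
    further scaled by 1/input_share to the total starting material.
    """
    if drip.locus != input_rec.locus:
        raise ValueError(
            f"locus mismatch: drip={drip.locus!r} vs input={input_rec.locus!r}"
        )
    q_total_input = input_rec.quantity() / input_rec.input_share
    q_total_drip = drip.quantity()
    return 100.0 * q_total_drip / q_total_input


def fold_enrichment(target: EnrichmentResult, reference: EnrichmentResult) -> EnrichmentResult:
    """Fold enrichment of the target locus over a reference locus.

    Equivalent to 2**(-ddCt) with all dilution/loading corrections carried
    through the two percent-of-input values.  Both results must come from
    the same sample.
    """
    if target.sample_id != reference.sample_id:
        raise ValueError("target and reference must come from the same sample")
    if reference.percent_input == 0:
        raise ValueError(f"reference locus {reference.locus!r} has zero percent input")
    return EnrichmentResult(
        sample_id=target.sample_id,
        locus=target.locus,
        percent_input=target.percent_input,
        reference_locus=reference.locus,
        fold_enrichment=target.percent_input / reference.percent_input,
    )


@dataclass
class RnaseHSummary:
    mean_before: float
    sem_before: float
    mean_after: float
    sem_after: float
    t_statistic: float
    p_value: float
    degenerate: bool = False
    test: str = "pooled"


def rnaseh_sensitivity(
    before: list[float], after: list[float], welch: bool = False
) -> RnaseHSummary:
    """Compare fold enrichments before vs after RNase H treatment.

    RNase H resolves RNA:DNA hybrids, so genuine R-loop signal collapses
    after treatment.  Performs an unpaired two-sample t-test on
    natural-log-transformed enrichments (pooled variance by default,
    Welch with ``welch=True``) and reports raw-scale means with SEM.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if len(b) < 2 or len(a) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.any(b <= 0) or np.any(a <= 0):
        raise ValueError("enrichment values must be positive to log-transform")
    lb, la = np.log(b), np.log(a)
    degenerate = np.var(lb, ddof=1) == 0 and np.var(la, ddof=1) == 0
    if degenerate:
        # zero within-group variance: t undefined unless means coincide
        if math.isclose(lb.mean(), la.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if lb.mean() > la.mean() else -math.inf, 0.0
    else:
        t, p = stats.ttest_ind(lb, la, equal_var=not welch)
        t, p = float(t), float(p)
    return RnaseHSummary(
        mean_before=float(b.mean()),
        sem_before=float(stats.sem(b)),
        mean_after=float(a.mean()),
        sem_after=float(stats.sem(a)),
        t_statistic=t,
        p_value=p,
        degenerate=bool(degenerate),
        test="welch" if welch else "pooled",
    )


def normalize_washout(series: WashoutSeries) -> WashoutSeries:
    """Express a washout time course as percent of peak recovery."""
    if len(series.timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if len(series.timepoints) != len(series.percent_input):
        raise ValueError("timepoints and percent_input differ in length")
    if series.peak_timepoint not in series.timepoints:
        raise ValueError(f"peak timepoint {series.peak_timepoint} not in series")
    peak = series.percent_input[series.timepoints.index(series.peak_timepoint)]
    if peak == 0:
        raise ValueError("peak recovery is zero")
    series.normalized_recovery = [100.0 * v / peak for v in series.percent_input]
    return series
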