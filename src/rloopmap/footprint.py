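"""Single-molecule R-loop footprints from non-denaturing bisulfite mapping.

Sodium bisulfite deaminates cytosine to uracil (read as T after PCR)
efficiently only in single-stranded DNA.  Applied without denaturation, it
therefore marks the displaced strand of an R-loop: cytosines that read as T
in a sequenced clone were single-stranded, cytosines that stay C were
base-paired.  This module aligns cloned bisulfite-PCR products to the
unconverted reference, scores per-cytosine conversion, assembles
clone-by-position conversion matrices, and extracts structural features:
protected (unconverted) runs inside the repeat tract that suggest hairpin
re-pairing of the displaced CGG strand, and the initiation point of each
footprint relative to G-clusters.

Alignment is a global affine-gap dynamic program with bisulfite-asymmetric
substitution scoring: reference C against clone T is scored as a match
(conversion is signal, not error), while the reverse (reference T vs clone
C) is penalized.  Inside an annotated CGG tract, gaps are constrained to
unit-aligned 3-nt multiples so that length-polymorphic repeat alleles align
unit-wise rather than smearing gaps through the tract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqsig import GCluster, GenomicSequence, RepeatAnnotation, reverse_complement

__all__ = [
    "CloneSequence",
    "AlignParams",
    "BisulfiteAlignment",
    "ConversionCall",
    "ConversionMatrix",
    "ProtectedRun",
    "FootprintSummary",
    "in_silico_convert",
    "align_clone",
    "score_conversion",
    "build_matrix",
    "detect_protected_runs",
    "summarize_footprint",
    "classify_configuration",
    "UnalignableCloneError",
]

CONVERTED = "converted"
UNCONVERTED = "unconverted"
MISSING = "missing"

_STATE_CODE = {CONVERTED: "1", UNCONVERTED: "0", MISSING: "."}


@dataclass
class CloneSequence:
    """One sequenced bisulfite-PCR clone (sense / displaced-strand space)."""

    clone_id: str
    seq: str
    allele_label: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("empty clone sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid characters in clone {self.clone_id!r}: {sorted(bad)}")


@dataclass
class AlignParams:
    """Scoring for the bisulfite-aware global aligner.

    ``min_score_fraction`` is the acceptance floor as a fraction of the
    perfect score (match_score * reference length); clones below it are
    rejected as unalignable.  ``band_extra`` widens the DP band beyond the
    length difference between clone and reference.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    unit_gap: float = -6.0  # one 3-nt unit indel inside the repeat tract
    min_score_fraction: float = 0.5
    band_extra: int = 25


class UnalignableCloneError(ValueError):
    pass


@dataclass
class BisulfiteAlignment:
    """A clone-to-reference alignment as (reference, clone) index pairs.

    ``pairs`` lists (ref_pos, clone_pos) with ``None`` on the gapped side;
    reference and clone positions are each strictly increasing.
    ``reverse_complemented`` records orientation auto-detection.
    """

    clone_id: str
    pairs: list[tuple[int | None, int | None]]
    score: float
    repeat_unit_indels: int = 0
    reverse_complemented: bool = False
    clone_seq: str = ""  # in aligned (sense) orientation


@dataclass(frozen=True)
class ConversionCall:
    position: int  # reference coordinate of the cytosine
    state: str  # converted | unconverted | missing

    def __post_init__(self) -> None:
        if self.state not in (CONVERTED, UNCONVERTED, MISSING):
            raise ValueError(f"bad state {self.state!r}")


@dataclass
class ProtectedRun:
    """A maximal run of consecutive unconverted cytosines (dsDNA evidence)."""

    start_index: int  # half-open, in cytosine-column space
    end_index: int
    start_pos: int  # reference coordinates of first / past-last member
    end_pos: int
    length: int
    inside_repeat: bool
    symmetric_about: int | None = None  # AGG interruption coordinate


@dataclass
class FootprintSummary:
    clone_id: str
    ss_intervals: list[tuple[int, int]]  # converted runs, ref coords, half-open
    initiation_site: int | None
    assigned_gcluster: GCluster | None
    gcluster_is_downstream: bool
    fraction_converted_inside_repeat: float
    fraction_converted_outside_repeat: float


def in_silico_convert(reference: GenomicSequence) -> GenomicSequence:
    """Fully bisulfite-convert a sequence in silico (every C becomes T)."""
    return GenomicSequence(
        id=reference.id + "|converted",
        seq=reference.seq.replace("C", "T"),
        offset=reference.offset,
        strand_label=reference.strand_label,
    )


def _sub_score(r: str, c: str, p: AlignParams) -> float:
    if r == "N" or c == "N":
        return 0.0
    if r == c or (r == "C" and c == "T"):
        return p.match
    return p.mismatch


def _banded_align(
    ref: str, clone: str, tract: tuple[int, int] | None, p: AlignParams
) -> tuple[float, list[tuple[int | None, int | None]], int] | None:
    """Global banded affine DP with unit-multiple gaps inside the tract.

    Returns (score, pairs, unit_indel_count) or None when the optimum falls
    outside the band (caller widens and retries).  Transitions, in traceback
    preference order (keeps gaps leftmost and deterministic): diagonal,
    unit deletion/insertion jumps, deletion, insertion.
    """
    n, m = len(ref), len(clone)
    ts, te = tract if tract else (-1, -1)
    W = abs(m - n) + p.band_extra
    lo = min(0, m - n) - W
    hi = max(0, m - n) + W
    NEG = float("-inf")

    def in_del_tract(i: int) -> bool:
        # deleting ref[i-3:i] as one repeat unit
        return ts <= i - 3 and i <= te and (i - 3 - ts) % 3 == 0

    def in_ins_tract(i: int) -> bool:
        return ts <= i <= te

    def interior(i: int) -> bool:
        return ts < i < te

    # B: best overall; X: gap in clone (ref consumed); Y: gap in ref
    B = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    # traceback: 'd' diag, 'D'/'I' unit jumps, 'x'/'X' del open/extend,
    # 'y'/'Y' ins open/extend
    TB = [[""] * (m + 1) for _ in range(n + 1)]
    B[0][0] = 0.0
    for i in range(n + 1):
        j_lo = max(0, i + lo)
        j_hi = min(m, i + hi)
        for j in range(j_lo, j_hi + 1):
            if i == 0 and j == 0:
                continue
            best, tb = NEG, ""
            if i > 0 and j > 0 and B[i - 1][j - 1] > NEG:
                s = B[i - 1][j - 1] + _sub_score(ref[i - 1], clone[j - 1], p)
                if s > best:
                    best, tb = s, "d"
            if i >= 3 and in_del_tract(i) and B[i - 3][j] > NEG:
                s = B[i - 3][j] + p.unit_gap
                if s > best:
                    best, tb = s, "D"
            if j >= 3 and in_ins_tract(i) and B[i][j - 3] > NEG:
                s = B[i][j - 3] + p.unit_gap
                if s > best:
                    best, tb = s, "I"
            if i > 0 and not interior(i - 1) and not interior(i):
                xo = B[i - 1][j] + p.gap_open if B[i - 1][j] > NEG else NEG
                xe = X[i - 1][j] + p.gap_extend if X[i - 1][j] > NEG else NEG
                X[i][j] = max(xo, xe)
                if X[i][j] > best:
                    best, tb = X[i][j], ("x" if xo >= xe else "X")
            if j > 0 and not interior(i):
                yo = B[i][j - 1] + p.gap_open if B[i][j - 1] > NEG else NEG
                ye = Y[i][j - 1] + p.gap_extend if Y[i][j - 1] > NEG else NEG
                Y[i][j] = max(yo, ye)
                if Y[i][j] > best:
                    best, tb = Y[i][j], ("y" if yo >= ye else "Y")
            B[i][j], TB[i][j] = best, tb

    if B[n][m] == NEG:
        return None
    # traceback
    pairs: list[tuple[int | None, int | None]] = []
    unit_indels = 0
    i, j = n, m
    state = "B"
    while i > 0 or j > 0:
        tb = TB[i][j] if state == "B" else state
        if state == "B" and tb == "d":
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == "B" and tb == "D":
            pairs.extend([(i - 1, None), (i - 2, None), (i - 3, None)])
            unit_indels += 1
            i -= 3
        elif state == "B" and tb == "I":
            pairs.extend([(None, j - 1), (None, j - 2), (None, j - 3)])
            unit_indels += 1
            j -= 3
        elif tb in ("x", "X"):
            # re-derive whether this deletion column opened or extended
            xo = B[i - 1][j] + p.gap_open if B[i - 1][j] > NEG else NEG
            xe = X[i - 1][j] + p.gap_extend if X[i - 1][j] > NEG else NEG
            pairs.append((i - 1, None))
            state = "B" if xo >= xe else "x"
            i -= 1
        elif tb in ("y", "Y"):
            yo = B[i][j - 1] + p.gap_open if B[i][j - 1] > NEG else NEG
            ye = Y[i][j - 1] + p.gap_extend if Y[i][j - 1] > NEG else NEG
            pairs.append((None, j - 1))
            state = "B" if yo >= ye else "y"
            j -= 1
        else:  # pragma: no cover - band too narrow mid-matrix
            return None
        if state in ("x", "X"):
            state = "x"
        if state in ("y", "Y"):
            state = "y"
    pairs.reverse()
    return B[n][m], pairs, unit_indels


def align_clone(
    clone: CloneSequence,
    reference: GenomicSequence,
    repeat: RepeatAnnotation | None = None,
    params: AlignParams | None = None,
) -> BisulfiteAlignment:
    """Globally align a bisulfite clone to the unconverted reference.

    Orientation is auto-detected by aligning both the clone and its reverse
    complement and keeping the better score (clones are sequenced from
    either end).  Raises :class:`UnalignableCloneError` when the best score
    falls below ``min_score_fraction`` of the perfect score.
    """
    if params is None:
        params = AlignParams()
    tract = None
    if repeat and repeat.unit_count > 0:
        tract = (repeat.start - reference.offset, repeat.end - reference.offset)

    candidates = []
    for rc, seq in ((False, clone.seq), (True, reverse_complement(clone.seq))):
        res = None
        extra = params.band_extra
        while res is None and extra <= max(len(reference), len(seq)) + 1:
            local = AlignParams(**{**params.__dict__, "band_extra": extra})
            res = _banded_align(reference.seq, seq, tract, local)
            extra *= 4
        if res is not None:
            candidates.append((res[0], rc, seq, res))
    if not candidates:
        raise UnalignableCloneError(f"clone {clone.clone_id!r}: no alignment found")
    score, rc, seq, (_, pairs, unit_indels) = max(candidates, key=lambda t: t[0])
    floor = params.min_score_fraction * params.match * len(reference)
    if score < floor:
        raise UnalignableCloneError(
            f"clone {clone.clone_id!r}: score {score:.1f} below floor {floor:.1f}"
        )
    off = reference.offset
    return BisulfiteAlignment(
        clone_id=clone.clone_id,
        pairs=[(r + off if r is not None else None, c) for r, c in pairs],
        score=score,
        repeat_unit_indels=unit_indels,
        reverse_complemented=rc,
        clone_seq=seq,
    )


def score_conversion(
    aln: BisulfiteAlignment, reference: GenomicSequence
) -> list[ConversionCall]:
    """Call conversion state at every reference cytosine.

    Clone T at a reference C is ``converted`` (was ssDNA when treated),
    clone C is ``unconverted`` (dsDNA), anything else — gap, N, or another
    base — is ``missing``.
    """
    off = reference.offset
    clone_at: dict[int, str | None] = {}
    for r, c in aln.pairs:
        if r is not None:
            clone_at[r] = aln.clone_seq[c] if c is not None else None
    calls: list[ConversionCall] = []
    for i, base in enumerate(reference.seq):
        if base != "C":
            continue
        pos = i + off
        b = clone_at.get(pos)
        if b == "T":
            state = CONVERTED
        elif b == "C":
            state = UNCONVERTED
        else:
            state = MISSING
        calls.append(ConversionCall(position=pos, state=state))
    return calls


@dataclass
class ConversionMatrix:
    """Clones x cytosine-position conversion states (the footprint figure).

    ``table`` is a DataFrame indexed by clone_id with one column per
    reference C coordinate; cells hold '1' (converted), '0' (unconverted)
    or '.' (missing).  Rows are ordered by allele group then clone_id.
    """

    table: pd.DataFrame
    allele_labels: dict[str, str] = field(default_factory=dict)

    @property
    def positions(self) -> list[int]:
        return list(self.table.columns)

    def column_conversion_fraction(self) -> pd.Series:
        """Per-column converted fraction among informative (non-missing) cells."""
        conv = (self.table == "1").sum(axis=0)
        info = (self.table != ".").sum(axis=0)
        return conv / info.replace(0, np.nan)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.columns = [f"pos:{c}" for c in out.columns]
        out.insert(0, "allele", [self.allele_labels.get(i, "") for i in out.index])
        out.to_csv(path, sep="\t", index_label="clone_id")

    @classmethod
    def from_tsv(cls, path) -> "ConversionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="clone_id", dtype=str)
        labels = df.pop("allele").fillna("").to_dict()
        df.columns = [int(c.split(":", 1)[1]) for c in df.columns]
        return cls(table=df, allele_labels=labels)


def build_matrix(
    calls_by_clone: dict[str, list[ConversionCall]],
    allele_labels: dict[str, str] | None = None,
) -> ConversionMatrix:
    """Assemble per-clone calls into a rectangular conversion matrix.

    All clones must be scored against the same amplicon (identical cytosine
    coordinate sets); rows are grouped by allele label, then clone_id.
    """
    if not calls_by_clone:
        raise ValueError("no clones")
    allele_labels = allele_labels or {}
    ref_positions: tuple[int, ...] | None = None
    rows = {}
    for cid, calls in calls_by_clone.items():
        positions = tuple(c.position for c in calls)
        if ref_positions is None:
            ref_positions = positions
        elif positions != ref_positions:
            raise ValueError(f"clone {cid!r} scored against a different amplicon")
        rows[cid] = [_STATE_CODE[c.state] for c in calls]
    order = sorted(rows, key=lambda cid: (allele_labels.get(cid, ""), cid))
    table = pd.DataFrame(
        [rows[cid] for cid in order], index=pd.Index(order, name="clone_id"),
        columns=list(ref_positions),
    )
    return ConversionMatrix(table=table, allele_labels=dict(allele_labels))


def detect_protected_runs(
    calls: list[ConversionCall],
    repeat: RepeatAnnotation | None = None,
    min_run: int = 3,
) -> list[ProtectedRun]:
    """Find maximal runs of >= min_run consecutive unconverted cytosines.

    Missing calls break a run (a sequence gap is not evidence of
    protection).  Runs are annotated as inside the repeat tract when every
    member lies within it, and flagged ``symmetric_about`` an AGG
    interruption when the interruption sits within one cytosine column of
    the run midpoint — the hairpin-stem signature.
    """
    runs: list[ProtectedRun] = []
    positions = [c.position for c in calls]
    i, n = 0, len(calls)
    while i < n:
        if calls[i].state != UNCONVERTED:
            i += 1
            continue
        j = i
        while j + 1 < n and calls[j + 1].state == UNCONVERTED:
            j += 1
        if j - i + 1 >= min_run:
            inside = bool(repeat) and all(
                repeat.contains(calls[k].position) for k in range(i, j + 1)
            )
            symmetric = None
            if repeat:
                mid = (i + j) / 2.0
                for agg in repeat.interruptions:
                    col = int(np.argmin([abs(p - agg) for p in positions]))
                    if abs(col - mid) <= 1.0:
                        symmetric = agg
                        break
            runs.append(
                ProtectedRun(
                    start_index=i,
                    end_index=j + 1,
                    start_pos=calls[i].position,
                    end_pos=calls[j].position + 1,
                    length=j - i + 1,
                    inside_repeat=inside,
                    symmetric_about=symmetric,
                )
            )
        i = j + 1
    return runs


def _region_fraction(calls: list[ConversionCall], member) -> float:
    conv = sum(1 for c in calls if member(c.position) and c.state == CONVERTED)
    info = sum(1 for c in calls if member(c.position) and c.state != MISSING)
    return conv / info if info else 0.0


def summarize_footprint(
    calls: list[ConversionCall],
    gclusters: list[GCluster],
    repeat: RepeatAnnotation | None = None,
    min_ss_run: int = 3,
    gcluster_tolerance: int = 12,
) -> FootprintSummary:
    """Summarize one clone's footprint: ssDNA extent and initiation point.

    ``ss_intervals`` lists every maximal run of converted cytosines.  The
    initiation site is the start of the first run of at least
    ``min_ss_run`` converted cytosines — sporadic conversion of dsDNA
    produces isolated converted positions that would otherwise masquerade
    as the footprint's 5' end.  Initiation is assigned to the nearest
    G-cluster starting at or upstream of it (within ``gcluster_tolerance``
    nt downstream, to absorb boundary scatter), which is where the RNA:DNA
    hybrid presumably nucleated; when only more-downstream clusters exist
    the nearest one is assigned and flagged.
    """
    clone_id = ""
    ss_intervals: list[tuple[int, int]] = []
    run_columns: list[int] = []
    i, n = 0, len(calls)
    while i < n:
        if calls[i].state != CONVERTED:
            i += 1
            continue
        j = i
        while j + 1 < n and calls[j + 1].state == CONVERTED:
            j += 1
        ss_intervals.append((calls[i].position, calls[j].position + 1))
        run_columns.append(j - i + 1)
        i = j + 1

    qualifying = [iv for iv, w in zip(ss_intervals, run_columns) if w >= min_ss_run]
    initiation = qualifying[0][0] if qualifying else None
    assigned, downstream = None, False
    if initiation is not None and gclusters:
        upstream = [g for g in gclusters if g.start <= initiation + gcluster_tolerance]
        if upstream:
            assigned = max(upstream, key=lambda g: g.start)
        else:
            assigned = min(gclusters, key=lambda g: g.start)
            downstream = True

    inside = (lambda p: repeat.contains(p)) if repeat else (lambda p: False)
    outside = lambda p: not inside(p)
    return FootprintSummary(
        clone_id=clone_id,
        ss_intervals=ss_intervals,
        initiation_site=initiation,
        assigned_gcluster=assigned,
        gcluster_is_downstream=downstream,
        fraction_converted_inside_repeat=_region_fraction(calls, inside) if repeat else 0.0,
        fraction_converted_outside_repeat=_region_fraction(calls, outside),
    )


def classify_configuration(
    calls: list[ConversionCall],
    repeat: RepeatAnnotation,
    ss_threshold: float = 0.5,
    flank_window: int = 150,
) -> str:
    """Classify a clone as regular / collapsed / hairpin / no_rloop.

    Uses converted fractions in three regions — the ``flank_window`` nt
    immediately upstream of the tract, the tract itself, and the
    ``flank_window`` nt immediately downstream — calling a region
    single-stranded when its fraction reaches ``ss_threshold``: a
    single-stranded tract is a regular R-loop; a protected tract flanked by
    ssDNA on both sides is the hairpin signature; ssDNA only downstream of
    the tract is the collapsed configuration; none single-stranded means no
    R-loop.  Restricting to tract-proximal windows keeps distal,
    never-displaced sequence from diluting the signal.
    """
    if not repeat:
        raise ValueError("classification requires a repeat annotation")
    up = _region_fraction(calls, lambda p: repeat.start - flank_window <= p < repeat.start)
    mid = _region_fraction(calls, repeat.contains)
    down = _region_fraction(calls, lambda p: repeat.end <= p < repeat.end + flank_window)
    if mid >= ss_threshold:
        return "regular"
    if up >= ss_threshold and down >= ss_threshold:
        return "hairpin"
    if down >= ss_threshold:
        return "collapsed"
    return "no_rloop"
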