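"""Sequence signatures predictive of R-loop formation.

R-loops form co-transcriptionally when the nascent RNA re-anneals with the
template DNA strand, displacing the non-template strand as single-stranded
DNA.  Their formation is favoured on the strand carrying excess guanine:
a G-rich non-template strand yields a thermodynamically stable RNA:DNA
hybrid, and runs of consecutive guanines (G-clusters) act as nucleation
points for the hybrid.  This module computes the classic sequence-level
predictors over a sliding window — GC content, GC skew (G-C)/(G+C) and the
CpG observed/expected ratio — calls CpG islands from those profiles, finds
G-clusters, and annotates CGG trinucleotide-repeat tracts with their AGG
interruptions.

All coordinates are 0-based, half-open, on the stored (sense, CGG-bearing)
strand; positive GC skew therefore marks the R-loop-favouring orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicSequence",
    "WindowProfile",
    "CgiParams",
    "CpGIslandCall",
    "GCluster",
    "RepeatAnnotation",
    "sliding_window_metrics",
    "call_cgi",
    "find_g_clusters",
    "annotate_cgg_repeat",
    "reverse_complement",
]

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomicSequence:
    """An uppercase IUPAC nucleotide sequence with a coordinate origin.

    ``offset`` shifts all reported coordinates (e.g. to anchor a profile at
    a transcription start site); ``strand_label`` records whether the stored
    strand is the mRNA-synonymous (CGG-bearing) sense strand.
    """

    id: str
    seq: str
    offset: int = 0
    strand_label: str = "sense"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"invalid characters in sequence {self.id!r}: {sorted(bad)}")
        if self.strand_label not in ("sense", "antisense"):
            raise ValueError("strand_label must be 'sense' or 'antisense'")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class WindowProfile:
    """Per-window GC%, GC skew and CpG O/E along a sequence.

    Undefined windows (no G+C for skew, no C or no G for CpG O/E, or any N
    in the window) hold NaN, never 0.
    """

    window_size: int
    step: int
    centers: np.ndarray
    starts: np.ndarray
    gc_pct: np.ndarray
    gc_skew: np.ndarray
    cpg_oe: np.ndarray
    seq_id: str = ""

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class CgiParams:
    """CpG-island thresholds: O/E > 0.6 and GC% > 50 over >= 200 nt."""

    min_cpg_oe: float = 0.6
    min_gc_pct: float = 50.0
    min_len: int = 200

    def __post_init__(self) -> None:
        if self.min_cpg_oe <= 0 or self.min_gc_pct <= 0 or self.min_len <= 0:
            raise ValueError("CGI parameters must be positive")


@dataclass
class CpGIslandCall:
    start: int
    end: int
    mean_gc_pct: float
    mean_cpg_oe: float


@dataclass
class GCluster:
    """A maximal run of >= min_run consecutive guanines."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatAnnotation:
    """A CGG-repeat tract: coordinates, unit count, AGG interruptions.

    ``interruptions`` holds the start coordinates of AGG units inside the
    tract; each is unit-aligned ((pos - start) % 3 == 0).  An empty
    annotation has unit_count 0.
    """

    start: int = 0
    end: int = 0
    unit_count: int = 0
    interruptions: list[int] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.unit_count > 0

    def contains(self, pos: int) -> bool:
        return self.unit_count > 0 and self.start <= pos < self.end


def sliding_window_metrics(
    seq: GenomicSequence,
    window_size: int = 100,
    step: int = 1,
    cpg_oe_form: str = "gardiner-garden",
) -> WindowProfile:
    """Compute GC%, GC skew and CpG O/E over a sliding window.

    Per window of length L: GC% = 100*(G+C)/L; skew = (G-C)/(G+C); CpG O/E
    uses the Gardiner-Garden & Frommer form (CpG * L)/(C * G) by default,
    or ``cpg_oe_form='length-corrected'`` for (CpG * L**2)/(C * G * (L-1)).
    CpG dinucleotides are counted within the window only.  Windows
    containing N are undefined (NaN in all three metrics).

    Coordinates in the returned profile include ``seq.offset``.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if len(seq) < window_size:
        raise ValueError(
            f"sequence length {len(seq)} shorter than window {window_size}"
        )
    if cpg_oe_form not in ("gardiner-garden", "length-corrected"):
        raise ValueError(f"unknown cpg_oe_form {cpg_oe_form!r}")

    s = np.frombuffer(seq.seq.encode(), dtype=np.uint8)
    is_g = (s == ord("G")).astype(np.int64)
    is_c = (s == ord("C")).astype(np.int64)
    is_n = (s == ord("N")).astype(np.int64)
    # CpG at i means C at i and G at i+1; a window [w, w+L) counts CpGs with
    # C position in [w, w+L-1).
    is_cpg = np.zeros(len(s), dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def winsum(arr: np.ndarray, length: int) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(arr)])
        return c[length:] - c[:-length]

    n_windows = (len(s) - window_size) // step + 1
    idx = np.arange(n_windows) * step
    g = winsum(is_g, window_size)[idx]
    c = winsum(is_c, window_size)[idx]
    n = winsum(is_n, window_size)[idx]
    # a window's CpG count looks at pairs starting within its first L-1 bases
    cpg = winsum(is_cpg, window_size - 1)[idx] if window_size > 1 else np.zeros(n_windows, dtype=np.int64)

    gc_pct = 100.0 * (g + c) / window_size
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_skew = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), np.nan)
        if cpg_oe_form == "gardiner-garden":
            oe = cpg * window_size / np.maximum(c * g, 1)
        else:
            oe = cpg * window_size**2 / np.maximum(c * g * (window_size - 1), 1)
        cpg_oe = np.where(c * g > 0, oe, np.nan)
    undef = n > 0
    gc_pct = np.where(undef, np.nan, gc_pct)
    gc_skew = np.where(undef, np.nan, gc_skew)
    cpg_oe = np.where(undef, np.nan, cpg_oe)

    starts = idx + seq.offset
    centers = starts + window_size / 2.0
    return WindowProfile(
        window_size=window_size,
        step=step,
        centers=centers,
        starts=starts.astype(np.int64),
        gc_pct=gc_pct,
        gc_skew=gc_skew,
        cpg_oe=cpg_oe,
        seq_id=seq.id,
    )


def call_cgi(profile: WindowProfile, params: CgiParams | None = None) -> list[CpGIslandCall]:
    """Call CpG islands from a window profile.

    Finds maximal runs of consecutive windows with CpG O/E > min_cpg_oe and
    GC% > min_gc_pct (undefined windows break a run), merges each run into
    the base-space union of its windows' spans, and keeps spans of at least
    ``min_len`` nt.  Returned islands are sorted and non-overlapping.
    """
    if params is None:
        params = CgiParams()
    if len(profile) == 0:
        raise ValueError("empty profile")
    ok = (
        ~np.isnan(profile.cpg_oe)
        & ~np.isnan(profile.gc_pct)
        & (profile.cpg_oe > params.min_cpg_oe)
        & (profile.gc_pct > params.min_gc_pct)
    )
    islands: list[CpGIslandCall] = []
    i = 0
    n = len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        start = int(profile.starts[i])
        end = int(profile.starts[j]) + profile.window_size
        if end - start >= params.min_len:
            islands.append(
                CpGIslandCall(
                    start=start,
                    end=end,
                    mean_gc_pct=float(np.mean(profile.gc_pct[i : j + 1])),
                    mean_cpg_oe=float(np.mean(profile.cpg_oe[i : j + 1])),
                )
            )
        i = j + 1
    return islands


def find_g_clusters(seq: GenomicSequence, min_run: int = 4) -> list[GCluster]:
    """Find maximal runs of >= min_run consecutive G on the stored strand."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out: list[GCluster] = []
    i = 0
    s = seq.seq
    n = len(s)
    while i < n:
        if s[i] != "G":
            i += 1
            continue
        j = i
        while j < n and s[j] == "G":
            j += 1
        if j - i >= min_run:
            out.append(GCluster(start=i + seq.offset, end=j + seq.offset))
        i = j
    return out


def annotate_cgg_repeat(seq: GenomicSequence, min_units: int = 5) -> RepeatAnnotation:
    """Locate the longest CGG tract, permitting internal AGG interruptions.

    Scans every codon frame for runs of CGG units in which AGG units are
    tolerated provided each is flanked by CGG units (the tract never starts
    or ends on an AGG, and two AGGs are never adjacent).  Returns the
    longest such tract if it reaches ``min_units`` units, else an empty
    annotation.  Coordinates include ``seq.offset``.
    """
    s = seq.seq
    n = len(s)
    best = RepeatAnnotation()
    for frame in range(3):
        units = [(p, s[p : p + 3]) for p in range(frame, n - 2, 3)]
        i = 0
        m = len(units)
        while i < m:
            if units[i][1] != "CGG":
                i += 1
                continue
            # extend a run of CGG/AGG; AGG must be followed by CGG
            j = i
            interruptions: list[int] = []
            while j + 1 < m:
                nxt = units[j + 1][1]
                if nxt == "CGG":
                    j += 1
                elif nxt == "AGG" and j + 2 < m and units[j + 2][1] == "CGG":
                    interruptions.append(units[j + 1][0])
                    j += 2
                else:
                    break
            count = j - i + 1
            if count > best.unit_count:
                best = RepeatAnnotation(
                    start=units[i][0] + seq.offset,
                    end=units[j][0] + 3 + seq.offset,
                    unit_count=count,
                    interruptions=[p + seq.offset for p in interruptions],
                )
            i = j + 1
    if best.unit_count < min_units:
        return RepeatAnnotation()
    return best
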