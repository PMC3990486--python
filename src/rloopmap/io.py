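"""Readers and writers for the formats the pipeline exchanges.

FASTA goes through Biopython; tabular outputs are TSV via pandas; interval
features are written as BED6 / bedGraph.  All coordinates in files follow
the BED convention (0-based, half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dripq import CtRecord, EnrichmentResult, WashoutSeries
from .footprint import CloneSequence
from .seqsig import CpGIslandCall, GCluster, GenomicSequence, RepeatAnnotation, WindowProfile

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_clone_fasta",
    "write_clone_fasta",
    "read_ct_table",
    "write_ct_table",
    "profile_to_frame",
    "write_profile_tsv",
    "write_bedgraph",
    "write_bed",
    "islands_to_bed_rows",
    "gclusters_to_bed_rows",
    "repeat_to_bed_rows",
    "write_enrichment_tsv",
    "write_washout_tsv",
]


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    records = [
        GenomicSequence(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: list[GenomicSequence], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs],
        str(path),
        "fasta",
    )


def read_clone_fasta(path: str | Path) -> list[CloneSequence]:
    """Read bisulfite clones; an ``allele=X`` token in the description is
    picked up as the allele label."""
    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = ""
        for token in rec.description.split():
            if token.startswith("allele="):
                label = token.split("=", 1)[1]
        clones.append(CloneSequence(clone_id=rec.id, seq=str(rec.seq).upper(), allele_label=label))
    if not clones:
        raise ValueError(f"no clone records in {path}")
    return clones


def write_clone_fasta(clones: list[CloneSequence], path: str | Path) -> None:
    SeqIO.write(
        [
            SeqRecord(Seq(c.seq), id=c.clone_id, description=f"allele={c.allele_label}")
            for c in clones
        ],
        str(path),
        "fasta",
    )


def write_ct_table(records: list[CtRecord], path: str | Path) -> None:
    k = max(len(r.ct_replicates) for r in records)
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "fraction": r.fraction,
            "locus": r.locus,
            "dilution": r.input_dilution,
            "assayed_fraction": r.assayed_fraction,
            "input_share": r.input_share,
        }
        for i in range(k):
            row[f"ct_{i + 1}"] = r.ct_replicates[i] if i < len(r.ct_replicates) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_table(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path)
    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    if not ct_cols:
        raise ValueError(f"no ct_* columns in {path}")
    records = []
    for _, row in df.iterrows():
        cts = [float(row[c]) for c in ct_cols if pd.notna(row[c])]
        records.append(
            CtRecord(
                sample_id=str(row["sample_id"]),
                fraction=str(row["fraction"]),
                locus=str(row["locus"]),
                ct_replicates=cts,
                input_dilution=float(row.get("dilution", 1.0)),
                assayed_fraction=float(row.get("assayed_fraction", 1.0)),
                input_share=float(row.get("input_share", 1.0)),
            )
        )
    return records


def profile_to_frame(profile: WindowProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": profile.seq_id,
            "start": profile.starts,
            "end": profile.starts + profile.window_size,
            "gc_pct": profile.gc_pct,
            "gc_skew": profile.gc_skew,
            "cpg_oe": profile.cpg_oe,
        }
    )


def write_profile_tsv(profile: WindowProfile, path: str | Path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(profile: WindowProfile, metric: str, path: str | Path) -> None:
    """One bedGraph track of a window metric, window span as the interval."""
    values = getattr(profile, metric)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{metric}"\n')
        for start, v in zip(profile.starts, values):
            if np.isnan(v):
                continue
            fh.write(f"{profile.seq_id}\t{start}\t{start + profile.window_size}\t{v:.6g}\n")


def write_bed(rows: list[tuple], path: str | Path) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def islands_to_bed_rows(
    islands: list[CpGIslandCall], seq: GenomicSequence
) -> list[tuple]:
    strand = "+" if seq.strand_label == "sense" else "-"
    return [
        (seq.id, isl.start, isl.end, f"CGI_{i + 1}", f"{isl.mean_cpg_oe:.3f}", strand)
        for i, isl in enumerate(islands)
    ]


def gclusters_to_bed_rows(clusters: list[GCluster], seq: GenomicSequence) -> list[tuple]:
    strand = "+" if seq.strand_label == "sense" else "-"
    return [
        (seq.id, g.start, g.end, f"Gcluster_{i + 1}", g.length, strand)
        for i, g in enumerate(clusters)
    ]


def repeat_to_bed_rows(repeat: RepeatAnnotation, seq: GenomicSequence) -> list[tuple]:
    if not repeat:
        return []
    strand = "+" if seq.strand_label == "sense" else "-"
    rows = [
        (seq.id, repeat.start, repeat.end, f"CGG_x{repeat.unit_count}", repeat.unit_count, strand)
    ]
    rows += [
        (seq.id, pos, pos + 3, "AGG_interruption", 0, strand)
        for pos in repeat.interruptions
    ]
    return rows


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "locus": r.locus,
                "percent_input": r.percent_input,
                "reference_locus": r.reference_locus or "",
                "fold_enrichment": r.fold_enrichment if r.fold_enrichment is not None else np.nan,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_washout_tsv(series: WashoutSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "timepoint_h": series.timepoints,
            "percent_input": series.percent_input,
            "normalized_recovery": series.normalized_recovery,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
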