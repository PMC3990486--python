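"""End-to-end orchestration and group-level statistics.

``run_pipeline`` chains the stages (simulate -> sequence signatures ->
DRIP-qPCR quantification -> bisulfite footprints -> group statistics) on
either synthetic or user-supplied inputs and writes every stage's artifacts
plus a machine-readable JSON summary.  ``compare_groups`` performs the
between-group enrichment comparison: experiments are first aggregated to
per-subject means (repeated measurements on a subject are correlated and
must not be treated as independent), then the groups are compared with an
unpaired t-test on log-transformed subject means together with an exact or
Monte-Carlo permutation test over subject-to-group assignments.  This is a
deliberately simple surrogate for a mixed-effects model and is labeled as
such in its output.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__, dripq, footprint, io, seqsig, simgen

__all__ = ["RunConfig", "GroupComparison", "StageError", "run_pipeline", "compare_groups"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


_KNOWN_KEYS = {
    "stages",
    "seed",
    "out_dir",
    "allele",
    "footprint_model",
    "qpcr_model",
    "n_clones",
    "window_size",
    "step",
    "cgi",
    "gcluster_min_run",
    "repeat_min_units",
    "min_protected_run",
    "reference_locus",
    "clones_fasta",
    "reference_fasta",
    "ct_table",
    "group_table",
}

_ALL_STAGES = ("simgen", "seqsig", "dripq", "footprint", "stats")


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    seed: int = 0
    out_dir: str = "rloopmap_out"
    allele: dict = field(default_factory=dict)
    footprint_model: dict = field(default_factory=dict)
    qpcr_model: dict = field(default_factory=dict)
    n_clones: int = 50
    window_size: int = 100
    step: int = 1
    cgi: dict = field(default_factory=dict)
    gcluster_min_run: int = 4
    repeat_min_units: int = 5
    min_protected_run: int = 3
    reference_locus: str = "ZNF554"
    clones_fasta: str | None = None
    reference_fasta: str | None = None
    ct_table: str | None = None
    group_table: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in _ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land is not part of what they are
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class GroupComparison:
    """Between-group enrichment comparison on subject means."""

    group_labels: tuple[str, str]
    subject_means: dict[str, dict[str, float]]  # group -> subject -> mean
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ranges: tuple[tuple[float, float], tuple[float, float]]
    t_statistic: float
    t_p_value: float
    permutation_p_value: float
    n_permutations: int
    permutation_exact: bool
    method: str = "subject-mean log-scale t-test + permutation (mixed-model surrogate)"


def compare_groups(
    experiments: pd.DataFrame,
    value_col: str = "fold_enrichment",
    subject_col: str = "subject",
    group_col: str = "group",
    max_exact: int = 20000,
    n_montecarlo: int = 10000,
    seed: int = 0,
) -> GroupComparison:
    """Compare enrichment between two groups of subjects.

    ``experiments`` has one row per experiment with subject, group and a
    positive enrichment value.  Per-subject aggregation precedes the
    between-group test; the permutation test reassigns whole subjects to
    groups (exact enumeration when the number of assignments is at most
    ``max_exact``, Monte-Carlo otherwise) using the difference of group
    means of log subject means as the statistic.
    """
    df = experiments[[subject_col, group_col, value_col]].copy()
    if (df[value_col] <= 0).any():
        raise ValueError("enrichment values must be positive")
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    subj = df.groupby([group_col, subject_col])[value_col].mean()
    per_group = {g: subj[g] for g in groups}
    for g in groups:
        if len(per_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    means, sds, ranges, logs = [], [], [], []
    for g in groups:
        v = per_group[g].to_numpy(dtype=float)
        means.append(float(v.mean()))
        sds.append(float(v.std(ddof=1)))
        ranges.append((float(v.min()), float(v.max())))
        logs.append(np.log(v))

    la, lb = logs
    if np.var(la, ddof=1) == 0 and np.var(lb, ddof=1) == 0:
        t, t_p = (0.0, 1.0) if math.isclose(la.mean(), lb.mean()) else (math.inf, 0.0)
    else:
        t, t_p = stats.ttest_ind(la, lb, equal_var=True)
        t, t_p = float(t), float(t_p)

    pooled = np.concatenate([la, lb])
    n_a = len(la)
    observed = abs(la.mean() - lb.mean())
    n_total = len(pooled)
    n_comb = math.comb(n_total, n_a)
    eps = 1e-12
    if n_comb <= max_exact:
        count = 0
        for idx in itertools.combinations(range(n_total), n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            if stat >= observed - eps:
                count += 1
        perm_p = count / n_comb
        n_perm, exact = n_comb, True
    else:
        rng = np.random.default_rng(seed)
        count = 1  # identity assignment
        for _ in range(n_montecarlo):
            perm = rng.permutation(n_total)
            stat = abs(pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean())
            if stat >= observed - eps:
                count += 1
        perm_p = count / (n_montecarlo + 1)
        n_perm, exact = n_montecarlo, False

    return GroupComparison(
        group_labels=(groups[0], groups[1]),
        subject_means={g: per_group[g].to_dict() for g in groups},
        group_means=(means[0], means[1]),
        group_sds=(sds[0], sds[1]),
        group_ranges=(ranges[0], ranges[1]),
        t_statistic=t,
        t_p_value=t_p,
        permutation_p_value=perm_p,
        n_permutations=n_perm,
        permutation_exact=exact,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write a reproducible report bundle.

    Returns the summary dict (also written as ``summary.json``).  Stage
    timings and versions go to ``run.log``; the JSON contains only
    seed-deterministic content so identical configs give byte-identical
    summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    log_lines = [f"rloopmap {__version__} seed={config.seed} hash={config.config_hash()}"]
    state: dict = {}

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            stage_summary = _STAGE_FNS[stage](config, state, out)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED at {stage}: {exc}\n")
            raise StageError(stage, exc) from exc
        summary["stages"][stage] = stage_summary
        log_lines.append(f"{stage}: {time.perf_counter() - t0:.2f}s")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _stage_simgen(config: RunConfig, state: dict, out: Path) -> dict:
    spec = simgen.AlleleSpec(**{"seed": config.seed, **config.allele})
    allele = simgen.make_allele(spec)
    model = simgen.FootprintModel(**{"seed": config.seed, **config.footprint_model})
    clones, clone_truth = simgen.simulate_clones(allele, model, config.n_clones)
    qmodel = simgen.QpcrModel(**{"seed": config.seed, **config.qpcr_model})
    records, ct_truth = simgen.simulate_ct_table(qmodel)

    io.write_fasta([allele.sequence], out / "allele.fa")
    io.write_clone_fasta(clones, out / "clones.fa")
    io.write_ct_table(records, out / "ct_table.csv")
    truth = {
        "repeat": {
            "start": allele.repeat.start,
            "end": allele.repeat.end,
            "unit_count": allele.repeat.unit_count,
            "interruptions": allele.repeat.interruptions,
        },
        "g_clusters": [[g.start, g.end] for g in allele.g_clusters],
        "tss_positions": allele.tss_positions,
        "clone_configurations": {t.clone_id: t.configuration for t in clone_truth},
        "true_percent_input": ct_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    state.update(allele=allele, clones=clones, clone_truth=clone_truth,
                 ct_records=records, ct_truth=ct_truth)
    return {
        "n_clones": len(clones),
        "allele_units": allele.repeat.unit_count,
        "files": ["allele.fa", "clones.fa", "ct_table.csv", "truth.json"],
    }


def _load_reference(config: RunConfig, state: dict) -> seqsig.GenomicSequence:
    if "allele" in state:
        return state["allele"].sequence
    if config.reference_fasta:
        return io.read_fasta(config.reference_fasta)[0]
    raise ValueError("no reference sequence: enable simgen or set reference_fasta")


def _stage_seqsig(config: RunConfig, state: dict, out: Path) -> dict:
    ref = _load_reference(config, state)
    profile = seqsig.sliding_window_metrics(ref, config.window_size, config.step)
    islands = seqsig.call_cgi(profile, seqsig.CgiParams(**config.cgi))
    clusters = seqsig.find_g_clusters(ref, config.gcluster_min_run)
    repeat = seqsig.annotate_cgg_repeat(ref, config.repeat_min_units)

    io.write_profile_tsv(profile, out / "profile.tsv")
    for metric in ("gc_pct", "gc_skew", "cpg_oe"):
        io.write_bedgraph(profile, metric, out / f"{metric}.bedgraph")
    io.write_bed(io.islands_to_bed_rows(islands, ref), out / "cgi.bed")
    io.write_bed(io.gclusters_to_bed_rows(clusters, ref), out / "gclusters.bed")
    io.write_bed(io.repeat_to_bed_rows(repeat, ref), out / "repeat.bed")

    state.update(reference=ref, profile=profile, islands=islands,
                 gclusters=clusters, repeat=repeat)
    peak_gc = float(np.nanmax(profile.gc_pct)) if len(profile) else float("nan")
    return {
        "n_windows": len(profile),
        "peak_gc_pct": peak_gc,
        "n_islands": len(islands),
        "n_g_clusters": len(clusters),
        "repeat_units": repeat.unit_count,
    }


def _stage_dripq(config: RunConfig, state: dict, out: Path) -> dict:
    records = state.get("ct_records")
    if records is None:
        if not config.ct_table:
            raise ValueError("no Ct table: enable simgen or set ct_table")
        records = io.read_ct_table(config.ct_table)

    by_key = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.locus), {})[r.fraction] = r
    results = []
    for (sample, locus), pair in sorted(by_key.items()):
        if "drip" not in pair or "input" not in pair:
            continue
        pi = dripq.percent_input(pair["drip"], pair["input"])
        results.append(dripq.EnrichmentResult(sample_id=sample, locus=locus, percent_input=pi))

    enriched = []
    for sample in sorted({r.sample_id for r in results}):
        sample_results = [r for r in results if r.sample_id == sample]
        ref = next((r for r in sample_results if r.locus == config.reference_locus), None)
        for r in sample_results:
            if ref is not None and r.locus != config.reference_locus:
                enriched.append(dripq.fold_enrichment(r, ref))
            else:
                enriched.append(r)
    io.write_enrichment_tsv(enriched, out / "enrichment.tsv")
    state["enrichments"] = enriched
    folds = {
        r.locus: r.fold_enrichment for r in enriched if r.fold_enrichment is not None
    }
    return {"n_results": len(enriched), "fold_enrichment": folds}


def _stage_footprint(config: RunConfig, state: dict, out: Path) -> dict:
    clones = state.get("clones")
    if clones is None:
        if not config.clones_fasta:
            raise ValueError("no clones: enable simgen or set clones_fasta")
        clones = io.read_clone_fasta(config.clones_fasta)
    ref = state.get("reference") or _load_reference(config, state)
    repeat = state.get("repeat") or seqsig.annotate_cgg_repeat(ref, config.repeat_min_units)
    clusters = state.get("gclusters") or seqsig.find_g_clusters(ref, config.gcluster_min_run)

    calls_by_clone: dict[str, list[footprint.ConversionCall]] = {}
    labels: dict[str, str] = {}
    run_rows, summ_rows = [], []
    n_rejected = 0
    config_counts: dict[str, int] = {}
    for clone in clones:
        try:
            aln = footprint.align_clone(clone, ref, repeat)
        except footprint.UnalignableCloneError:
            n_rejected += 1
            continue
        calls = footprint.score_conversion(aln, ref)
        calls_by_clone[clone.clone_id] = calls
        labels[clone.clone_id] = clone.allele_label
        for run in footprint.detect_protected_runs(calls, repeat, config.min_protected_run):
            run_rows.append(
                (ref.id, run.start_pos, run.end_pos,
                 f"{clone.clone_id}|protected", run.length,
                 "+" if ref.strand_label == "sense" else "-")
            )
        s = footprint.summarize_footprint(calls, clusters, repeat)
        cfg_label = footprint.classify_configuration(calls, repeat) if repeat else "n/a"
        config_counts[cfg_label] = config_counts.get(cfg_label, 0) + 1
        summ_rows.append(
            {
                "clone_id": clone.clone_id,
                "initiation_site": s.initiation_site if s.initiation_site is not None else "",
                "assigned_gcluster_start": s.assigned_gcluster.start if s.assigned_gcluster else "",
                "gcluster_is_downstream": s.gcluster_is_downstream,
                "frac_conv_inside_repeat": s.fraction_converted_inside_repeat,
                "frac_conv_outside_repeat": s.fraction_converted_outside_repeat,
                "configuration": cfg_label,
            }
        )
    if not calls_by_clone:
        raise ValueError("no clone aligned above the score floor")
    matrix = footprint.build_matrix(calls_by_clone, labels)
    matrix.to_tsv(out / "conversion_matrix.tsv")
    io.write_bed(run_rows, out / "protected_runs.bed")
    pd.DataFrame(summ_rows).to_csv(out / "footprint_summary.tsv", sep="\t", index=False)
    state["matrix"] = matrix
    state["footprint_configs"] = config_counts
    return {
        "n_clones_aligned": len(calls_by_clone),
        "n_clones_rejected": n_rejected,
        "configuration_counts": dict(sorted(config_counts.items())),
    }


def _stage_stats(config: RunConfig, state: dict, out: Path) -> dict:
    if config.group_table:
        df = pd.read_csv(config.group_table)
        cmp = compare_groups(df, seed=config.seed)
        result = {
            "groups": list(cmp.group_labels),
            "group_means": list(cmp.group_means),
            "group_sds": list(cmp.group_sds),
            "group_ranges": [list(r) for r in cmp.group_ranges],
            "t_statistic": cmp.t_statistic,
            "t_p_value": cmp.t_p_value,
            "permutation_p_value": cmp.permutation_p_value,
            "method": cmp.method,
        }
        with open(out / "group_comparison.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return result
    # without a subject table, report recovered vs true simulation values
    report: dict = {}
    if "ct_truth" in state and "enrichments" in state:
        truth = state["ct_truth"]
        ref_locus = config.reference_locus
        if ref_locus in truth:
            report["true_fold_enrichment"] = {
                locus: pi / truth[ref_locus] for locus, pi in truth.items() if locus != ref_locus
            }
        report["estimated_fold_enrichment"] = {
            r.locus: r.fold_enrichment
            for r in state["enrichments"]
            if r.fold_enrichment is not None
        }
    if "clone_truth" in state and "footprint_configs" in state:
        true_counts: dict[str, int] = {}
        for t in state["clone_truth"]:
            true_counts[t.configuration] = true_counts.get(t.configuration, 0) + 1
        report["true_configuration_counts"] = dict(sorted(true_counts.items()))
        report["estimated_configuration_counts"] = dict(sorted(state["footprint_configs"].items()))
    return report


_STAGE_FNS = {
    "simgen": _stage_simgen,
    "seqsig": _stage_seqsig,
    "dripq": _stage_dripq,
    "footprint": _stage_footprint,
    "stats": _stage_stats,
}
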