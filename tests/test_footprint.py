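"""Bisulfite alignment, conversion scoring, matrices and footprint features."""

import sys
from functools import lru_cache

import numpy as np
import pytest

from rloopmap import footprint, simgen
from rloopmap.footprint import (
    AlignParams,
    BisulfiteAlignment,
    CloneSequence,
    ConversionCall,
    UnalignableCloneError,
    align_clone,
    build_matrix,
    classify_configuration,
    detect_protected_runs,
    in_silico_convert,
    score_conversion,
    summarize_footprint,
)
from rloopmap.seqsig import GenomicSequence, RepeatAnnotation, reverse_complement


def oracle_best_score(ref, clone, tract, p=None):
    """Exhaustive recursive DP over (i, j, state): independent of the
    banded iterative implementation.  Score only; <= ~60 nt inputs."""
    if p is None:
        p = AlignParams()
    ts, te = tract if tract else (-1, -1)
    NEG = float("-inf")
    sys.setrecursionlimit(100000)

    def sub(r, c):
        if r == "N" or c == "N":
            return 0.0
        return p.match if (r == c or (r == "C" and c == "T")) else p.mismatch

    def interior(i):
        return ts < i < te

    @lru_cache(maxsize=None)
    def X(i, j):  # gap in clone, ref[i-1] deleted
        if i < 1 or interior(i - 1) or interior(i):
            return NEG
        return max(B(i - 1, j) + p.gap_open, X(i - 1, j) + p.gap_extend)

    @lru_cache(maxsize=None)
    def Y(i, j):  # gap in ref, clone[j-1] inserted
        if j < 1 or interior(i):
            return NEG
        return max(B(i, j - 1) + p.gap_open, Y(i, j - 1) + p.gap_extend)

    @lru_cache(maxsize=None)
    def B(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i < 0 or j < 0:
            return NEG
        cands = [X(i, j), Y(i, j)]
        if i > 0 and j > 0:
            cands.append(B(i - 1, j - 1) + sub(ref[i - 1], clone[j - 1]))
        if i >= 3 and ts <= i - 3 and i <= te and (i - 3 - ts) % 3 == 0:
            cands.append(B(i - 3, j) + p.unit_gap)
        if j >= 3 and ts <= i <= te:
            cands.append(B(i, j - 3) + p.unit_gap)
        return max(cands)

    return B(len(ref), len(clone))


class TestInSilicoConvert:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ATGT"), ("TTTT", "TTTT"), ("CGG" * 3, "TGG" * 3)],
    )
    def test_every_c_becomes_t(self, seq, expected):
        assert in_silico_convert(GenomicSequence(id="r", seq=seq)).seq == expected


def toy_reference():
    seq = "ATTGACCGA" + "CGG" * 6 + "TACGTTGA"
    ref = GenomicSequence(id="ref", seq=seq)
    repeat = RepeatAnnotation(start=9, end=9 + 18, unit_count=6)
    return ref, repeat


class TestAlignClone:
    def test_fully_converted_clone_perfect_ungapped(self):
        ref, repeat = toy_reference()
        clone = CloneSequence(clone_id="c", seq=in_silico_convert(ref).seq)
        aln = align_clone(clone, ref, repeat)
        assert aln.score == AlignParams().match * len(ref)
        assert aln.pairs == [(i, i) for i in range(len(ref))]
        assert aln.repeat_unit_indels == 0

    def test_unconverted_clone_perfect_ungapped(self):
        ref, repeat = toy_reference()
        aln = align_clone(CloneSequence(clone_id="c", seq=ref.seq), ref, repeat)
        assert aln.score == AlignParams().match * len(ref)
        assert not aln.reverse_complemented

    def test_orientation_autodetect(self):
        ref, repeat = toy_reference()
        clone = CloneSequence(clone_id="c", seq=reverse_complement(in_silico_convert(ref).seq))
        aln = align_clone(clone, ref, repeat)
        assert aln.reverse_complemented
        assert aln.score == AlignParams().match * len(ref)

    def test_one_missing_unit_gives_single_unit_gap(self):
        ref, repeat = toy_reference()
        converted = "ATTGATTGA" + "TGG" * 5 + "TATGTTGA"  # one CGG unit fewer, converted
        aln = align_clone(CloneSequence(clone_id="c", seq=converted), ref, repeat)
        assert aln.repeat_unit_indels == 1
        gaps = [r for r, c in aln.pairs if c is None]
        assert len(gaps) == 3
        assert all(repeat.start <= g < repeat.end for g in gaps)
        # flanks align position-shifted but ungapped
        flank_pairs = [(r, c) for r, c in aln.pairs if r is not None and r >= repeat.end]
        assert all(r - c == 3 for r, c in flank_pairs)

    @pytest.mark.parametrize("delta_units", [-1, 0, 1])
    def test_score_matches_exhaustive_dp_on_toys(self, delta_units):
        """Banded DP equals an exhaustive recursion on <= 60 nt instances."""
        flank5, flank3 = "ATTGACCGA", "TACGTTGA"
        n_ref, n_clone = 6, 6 + delta_units
        ref = GenomicSequence(id="r", seq=flank5 + "CGG" * n_ref + flank3)
        tract = (len(flank5), len(flank5) + 3 * n_ref)
        clone_seq = (flank5 + "CGG" * n_clone + flank3).replace("C", "T")
        repeat = RepeatAnnotation(start=tract[0], end=tract[1], unit_count=n_ref)
        aln = align_clone(CloneSequence(clone_id="c", seq=clone_seq), ref, repeat)
        assert aln.score == oracle_best_score(ref.seq, clone_seq, tract)

    def test_mismatch_scores_match_oracle(self):
        ref, repeat = toy_reference()
        clone_seq = list(in_silico_convert(ref).seq)
        clone_seq[2] = "C" if clone_seq[2] != "C" else "A"  # one real mismatch
        clone_seq = "".join(clone_seq)
        aln = align_clone(CloneSequence(clone_id="c", seq=clone_seq), ref, repeat)
        assert aln.score == oracle_best_score(
            ref.seq, clone_seq, (repeat.start, repeat.end)
        )

    def test_unalignable_clone_rejected(self):
        ref, repeat = toy_reference()
        junk = "A" * len(ref)
        with pytest.raises(UnalignableCloneError):
            align_clone(CloneSequence(clone_id="c", seq=junk), ref, repeat)

    def test_conversion_invariance_of_gap_placement(self):
        """Aligning a clone and its further-converted copy places gaps
        identically (conversion is never evidence for or against a gap)."""
        ref, repeat = toy_reference()
        partial = "ATTGACCGA" + "CGG" * 3 + "TGG" * 2 + "TACGTTGA"  # one unit fewer
        fully = partial.replace("C", "T")
        a1 = align_clone(CloneSequence(clone_id="p", seq=partial), ref, repeat)
        a2 = align_clone(CloneSequence(clone_id="f", seq=fully), ref, repeat)
        assert [r for r, c in a1.pairs if c is None] == [r for r, c in a2.pairs if c is None]


def identity_alignment(clone_seq, ref):
    return BisulfiteAlignment(
        clone_id="c",
        pairs=[(i, i) for i in range(len(ref))],
        score=0.0,
        clone_seq=clone_seq,
    )


class TestScoreConversion:
    def test_fully_converted_and_unconverted(self):
        ref, repeat = toy_reference()
        conv = score_conversion(identity_alignment(in_silico_convert(ref).seq, ref), ref)
        assert all(c.state == "converted" for c in conv)
        unconv = score_conversion(identity_alignment(ref.seq, ref), ref)
        assert all(c.state == "unconverted" for c in unconv)

    def test_three_state_toy(self):
        ref = GenomicSequence(id="r", seq="AACAATTTTCAAATTTTTTTTTCAAATTTG")
        c_positions = [i for i, b in enumerate(ref.seq) if b == "C"]
        assert len(c_positions) == 3
        clone = list(ref.seq)
        clone[c_positions[0]] = "T"  # converted
        # second stays C -> unconverted
        pairs = [(i, i) for i in range(len(ref))]
        pairs[c_positions[2]] = (c_positions[2], None)  # gap -> missing
        aln = BisulfiteAlignment(clone_id="c", pairs=pairs, score=0.0, clone_seq="".join(clone))
        states = [c.state for c in score_conversion(aln, ref)]
        assert states == ["converted", "unconverted", "missing"]

    def test_matches_naive_positional_oracle_on_ungapped(self, rng):
        ref_seq = "".join(rng.choice(list("ACGT"), size=120))
        ref = GenomicSequence(id="r", seq=ref_seq)
        clone = [
            ("T" if rng.random() < 0.5 else b) if b == "C" else
            (b if rng.random() > 0.03 else "N")
            for b in ref_seq
        ]
        clone_seq = "".join(clone)
        got = score_conversion(identity_alignment(clone_seq, ref), ref)
        expected = []
        for r, c in zip(ref_seq, clone_seq):
            if r != "C":
                continue
            expected.append("converted" if c == "T" else "unconverted" if c == "C" else "missing")
        assert [c.state for c in got] == expected


class TestBuildMatrix:
    def _calls(self, states, positions=None):
        positions = positions or list(range(0, 10 * len(states), 10))
        return [ConversionCall(position=p, state=s) for p, s in zip(positions, states)]

    def test_single_clone(self):
        m = build_matrix({"c1": self._calls(["converted", "missing"])})
        assert m.table.shape == (1, 2)
        assert list(m.table.loc["c1"]) == ["1", "."]

    def test_identical_clones_identical_rows(self):
        calls = self._calls(["converted", "unconverted"])
        m = build_matrix({"a": calls, "b": list(calls)})
        assert (m.table.loc["a"] == m.table.loc["b"]).all()

    def test_mixed_amplicons_rejected(self):
        with pytest.raises(ValueError, match="different amplicon"):
            build_matrix({
                "a": self._calls(["converted"]),
                "b": self._calls(["converted"], positions=[5]),
            })

    def test_rows_grouped_by_allele(self):
        calls = self._calls(["converted"])
        m = build_matrix(
            {"z": list(calls), "a": list(calls), "m": list(calls)},
            allele_labels={"z": "30", "a": "95", "m": "30"},
        )
        assert list(m.table.index) == ["m", "z", "a"]

    def test_tsv_round_trip_lossless(self, tmp_path):
        m = build_matrix(
            {"a": self._calls(["converted", "unconverted", "missing"]),
             "b": self._calls(["missing", "missing", "converted"])},
            allele_labels={"a": "29", "b": "29"},
        )
        path = tmp_path / "matrix.tsv"
        m.to_tsv(path)
        back = footprint.ConversionMatrix.from_tsv(path)
        assert back.table.equals(m.table)
        assert back.allele_labels == m.allele_labels

    def test_marginals_match_generative_probabilities(self, small_allele):
        """Per-column conversion fractions of a simulated batch sit inside
        exact binomial bands around the generative probability."""
        from scipy.stats import binom

        model = simgen.FootprintModel(
            config_probs={"no_rloop": 1.0, "regular": 0.0, "collapsed": 0.0, "hairpin": 0.0},
            p_convert_ds=0.3, p_convert_ss=0.9, seq_error_rate=0.0, seed=42,
        )
        clones, _ = simgen.simulate_clones(small_allele, model, 20)
        ref = small_allele.sequence
        calls = {
            c.clone_id: score_conversion(align_clone(c, ref, small_allele.repeat), ref)
            for c in clones
        }
        m = build_matrix(calls)
        conv_counts = (m.table == "1").sum(axis=0)
        lo, hi = binom.ppf(0.0005, 20, 0.3), binom.ppf(0.9995, 20, 0.3)
        assert ((conv_counts >= lo) & (conv_counts <= hi)).all()


class TestProtectedRuns:
    def _calls(self, states, start=0):
        return [ConversionCall(position=start + 3 * i, state=s) for i, s in enumerate(states)]

    def test_all_converted_no_runs(self):
        assert detect_protected_runs(self._calls(["converted"] * 8)) == []

    def test_single_run_detected(self):
        calls = self._calls(["converted"] + ["unconverted"] * 5 + ["converted"])
        runs = detect_protected_runs(calls)
        assert len(runs) == 1 and runs[0].length == 5
        assert (runs[0].start_index, runs[0].end_index) == (1, 6)

    def test_missing_breaks_a_run(self):
        calls = self._calls(["unconverted"] * 3 + ["missing"] + ["unconverted"] * 3)
        runs = detect_protected_runs(calls, min_run=3)
        assert [r.length for r in runs] == [3, 3]

    def test_min_run_threshold(self):
        calls = self._calls(["unconverted"] * 2 + ["converted"] * 3)
        assert detect_protected_runs(calls, min_run=3) == []

    def test_hairpin_runs_flank_the_agg(self, small_allele):
        """Noise-free hairpin clones: the tract splits into two protected
        runs whose shared boundary sits within one column of the AGG."""
        model = simgen.FootprintModel(
            config_probs={"hairpin": 1.0, "regular": 0.0, "collapsed": 0.0, "no_rloop": 0.0},
            p_convert_ss=1.0, p_convert_ds=0.0, boundary_jitter=0.0,
            seq_error_rate=0.0, seed=9,
        )
        clones, truths = simgen.simulate_clones(small_allele, model, 5)
        ref, repeat = small_allele.sequence, small_allele.repeat
        agg = repeat.interruptions[0]
        for clone in clones:
            calls = score_conversion(align_clone(clone, ref, repeat), ref)
            inside = [r for r in detect_protected_runs(calls, repeat) if r.inside_repeat]
            assert len(inside) == 2
            positions = [c.position for c in calls]
            agg_col = int(np.argmin([abs(p - agg) for p in positions]))
            boundary = (inside[0].end_index + inside[1].start_index) / 2
            assert abs(boundary - agg_col) <= 1


class TestSummarizeFootprint:
    def test_fully_converted_clone(self, small_allele):
        ref = small_allele.sequence
        calls = score_conversion(
            identity_alignment(in_silico_convert(ref).seq, ref), ref
        )
        s = summarize_footprint(calls, small_allele.g_clusters, small_allele.repeat)
        first_c = ref.seq.index("C")
        assert s.initiation_site == first_c
        assert s.fraction_converted_inside_repeat == 1.0
        assert s.fraction_converted_outside_repeat == 1.0

    def test_fully_unconverted_clone(self, small_allele):
        ref = small_allele.sequence
        calls = score_conversion(identity_alignment(ref.seq, ref), ref)
        s = summarize_footprint(calls, small_allele.g_clusters, small_allele.repeat)
        assert s.initiation_site is None
        assert s.ss_intervals == []
        assert s.fraction_converted_inside_repeat == 0.0

    def test_collapsed_clones_assign_downstream_gcluster(self, small_allele):
        """ssDNA only downstream of the tract is traced to the planted
        downstream G-cluster for nearly all clones."""
        model = simgen.FootprintModel(
            config_probs={"collapsed": 1.0, "regular": 0.0, "hairpin": 0.0, "no_rloop": 0.0},
            p_convert_ss=0.8, p_convert_ds=0.05, seq_error_rate=0.0, seed=13,
        )
        clones, _ = simgen.simulate_clones(small_allele, model, 100)
        ref, repeat = small_allele.sequence, small_allele.repeat
        down = small_allele.downstream_g_clusters[0]
        hits = 0
        for clone in clones:
            calls = score_conversion(align_clone(clone, ref, repeat), ref)
            s = summarize_footprint(calls, small_allele.g_clusters, repeat)
            if s.assigned_gcluster and s.assigned_gcluster.start == down.start:
                hits += 1
        assert hits >= 95


class TestClassifyConfiguration:
    def test_all_four_configurations_recovered(self, small_allele):
        model = simgen.FootprintModel(seed=21)
        clones, truths = simgen.simulate_clones(small_allele, model, 60)
        ref, repeat = small_allele.sequence, small_allele.repeat
        correct = 0
        for clone, truth in zip(clones, truths):
            calls = score_conversion(align_clone(clone, ref, repeat), ref)
            if classify_configuration(calls, repeat) == truth.configuration:
                correct += 1
        assert correct >= 57  # allow a few boundary-jitter flips
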