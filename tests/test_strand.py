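"""Binomial strand calls, agreement scoring, and artifact-removal filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncdyn.genome import AnnotationSet, TranscriptModel, neighbor_table
from lncdyn.strand import (StrandEvidence, binomial_strand_call,
                           bridging_read_filter, correlated_neighbor_filter,
                           effective_strand, strand_agreement)


def make(tid, exons, strand="unknown", chrom="chr1", biotype="candidate"):
    return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=tuple(exons),
                           biotype=biotype)


def pmf_two_sided(k, n):
    """Oracle: exact two-sided binomial p at p0=0.5 by pmf enumeration (minlike)."""
    pmf = [math.comb(n, i) * 0.5 ** n for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-12)))


class TestBinomialCall:
    def test_ten_zero_called_plus(self):
        ev = binomial_strand_call(10, 0)
        assert ev.call == "+" and ev.p_value == pytest.approx(2 * 0.5 ** 10)

    def test_six_zero_undetermined(self):
        ev = binomial_strand_call(6, 0)
        assert ev.p_value == pytest.approx(0.03125) and ev.call == "undetermined"

    @pytest.mark.parametrize("k", [1, 5, 17])
    def test_balanced_counts_undetermined(self, k):
        ev = binomial_strand_call(k, k)
        assert ev.p_value == pytest.approx(1.0) and ev.call == "undetermined"

    def test_zero_total_undetermined_without_test(self):
        ev = binomial_strand_call(0, 0)
        assert ev.call == "undetermined" and ev.p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_strand_call(-1, 5)

    def test_alpha_is_strict_boundary(self):
        # p = 2*0.5^7 = 0.015625 > 0.01 -> undetermined; 2*0.5^8 < 0.01 -> called
        assert binomial_strand_call(7, 0).call == "undetermined"
        assert binomial_strand_call(8, 0).call == "+"
        assert binomial_strand_call(0, 8).call == "-"

    def test_matches_enumeration_small_totals(self):
        for n in range(1, 16):
            for k in range(n + 1):
                ev = binomial_strand_call(k, n - k)
                assert ev.p_value == pytest.approx(pmf_two_sided(k, n), rel=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_strand_swap_symmetry(self, p, m):
        if p + m == 0:
            return
        a = binomial_strand_call(p, m)
        b = binomial_strand_call(m, p)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        flip = {"+": "-", "-": "+", "undetermined": "undetermined"}
        assert b.call == flip[a.call]


class TestAgreement:
    def _ev(self, tid, call):
        return StrandEvidence(tid, 10, 0, 0.001, call)

    def _summary(self, n_agree, n_total):
        asm = {f"t{i}": "+" for i in range(n_total)}
        ev = {f"t{i}": self._ev(f"t{i}", "+" if i < n_agree else "-")
              for i in range(n_total)}
        return strand_agreement(asm, ev)

    def test_study_scale_percentages(self):
        assert self._summary(1418, 1849)["percent"] == 77
        assert self._summary(2707, 5108)["percent"] == 53

    def test_identical_sets_100(self):
        assert self._summary(25, 25)["percent"] == 100

    def test_empty_denominator_is_na(self):
        out = strand_agreement({"a": "+"}, {"a": self._ev("a", "undetermined")})
        assert out["n_expressed"] == 0 and out["percent"] is None


class TestEffectiveStrand:
    def test_evidence_wins(self):
        m = make("t", [(1, 100), (200, 300)], strand="+")
        assert effective_strand(m, StrandEvidence("t", 0, 20, 1e-5, "-")) == ("-", "evidence")

    def test_single_exon_assembler_ignored(self):
        m = make("t", [(1, 300)], strand="+")
        assert effective_strand(m, None) == ("unknown", "none")
        und = StrandEvidence("t", 3, 2, 1.0, "undetermined")
        assert effective_strand(m, und) == ("unknown", "none")

    def test_multi_exon_assembler_fallback(self):
        m = make("t", [(1, 100), (200, 300)], strand="-")
        assert effective_strand(m, None) == ("-", "assembler")


def _scenario(lnc_strand, gene_strand, r_target, evidence_call, multi_exon=True):
    """One lncRNA flanked by one gene, profiles engineered to correlation r_target."""
    exons = [(5000, 5100), (5200, 5300)] if multi_exon else [(5000, 5300)]
    lnc = make("lnc", exons, strand=lnc_strand)
    gene = make("gene", [(1000, 2000)], strand=gene_strand, biotype="coding")
    lncs = AnnotationSet.from_models([lnc])
    genes = AnnotationSet.from_models([gene])
    t = np.linspace(0, 1, 60)
    x = np.sin(2 * np.pi * t)
    z = np.cos(2 * np.pi * t)  # orthogonal, both zero-mean on this grid
    x = (x - x.mean()) / np.std(x)
    z = (z - z.mean()) / np.std(z)
    z = z - (z @ x) / (x @ x) * x
    z /= np.std(z)
    y = r_target * x + math.sqrt(max(0.0, 1 - r_target ** 2)) * z
    profiles = pd.DataFrame([x, y], index=["lnc", "gene"])
    ev = {}
    if evidence_call is not None:
        ev["lnc"] = StrandEvidence("lnc", 20, 0, 1e-6, evidence_call)
    nbrs = neighbor_table(lncs, genes)
    return lncs, genes, profiles, nbrs, ev


class TestCorrelatedNeighborFilter:
    def test_same_strand_high_r_removed_class1(self):
        args = _scenario("+", "+", 0.95, "+")
        rep, classes = correlated_neighbor_filter(*args)
        assert rep.ids_removed == ["lnc"]
        assert classes[0].class_label == "class1" and classes[0].gene_id == "gene"

    def test_opposite_strand_high_r_kept(self):
        rep, _ = correlated_neighbor_filter(*_scenario("+", "-", 0.95, "+"))
        assert rep.ids_kept == ["lnc"]

    def test_assembler_fallback_is_class2(self):
        rep, classes = correlated_neighbor_filter(*_scenario("+", "+", 0.95, None))
        assert rep.ids_removed == ["lnc"] and classes[0].class_label == "class2"

    def test_unknown_by_both_never_removed(self):
        rep, _ = correlated_neighbor_filter(
            *_scenario("unknown", "+", 0.99, None, multi_exon=False))
        assert rep.ids_kept == ["lnc"]

    def test_low_r_kept(self):
        rep, _ = correlated_neighbor_filter(*_scenario("+", "+", 0.5, "+"))
        assert rep.ids_kept == ["lnc"]

    def test_zero_variance_profile_skipped(self):
        lncs, genes, profiles, nbrs, ev = _scenario("+", "+", 0.95, "+")
        profiles.loc["gene"] = 1.0  # constant: correlation undefined
        rep, classes = correlated_neighbor_filter(lncs, genes, profiles, nbrs, ev)
        assert rep.ids_kept == ["lnc"] and not classes

    def test_removals_shrink_as_threshold_rises(self, sim1, pipeline1):
        lnc_ids = [t for t in pipeline1.final_lnc.ids()] \
            + [t for t in sim1.truth.index[sim1.truth.label == "exon_decoy"]
               if t in pipeline1.smoothed.index]
        sub = AnnotationSet.from_models(
            [sim1.candidates[t] for t in lnc_ids if t in sim1.candidates.transcripts])
        nbrs = neighbor_table(sub, sim1.genes)
        removed = []
        for thr in (0.5, 0.8, 0.9, 0.99):
            rep, _ = correlated_neighbor_filter(sub, sim1.genes, pipeline1.smoothed,
                                                nbrs, pipeline1.evidence, thr)
            removed.append(set(rep.ids_removed))
        for a, b in zip(removed, removed[1:]):
            assert b <= a


class TestBridgingFilter:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "chrom1", "start1", "end1",
                                           "chrom2", "start2", "end2"])

    def test_exon_to_exon_pair_removes(self):
        lnc = make("lnc", [(5000, 5400)])
        gene = make("gene", [(1000, 1500), (2000, 2500)], strand="+", biotype="coding")
        lncs, genes = AnnotationSet.from_models([lnc]), AnnotationSet.from_models([gene])
        nbrs = neighbor_table(lncs, genes)
        pairs = self._pairs([("r1", "chr1", 5100, 5160, "chr1", 2100, 2160)])
        rep = bridging_read_filter(lncs, genes, pairs, nbrs)
        assert rep.ids_removed == ["lnc"]
        # mate order must not matter
        swapped = self._pairs([("r1", "chr1", 2100, 2160, "chr1", 5100, 5160)])
        assert bridging_read_filter(lncs, genes, swapped, nbrs).ids_removed == ["lnc"]

    def test_mate_in_intron_kept(self):
        lnc = make("lnc", [(5000, 5400)])
        gene = make("gene", [(1000, 1500), (2000, 2500)], strand="+", biotype="coding")
        lncs, genes = AnnotationSet.from_models([lnc]), AnnotationSet.from_models([gene])
        nbrs = neighbor_table(lncs, genes)
        pairs = self._pairs([("r1", "chr1", 5100, 5160, "chr1", 1600, 1660)])
        assert bridging_read_filter(lncs, genes, pairs, nbrs).ids_kept == ["lnc"]

    def test_planted_bridged_decoys_exactly_removed(self, sim1):
        decoys = sim1.truth[sim1.truth.label == "exon_decoy"]
        sub = sim1.candidates.subset(decoys.index)
        nbrs = neighbor_table(sub, sim1.genes)
        rep = bridging_read_filter(sub, sim1.genes, sim1.read_pairs, nbrs)
        bridged = set(decoys.index[decoys.bridged.astype(bool)])
        assert set(rep.ids_removed) == bridged
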