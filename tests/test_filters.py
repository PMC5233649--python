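"""ORF scanning and the early filter funnel (coding, length, miRNA, collapse)."""

import itertools

import numpy as np
import pytest

from lncdyn.filters import (collapse_representatives, filter_coding, filter_genic,
                            filter_mirna_overlap, filter_short, longest_orf_aa,
                            partition_by_exons, reverse_complement)
from lncdyn.genome import AnnotationSet, TranscriptModel, overlaps

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orf(seq, strand="unknown"):
    """Oracle: scan every ATG in every frame, walk to the first in-frame stop."""
    best = 0
    strands = [seq] if strand != "unknown" else [seq, reverse_complement(seq)]
    for s in strands:
        for i in range(len(s) - 2):
            if s[i:i + 3] != "ATG":
                continue
            for j in range(i + 3, len(s) - 2, 3):
                if s[j:j + 3] in STOPS:
                    best = max(best, (j - i) // 3)
                    break
    return best


def make(tid, exons, chrom="chr1", strand="unknown"):
    return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=tuple(exons))


def orf_seq(n_aa):
    """ATG + (n_aa − 1) leucine codons + stop: exactly n_aa amino acids."""
    return "ATG" + "CTG" * (n_aa - 1) + "TAA"


class TestLongestOrf:
    def test_constructed_100aa(self):
        assert longest_orf_aa(orf_seq(100), strand="+") == 100

    def test_no_atg_is_zero(self):
        assert longest_orf_aa("CCCGGGCCCGGG" * 10, strand="unknown") == 0

    def test_open_ended_run_does_not_count(self):
        # ATG followed by no stop: not a complete ORF
        assert longest_orf_aa("ATG" + "CTG" * 50, strand="+") == 0

    def test_empty_and_short(self):
        assert longest_orf_aa("", "+") == 0
        assert longest_orf_aa("ATG", "+") == 0

    def test_reverse_strand_found_when_unknown(self):
        seq = reverse_complement(orf_seq(30))
        assert longest_orf_aa(seq, strand="unknown") == 30
        assert longest_orf_aa(seq, strand="+") < 30

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for strand in ("+", "unknown"):
            for _ in range(100):
                seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 400))))
                assert longest_orf_aa(seq, strand) == brute_force_orf(seq, strand)


class TestCodingFilter:
    def test_boundary_99_kept_100_removed(self):
        cands = AnnotationSet.from_models([
            make("a99", [(1, 300)], strand="+"), make("a100", [(1, 303)], strand="+")])
        seqs = {"a99": orf_seq(99), "a100": orf_seq(100)}
        rep = filter_coding(cands, seqs)
        assert rep.ids_kept == ["a99"] and rep.ids_removed == ["a100"]

    def test_missing_sequence_names_id(self):
        cands = AnnotationSet.from_models([make("lost", [(1, 300)])])
        with pytest.raises(KeyError, match="lost"):
            filter_coding(cands, {})

    def test_planted_coding_decoys_exactly_removed(self, sim1):
        rep = filter_coding(sim1.candidates, sim1.sequences)
        decoys = set(sim1.truth.index[sim1.truth.label == "coding_decoy"])
        assert set(rep.ids_removed) == decoys


class TestShortFilter:
    def test_boundary_199_removed_200_kept(self):
        cands = AnnotationSet.from_models([make("s", [(1, 199)]), make("k", [(1, 200)])])
        rep = filter_short(cands)
        assert rep.ids_removed == ["s"] and rep.ids_kept == ["k"]

    def test_exonic_not_span_length(self):
        # two 100 nt exons spanning 1 kb: exonic length 200 -> kept
        cands = AnnotationSet.from_models([make("m", [(1, 100), (901, 1000)])])
        assert filter_short(cands).ids_kept == ["m"]

    def test_survivors_remeasured(self, rng):
        models = [make(f"t{i}", [(1, int(rng.integers(50, 400)))]) for i in range(50)]
        ann = AnnotationSet.from_models(models)
        rep = filter_short(ann)
        assert all(ann[t].length >= 200 for t in rep.ids_kept)
        assert all(ann[t].length < 200 for t in rep.ids_removed)


class TestMirnaFilter:
    def test_exon_overlap_removed_intron_kept(self):
        mirnas = AnnotationSet.from_models([make("mir", [(250, 271)], strand="+")])
        hit = make("hit", [(100, 300)])
        intronic = make("skip", [(100, 200), (400, 500)])  # miRNA in the intron
        rep = filter_mirna_overlap(AnnotationSet.from_models([hit, intronic]), mirnas)
        assert rep.ids_removed == ["hit"] and rep.ids_kept == ["skip"]

    def test_matches_bruteforce(self, rng):
        from tests.test_genome import random_annotation
        cands = random_annotation(rng, 30)
        mirs = random_annotation(rng, 10)
        rep = filter_mirna_overlap(cands, mirs)
        for m in cands:
            expect = any(overlaps(m, mi, mode="exon") for mi in mirs)
            assert (m.id in rep.ids_removed) == expect


class TestCollapse:
    def test_tiebreak_chain(self):
        # longest wins; equal length -> more exons; then smaller id
        a = make("a", [(1, 300)])                     # 300 nt
        b = make("b", [(100, 599)])                   # 500 nt, 1 exon
        c = make("c", [(200, 449), (500, 749)])       # 500 nt, 2 exons
        rep = collapse_representatives(AnnotationSet.from_models([a, b, c]))
        assert rep.ids_kept == ["c"] and set(rep.ids_removed) == {"a", "b"}

    def test_non_overlapping_all_kept(self):
        ann = AnnotationSet.from_models([make("a", [(1, 300)]), make("b", [(1000, 1300)])])
        rep = collapse_representatives(ann)
        assert sorted(rep.ids_kept) == ["a", "b"] and not rep.ids_removed

    def test_one_survivor_per_component(self, rng):
        from tests.test_genome import random_annotation
        ann = random_annotation(rng, 40)
        rep = collapse_representatives(ann)
        # recompute components independently (BFS over pairwise overlap)
        ids = ann.ids()
        adj = {i: {j for j in ids if j != i and overlaps(ann[i], ann[j])} for i in ids}
        seen, comps = set(), []
        for i in ids:
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        kept = set(rep.ids_kept)
        for comp in comps:
            winners = kept & comp
            assert len(winners) == 1
            w = ann[winners.pop()]
            best = sorted((ann[i] for i in comp),
                          key=lambda m: (-m.length, -m.n_exons, m.id))[0]
            assert w.id == best.id


class TestPartitionAndProperties:
    def test_partition(self):
        ann = AnnotationSet.from_models([make("m", [(1, 100), (200, 300)]),
                                         make("s", [(1, 250)])])
        multi, single = partition_by_exons(ann)
        assert multi.ids() == ["m"] and single.ids() == ["s"]
        assert len(multi) + len(single) == len(ann)

    def test_steps_2_to_4_commute(self, rng):
        """Applying coding/length/miRNA filters in any order keeps the same set."""
        from lncdyn.simulate import noncoding_sequence
        models, seqs = [], {}
        for i in range(20):
            length = int(rng.integers(150, 400))
            m = make(f"t{i}", [(1 + 1000 * i, 1000 * i + length)], strand="+")
            models.append(m)
            seqs[m.id] = (orf_seq(120) + noncoding_sequence(rng, max(0, length - 363))
                          if rng.random() < 0.3 else noncoding_sequence(rng, length))
        mirnas = AnnotationSet.from_models(
            [make(f"mir{i}", [(1 + 1000 * i, 80 + 1000 * i)]) for i in range(0, 20, 5)])

        def kept_after(order, ann):
            steps = {"coding": lambda a: filter_coding(a, seqs),
                     "short": filter_short,
                     "mirna": lambda a: filter_mirna_overlap(a, mirnas)}
            for s in order:
                ann = ann.subset(steps[s](ann).ids_kept)
            return set(ann.ids())

        base = AnnotationSet.from_models(models)
        results = {kept_after(order, base) == kept_after(("coding", "short", "mirna"), base)
                   for order in itertools.permutations(("coding", "short", "mirna"))}
        assert results == {True}

    def test_reports_partition_input(self, sim1):
        for rep in (filter_genic(sim1.candidates, sim1.genes),
                    filter_coding(sim1.candidates, sim1.sequences),
                    filter_short(sim1.candidates),
                    filter_mirna_overlap(sim1.candidates, sim1.mirnas),
                    collapse_representatives(sim1.candidates)):
            rep.check_partition(sim1.candidates.ids())

    def test_true_lncs_survive_early_funnel(self, sim1):
        cands = sim1.candidates
        for rep in (filter_genic(cands, sim1.genes),
                    filter_coding(cands, sim1.sequences),
                    filter_short(cands),
                    filter_mirna_overlap(cands, sim1.mirnas),
                    collapse_representatives(cands)):
            cands = cands.subset(rep.ids_kept)
        lost = set(sim1.truth.index[sim1.truth.label == "true_lnc"]) - set(cands.ids())
        assert not lost
        survivors = set(sim1.truth.loc[cands.ids()].label) - {"true_lnc", "exon_decoy"}
        assert not survivors
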