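"""Candidate filtering: coding potential, length, miRNA overlap, collapsing, partition.

These are the early funnel stages of intergenic lncRNA discovery: drop
candidates that look protein-coding (an ATG-initiated open reading frame of
at least 100 amino acids on any relevant frame), candidates shorter than
200 nt of exonic sequence, and candidates overlapping annotated miRNA loci;
then keep a single representative among mutually overlapping models and
split the survivors into multi-exon and single-exon sets, which downstream
stages treat separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import AnnotationSet, TranscriptModel, overlaps

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class FilterReport:
    """Audit record for one filter step: partition of the input into kept/removed."""

    step: str
    ids_kept: list[str] = field(default_factory=list)
    ids_removed: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)

    def check_partition(self, input_ids) -> None:
        inp = set(input_ids)
        kept, removed = set(self.ids_kept), set(self.ids_removed)
        if kept & removed:
            raise AssertionError(f"{self.step}: kept/removed overlap")
        if kept | removed != inp:
            raise AssertionError(f"{self.step}: kept ∪ removed != input")

    @property
    def n_removed(self) -> int:
        return len(self.ids_removed)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _longest_orf_frames(seq: str) -> int:
    """Longest ATG-initiated, stop-terminated ORF (aa) over the 3 sense frames."""
    best = 0
    n = len(seq)
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, n - 2, 3)]
        start = None
        for j, codon in enumerate(codons):
            if codon in _STOPS:
                if start is not None:
                    best = max(best, j - start)  # Met included, stop excluded
                    start = None
            elif start is None and codon == "ATG":
                start = j
        # an ORF must terminate at an in-frame stop; open-ended runs don't count
    return best


def longest_orf_aa(sequence: str, strand: str = "unknown") -> int:
    """Length in amino acids of the longest complete ORF in `sequence`.

    An ORF starts at ATG and ends at the first in-frame stop; its length
    counts the initiator Met and excludes the stop. When the strand is
    unknown all 6 frames are scanned, otherwise only the 3 sense frames
    (the sequence is taken to be the sense-strand transcript sequence).
    """
    seq = sequence.upper()
    if len(seq) < 6:
        return 0
    best = _longest_orf_frames(seq)
    if strand == "unknown":
        best = max(best, _longest_orf_frames(reverse_complement(seq)))
    return best


def filter_coding(candidates: AnnotationSet, sequences: dict[str, str],
                  min_orf_aa: int = 100) -> FilterReport:
    """Remove candidates whose longest ORF reaches `min_orf_aa` amino acids."""
    rep = FilterReport(step="coding_potential")
    for m in candidates:
        if m.id not in sequences:
            raise KeyError(f"no sequence provided for candidate {m.id!r}")
        aa = longest_orf_aa(sequences[m.id], strand=m.strand)
        if aa >= min_orf_aa:
            rep.ids_removed.append(m.id)
            rep.reasons[m.id] = f"orf_{aa}aa"
        else:
            rep.ids_kept.append(m.id)
    return rep


def filter_short(candidates: AnnotationSet, min_length: int = 200) -> FilterReport:
    """Remove candidates with summed exonic length below `min_length` nt."""
    rep = FilterReport(step="short_transcript")
    for m in candidates:
        if m.length < min_length:
            rep.ids_removed.append(m.id)
            rep.reasons[m.id] = f"length_{m.length}nt"
        else:
            rep.ids_kept.append(m.id)
    return rep


def filter_mirna_overlap(candidates: AnnotationSet, mirnas: AnnotationSet) -> FilterReport:
    """Remove candidates whose exons overlap any miRNA locus (strand-unaware)."""
    rep = FilterReport(step="mirna_overlap")
    for m in candidates:
        hit = next((mid for mid in mirnas.overlapping(m, mode="exon")), None)
        if hit is not None:
            rep.ids_removed.append(m.id)
            rep.reasons[m.id] = f"overlaps_{hit}"
        else:
            rep.ids_kept.append(m.id)
    return rep


def filter_genic(candidates: AnnotationSet, coding: AnnotationSet) -> FilterReport:
    """Keep only intergenic candidates: no genomic-span overlap with coding genes."""
    rep = FilterReport(step="genic_overlap")
    for m in candidates:
        hits = coding.overlapping(m, mode="span")
        if hits:
            rep.ids_removed.append(m.id)
            rep.reasons[m.id] = f"overlaps_{sorted(hits)[0]}"
        else:
            rep.ids_kept.append(m.id)
    return rep


def _representative(models: list[TranscriptModel]) -> TranscriptModel:
    # longest exonic length, then more exons, then lexicographically smallest id
    return sorted(models, key=lambda m: (-m.length, -m.n_exons, m.id))[0]


def collapse_representatives(candidates: AnnotationSet) -> FilterReport:
    """Keep one representative per connected component of exon-overlapping models."""
    ids = candidates.ids()
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for m in candidates:
        for other in candidates.overlapping(m, mode="exon"):
            union(m.id, other)

    components: dict[str, list[TranscriptModel]] = {}
    for m in candidates:
        components.setdefault(find(m.id), []).append(m)

    rep = FilterReport(step="collapse_overlapping")
    for members in components.values():
        keep = _representative(members)
        rep.ids_kept.append(keep.id)
        for m in members:
            if m.id != keep.id:
                rep.ids_removed.append(m.id)
                rep.reasons[m.id] = f"represented_by_{keep.id}"
    return rep


def partition_by_exons(candidates: AnnotationSet) -> tuple[AnnotationSet, AnnotationSet]:
    """Split candidates into (multi-exon, single-exon) sets."""
    multi = AnnotationSet.from_models(m for m in candidates if m.n_exons >= 2)
    single = AnnotationSet.from_models(m for m in candidates if m.n_exons == 1)
    return multi, single
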