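"""Core genomic data types, annotation I/O, interval arithmetic and neighbor search.

All coordinates follow the GTF convention: 1-based, inclusive on both ends.
BED input (0-based, half-open) is converted on read. A transcript is a set of
non-overlapping exon intervals on one chromosome with a strand that may be
unknown (``.`` in GTF), which is the common state of single-exon candidates
assembled from unstranded libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", "unknown")

#: biotypes a TranscriptModel may carry
BIOTYPES = ("candidate", "coding", "miRNA", "lncRNA")


class GtfParseError(ValueError):
    """Raised for malformed annotation lines; carries the offending line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured genomic interval set for one transcript.

    Exons are ``(start, end)`` pairs in 1-based inclusive coordinates, sorted
    ascending and non-overlapping.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.id}: strand must be one of {STRANDS}, got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript must have at least one exon")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e < s:
                raise ValueError(f"{self.id}: exon end {e} < start {s}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.id}: exons overlap or touch out of order")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        """Genomic-span start (first exon start)."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """Genomic-span end (last exon end)."""
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Summed exonic length in nucleotides."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class AnnotationSet:
    """A keyed collection of transcript models with per-chromosome interval indexes."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    chrom_order: list[str] = field(default_factory=list)

    @classmethod
    def from_models(cls, models: Iterable[TranscriptModel]) -> "AnnotationSet":
        out = cls()
        for m in models:
            out.add(m)
        return out

    def add(self, model: TranscriptModel) -> None:
        if model.id in self.transcripts:
            raise ValueError(f"duplicate transcript id {model.id!r}")
        self.transcripts[model.id] = model
        if model.chrom not in self.chrom_order:
            self.chrom_order.append(model.chrom)
        self._indexes = None  # invalidate

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def ids(self) -> list[str]:
        return list(self.transcripts)

    def subset(self, ids: Iterable[str]) -> "AnnotationSet":
        keep = set(ids)
        return AnnotationSet.from_models(m for m in self if m.id in keep)

    # -- interval index ----------------------------------------------------
    _indexes: Optional[dict[str, IntervalTree]] = field(default=None, repr=False, compare=False)

    def _exon_index(self) -> dict[str, IntervalTree]:
        if self._indexes is None:
            trees: dict[str, IntervalTree] = {}
            for m in self:
                tree = trees.setdefault(m.chrom, IntervalTree())
                for s, e in m.exons:
                    # half-open internally for intervaltree; +1 on end
                    tree.addi(s, e + 1, m.id)
            self._indexes = trees
        return self._indexes

    def overlapping(self, model: TranscriptModel, mode: str = "exon") -> set[str]:
        """Ids of transcripts in this set whose exons (or span) intersect `model`'s."""
        trees = self._exon_index()
        tree = trees.get(model.chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        if mode == "span":
            # span overlap: exon index is insufficient (a target's exons may
            # flank the query span) so scan spans on this chromosome directly
            return {t.id for t in self
                    if t.chrom == model.chrom and t.id != model.id
                    and t.start <= model.end and model.start <= t.end}
        for s, e in model.exons:
            hits |= {iv.data for iv in tree.overlap(s, e + 1)}
        return hits - {model.id}


@dataclass(frozen=True)
class NeighborPair:
    """A lncRNA with its closest flanking genes in genome coordinates.

    Upstream/downstream are defined by coordinate (left/right of the locus),
    not relative to the lncRNA's strand, since most single-exon candidates
    carry no strand call. Distances are genomic-span gaps in bp (adjacent
    intervals have distance 0); an absent side is None.
    """

    lnc_id: str
    upstream_gene: Optional[str] = None
    upstream_distance: Optional[int] = None
    downstream_gene: Optional[str] = None
    downstream_distance: Optional[int] = None
    orientation_up: str = "unknown"
    orientation_down: str = "unknown"

    def __post_init__(self) -> None:
        for d in (self.upstream_distance, self.downstream_distance):
            if d is not None and d < 0:
                raise ValueError("neighbor distances must be >= 0")

    def neighbors(self) -> list[tuple[str, int, str]]:
        """(gene_id, distance, orientation) for each present side."""
        out = []
        if self.upstream_gene is not None:
            out.append((self.upstream_gene, self.upstream_distance, self.orientation_up))
        if self.downstream_gene is not None:
            out.append((self.downstream_gene, self.downstream_distance, self.orientation_down))
        return out


def _orientation(a: str, b: str) -> str:
    if a == "unknown" or b == "unknown":
        return "unknown"
    return "parallel" if a == b else "anti-parallel"


def overlaps(a: TranscriptModel, b: TranscriptModel, strand_aware: bool = False,
             mode: str = "exon") -> bool:
    """True iff transcripts intersect, at exon resolution by default.

    mode="exon": any exon of `a` intersects any exon of `b` (closed intervals).
    mode="span": genomic spans intersect.
    Strand is ignored unless strand_aware, in which case differing known
    strands never overlap (unknown matches anything).
    """
    if a.chrom != b.chrom:
        return False
    if strand_aware and a.strand != "unknown" and b.strand != "unknown" and a.strand != b.strand:
        return False
    if mode == "span":
        return a.start <= b.end and b.start <= a.end
    if mode != "exon":
        raise ValueError(f"unknown overlap mode {mode!r}")
    if a.end < b.start or b.end < a.start:
        return False
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def span_gap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Gap in bp between genomic spans; 0 when spans touch or overlap."""
    if a.start > b.end:
        return max(0, a.start - b.end - 1)
    if b.start > a.end:
        return max(0, b.start - a.end - 1)
    return 0


def closest_neighbors(lnc: TranscriptModel, genes: AnnotationSet) -> NeighborPair:
    """Nearest gene on each side of `lnc` on the same chromosome, any strand.

    "Upstream" is the nearest gene entirely left of the lncRNA span,
    "downstream" entirely right (genome coordinates, strand-agnostic).
    Candidates are intergenic by construction; a gene whose span intersects
    the lncRNA span is skipped. Distance is the span gap (adjacent -> 0);
    ties broken by lexicographically smaller gene id.
    """
    up_gene = up_d = down_gene = down_d = None
    for g in genes:
        if g.chrom != lnc.chrom or g.id == lnc.id:
            continue
        if g.end < lnc.start:
            d = span_gap(lnc, g)
            if up_d is None or d < up_d or (d == up_d and g.id < up_gene):
                up_gene, up_d = g.id, d
        elif g.start > lnc.end:
            d = span_gap(lnc, g)
            if down_d is None or d < down_d or (d == down_d and g.id < down_gene):
                down_gene, down_d = g.id, d
    return NeighborPair(
        lnc_id=lnc.id,
        upstream_gene=up_gene,
        upstream_distance=up_d,
        downstream_gene=down_gene,
        downstream_distance=down_d,
        orientation_up=_orientation(lnc.strand, genes[up_gene].strand) if up_gene else "unknown",
        orientation_down=_orientation(lnc.strand, genes[down_gene].strand) if down_gene else "unknown",
    )


def neighbor_table(lncs: AnnotationSet, genes: AnnotationSet) -> dict[str, NeighborPair]:
    return {m.id: closest_neighbors(m, genes) for m in lncs}


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str) -> None:
    """Cheap structural pass so malformed lines are reported with line numbers."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{i}: expected 9 tab-separated columns, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"{path}:{i}: non-integer coordinates") from exc
            if end < start:
                raise GtfParseError(f"{path}:{i}: end {end} < start {start}")
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{i}: invalid strand {fields[6]!r}")


def read_gtf(path: str, biotype: str = "candidate") -> AnnotationSet:
    """Read exon features from a GTF file into an AnnotationSet.

    Exons are grouped by ``transcript_id`` and sorted; strand ``.`` maps to
    unknown. Uses gffutils for attribute parsing after a structural validation
    pass that reports malformed lines by number.
    """
    import gffutils

    _validate_gtf_lines(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    n = 0
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise GtfParseError(f"{path}: exon feature without transcript_id near {feat.seqid}:{feat.start}")
        exons.setdefault(tid, []).append((feat.start, feat.end))
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        meta[tid] = (feat.seqid, strand)
        n += 1
    out = AnnotationSet()
    for tid, ex in exons.items():
        chrom, strand = meta[tid]
        out.add(TranscriptModel(id=tid, chrom=chrom, strand=strand,
                                exons=tuple(sorted(ex)), biotype=biotype))
    logger.info("read %d exon records, %d transcripts from %s", n, len(out), path)
    return out


def write_gtf(annotations: AnnotationSet, path: str, source: str = "lncdyn") -> None:
    """Write exon features (ensembl-style attributes) for every transcript."""
    with open(path, "w") as fh:
        for m in annotations:
            strand = m.strand if m.strand in ("+", "-") else "."
            for s, e in m.exons:
                attrs = f'gene_id "{m.id}"; transcript_id "{m.id}"; biotype "{m.biotype}";'
                fh.write(f"{m.chrom}\t{source}\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")


def read_bed6(path: str, biotype: str = "miRNA") -> AnnotationSet:
    """Read a BED6 file as single-exon loci, converting to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "name": str})
    out = AnnotationSet()
    skipped = 0
    for _, row in df.iterrows():
        start0, end0 = int(row["start"]), int(row["end"])
        if end0 <= start0:
            skipped += 1
            continue
        strand = row["strand"] if row["strand"] in ("+", "-") else "unknown"
        out.add(TranscriptModel(id=str(row["name"]), chrom=str(row["chrom"]), strand=strand,
                                exons=((start0 + 1, end0),), biotype=biotype))
    logger.info("read %d BED records (%d skipped) from %s", len(out), skipped, path)
    return out
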