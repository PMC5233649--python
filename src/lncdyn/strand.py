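"""Strand assignment and removal of unannotated-exon artifacts.

Unstranded time-course libraries cannot orient a transcript, so strand
calls come from two sources: stranded libraries covering early development
(an exact two-sided binomial test on per-strand read counts, p < 0.01), and
the assembler's splice-junction-based prediction for multi-exon models
(treated as unknown for single-exon models, where it is no better than
random). A candidate that is really an unannotated exon of a neighboring
gene betrays itself by (a) sharing the gene's strand while its temporal
profile correlates with the gene's above 0.9 (removed with a class label:
class 1 when the strand was confirmed by stranded data, class 2 when only
the assembler call was available), or (b) being physically linked to the
gene by a bridging paired-end fragment with one mate in each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .filters import FilterReport
from .genome import AnnotationSet, NeighborPair, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrandEvidence:
    """Stranded read counts for one transcript and the binomial verdict."""

    transcript_id: str
    plus_reads: int
    minus_reads: int
    p_value: float
    call: str  # "+", "-", or "undetermined"

    def __post_init__(self) -> None:
        if self.plus_reads < 0 or self.minus_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class RemovalClass:
    """Step-8 removal record: which neighbor tripped the rule and how the strand was known."""

    lnc_id: str
    class_label: str  # "class1" (stranded data) or "class2" (assembler call)
    gene_id: str
    correlation: float


def binomial_strand_call(plus: int, minus: int, alpha: float = 0.01,
                         transcript_id: str = "") -> StrandEvidence:
    """Exact two-sided binomial test of strand balance against p=0.5.

    The call is the majority strand when the test rejects at `alpha`,
    otherwise undetermined. Zero total reads → undetermined without a test
    (p-value 1).
    """
    if plus < 0 or minus < 0:
        raise ValueError("read counts must be non-negative")
    total = plus + minus
    if total == 0:
        return StrandEvidence(transcript_id, plus, minus, 1.0, "undetermined")
    p = float(stats.binomtest(plus, total, p=0.5, alternative="two-sided").pvalue)
    if p < alpha and plus != minus:
        call = "+" if plus > minus else "-"
    else:
        call = "undetermined"
    return StrandEvidence(transcript_id, plus, minus, p, call)


def evidence_from_table(table: pd.DataFrame, alpha: float = 0.01) -> dict[str, StrandEvidence]:
    """Binomial calls for a stranded-count table (id, plus_reads, minus_reads)."""
    out = {}
    for tid, row in table.iterrows():
        out[str(tid)] = binomial_strand_call(int(row["plus_reads"]), int(row["minus_reads"]),
                                             alpha=alpha, transcript_id=str(tid))
    return out


def strand_agreement(assembler_calls: dict[str, str],
                     evidence_calls: dict[str, StrandEvidence]) -> dict:
    """Fraction of assembler strand predictions confirmed by stranded evidence.

    Only transcripts with a determined evidence call (i.e. detectably
    expressed in the stranded window) enter the denominator. Percent is
    rounded to the nearest integer; with an empty denominator it is NA.
    """
    n_expressed = 0
    n_agree = 0
    for tid, ev in evidence_calls.items():
        if ev.call == "undetermined":
            continue
        asm = assembler_calls.get(tid)
        if asm not in ("+", "-"):
            continue
        n_expressed += 1
        if asm == ev.call:
            n_agree += 1
    percent: Optional[int] = round(100 * n_agree / n_expressed) if n_expressed else None
    return {"n_expressed": n_expressed, "n_agree": n_agree, "percent": percent}


def effective_strand(model: TranscriptModel, evidence: Optional[StrandEvidence]) -> tuple[str, str]:
    """(strand, source) for a candidate.

    The stranded-evidence call wins when determined; otherwise the assembler
    call, but only for multi-exon models (single-exon assembler calls are
    treated as unknown). Source is "evidence", "assembler" or "none".
    """
    if evidence is not None and evidence.call in ("+", "-"):
        return evidence.call, "evidence"
    if model.n_exons >= 2 and model.strand in ("+", "-"):
        return model.strand, "assembler"
    return "unknown", "none"


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    sx, sy = np.std(x), np.std(y)
    if sx <= 0 or sy <= 0 or not (np.isfinite(sx) and np.isfinite(sy)):
        return None
    return float(np.corrcoef(x, y)[0, 1])


def correlated_neighbor_filter(
    lncs: AnnotationSet,
    genes: AnnotationSet,
    profiles: pd.DataFrame,
    neighbors: dict[str, NeighborPair],
    evidence: dict[str, StrandEvidence],
    r_threshold: float = 0.9,
) -> tuple[FilterReport, list[RemovalClass]]:
    """Remove candidates strand-matched and correlated (> r_threshold) with a flanking gene.

    `profiles` holds one smoothed temporal profile per row for candidates and
    genes on a common grid. Both neighbors are tested; either can trip the
    rule. Candidates whose strand is unknown by both evidence and assembler
    are never removed here.
    """
    rep = FilterReport(step="correlated_neighbor")
    removals: list[RemovalClass] = []
    for lnc in lncs:
        strand, source = effective_strand(lnc, evidence.get(lnc.id))
        removed = False
        if strand != "unknown" and lnc.id in profiles.index:
            x = profiles.loc[lnc.id].to_numpy(dtype=float)
            for gene_id, _dist, _orient in neighbors[lnc.id].neighbors():
                gene = genes[gene_id]
                if gene.strand != strand or gene_id not in profiles.index:
                    continue
                r = _pearson(x, profiles.loc[gene_id].to_numpy(dtype=float))
                if r is None:
                    logger.info("skipping zero-variance profile pair %s/%s", lnc.id, gene_id)
                    continue
                if r > r_threshold:
                    label = "class1" if source == "evidence" else "class2"
                    removals.append(RemovalClass(lnc.id, label, gene_id, r))
                    rep.ids_removed.append(lnc.id)
                    rep.reasons[lnc.id] = f"{label}_r{r:.3f}_{gene_id}"
                    removed = True
                    break
        if not removed:
            rep.ids_kept.append(lnc.id)
    return rep, removals


def _mate_overlaps_exons(model: TranscriptModel, chrom: str, start: int, end: int) -> bool:
    if chrom != model.chrom:
        return False
    return any(s <= end and start <= e for s, e in model.exons)


def bridging_read_filter(
    lncs: AnnotationSet,
    genes: AnnotationSet,
    read_pairs: pd.DataFrame,
    neighbors: dict[str, NeighborPair],
) -> FilterReport:
    """Remove candidates linked to an adjacent gene's exons by any paired-end fragment.

    `read_pairs` columns: read_id, chrom1, start1, end1, chrom2, start2, end2
    (1-based inclusive mate intervals; multi-mapping pairs included). A single
    pair with one mate in the candidate's exons and the other in either
    neighbor's exons removes the candidate.
    """
    rep = FilterReport(step="bridging_reads")
    pairs = read_pairs[["read_id", "chrom1", "start1", "end1",
                        "chrom2", "start2", "end2"]].itertuples(index=False)
    pair_list = list(pairs)
    for lnc in lncs:
        neighbor_genes = [genes[gid] for gid, _d, _o in neighbors[lnc.id].neighbors()]
        hit = None
        for rp in pair_list:
            for (c_a, s_a, e_a), (c_b, s_b, e_b) in (
                ((rp.chrom1, rp.start1, rp.end1), (rp.chrom2, rp.start2, rp.end2)),
                ((rp.chrom2, rp.start2, rp.end2), (rp.chrom1, rp.start1, rp.end1)),
            ):
                if not _mate_overlaps_exons(lnc, c_a, s_a, e_a):
                    continue
                for gene in neighbor_genes:
                    if _mate_overlaps_exons(gene, c_b, s_b, e_b):
                        hit = (rp.read_id, gene.id)
                        break
                if hit:
                    break
            if hit:
                break
        if hit:
            rep.ids_removed.append(lnc.id)
            rep.reasons[lnc.id] = f"pair_{hit[0]}_to_{hit[1]}"
        else:
            rep.ids_kept.append(lnc.id)
    return rep
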