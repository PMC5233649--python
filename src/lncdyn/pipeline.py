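"""End-to-end orchestration of the lncRNA discovery funnel and downstream analyses.

Runs the full filter cascade in its canonical order — intergenic pre-filter,
coding potential, minimum length, miRNA overlap, representative collapsing,
exon-count partition, consecutive-expression and SNR screens, correlated
same-strand neighbor removal, bridging-read removal — followed by temporal
clustering, neighbor-correlation permutation analysis and two spatial
contrasts, all driven by one config and one root seed. Multi- and
single-exon candidates run through steps 7–9 separately, as in the study
design, and the funnel is audited for conservation at every step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import filters, gp
from .genome import AnnotationSet, neighbor_table
from .neighborcor import pair_correlations, permutation_shift_test
from .profiles import ExpressionMatrix, rpkm, max_normalize, cluster_profiles, ClusterResult
from .spatial import SpatialDEModel, SpatialDEResults
from .strand import (RemovalClass, bridging_read_filter, correlated_neighbor_filter,
                     evidence_from_table, strand_agreement)


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the discovery pipeline."""

    min_orf_aa: int = 100
    min_len: int = 200
    min_run: int = 5
    snr_threshold: float = 0.6
    strand_alpha: float = 0.01
    corr_threshold: float = 0.9
    de_alpha: float = 0.05
    k: int = 8
    seed: int = 0
    gp_restarts: int = 5
    raw_profiles: bool = False  # step-8/neighbor correlations on raw log profiles
    n_random_pairs: int = 2
    n_perm: int = 10000

    def __post_init__(self) -> None:
        if not (0 < self.strand_alpha < 1 and 0 < self.de_alpha < 1):
            raise ValueError("alpha thresholds must be in (0,1)")
        if not (-1.0 <= self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in [-1,1]")
        for name in ("min_orf_aa", "min_len", "min_run", "k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # derived sub-seeds so each stochastic stage has its own stream
    @property
    def gp_seed(self) -> int:
        return (self.seed * 7919 + 1) % (2 ** 31)

    @property
    def kmeans_seed(self) -> int:
        return (self.seed * 7919 + 2) % (2 ** 31)

    @property
    def random_pair_seed(self) -> int:
        return (self.seed * 7919 + 3) % (2 ** 31)

    @property
    def perm_seed(self) -> int:
        return (self.seed * 7919 + 4) % (2 ** 31)


@dataclass
class PipelineInputs:
    """Everything the funnel consumes; spatial data is optional."""

    candidates: AnnotationSet
    genes: AnnotationSet
    mirnas: AnnotationSet
    sequences: dict[str, str]
    counts: ExpressionMatrix
    stranded: pd.DataFrame
    read_pairs: pd.DataFrame
    spatial: Optional[ExpressionMatrix] = None

    @classmethod
    def from_simulation(cls, sim) -> "PipelineInputs":
        return cls(candidates=sim.candidates, genes=sim.genes, mirnas=sim.mirnas,
                   sequences=sim.sequences, counts=sim.counts, stranded=sim.stranded,
                   read_pairs=sim.read_pairs, spatial=sim.spatial)

    def transcript_lengths(self) -> dict[str, int]:
        out = {m.id: m.length for m in self.candidates}
        out.update({m.id: m.length for m in self.genes})
        return out

    def library_sizes(self) -> Optional[pd.Series]:
        if "library_size" in self.counts.samples.columns:
            return self.counts.samples["library_size"]
        return None


class FunnelSummary:
    """Per-step bookkeeping with conservation checks (n_out = n_in − n_removed)."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, step: str, n_in: int, n_removed: int, subset: str = "all") -> None:
        row = {"step": step, "subset": subset, "n_in": n_in,
               "n_removed": n_removed, "n_out": n_in - n_removed}
        if row["n_out"] < 0:
            raise AssertionError(f"funnel step {step}: negative output count")
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "subset", "n_in", "n_removed", "n_out"])

    def check_conservation(self) -> None:
        for row in self.rows:
            if row["n_out"] != row["n_in"] - row["n_removed"]:
                raise AssertionError(f"funnel step {row['step']}: conservation violated")

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


@dataclass
class PipelineResults:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    funnel: FunnelSummary
    reports: dict[str, "filters.FilterReport"]
    final_lnc: AnnotationSet
    final_multi: list[str]
    final_single: list[str]
    removed_step9: list[str]
    fits: dict[str, gp.GPResults]
    fit_table: pd.DataFrame
    smoothed: pd.DataFrame
    evidence: dict
    agreement_multi: dict
    removal_classes: list[RemovalClass]
    clusters: Optional[ClusterResult] = None
    neighbor_corr: Optional[pd.DataFrame] = None
    random_corr: Optional[pd.DataFrame] = None
    opposing_corr: Optional[pd.DataFrame] = None
    permutation: Optional[dict] = None
    spatial_av: Optional[SpatialDEResults] = None
    spatial_dv: Optional[SpatialDEResults] = None

    def summary(self) -> str:
        lines = [f"lncdyn pipeline run (config {self.config.hash()})", "",
                 str(self.funnel), "",
                 f"final lncRNAs: {len(self.final_multi)} multi-exon + "
                 f"{len(self.final_single)} single-exon = {len(self.final_lnc)}"]
        if self.agreement_multi.get("percent") is not None:
            a = self.agreement_multi
            lines.append(f"assembler strand accuracy (multi-exon, stranded window): "
                         f"{a['percent']}% ({a['n_agree']}/{a['n_expressed']})")
        if self.permutation is not None:
            lines.append(f"neighbor-vs-random correlation shift: "
                         f"{self.permutation['shift']:.3f} (p={self.permutation['p']:.2e})")
        if self.clusters is not None:
            sizes = " ".join(str(v) for v in self.clusters.sizes())
            lines.append(f"temporal clusters (k={self.clusters.k}) sizes: {sizes}")
        for name, res in (("animal/vegetal", self.spatial_av), ("dorsal/ventral", self.spatial_dv)):
            if res is not None:
                e = res.enriched_ids
                lines.append(f"spatial {name}: {len(e[res.condition_a])} + "
                             f"{len(e[res.condition_b])} enriched at p<{res.alpha}")
        return "\n".join(lines)


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig | None = None,
                 run_downstream: bool = True) -> PipelineResults:
    """Execute the discovery funnel (and downstream analyses) on `inputs`."""
    cfg = config or PipelineConfig()
    funnel = FunnelSummary()
    reports: dict[str, filters.FilterReport] = {}
    cands = inputs.candidates

    def apply(step: str, rep, subset="all"):
        nonlocal cands
        rep.check_partition(cands.ids())
        reports[f"{step}_{subset}" if subset != "all" else step] = rep
        funnel.add(step, len(cands), rep.n_removed, subset)
        cands = cands.subset(rep.ids_kept)

    apply("0_intergenic", filters.filter_genic(cands, inputs.genes))
    apply("2_coding_potential", filters.filter_coding(cands, inputs.sequences, cfg.min_orf_aa))
    apply("3_min_length", filters.filter_short(cands, cfg.min_len))
    apply("4_mirna_overlap", filters.filter_mirna_overlap(cands, inputs.mirnas))
    apply("5_collapse", filters.collapse_representatives(cands))
    multi, single = filters.partition_by_exons(cands)
    funnel.add("6_partition_multi", len(cands), len(cands) - len(multi), "multi")
    funnel.add("6_partition_single", len(cands), len(cands) - len(single), "single")

    # step 7a: consecutive expression, per subset
    survivors: dict[str, AnnotationSet] = {}
    for name, sub in (("multi", multi), ("single", single)):
        rep = gp.consecutive_expression_filter(
            inputs.counts.values.loc[sub.ids()], cfg.min_run)
        rep.check_partition(sub.ids())
        reports[f"7a_consecutive_{name}"] = rep
        funnel.add("7a_consecutive", len(sub), rep.n_removed, name)
        survivors[name] = sub.subset(rep.ids_kept)

    # GP fits for surviving candidates and all genes (genes are needed for
    # neighbor correlations); RPKM against the sample-sheet library sizes
    expr = rpkm(inputs.counts, inputs.transcript_lengths(), inputs.library_sizes())
    fit_ids = survivors["multi"].ids() + survivors["single"].ids() \
        + [g.id for g in inputs.genes]
    fits = gp.fit_transcripts(expr.values.loc[fit_ids], expr.times,
                              restarts=cfg.gp_restarts, seed=cfg.gp_seed)
    fit_table = gp.fits_to_frame(fits)
    if cfg.raw_profiles:
        smoothed = pd.DataFrame(
            gp.log2p1(expr.values.loc[fit_ids].to_numpy()),
            index=fit_ids, columns=[f"t{i}" for i in range(expr.values.shape[1])])
    else:
        smoothed = gp.smoothed_profiles(fits)

    # step 7b: SNR screen
    for name in ("multi", "single"):
        sub = survivors[name]
        rep = gp.snr_filter({tid: fits[tid] for tid in sub.ids()}, cfg.snr_threshold)
        rep.check_partition(sub.ids())
        reports[f"7b_snr_{name}"] = rep
        funnel.add("7b_snr", len(sub), rep.n_removed, name)
        survivors[name] = sub.subset(rep.ids_kept)

    # stranded evidence and assembler-agreement bookkeeping
    present = [tid for tid in inputs.stranded.index
               if tid in survivors["multi"].transcripts or tid in survivors["single"].transcripts]
    evidence = evidence_from_table(inputs.stranded.loc[present], alpha=cfg.strand_alpha)
    agreement_multi = strand_agreement(
        {m.id: m.strand for m in survivors["multi"]},
        {tid: ev for tid, ev in evidence.items() if tid in survivors["multi"].transcripts})

    # steps 8 and 9 per subset
    removal_classes: list[RemovalClass] = []
    removed_step9: list[str] = []
    for name in ("multi", "single"):
        sub = survivors[name]
        nbrs = neighbor_table(sub, inputs.genes)
        rep8, classes = correlated_neighbor_filter(
            sub, inputs.genes, smoothed, nbrs, evidence, cfg.corr_threshold)
        rep8.check_partition(sub.ids())
        reports[f"8_correlated_neighbor_{name}"] = rep8
        funnel.add("8_correlated_neighbor", len(sub), rep8.n_removed, name)
        removal_classes.extend(classes)
        sub = sub.subset(rep8.ids_kept)

        nbrs = {tid: nbrs[tid] for tid in sub.ids()}
        rep9 = bridging_read_filter(sub, inputs.genes, inputs.read_pairs, nbrs)
        rep9.check_partition(sub.ids())
        reports[f"9_bridging_{name}"] = rep9
        funnel.add("9_bridging", len(sub), rep9.n_removed, name)
        removed_step9.extend(rep9.ids_removed)
        survivors[name] = sub.subset(rep9.ids_kept)

    funnel.check_conservation()
    final_multi = survivors["multi"].ids()
    final_single = survivors["single"].ids()
    final = AnnotationSet.from_models(
        list(survivors["multi"]) + list(survivors["single"]))

    results = PipelineResults(
        config=cfg, funnel=funnel, reports=reports, final_lnc=final,
        final_multi=final_multi, final_single=final_single,
        removed_step9=removed_step9, fits=fits, fit_table=fit_table,
        smoothed=smoothed, evidence=evidence, agreement_multi=agreement_multi,
        removal_classes=removal_classes,
    )
    if not run_downstream:
        return results

    # temporal clustering of the final set (max-normalized smoothed profiles)
    final_profiles = smoothed.loc[[t for t in final.ids() if t in smoothed.index]]
    normalized, _dropped = max_normalize(final_profiles)
    if len(normalized) >= cfg.k:
        results.clusters = cluster_profiles(normalized, k=cfg.k, seed=cfg.kmeans_seed)

    # neighbor correlation and permutation analysis
    nbrs_final = neighbor_table(final, inputs.genes)
    results.neighbor_corr = pair_correlations(final, inputs.genes, smoothed,
                                              nbrs_final, "neighbor")
    results.random_corr = pair_correlations(final, inputs.genes, smoothed, nbrs_final,
                                            "random", n_random=cfg.n_random_pairs,
                                            seed=cfg.random_pair_seed)
    strands = {tid: (evidence[tid].call if tid in evidence
                     and evidence[tid].call != "undetermined"
                     else final[tid].strand if final[tid].n_exons >= 2 else "unknown")
               for tid in final.ids()}
    results.opposing_corr = pair_correlations(final, inputs.genes, smoothed, nbrs_final,
                                              "opposing_neighbor", lnc_strands=strands)
    if len(results.neighbor_corr) and len(results.random_corr):
        shift, p = permutation_shift_test(results.neighbor_corr["r"].values,
                                          results.random_corr["r"].values,
                                          n_perm=cfg.n_perm, seed=cfg.perm_seed)
        results.permutation = {"shift": shift, "p": p, "n_perm": cfg.n_perm,
                               "n_neighbor": len(results.neighbor_corr),
                               "n_random": len(results.random_corr)}

    # spatial contrasts on the final lncRNA set
    if inputs.spatial is not None:
        sp = inputs.spatial
        ids = [t for t in final.ids() if t in sp.values.index]
        regions = sp.samples.loc[sp.values.columns, "region"]
        for attr, (a, b) in (("spatial_av", ("animal", "vegetal")),
                             ("spatial_dv", ("dorsal", "ventral"))):
            cols = regions.isin([a, b])
            if cols.sum() >= 4 and len(ids):
                model = SpatialDEModel(sp.values.loc[ids, cols.index[cols]],
                                       regions[cols], a, b)
                setattr(results, attr, model.fit(alpha=cfg.de_alpha))
    return results
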