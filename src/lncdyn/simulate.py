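"""Synthetic toy genome and data generator with planted ground truth.

Emulates the inputs of the discovery pipeline so every stage can be tested
end-to-end without downloads: a small multi-chromosome genome carrying
coding genes, intergenic true lncRNAs, "unannotated exon" decoys riding
their host gene's expression, and coding decoys hiding a long ORF; a dense
90-timepoint expression time course over 0–66 h drawn from Matérn-5/2 GPs
around maternal/zygotic archetype mean curves; stranded read counts for the
early (< 9 h) window; bridging read pairs physically linking a fraction of
the exon decoys to their hosts; and a two-axis spatial dissection count
matrix (animal/vegetal, dorsal/ventral) with replicates and planted
fold-changes.

Everything is driven by one integer seed; a fixed config is a fixed dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .filters import longest_orf_aa
from .genome import AnnotationSet, TranscriptModel
from .gp import matern52_gram
from .profiles import ExpressionMatrix

REGIONS = ("animal", "vegetal", "dorsal", "ventral")

_NON_STOP_CODONS = [a + b + c
                    for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in ("TAA", "TAG", "TGA")]


class LayoutError(ValueError):
    """The requested annotation does not fit in the configured genome."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    The defaults mirror the real study's shape: 90 timepoints over 66 h,
    eight temporal archetypes split between maternal and zygotic behavior,
    stranded data confined to the first 9 h with reads favoring the true
    strand at 0.95, and four dissected regions with 3 replicates each.
    """

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_coding: int = 80
    n_true_lnc: int = 50
    n_exon_decoys: int = 20
    n_coding_decoys: int = 20
    n_mirna: int = 8
    n_cis_lnc: int = 20  # subset of true lncRNAs co-expressed with a neighbor, opposite strand
    # time course
    n_timepoints: int = 90
    t_max: float = 66.0
    archetype_mix: tuple = (0.125,) * 8
    # GP hyperparameter ranges for planted transcripts (natural-log units);
    # the wiggle stays below the archetype amplitude so expression rarely
    # crosses zero, where the count floor would truncate the signal
    sigma_f2_range: tuple = (0.3, 1.0)
    snr_range: tuple = (1.0, 3.0)
    tau_range: tuple = (4.0, 10.0)
    amplitude_range: tuple = (2.0, 3.5)
    basal_log_expression: float = 0.3
    # counts: library size is the genome-wide normalization constant (total
    # mapped reads); the simulated transcripts are a small subset of it
    library_size: int = 20_000_000
    # decoys / strand evidence
    exon_decoy_noise_sd: float = 0.1
    cis_noise_sd: float = 0.15
    bridge_fraction: float = 0.5
    bridge_pairs_per_decoy: int = 3
    n_background_pairs: int = 50
    stranded_window_h: float = 9.0
    stranded_accuracy: float = 0.95
    stranded_depth: float = 3.0
    assembler_accuracy: float = 0.77
    # spatial design
    n_replicates: int = 3
    spatial_log2fc: float = 2.0
    n_spatial: dict = field(default_factory=lambda: {
        "animal": 8, "vegetal": 8, "dorsal": 3, "ventral": 3})
    spatial_dispersion: float = 0.1
    spatial_mean_range: tuple = (50.0, 800.0)

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")
        for name in ("n_chroms", "n_coding", "n_true_lnc", "n_exon_decoys",
                     "n_coding_decoys", "n_mirna", "n_timepoints"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cis_lnc > self.n_true_lnc:
            raise ValueError("n_cis_lnc cannot exceed n_true_lnc")
        if self.n_exon_decoys > self.n_coding:
            raise LayoutError("each exon decoy needs its own host gene")

    @property
    def timepoints(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_timepoints)


@dataclass
class Simulation:
    """All generated artifacts plus the ground truth."""

    config: SimulationConfig
    candidates: AnnotationSet
    genes: AnnotationSet
    mirnas: AnnotationSet
    sequences: dict[str, str]
    counts: ExpressionMatrix
    stranded: pd.DataFrame        # index id; plus_reads, minus_reads
    read_pairs: pd.DataFrame
    spatial: ExpressionMatrix
    truth: pd.DataFrame           # index id; label, strand, archetype, ...

    def transcript_lengths(self) -> dict[str, int]:
        out = {m.id: m.length for m in self.candidates}
        out.update({m.id: m.length for m in self.genes})
        return out

    def write(self, outdir) -> None:
        """Write every artifact in the plain-text formats the pipeline reads."""
        import os
        from .genome import write_gtf
        os.makedirs(outdir, exist_ok=True)
        join = lambda n: os.path.join(outdir, n)
        write_gtf(self.candidates, join("candidates.gtf"))
        write_gtf(self.genes, join("genes.gtf"))
        with open(join("mirnas.bed"), "w") as fh:
            for m in self.mirnas:
                s, e = m.exons[0]
                strand = m.strand if m.strand in "+-" else "."
                fh.write(f"{m.chrom}\t{s - 1}\t{e}\t{m.id}\t0\t{strand}\n")
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        SeqIO.write((SeqRecord(Seq(seq), id=tid, description="")
                     for tid, seq in self.sequences.items()),
                    join("candidates.fa"), "fasta")
        self.counts.to_tsv(join("counts.tsv"), join("samples.tsv"))
        self.stranded.to_csv(join("stranded_counts.tsv"), sep="\t", index_label="transcript_id")
        self.read_pairs.to_csv(join("read_pairs.tsv"), sep="\t", index=False)
        self.spatial.to_tsv(join("spatial_counts.tsv"), join("spatial_samples.tsv"))
        self.truth.to_csv(join("ground_truth.tsv"), sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# temporal archetypes
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def archetype_mean(archetype: int, t: np.ndarray, amplitude: float,
                   shift: float = 0.0) -> np.ndarray:
    """Mean log-expression curve for one of the 8 temporal archetypes.

    1: maternal, cleared at zygotic genome activation; 2: maternal,
    persisting; 3–5: zygotic transient with increasingly later peaks;
    6–8: zygotic persistent with increasingly later activation. `shift`
    jitters the characteristic time per transcript (hours).
    """
    if archetype == 1:
        return amplitude * (1.0 - _sigmoid((t - (7.0 + shift)) / 2.5))
    if archetype == 2:
        return amplitude * (1.0 - 0.35 * _sigmoid((t - (8.0 + shift)) / 3.0))
    if archetype in (3, 4, 5):
        peak = {3: 18.0, 4: 30.0, 5: 42.0}[archetype] + shift
        return amplitude * np.exp(-((t - peak) / 6.0) ** 2)
    if archetype in (6, 7, 8):
        onset = {6: 10.0, 7: 22.0, 8: 34.0}[archetype] + shift
        return amplitude * _sigmoid((t - onset) / 3.0)
    raise ValueError("archetype must be 1..8")


def archetype_profile_fixture(n_per_archetype: int = 30, noise_sd: float = 0.05,
                              n_timepoints: int = 90, t_max: float = 66.0,
                              seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Max-normalized profiles with known archetype labels, for clustering checks."""
    t = np.linspace(0.0, t_max, n_timepoints)
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for a in range(1, 9):
        for i in range(n_per_archetype):
            m = archetype_mean(a, t, amplitude=1.0, shift=rng.uniform(-1.5, 1.5))
            m = m + rng.normal(0.0, noise_sd, size=t.size)
            m = m - m.min()
            mx = m.max()
            rows.append(m / mx if mx > 0 else m)
            labels.append(a)
    ids = [f"p{i}" for i in range(len(rows))]
    profiles = pd.DataFrame(rows, index=ids, columns=[f"t{i}" for i in range(n_timepoints)])
    return profiles, pd.Series(labels, index=ids, name="archetype")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def noncoding_sequence(rng: np.random.Generator, length: int,
                       max_orf_aa: int = 99, max_tries: int = 200) -> str:
    """Random sequence guaranteed to contain no ORF longer than `max_orf_aa`."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if longest_orf_aa(seq, strand="unknown") <= max_orf_aa:
            return seq
    raise RuntimeError("could not generate an ORF-free sequence")


def coding_sequence(rng: np.random.Generator, length: int, orf_aa: int) -> str:
    """Random sequence with a planted ATG…stop ORF of `orf_aa` amino acids."""
    orf_nt = 3 * (orf_aa + 1)  # incl. stop codon
    if orf_nt + 6 > length:
        raise ValueError("transcript too short for requested ORF")
    body = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=orf_aa - 1)) + "TAA"
    utr5 = noncoding_sequence(rng, max(0, (length - orf_nt) // 2))
    utr3 = noncoding_sequence(rng, length - orf_nt - len(utr5))
    # keep the planted frame: pad the 5' UTR to a codon boundary is not
    # needed because ORF detection scans every frame
    return utr5 + body + utr3


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, exon_lengths: list[int],
                intron_range=(200, 800)) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el - 1))
        pos += el + int(rng.integers(*intron_range))
    return tuple(exons)


def simulate(config: SimulationConfig) -> Simulation:
    """Generate the full synthetic dataset for `config` (fully seeded)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t = cfg.timepoints

    # ---- assign intergenic items to inter-gene slots -----------------------
    items = ([("lnc", i) for i in range(cfg.n_true_lnc)]
             + [("cdecoy", i) for i in range(cfg.n_coding_decoys)]
             + [("mirna", i) for i in range(cfg.n_mirna)])
    if len(items) > cfg.n_coding:
        raise LayoutError(
            f"{len(items)} intergenic features need at least as many coding genes "
            f"(have {cfg.n_coding})")
    slot_of = {i: items[i] for i in range(len(items))}
    slot_perm = rng.permutation(cfg.n_coding)
    item_at_slot: dict[int, tuple] = {}
    for rank, slot in enumerate(slot_perm[:len(items)]):
        item_at_slot[int(slot)] = slot_of[rank]
    decoy_hosts = set(int(g) for g in rng.permutation(cfg.n_coding)[:cfg.n_exon_decoys])

    genes = AnnotationSet()
    candidates = AnnotationSet()
    mirnas = AnnotationSet()
    sequences: dict[str, str] = {}
    truth_rows: dict[str, dict] = {}
    host_of_decoy: dict[str, str] = {}
    lnc_flanks: dict[str, tuple[str, str]] = {}

    cis_idx = set(int(i) for i in rng.choice(cfg.n_true_lnc, size=cfg.n_cis_lnc,
                                              replace=False)) if cfg.n_cis_lnc else set()

    cursors = {f"chr{c + 1}": 1000 for c in range(cfg.n_chroms)}
    prev_gene_on_chrom: dict[str, Optional[str]] = {c: None for c in cursors}
    decoy_counter = 0

    for g_idx in range(cfg.n_coding):
        chrom = f"chr{(g_idx % cfg.n_chroms) + 1}"
        cursor = cursors[chrom]
        # coding gene: 3 exons
        exon_lengths = [int(rng.integers(300, 600)) for _ in range(3)]
        exons = _make_exons(rng, cursor, exon_lengths)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{g_idx:03d}"
        gene = TranscriptModel(id=gid, chrom=chrom, strand=strand,
                               exons=exons, biotype="coding")
        genes.add(gene)
        truth_rows[gid] = {"label": "coding", "strand": strand}
        cursor = gene.end + 1

        if g_idx in decoy_hosts:
            # unannotated-exon decoy: 2-exon fragment just downstream of the host
            did = f"xdecoy{decoy_counter:03d}"
            decoy_counter += 1
            dstart = cursor + int(rng.integers(150, 400))
            dexons = _make_exons(rng, dstart, [int(rng.integers(120, 250)) for _ in range(2)],
                                 intron_range=(150, 400))
            decoy = TranscriptModel(id=did, chrom=chrom, strand=strand,
                                    exons=dexons, biotype="candidate")
            candidates.add(decoy)
            host_of_decoy[did] = gid
            truth_rows[did] = {"label": "exon_decoy", "strand": strand, "host": gid}
            cursor = decoy.end + 1

        item = item_at_slot.get(g_idx)
        gap = int(rng.integers(2500, 6000))
        if item is not None:
            kind, idx = item
            istart = cursor + gap
            if kind == "lnc":
                lid = f"lnc{idx:03d}"
                true_strand = "+" if rng.random() < 0.5 else "-"
                # cis-regulatory antisense lncRNAs are modeled single-exon;
                # others are a single/multi mix
                if idx not in cis_idx and rng.random() < 0.4:
                    lex = [int(rng.integers(150, 500)), int(rng.integers(150, 500))]
                else:
                    lex = [int(rng.integers(300, 1000))]
                lexons = _make_exons(rng, istart, lex)
                lnc = TranscriptModel(id=lid, chrom=chrom, strand="unknown",
                                      exons=lexons, biotype="candidate")
                candidates.add(lnc)
                truth_rows[lid] = {"label": "true_lnc", "strand": true_strand}
                lnc_flanks[lid] = (f"gene{g_idx:03d}", None)
            elif kind == "cdecoy":
                cid = f"cdecoy{idx:03d}"
                true_strand = "+" if rng.random() < 0.5 else "-"
                clen = int(rng.integers(600, 1000))
                cexons = _make_exons(rng, istart, [clen])
                cd = TranscriptModel(id=cid, chrom=chrom, strand="unknown",
                                     exons=cexons, biotype="candidate")
                candidates.add(cd)
                truth_rows[cid] = {"label": "coding_decoy", "strand": true_strand}
            else:
                mid = f"mir{idx:03d}"
                mstart = istart
                mirnas.add(TranscriptModel(id=mid, chrom=chrom, strand="+",
                                           exons=((mstart, mstart + 80),), biotype="miRNA"))
                truth_rows[mid] = {"label": "mirna", "strand": "+"}
            last = (candidates[lid] if kind == "lnc"
                    else candidates[cid] if kind == "cdecoy" else mirnas[mid])
            cursor = last.end + 1 + gap
        else:
            cursor += gap
        cursors[chrom] = cursor
        if cursor >= cfg.chrom_length:
            raise LayoutError(
                f"{chrom} overflows ({cursor} > {cfg.chrom_length}); increase "
                "chrom_length or n_chroms, or reduce feature counts")

    # right-hand flank of each lncRNA = next gene placed on its chromosome
    gene_list = sorted(genes, key=lambda g: (g.chrom, g.start))
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lid, (left, _) in list(lnc_flanks.items()):
        lnc = candidates[lid]
        right = next((g.id for g in by_chrom.get(lnc.chrom, []) if g.start > lnc.end), None)
        lnc_flanks[lid] = (left, right)

    # ---- sequences --------------------------------------------------------
    for m in candidates:
        lab = truth_rows[m.id]["label"]
        if lab == "coding_decoy":
            orf_aa = int(rng.integers(110, 180))
            sequences[m.id] = coding_sequence(rng, m.length, orf_aa)
            truth_rows[m.id]["orf_aa"] = orf_aa
        else:
            sequences[m.id] = noncoding_sequence(rng, m.length)

    # ---- temporal profiles on the natural-log concentration scale ---------
    mix = np.asarray(cfg.archetype_mix, dtype=float)
    all_ids = [g.id for g in genes] + [c.id for c in candidates]

    log_profiles: dict[str, np.ndarray] = {}
    gp_params: dict[str, tuple[float, float, float]] = {}
    archetypes: dict[str, int] = {}

    def draw_profile(tid: str) -> None:
        a = int(rng.choice(np.arange(1, 9), p=mix))
        amp = rng.uniform(*cfg.amplitude_range)
        shift = rng.uniform(-4.0, 4.0)
        sf2 = rng.uniform(*cfg.sigma_f2_range)
        snr = rng.uniform(*cfg.snr_range)
        sn2 = sf2 / math.exp(snr)
        tau = rng.uniform(*cfg.tau_range)
        mean = cfg.basal_log_expression + archetype_mean(a, t, amp, shift)
        K = matern52_gram(t, sf2, tau)
        wiggle = np.linalg.cholesky(K + 1e-10 * np.eye(len(t))) @ rng.standard_normal(len(t))
        noise = rng.normal(0.0, math.sqrt(sn2), size=len(t))
        log_profiles[tid] = mean + wiggle + noise
        gp_params[tid] = (sf2, tau, sn2)
        archetypes[tid] = a

    for g in genes:
        draw_profile(g.id)

    lnc_ids = [c.id for c in candidates if truth_rows[c.id]["label"] == "true_lnc"]
    cis_ids = [f"lnc{i:03d}" for i in sorted(cis_idx) if f"lnc{i:03d}" in candidates.transcripts]
    cis_ids_set = set(cis_ids)
    for c in candidates:
        lab = truth_rows[c.id]["label"]
        if lab == "exon_decoy":
            host = host_of_decoy[c.id]
            log_profiles[c.id] = (log_profiles[host]
                                  + rng.normal(0.0, cfg.exon_decoy_noise_sd, size=len(t)))
            gp_params[c.id] = gp_params[host]
            archetypes[c.id] = archetypes[host]
        elif c.id in cis_ids_set:
            left, right = lnc_flanks[c.id]
            partner = left if (right is None or rng.random() < 0.5) else right
            log_profiles[c.id] = (log_profiles[partner]
                                  + rng.normal(0.0, cfg.cis_noise_sd, size=len(t)))
            gp_params[c.id] = gp_params[partner]
            archetypes[c.id] = archetypes[partner]
            # opposite strand to the co-expressed neighbor: a cis-regulatory
            # pair, not an unannotated exon
            partner_strand = genes[partner].strand
            truth_rows[c.id]["strand"] = "-" if partner_strand == "+" else "+"
            truth_rows[c.id]["cis_partner"] = partner
        else:
            draw_profile(c.id)

    # ---- counts -----------------------------------------------------------
    lengths = {m.id: m.length for m in genes}
    lengths.update({m.id: m.length for m in candidates})
    # the planted log profile is log(RPKM + 1): counts are its exact RPKM
    # inverse at each transcript's length and the library size, so the
    # fitting transform recovers the planted GP up to a 1/ln2 rescaling
    conc = np.vstack([np.maximum(np.expm1(log_profiles[tid]), 0.0) for tid in all_ids])
    len_kb = np.array([lengths[tid] for tid in all_ids])[:, None] / 1e3
    counts = np.rint(conc * len_kb * (cfg.library_size / 1e6)).astype(int)
    sample_ids = [f"tp{i:02d}" for i in range(cfg.n_timepoints)]
    counts_df = pd.DataFrame(counts, index=all_ids, columns=sample_ids)
    samples = pd.DataFrame({"time": t,
                            "library_size": cfg.library_size},
                           index=pd.Index(sample_ids, name="sample_id"))
    counts_em = ExpressionMatrix(counts_df, samples, units="counts")

    # ---- assembler strand calls on candidates ------------------------------
    for c in candidates:
        lab = truth_rows[c.id]["label"]
        true_strand = truth_rows[c.id]["strand"]
        if c.n_exons == 1:
            asm = "unknown"
        elif lab == "exon_decoy":
            # splice junctions are the host's: the assembler gets these right
            asm = true_strand
        else:
            correct = rng.random() < cfg.assembler_accuracy
            asm = true_strand if correct else ("-" if true_strand == "+" else "+")
        if asm != c.strand:
            object.__setattr__(c, "strand", asm)
        truth_rows[c.id]["assembler_strand"] = asm

    # ---- stranded counts (first 9 h window) --------------------------------
    early = t < cfg.stranded_window_h
    rpkm_vals = counts / len_kb / (cfg.library_size / 1e6)
    early_mean = rpkm_vals[:, early].mean(axis=1)
    stranded_rows = {}
    for i, tid in enumerate(all_ids):
        if tid not in candidates.transcripts:
            continue
        total = int(rng.poisson(cfg.stranded_depth * early_mean[i]))
        true_strand = truth_rows[tid]["strand"]
        toward_plus = cfg.stranded_accuracy if true_strand == "+" else 1 - cfg.stranded_accuracy
        plus = int(rng.binomial(total, toward_plus)) if total else 0
        stranded_rows[tid] = {"plus_reads": plus, "minus_reads": total - plus}
    stranded = pd.DataFrame.from_dict(stranded_rows, orient="index")
    stranded.index.name = "transcript_id"

    # ---- read pairs --------------------------------------------------------
    pair_rows = []
    bridged = []
    decoy_ids = sorted(host_of_decoy)
    n_bridged = int(round(cfg.bridge_fraction * len(decoy_ids)))
    bridged = list(rng.choice(decoy_ids, size=n_bridged, replace=False)) if n_bridged else []
    read_counter = 0

    def _interval_in(exon, width=60):
        s, e = exon
        w = min(width, e - s + 1)
        start = int(rng.integers(s, e - w + 2))
        return start, start + w - 1

    for did in bridged:
        decoy = candidates[did]
        host = genes[host_of_decoy[did]]
        for _ in range(cfg.bridge_pairs_per_decoy):
            m1 = _interval_in(decoy.exons[0])
            m2 = _interval_in(host.exons[-1])
            pair_rows.append({"read_id": f"rp{read_counter:05d}",
                              "chrom1": decoy.chrom, "start1": m1[0], "end1": m1[1],
                              "chrom2": host.chrom, "start2": m2[0], "end2": m2[1]})
            read_counter += 1
        truth_rows[did]["bridged"] = True
    for did in decoy_ids:
        truth_rows[did].setdefault("bridged", False)
    # background pairs: both mates within one transcript
    pool = [genes[g.id] for g in genes] + [candidates[c] for c in candidates.ids()]
    for _ in range(cfg.n_background_pairs):
        m = pool[int(rng.integers(len(pool)))]
        exon = m.exons[int(rng.integers(m.n_exons))]
        m1 = _interval_in(exon)
        m2 = _interval_in(exon)
        pair_rows.append({"read_id": f"rp{read_counter:05d}",
                          "chrom1": m.chrom, "start1": m1[0], "end1": m1[1],
                          "chrom2": m.chrom, "start2": m2[0], "end2": m2[1]})
        read_counter += 1
    read_pairs = pd.DataFrame(pair_rows, columns=["read_id", "chrom1", "start1", "end1",
                                                  "chrom2", "start2", "end2"])

    # ---- spatial counts ----------------------------------------------------
    n_spatial_total = sum(cfg.n_spatial.values())
    non_cis = [l for l in lnc_ids if l not in cis_ids]
    pool_sp = non_cis + cis_ids  # prefer non-cis for spatial labels, then cis
    if n_spatial_total > len(lnc_ids):
        raise LayoutError("more spatially enriched lncRNAs requested than true lncRNAs")
    order = list(rng.permutation(pool_sp))
    spatial_label: dict[str, str] = {}
    k = 0
    for region in REGIONS:
        for _ in range(cfg.n_spatial.get(region, 0)):
            spatial_label[order[k]] = region
            k += 1
    sp_samples = []
    for region in REGIONS:
        for rep in range(1, cfg.n_replicates + 1):
            sp_samples.append((f"{region}_{rep}", region, rep))
    sp_index = [s[0] for s in sp_samples]
    base_mean = np.exp(rng.uniform(np.log(cfg.spatial_mean_range[0]),
                                   np.log(cfg.spatial_mean_range[1]), size=len(all_ids)))
    fc = 2.0 ** cfg.spatial_log2fc
    disp = cfg.spatial_dispersion
    r_nb = 1.0 / disp
    sp_counts = np.zeros((len(all_ids), len(sp_samples)), dtype=int)
    for j, (_, region, _rep) in enumerate(sp_samples):
        mu = base_mean.copy()
        for i, tid in enumerate(all_ids):
            if spatial_label.get(tid) == region:
                mu[i] = base_mean[i] * fc
        p_nb = r_nb / (r_nb + mu)
        sp_counts[:, j] = rng.negative_binomial(r_nb, p_nb)
    spatial_df = pd.DataFrame(sp_counts, index=all_ids, columns=sp_index)
    sp_meta = pd.DataFrame({"region": [s[1] for s in sp_samples],
                            "replicate": [s[2] for s in sp_samples]},
                           index=pd.Index(sp_index, name="sample_id"))
    spatial_em = ExpressionMatrix(spatial_df, sp_meta, units="counts")

    # ---- ground truth ------------------------------------------------------
    for tid in all_ids:
        row = truth_rows[tid]
        row.setdefault("host", "")
        row.setdefault("cis_partner", "")
        row.setdefault("assembler_strand", truth_rows[tid].get("strand", "unknown"))
        row["archetype"] = archetypes.get(tid, 0)
        row["spatial"] = spatial_label.get(tid, "none")
        sf2, tau, sn2 = gp_params.get(tid, (np.nan, np.nan, np.nan))
        row["sigma_f2"], row["tau"], row["sigma_n2"] = sf2, tau, sn2
    for m in mirnas:
        truth_rows[m.id].setdefault("archetype", 0)
        truth_rows[m.id].setdefault("spatial", "none")
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index.name = "transcript_id"
    cols = ["label", "strand", "assembler_strand", "host", "cis_partner", "bridged",
            "orf_aa", "archetype", "spatial", "sigma_f2", "tau", "sigma_n2"]
    for c in cols:
        if c not in truth.columns:
            truth[c] = np.nan
    truth = truth[cols]
    truth["bridged"] = [bool(v) if pd.notna(v) else False for v in truth["bridged"]]
    truth["host"] = truth["host"].fillna("")
    truth["cis_partner"] = truth["cis_partner"].fillna("")

    return Simulation(config=cfg, candidates=candidates, genes=genes, mirnas=mirnas,
                      sequences=sequences, counts=counts_em, stranded=stranded,
                      read_pairs=read_pairs, spatial=spatial_em, truth=truth)
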