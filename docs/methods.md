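# Methods

`lncdyn` implements a discovery funnel for intergenic long non-coding RNAs
(lncRNAs) from a dense developmental RNA-seq time course, plus the three
downstream analyses that characterize the surviving catalogue: temporal
clustering, neighbor-correlation permutation analysis, and spatial
differential expression across dissected embryo regions. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic-data results do and do not demonstrate.

## The discovery funnel

Candidates (assembled transcript models) pass through, in order:

0. **Intergenic pre-filter** — genomic-span overlap with any coding gene
   removes the candidate.
1. *(assembly — out of scope; candidates are an input)*
2. **Coding potential** — a candidate whose longest ATG-initiated,
   stop-terminated open reading frame reaches **100 aa** is removed. The ORF
   rule counts the initiator Met, excludes the stop, and scans 3 frames when
   the strand is known, 6 when unknown (most single-exon candidates carry no
   strand call).
3. **Length** — exonic length **< 200 nt** removes the candidate (the
   defining lncRNA length rule; exonic sum, not genomic span).
4. **miRNA overlap** — exon overlap with an annotated miRNA locus removes
   the candidate, strand-unaware (candidate strands are mostly unknown at
   this stage).
5. **Representative collapsing** — connected components under pairwise
   exon overlap keep one model each: longest exonic length, then more exons,
   then lexicographically smallest id. (The original selection rule is
   unstated; this deterministic ordering is our declared choice.)
6. **Partition** — multi-exon (≥ 2 exons) and single-exon candidates run
   through the remaining steps separately.
7. **Temporal screens** — (a) at least **5 consecutive timepoints** with
   counts > 0; "expressed" is taken as a raw count above zero, not an RPKM
   floor. (b) the GP signal-to-noise screen, **SNR > 0.6** strictly (below).
8. **Correlated same-strand neighbor** — Pearson r **> 0.9** (strict) with
   either flanking gene's smoothed profile *and* matching strand removes the
   candidate. The candidate's strand is the stranded-evidence call when the
   binomial test is decisive (removal labelled *class 1*), else the
   assembler's call for multi-exon models (*class 2*); single-exon assembler
   calls are treated as unknown because splice-junction-free strand guesses
   are no better than random. Both neighbors are tested; either can trip the
   rule. Correlations are computed on GP posterior means on the log2 scale
   (a `raw_profiles` switch uses raw log2 profiles instead).
9. **Bridging read pairs** — any paired-end fragment (multi-mappers
   included) with one mate in the candidate's exons and the other in an
   adjacent gene's exons removes the candidate; one pair suffices. Step-9
   removals are reported separately because the rule is deliberately
   over-stringent and can discard genuine lncRNAs.

Filters 2–4 commute; the fixed order exists so per-step counts are
comparable across runs. Every step emits a kept/removed partition that is
checked for conservation.

## Gaussian-process screen

Each transcript's time course is RPKM-normalized
(count / (length_kb × library_size_millions); the library size is the
genome-wide normalization constant carried on the sample sheet), transformed
to log2(RPKM + 1) — the transform stabilizes variance across the dynamic
range; the original work does not state its transform — and modelled as a GP
with covariance

    k(r) = σf² (1 + √5 r/τ + 5 r²/(3τ²)) exp(−√5 r/τ) + σm²,  r = |t − t′|,

plus i.i.d. Gaussian noise σn². The Matérn ν = 5/2 form gives
twice-differentiable sample paths — smooth but not unrealistically rigid for
expression kinetics. σf² (signal variance) tracks the scale of genuine
temporal change, τ (timescale, hours) how fast expression can change, σn²
the sampling noise. The constant "level" component σm² absorbs the mean
expression level; modelling the mean this way rather than subtracting the
sample mean matters because at long timescales the sample mean contains a
large share of the signal, and subtracting it biases σf² (and the SNR) down
by ~0.4 on the natural-log scale.

Hyperparameters maximize the exact log marginal likelihood by L-BFGS-B over
log-parameters with analytic gradients, 5 starts (one data-driven, four
seeded log-uniform draws), bounds σf², σn² ∈ [1e−6, 1e4], τ ∈ [0.25, 132] h
(a fraction of the sampling interval to twice the 66 h span). A transcript
is kept when

    SNR = log(σf²/σn²) > 0.6   (natural log, strict).

SNR is scale-free: both variances scale together under rescaling of the
series, so the screen does not simply reward high expression — the design
rationale for preferring it over an absolute expression floor. Failed fits
(all starts diverge) are excluded downstream with a `fit_failure` reason.

**Estimator granularity.** On 90 evenly spaced points over 66 h, the
Cramér–Rao bound for sd(SNR) is ≈ 0.43 at τ = 3 h and ≈ 0.65–0.69 at
τ = 10 h — a 10 h timescale leaves only ~7 effectively independent signal
fluctuations in the window. Maximum likelihood attains roughly this floor
with a small negative bias, so the median absolute SNR error is ~0.3
(short timescales) to ~0.5 (long); the 0.6 threshold should be read with
that granularity. A Fisher-information-based debiasing of the log-variances
was prototyped and rejected: evaluated at noisy estimates it overcorrects
asymmetrically.

Posterior summaries use the fitted kernel including the level component;
the 95% band is predictive, mean ± 1.96·√(posterior variance + σn²).
Prediction is on the observation grid (filtering needs no super-resolution).

## Strand assignment

Stranded libraries cover only the first 9 h of the course. Per transcript,
an exact two-sided binomial test (min(1, 2·min-tail)) on plus/minus read
counts against p = 0.5 yields a call when p < 0.01 (strict) and the majority
strand is unique; zero totals are undetermined without a test. Calls are
symmetric under strand swap. Assembler agreement is summarized as
round(100·n_agree/n_determined) over transcripts detectably expressed in the
stranded window.

## Temporal clustering

Final-catalogue profiles (GP posterior means, log2 scale) are divided by
their row maxima — all-zero rows are excluded and logged — and clustered by
Euclidean k-means, k = 8, k-means++ seeding, 25 restarts, fixed seed.
Distance, initialization and restart count are unstated in the original
analysis; these are our declared defaults. Clusters are renumbered by
ascending centroid peak time (ties by centroid mean) so cluster 1 is the
earliest maternal shape and labels are reproducible.

## Neighbor-correlation permutation analysis

For each lncRNA, Pearson correlations with its ≤ 2 flanking genes
("upstream/downstream" in genome coordinates — strand-relative directions
are undefined for unknown-strand candidates; closest gene by genomic-span
gap, unbounded search, overlap distance 0) are compared with correlations
against genes sampled uniformly from non-neighbors. The quantification is a
mean-shift permutation test: observed shift = mean(neighbor r) −
mean(random r); the null pools both samples and re-splits at the original
sizes 10 000 times; one-sided p = (1 + #{shift* ≥ shift})/(1 + n_perm). The
original figures show the two distributions without naming a statistic; the
mean-shift with a pooled null is our declared quantification, and both
distributions are emitted for plotting. An opposing-strand subset (known,
opposite strands only) controls for unrecognized-exon contamination:
correlation that persists there cannot come from a candidate being a
same-strand fragment of its neighbor.

## Spatial differential expression

Dissected-region counts (animal/vegetal for ectoderm/endoderm,
dorsal/ventral for mesoderm subregions; two independent contrasts on their
own replicate sets) are analyzed with a voom-style precision-weighted
moderated t-test, re-implemented rather than called:

- log-cpm = log2((count + 0.5)/(libsize + 1) × 1e6);
- per-transcript OLS residual sd; lowess (span 0.5) of √sd against mean
  log2 count; weights are the inverse fourth power of the trend value at
  each observation's fitted log-count (floored at 1e−4 so weights stay
  finite on degenerate inputs);
- weighted least squares per transcript; empirical-Bayes shrinkage
  s̃² = (d0·s0² + d·s²)/(d0 + d), with (d0, s0²) by moment matching on
  log s² (trigamma inversion by Newton; a spread at the χ²_d noise floor
  yields d0 = ∞, the common-variance limit);
- moderated t referred to t with d0 + d degrees of freedom; enrichment at
  **unadjusted p < 0.05** with the fold-change sign choosing the side —
  deliberately mirroring the original analysis; a `fdr` flag adds
  Benjamini–Hochberg but is off by default.

Against Bioconductor limma-voom on the same counts the implementation
agrees to |Δlog2FC| < 3e−4 and p-value rank correlation > 0.999 (asserted,
loosely, in the test suite); exact numerical parity is not a goal.

## Synthetic data: what it emulates and what it does not

The generator plants a complete, fully seeded ground truth:

- **Genome** — 4 chromosomes × 2 Mb carrying 80 three-exon coding genes and,
  between them, 50 true lncRNAs (singles and 2-exon models, ≥ 200 nt,
  ORF-free on both strands), 20 coding decoys (intergenic candidates hiding
  a 110–180 aa ORF; must die at step 2), 20 "unannotated exon" decoys
  (2-exon fragments 150–400 bp downstream of a host gene, same strand,
  expression = host ± N(0, 0.1) on the log scale; must die at steps 8–9),
  and 8 miRNA loci.
- **Time course** — 90 timepoints over 66 h. Each transcript follows one of
  8 archetype mean curves (maternal cleared / maternal persistent at
  zygotic genome activation ~7–8 h; three zygotic transients peaking ~18,
  30, 42 h; three zygotic persistents activating ~10, 22, 34 h), with
  per-transcript amplitude U(2, 3.5) natural-log units, ±4 h timing jitter,
  a small basal level (0.3) so low expression is not constantly clipped at
  zero, plus a Matérn-5/2 wiggle with σf² ∈ [0.3, 1.0], τ ∈ [4, 10] h and
  i.i.d. noise set by a planted SNR ∈ [1, 3]. The log profile is
  log(RPKM + 1); counts are its exact RPKM-inverse at a 20 M-read library
  (the library size is the genome-wide constant — these transcripts are a
  small subset of it — so recomputed RPKM returns the planted scale and
  the fitting transform recovers the planted GP up to 1/ln 2). A
  share-normalization variant that forces per-sample totals to the library
  size was rejected: on a ~170-transcript toy subset it inflates RPKM
  ×~1000 and turns low expression into a 0↔11 telegraph signal on the log2
  scale.
- **Cis pairs** — 20 of the 50 lncRNAs copy a flanking gene's profile
  (± N(0, 0.15)) on the *opposite* strand: high neighbor correlation that
  must survive step 8, the planted signal for the permutation analysis.
  The dedicated cis fixture for the power check raises this to 35 with
  noise 0.1, sized so the planted shift is detectable at p < 0.01.
- **Strand evidence** — totals Poisson-scaled (×3) from mean early (< 9 h)
  RPKM, reads binomial with 0.95 toward the true strand; zygotic
  transcripts are naturally undetermined. Assembler calls are correct for
  exon decoys (their junctions are the host's), 77%-accurate for other
  multi-exon candidates, unknown for single-exon models.
- **Bridging pairs** — half the exon decoys emit 3 read pairs linking their
  first exon to the host's last exon, plus 50 background within-transcript
  pairs.
- **Spatial counts** — 4 regions × 3 replicates, negative binomial
  (dispersion 0.1, baseline means 50–800), with 8 animal-, 8 vegetal-,
  3 dorsal- and 3 ventral-enriched lncRNAs at log2FC = 2 (the
  dorsal/ventral axis planted sparse, as observed in the embryo).

**What passing tests show** — every decision rule, boundary and statistic
behaves as specified; the funnel separates planted truth from planted
artifacts essentially perfectly at these settings; the estimators are
calibrated (GP/SNR near its information bound, permutation p uniform under
exchangeability, moderated-t type-I at nominal level, limma-level agreement).

**What they do not show** — performance on real assemblies: no splicing
ambiguity, no shared-exon isoform complexity, no mapping bias, no
sequence-composition realism beyond ORF content, no overdispersion in the
time-course counts beyond the planted log-normal noise, and archetype
shapes far cleaner than real dynamics. Recovery rates on this fixture are
upper bounds, not forecasts.

**Detection-limit behavior** — with planted SNR as low as 1 the realized
GP path occasionally carries little variance (or is largely clipped at
zero), and the fitted SNR — correct for those data — falls below 0.6; and
two independent same-strand monotone zygotic profiles occasionally exceed
r = 0.9 after smoothing. Both lose a genuine lncRNA in a minority of seeds
(~2–3% of transcripts at the low-SNR end), which is the same stringency
trade-off the original pipeline accepts. The end-to-end recovery checks
therefore quantify losses over many seeds rather than asserting per-seed
perfection.

## Determinism and problem sizes

All randomness flows from explicit integer seeds: the generator from its
config seed, the pipeline from one root seed via fixed named sub-streams
(GP restarts, k-means, random gene pairing, permutations), per-transcript
GP seeds derived from root seed and row position so results are independent
of fitting order. Identical config (hash embedded in output headers) means
identical outputs. The test suite and the acceptance script run the
calibrations at moderate sizes chosen for a laptop-class single core —
200 series per GP grid cell (25 in the script), 50-seed end-to-end and
spatial-null loops, 10 000 permutations — sizes at which every reported
median or rate is stable to well within its asserted tolerance.

## Known limitations

- The GP screen fits each transcript independently; no sharing of
  timescales across transcripts, no non-Gaussian likelihood for counts.
- Step 5 keeps a representative by length, not by expression support.
- Neighbor search is unbounded by distance; on sparse annotations a
  "neighbor" can be megabases away.
- The binomial strand test ignores positional read structure; the voom
  re-implementation supports only two-condition contrasts.
- Absolute-quantification normalization of the original time course is out
  of scope; RPKM is the unit throughout.
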