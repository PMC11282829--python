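# Methods

## Problem and model

The pipeline screens bulk RNA-seq count matrices from several independent
cohorts for cell-surface receptors (GPCRs) that are recurrently expressed in
cancer tissue and weakly expressed in the healthy tissue a locally
administered nanomedicine would contact.  It is a threshold cascade, not an
inferential procedure: no differential-expression test or multiple-testing
correction is involved, because the selection criteria are absolute
("at least X % of the reference in at least Y % of samples"), chosen for
interpretability across cohorts with very different depths and protocols.

## Normalization

Each cohort is processed independently: low-expression filter, TMM scaling
factors, RPKM.  The filter has two dialects because both appear in practice —
discarding genes with CPM = 0 in more than `sample_fraction` of samples
(default, `nonzero_fraction`), or keeping genes with CPM > 1 in at least
`sample_fraction` of samples (`cpm_gt1`).  The default is the weaker filter;
it decides only which genes enter TMM and the expressed calls, never the
counts themselves.

TMM is implemented from its definition rather than delegated, since
reference-relative thresholds downstream inherit any normalization error.
Details that matter for reproducibility:

* reference sample: 75th-percentile CPM (linear interpolation between order
  statistics) closest to the mean of those percentiles; first sample on ties;
* genes with a zero count in either member of a pair are excluded from the
  M/A computation (log-safety);
* trimming is rank-based with stable sorting, dropping `floor(n·trim)`
  genes at each end for both the M (30 %) and A (5 %) criteria — fully
  deterministic under ties;
* if a column pair is exactly proportional (all |M| < 1e-10) the factor is 1
  by definition, avoiding spurious last-ulp factors from floating-point
  division;
* if the double trim empties the gene set, the untrimmed weighted mean is
  used and a warning logged;
* factors are rescaled by their geometric mean (so they multiply to 1), and
  effective library sizes are `N_k · f_k`.

The test suite checks the implementation against a literal loop-based
transcription of this definition on 100 random matrices (agreement to 1e-10)
and against edgeR's `calcNormFactors` on one fixture (agreement to 1e-6).

RPKM uses effective library sizes: normalization precedes the length
correction.  Gene lengths are an explicit annotation input (`length_bp ≥ 1`),
since count matrices do not carry them.

## Reference gene and relative expression

CV % uses the sample standard deviation (n−1): the healthy comparator cohorts
are small (9, or 3 in the peritoneal scope), where the denominator choice is
material.  CV is computed on the RPKM scale of the designated healthy cohort.
The default candidate list contains 15 widely used housekeeping genes
(SDHA, GAPDH, ACTB, B2M, HPRT1, TBP, UBC, YWHAZ, RPL13A, PGK1, PPIA, GUSB,
TFRC, HMBS, RPLP0) and is overridable; ties are broken alphabetically so the
selection is deterministic.

Percent-of-reference expression divides each column by its reference value.
Samples where the reference is zero are marked *unavailable* (NaN) rather
than dropped; every downstream fraction excludes unavailable cells from both
numerator and denominator, and the clustering step zero-imputes them
(configurable to pairwise-rescaled distances).

## Selection cascade

Thresholds (all `SelectionConfig` fields, all compared with ≥ so boundary
cases pass): level 40 % of reference, within-cohort fraction 30 %, minimum
3 cohorts, healthy cutoff mean + 2 SD, pooled fraction 65 %.  The healthy
comparator defaults to the peritoneal samples only (`peritoneal_only`),
because adverse effects on peritoneum were the design concern; `all_healthy`
widens the scope.  The healthy filter runs on the RPKM scale by default; a
`PCT_REF` option exists because absolute RPKM comparability across
independently normalized cohorts is questionable, whereas reference-relative
values are anchored per sample.  Pooling concatenates cohorts without any
re-normalization beyond each cohort's own TMM/RPKM; genes filtered out of a
cohort appear as unavailable cells in the pool, and a pre-selected gene
entirely absent from the healthy matrix is assigned a zero healthy baseline
(mean = SD = 0), i.e. treated as not detected in healthy tissue.

Co-expression summaries reuse the 40 %-of-reference expressed definition per
sample and report marginal and joint fractions for gene pairs of the final
panel.

## Clustering

Pooled cancer samples are clustered on the %-of-reference matrix restricted
to the final panel.  No distance/linkage is canonical for this kind of
heatmap; Ward on Euclidean distances is the default, with average/complete
linkage and correlation distance configurable.  k defaults to 12 and is
user-set — no automatic model selection is attempted.  The merge history is
retained so the dendrogram can be re-cut at any k, and the cut must produce
exactly k non-empty clusters (tied merges that collapse the cut raise an
error instead of silently returning fewer clusters).  Labels are numbered by
first appearance in the input sample order, making them deterministic and
permutation-consistent.

## qPCR quantification

ΔCt is target minus reference per sample, so positive values mean *less*
expressed than the reference; fold-reduction is `(1+E)^ΔCt` with
amplification efficiency `E ∈ (0, 1]`, default 1.0 (the usual `2^ΔCt`).
A per-run efficiency accommodates primer pairs with efficiency below 90 %.
Target Ct above the detection limit (35 cycles) flags the cell not detected;
an undetected *reference* invalidates the whole sample.  Replicate wells in
long-format input are averaged per sample × gene before ΔCt, with the
replicate SD retained.

## Synthetic data

The generator's role is to reproduce the statistical structure the cascade
assumes, not to fit any real cohort.  Counts are negative binomial
(gamma–Poisson, dispersion 0.2 by default) with lognormal library sizes
(ln-mean 14.5, ln-sd 0.35; median ≈ 2 M reads).  Default design: five cancer
cohorts of 77/9/10/20/35 samples and one healthy cohort of 9 (3 peritoneal,
3 fallopian, 3 ovarian surface), 2 000 genes of which 200 are GPCR-flagged.
Gene abundances are lognormal, with the receptor family drawn from a lower,
narrower distribution than the bulk transcriptome (receptors genuinely are
low-to-moderately expressed).  Specific populations:

* the housekeeping gene sits at abundance 1.0 with its dispersion calibrated
  per sample to `(CV_target/100)² − 1/μ`, so its across-sample RPKM CV tracks
  the 9 % target (within ±3 points on the mean over 100 seeds; a single
  9-sample cohort estimates CV with an SD of ≈ 2 points, so per-seed values
  scatter more than the band);
* the other 14 candidates get per-sample lognormal jitter (ln-sd 0.20–0.40,
  giving CVs around 20–40 %) on a low base dispersion, emulating ordinarily
  variable housekeeping genes;
* planted targets (default: the 13-receptor panel the cascade is meant to
  find) are at a low quantile (default 0.25) of the receptor abundance
  distribution in healthy tissue and jump to 120–250 % of the reference in a
  penetrance fraction (default 0.85) of cancer samples — comfortably above
  every cascade threshold, so exact recovery is a property of the design, not
  of a lucky seed;
* ubiquitous decoys are expressed at 60–100 % of the reference in *all*
  samples, healthy included, with low dispersion: they pass stages 1–2 and
  must be removed by the healthy filter;
* cohort-restricted decoys are expressed in exactly two cancer cohorts: they
  must fail the ≥ 3-cohort frequency ranking.

The generator does **not** model gene–gene correlation, batch effects, GC or
length biases beyond the explicit length term, or tumor-microenvironment
admixture; passing tests therefore demonstrate the pipeline's correctness and
its behavior under the intended signal structure, not performance on real
heterogeneous tissue.

The qPCR simulator draws reference Ct uniform in 20–23 cycles, per-gene mean
ΔCt uniform in 3–12 (or an explicit grid), Gaussian well noise (SD 0.8
cycles), and pushes a configurable fraction of wells above the detection
limit.

## Problem sizes and determinism

All randomness flows through seeded NumPy PCG64 generators; identical seeds
give byte-identical written outputs.  The test suite and the acceptance
script run the full default-size collection (2 000 genes × 160 samples,
151 pooled cancer samples) — a full cascade takes well under a second — and
the TMM brute-force comparison uses 100 matrices of up to 30 genes × 6
samples.  The pipeline manifest records the configuration hash, input
checksums, package version and seed.

## Known limitations

* Cross-cohort pooling on the RPKM scale assumes each cohort's TMM/RPKM puts
  samples on comparable footing; the `PCT_REF` healthy-filter scale is the
  escape hatch when it does not.
* The healthy baseline rests on as few as 3 peritoneal samples, so the
  mean + 2 SD cutoff is itself noisy; the pipeline reports per-gene pass
  fractions so borderline candidates can be inspected.
* The expressed-call and healthy-filter thresholds are design constants, not
  estimated quantities; sensitivity to them is the user's responsibility
  (they are all exposed in `SelectionConfig`).
* No automatic choice of cluster number; k = 12 is a convention carried over
  from the study design the defaults emulate.
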