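# Methods

This note documents the models, parameter choices and numerical decisions
behind `methcanyon`, and what the synthetic cohort does and does not show
about real WGBS data.

## Coordinates and input

All internal intervals are 0-based half-open. BSMAP-style ratio tables
(1-based positions) are shifted by −1 exactly once, at read time; bedGraph
input is taken as already 0-based. Three methylation-table dialects are
auto-detected from column count and numeric ranges (see
`io_formats.read_methylome`); ambiguous files should be converted to the
5-column ratio-table form. CpGs with fewer than 4 reads are dropped, the
conventional depth for a trustworthy per-CpG ratio. Chromosome names are
used verbatim — no "chr" stripping — and `validate_chrom_names` reports
name-set disagreement between inputs rather than papering over it.

## UMR segmentation

A UMR is a maximal run of consecutive CpGs satisfying three constraints:
every CpG below a per-CpG cap (`cpg_threshold`), adjacent CpGs at most
`max_gap` = 1000 bp apart (so calls never bridge CpG deserts with no data),
and run mean methylation below `max_mean` = 0.10 with at least
`min_cpgs` = 4 CpGs. The emitted region runs from the first CpG to the last
CpG + 2, covering the terminal dinucleotide.

The binding scientific rule is the run mean < 10%. The per-CpG cap exists
only to stop runs at confidently methylated CpGs, and the library default
(0.10) makes the mean bound redundant, giving a pure maximal-run
segmentation that the test suite checks against an independent O(n²)
enumeration. The *pipeline* default is a cap of 0.5: at ~30× coverage a CpG
with latent methylation 0.05 shows an observed ratio ≥ 0.1 about one time in
five purely through binomial read sampling, so a hard 0.1 per-CpG cutoff
shatters genuine UMRs into fragments; a 0.5 cap rejects only CpGs that are
confidently methylated while the run-mean bound still enforces the 10%
definition. This stands in for the HMM segmentation used in earlier canyon
work, which tolerates isolated noisy CpGs for the same reason; the HMM
itself is out of scope.

When the cap exceeds `max_mean`, a candidate run can fail the mean bound
while containing qualifying sub-runs. Mean-constrained maximal runs are not
nested, so the implementation uses a deterministic peak trim: remove the
highest-ratio CpG (leftmost on ties), split there, recurse. When the cap is
≤ `max_mean` this provably never fires.

The optional CpG observed/expected filter uses the classic CpG-island
composition form (N_CpG × L)/(N_C × N_G) on the + strand; regions with
O/E < 0.1 sit in CpG-depleted sequence where segmentation from sparse data
is unreliable and are dropped. The ratio is undefined (missing, never
filtered) when the sequence lacks C or G entirely.

## Reference atlas

Atomic segmentation splits the merged UMR union at every per-sample UMR
boundary, so the occupancy count k is constant per segment; UOF = k/N. The
Poisson background rate defaults to λ = mean k over all atomic segments —
the genome-wide-background analogue of ChIP-seq peak calling — and can be
overridden. The upper tail P(X ≥ k | λ) is BH-adjusted over all segments
and thresholded at adjusted p < 1e-8; adjacent passing segments separated by
at most `merge_gap` (default 0: book-ended) merge into one reference UMR
whose k is the occupancy with the largest base coverage among its segments
(ties to the larger k) and whose p/FDR are the minima. Testing precedes
merging so the test never depends on merge bookkeeping. Canyons are
reference UMRs strictly longer than 3500 bp; length exactly 3500 is a cUMR.

Two consequences worth knowing. First, the 1e-8 cutoff is a population-scale
criterion: with fewer than ~25 samples even k = N is not that surprising
under any λ the data can produce, so small cohorts yield empty atlases by
design rather than by failure. Second, λ as a mean over segments is only
meaningful when the occupancy profile contains a realistic background of
low-recurrence, sample-specific UMRs; a profile consisting solely of
fully-shared regions drives λ toward N and nothing is callable. Real
methylome collections have exactly this background (hundreds of thousands of
non-redundant UMRs, mostly private); the synthetic generator plants it
explicitly (below).

## Entropy heterogeneity filter

For each reference UMR the per-normal mean methylation vector x is converted
to p_j = (x_j + ε)/Σ(x_k + ε) with ε = 0.01 and scored by Shannon entropy in
bits. Constant behaviour across normals attains the maximum log2(N);
tissue-specific behaviour (unmethylated in a few normals, methylated in the
rest, or vice versa) scores low. Regions below log2(N) − 1 bits are removed
before differential testing — the methylation analogue of dropping
high-frequency germline variants from a disease cohort. This is a plain
normalized-entropy specificity score, not a re-implementation of QDMR's
standard-deviation-weighted variant; it preserves the intended behaviour
(low entropy ⇔ sample-specific) in a fully testable form, and the threshold
is configurable because QDMR's data-derived default is not recoverable.
With the default contrast (≈0.05 in 90% of normals, ≈0.8 in 10%) the score
sits ~0.7 bits below threshold; homogeneous regions with realistic sampling
noise stay ≥ 0.9 bits above it.

## Beta likelihood-ratio test

Per region, per-sample region-mean methylation levels are modelled
Beta(α, β) within each group. The null (shared α, β) is tested against
separate group parameters with D = 2(ℓ_normal + ℓ_tumor − ℓ_shared),
referred to χ² with df = 4 − 2 = 2. Fitting is maximum likelihood on
(log α, log β) with the analytic digamma gradient (L-BFGS-B, log-likelihood
tolerance 1e-8), initialized at the method of moments
α = m(m(1−m)/v − 1); values at the boundary are clamped to
[1e-6, 1 − 1e-6] (the beta likelihood is undefined at 0/1), and
zero-variance groups fall back to moment estimates with the concentration
capped at α + β = 1e4, flagged `converged=False`. If the optimizer fails to
improve on the moment start, the moment fit is used and flagged.

The χ² reference is asymptotic: at group sizes of 15 the empirical type-I
error at nominal 0.05 runs ≈ 0.065, and ≈ 1.7× nominal at α = 0.001 — the
suite pins both. Significance requires both BH-adjusted p < 0.001 (one BH
family per comparison, over all tested regions) and DM value
|mean(tumor) − mean(normal)| > 0.1; the effect-size clause is what keeps
trivially-tight regions (huge concentration, microscopic mean difference)
out of the call set. The pan-cancer test pools all tumors against all
normals; per-tumor-type tests (same rule, own BH family) only annotate
recurrence and define the conserved controls (regions significant in no
individual type). Groups with fewer than 3 usable samples skip the region
with a logged reason.

## Gene association, DE filter, enrichment

A UMR associates with every gene whose promoter (TSS −1 kb … +500 bp,
strand-aware) or gene body (TSS +500 bp … TTS) it overlaps by ≥ 1 bp;
covering the entire gene body is tracked separately because hypermethylated
canyons frequently do. Differential expression is a rank-sum test with BH
adjustment plus a fold-change filter on pseudocounted group means
((mean_t + 1)/(mean_n + 1), pass if max(FC, 1/FC) > 2) — a deliberately
self-contained stand-in for a negative-binomial count model, adequate here
because the generator's expression is log-normal around its couplings.
Enrichment is the two-sided Fisher exact test on the category × set table
over an explicit background universe (here: all simulated genes).

## Metagene frame

Bins 11–60 divide the gene body into 50 equal genomic fractions (exactly
100 bp each when the body is 5 kb); bins 1–10 and 61–70 are fixed 100-bp
flanks immediately 5'/3' of the body, reversed for minus-strand genes so bin
1 is always 5'-most. Anchoring the frame on the gene body places the
upstream flank over TSS −500 … +500 — the promoter core — which is what
allows promoter-hypermethylated, down-regulated genes to produce the
negative promoter-proximal correlations while body-hypermethylated,
up-regulated canyon genes produce the positive body correlations. The
methylation change is the signed difference tumor − normal: a
magnitude-only difference could never produce those negative promoter
correlations. Expression change is the fold change of pseudocounted values.
Per-bin Spearman uses average ranks, drops missing pairs pairwise, requires
min_n = 10 genes per bin, and computes p exactly (full permutation
enumeration) for n ≤ 8, by t-approximation above.

## Synthetic cohort

Defaults, one synthetic chromosome (~4.6 Mb):

| parameter | default | rationale |
|---|---|---|
| samples | 30 normal / 35 tumor, 7 type labels | pan-cancer design at desk scale |
| background CpG gap | geometric, mean 120 bp; ×5 denser in planted regions | CpG-island-like density where UMRs live |
| background methylation | Beta(8.5, 1.5), mean 0.85 | somatic methylated background |
| UMR methylation | Beta(1, 19), mean 0.05 | deep hypomethylation |
| canyons | 60, lengths 4.2–8 kb; 18% hyper / 5% hypo in tumors | the canyon asymmetry under study |
| cUMRs | 150, lengths 0.7–2.2 kb; 10%/10% hyper/hypo | roughly balanced controls |
| hyper effect | tumor mean 0.50 (body), 0.60 (promoter), concentration 20 fixed | mean shift at constant concentration keeps the LRT well-specified |
| hypo regions | normals at 0.30, tumors at 0.05 | enter the atlas through the tumor arm |
| unstable regions | 12; low in 90% of normals, 0.8 in the rest | what the entropy filter must remove |
| decoy UMRs | 30,000 sites × 800 bp, per-sample activation 0.01 | the sample-specific UMR background that makes λ meaningful |
| coverage | gamma-Poisson, mean 30×, shape 8, ratio = Binomial(cov, latent)/cov | realistic WGBS read sampling |
| expression | 2^(N(5,1) + 4·body_meth − 4·prom_meth + N(0,0.3)) | RSEM-like positive/negative couplings |

Inter-element gaps are 8–18 kb so planted regions occupy a minority of the
chromosome; decoy sites are placed in the methylated background with at
least 5 CpGs each so an activated decoy is actually callable. The seed fully
determines the cohort (identical seeds give byte-identical outputs).

What passing tests show — and don't. The generator realizes the model the
pipeline assumes: beta-distributed region means, mean-shift tumor effects at
fixed concentration, independent samples, no covariates. Recovery there
demonstrates correctness of the machinery, not robustness to tumor purity,
batch structure, copy-number artifacts, partially-methylated domains, or
HMM-grade boundary precision — none of which are simulated. Genome-scale
counts (tens of thousands of reference UMRs) are likewise out of reach of a
single small chromosome and are not asserted anywhere.

## Problem sizes used by the test suite

Oracle-equivalence checks run 1,000 random methylomes of ≤ 200 CpGs; null
calibration uses 2,000 replicates at group size 15 (and 10,000 for the far
tail at α = 0.001); the end-to-end checks run the full default cohort once
(a few seconds) and share it across tests. Fisher agreement enumerates 300
random tables with margins ≤ 100.

## Known limitations

* The per-CpG cap / run-mean rule is a deterministic stand-in for HMM
  segmentation; boundary placement near gradual methylation slopes differs.
* λ as a global segment mean ignores regional occupancy structure; a local
  background (as in ChIP-seq local λ) is not implemented.
* The rank-sum DE filter is not a count model; on real RNA-seq counts a
  negative-binomial fit should replace it.
* Exact Spearman p stops at n = 8; above that the t-approximation is used.
* Tumor purity, CNV and 450K-array processing are out of scope.
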