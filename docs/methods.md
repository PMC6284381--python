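# Methods

This note documents the models, parameter choices and numerical decisions
behind `pdxfid`, and what the synthetic-data experiments do and do not
demonstrate about real cohorts.

## Clone-tree and allele-frequency model

A tumor sample is a rooted tree of clones. Each clone carries a cell
fraction (itself plus descendants); nesting constraints hold throughout
(child ≤ parent, sibling sum ≤ parent). Mutations belong to exactly one
clone. Observed variant tables follow a heterozygous-diploid read-sampling
model: expected AF = 0.5 × blast × cell fraction, total reads
Poisson(depth), alt reads binomial, detection at ≥5 supporting reads with a
multi-sample rescue within a patient. Copy-number-aware AFs are out of
scope; all reasoning is on raw AFs, with the clonal/subclonal boundary at
AF ≥ 0.30 (inclusive, as are all thresholds in the package).

Tree generation draws each new clone under a random existing parent with
probability proportional to the parent's remaining fraction budget, taking a
U(0.3, 0.9) share of it; clone and mutation counts are uniform over
configured ranges (defaults 2–5 clones, 20–40 mutations per sample — real
cohorts do not constrain these, so they are invented and should be treated
as such). Defaults for depth (50×) and blast content (initial diagnosis
0.87 ± 0.07, relapse 0.69 ± 0.27, truncated; PDX ≈ 1 because engraftment
enriches leukemic cells) follow the magnitudes typical of pediatric T-ALL
cohorts profiled by exome sequencing.

Relapse evolution: type 1 keeps all mutations and expands a new relapse
subclone carrying gained mutations (relapses always gain mutations); type 2
additionally deletes a non-empty proper subset of the initially clonal
mutations, modeling a relapse that expands from an ancestral branch
predating them. Engraftment: mode A retains every clone with fractions
jittered by at most ±5%; mode B applies one of three selection events —
eradication of a mid-size subclone, amplification of a small subclone to
near-dominance (≥2-fold, typically a sweep), or the rise of a previously
undetected clone above the detection limit — plus stochastic loss of small
subclones with probability exp(−20·fraction). The three events mirror the
remodeling patterns reported for real T-ALL xenografts; their effect sizes
are set to sweeps because that is what bulk sequencing at 50× can resolve,
and because observed selection events in such cohorts are of this magnitude.

## Engraftment-mode classification

Mode A requires: every clonal primary mutation preserved, no architecture
shift, and no PDX-specific clonal cluster. A naive per-mutation rule
"|ΔAF| > 0.15 ⇒ shift" is unusable at 50×: the per-mutation sampling SD of
the AF difference is ≈0.1, so the maximum over tens of mutations exceeds
0.15 almost surely in perfectly concordant pairs. Each criterion is
therefore anchored in read-count evidence, at a per-patient significance
level α = 10⁻³:

* **clonal_loss** — a blast-corrected clonal primary mutation absent from
  the PDX (dropout probability at these AFs is ≪ α by itself);
* **af_shift** — a preserved mutation whose blast-corrected AF moves by more
  than the 0.15 tolerance *and* whose supporting read counts reject equal
  underlying frequency in a two-sided Fisher exact test at α Bonferroni-
  corrected across preserved mutations;
* **subclone_selection** — a cluster of ≥2 PDX-specific variants at
  clonal-level AF, or a Poisson-binomial tail test showing that more
  detected subclonal mutations dropped out of the PDX than sampling
  explains. The dropout test restricts to mutations with blast-corrected
  primary AF ≥ 0.15 to avoid winner's-curse bias at the detection limit, and
  uses the exact Poisson-binomial distribution (O(n²) DP convolution) of the
  per-mutation dropout probabilities.

Blast correction divides AFs by the sample's blast content (capped at 1);
without it, ordinary blast differences between patient and mouse material
masquerade as selection. Relapse-type classification is set-based:
"maintained" means detected at relapse at any AF, since requiring clonal AF
at relapse would conflate clone-size changes with loss.

## Copy-number analysis

Coverage in uniform 10-kb bins is GC-corrected by dividing each bin by the
median count of its GC decile and rescaling to genome-wide median 1 — a
deterministic, dependency-light alternative to loess that removes monotone
GC bias to the accuracy needed for >1 Mb events. Tumor/remission log2 ratios
use a 0.5-count pseudocount and mask bins with remission coverage below 10
reads. Segmentation is recursive binary splitting on the two-sample z
statistic of segment means (threshold 5, minimum 10 bins per side) — full
circular binary segmentation with permutation p-values is unnecessary when
only >1 Mb events are consumed. Calls use ±0.3 log2 cutoffs, between diploid
0 and the single-copy gain/loss levels (+0.585/−1). Set concordance uses
same-direction ≥50% reciprocal overlap. The amplitude cutoffs are invented
(chosen between the relevant copy-number levels), as published cohorts
rarely state them.

## Promoter methylation

Promoters are strand-aware TSS windows (−1500/+500 bp); probes in
overlapping windows count in each; promoters need ≥3 probes and a gene
symbol for differential analysis but remain in global-concordance
computations. An event is |Δβ| ≥ 0.2, boundary inclusive; swapping the two
samples exactly swaps hyper and hypo labels. Baseline event probabilities
are direction totals over (promoters × pairs) — the natural reconstruction
of "baseline probability of an event" — and the recurrence significance
default is the count rule (hyper in ≥4 pairs, hypo in ≥3), with exact
binomial upper tails reported alongside and a tail-probability rule
selectable. No multiple-testing correction is applied, matching the
thresholds-only character of the procedure. The printed significance levels
in the source literature do not forward-check against the exact binomial
tail at the stated baselines; the package reports exact tails and does not
force agreement.

The β generator mixes a leukemic and a normal methylome by blast content
(PDX side is pure leukemia), with Beta(0.4, 0.4) bimodal promoter levels,
a 30% differential subset shifted by Laplace(0, 0.15) between the two
methylomes (moderate shifts, as between related hematopoietic cell types),
Gaussian noise (σ = 0.05), and a planted hypermethylated set (+0.3 in the
PDX compartment of 5 of the patients) drawn from promoters with
β_leukemia ≤ 0.5 — methylation gains require headroom, and the real
recurrently hypermethylated genes are transcriptionally silent, lowly
methylated immune loci. Blast dilution makes event counts rise as blast
falls, which is what produces the strong negative blast-vs-events
correlation in wide-blast cohorts.

## ATAC-seq

TSS enrichment is the ENCODE-style ratio: mean coverage of the central
±50 bp of the aggregate profile over the outermost 100-bp flanks. "Shared"
peaks mean ≥1 bp overlap under 0-based half-open semantics (adjacent
intervals do not overlap). Size factors are median-of-ratios, anchored to
geometric mean 1, with a total-count fallback when no peak is nonzero
everywhere.

The differential test is a self-contained paired NB Wald test, not a wrapper
around an external engine: counts are size-factor normalized; per peak, the
condition effect is the inverse-variance-weighted mean of per-patient log2
ratios (patient as blocking factor); the variance combines delta-method
count noise (1/μ terms) with a method-of-moments dispersion shrunk halfway
toward a mean-binned median trend; the Wald statistic is referred to a t
distribution with (pairs − 1) degrees of freedom, which keeps the test
calibrated-to-conservative at six pairs (empirical type-I ≈ 0.02 at nominal
0.05 across dispersions 0.01–0.5). Significance requires p < 0.05 and
|log2FC| > 0.1. Its outputs are validated against an independent NB GLM
implementation on synthetic data but are not claimed identical to any
external tool's peak lists.

The generator places peaks on a 3 × 10 Mb toy genome with lognormal heights
(median 80 reads, log-SD 0.8 — IDR-filtered peak sets are dominated by
well-covered peaks); a primary peak is re-called in the PDX with probability
1 − exp(−height/19), chosen so that peaks of height ≥ 50 are shared at
roughly the rates seen in matched leukemia/xenograft data. Counts are NB
with a within-patient residual dispersion of 0.05; patient-to-patient
variability is modeled separately as a lognormal per-peak patient effect
(log-SD 0.3, i.e. ≈ 0.09 between-patient dispersion), which is the
inter-patient heterogeneity the paired design blocks out. The
shuffle-based enrichment null preserves peak widths and chromosome
assignment with uniform placement.

## Problem sizes and determinism

Default experiment sizes — 100-patient classifier and preservation-recovery
cohorts, 11-pair methylation cohorts with 2,000 promoters, six ATAC pairs
with 5,000 peaks, two 30-Mb chromosomes of 10-kb coverage bins — are chosen
so each simulation study yields stable estimates (binomial SEs of a few
percent) while a full analysis run completes in seconds. Every stochastic
function takes an explicit seed and is byte-identical across runs for a
fixed seed; cohort-level functions derive independent sub-seeds from one
master seed.

## What the synthetic experiments do not show

The generator emulates read sampling, blast dilution, clonal selection and
planted epigenetic effects, but not: alignment or calling artifacts
(mouse-read contamination is bookkeeping only), array probe chemistry and
normalization residuals, copy-number-modulated AFs, subclonal phylogenies
more complex than trees with uniform priors, or spatially structured
chromatin domains. Passing recovery tests therefore demonstrates that the
statistics are implemented correctly and are well calibrated under the
stated noise models — not that real cohorts will reach the same accuracies.
Published cohort-level numbers can be recomputed by feeding the study's
per-variant supplementary tables through the same entry points
(`apply_detection_filters`, `pair_variants`, `preservation_summary`,
`mlpa_concordance`); those tables ship with the article, not with this
package.
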