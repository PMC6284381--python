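# pdxfid

Multi-level fidelity assessment of patient-derived xenografts (PDXs).

When a patient's leukemia is engrafted into immunodeficient mice, how much of
the original tumor does the model actually preserve? `pdxfid` answers this
question quantitatively, across four molecular levels, for cohorts of matched
primary/PDX samples (optionally longitudinal: initial diagnosis and relapse):

* **Somatic variants and clonal architecture** — pairing of SNV/InDel calls
  between matched samples, preservation rates stratified by allele frequency
  (clonal: AF ≥ 30%, subclonal: AF < 30%), AF concordance (Pearson r,
  Wilcoxon signed-rank shift test), PDX-specific variant detection with a
  single-clone consistency check, and per-patient classification of the
  relapse type (type 1: all clonal mutations maintained at relapse; type 2: a
  clonal subset lost) and the engraftment mode (mode A: clonal composition
  and architecture captured; mode B: remodeled by clonal selection).
* **Large copy-number alterations** — GC-corrected 10-kb binned low-coverage
  WGS, tumor/remission log2 ratios, binary segmentation, >1 Mb
  amplification/deletion calls, and CNA/MLPA concordance between matched
  samples.
* **Promoter DNA methylation** — probe-to-promoter aggregation (strand-aware
  −1.5 kb/+0.5 kb TSS windows, ≥3 probes), Δβ ≥ 0.2 event calling per matched
  pair, an exact binomial recurrence test across patients, blast-content
  correlation, and global rank/linear concordance.
* **Chromatin accessibility (ATAC-seq)** — TSS enrichment, FRiP and
  insert-size QC, height-stratified peak sharing, per-peak count concordance,
  PCA, a paired negative-binomial Wald test for differential accessibility
  (patient as blocking factor), and shuffle-based annotation-overlap
  enrichment.

A first-class synthetic-cohort generator produces all of these data types
with known ground truth — clone trees with binomially sampled allele
frequencies at configurable depth and blast content, type-1/type-2 relapse
evolution, mode-A/mode-B engraftment selection, blast-mixture β matrices
with a planted recurrently hypermethylated promoter set, NB-distributed peak
counts with height-dependent peak reproducibility, and GC-biased binned
coverage with planted copy-number segments — so every stage is testable
without access to patient data.

## The core model

Somatic allele frequencies follow a heterozygous-diploid clone-tree model: a
mutation assigned to a clone with cell fraction *f*, observed in a sample
with blast content *b* at sequencing depth *D*, has expected allele
frequency

```
E[AF] = 0.5 · b · f,   alt ~ Binomial(N, E[AF]),   N ~ Poisson(D),
```

with variants called at ≥5 supporting reads (rescued if called in another
sample of the same patient). Promoter methylation is a blast mixture,
β_obs = b·β_leukemia + (1−b)·β_normal + ε. Recurrence of Δβ ≥ 0.2 events is
scored with the exact binomial upper tail P(X ≥ k) at per-direction baseline
event probabilities. ATAC counts per peak are negative binomial around
height × patient effect × size factor, tested for condition effects with a
weighted paired Wald statistic on per-patient log2 ratios (t reference,
pairs − 1 df).

## Worked example

Simulate a 12-patient matched cohort and run the full pipeline:

```
pdxfid simulate --outdir cohort --seed 7
pdxfid all --manifest cohort/manifest.yaml --outdir bundle --seed 7
```

which prints the per-stage status

```
variants: ok
cna: ok
methylation: ok
atac: ok
```

and writes `bundle/` with the pairing table, preservation summary,
per-patient relapse-type/engraftment-mode classifications, CNA calls,
methylation event and recurrence tables, ATAC sharing/differential/PCA
tables and a `run_metadata.json` carrying the seed and configuration hash.
The same analyses are available as library functions; for example,
classifier label recovery on 100 simulated patients:

```python
>>> from pdxfid.experiments import classifier_recovery
>>> classifier_recovery(n_patients=100, seed=42)
{'n_patients': 100, 'relapse_type_accuracy': 0.97,
 'engraftment_mode_accuracy': 1.0}
```

i.e. at 50× depth and default noise, 97% of planted relapse-type labels and
100% of planted engraftment-mode labels are recovered from the read-level
data alone.

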