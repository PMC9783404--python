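# ribofold-te

How much of a transcript's translation efficiency can be read off its
RNA secondary structure — and from which part of the mRNA? `ribofold-te`
is a reusable pipeline for relating transcriptome-wide RNA structure
probing data (icSHAPE, DMS-seq) to ribosome-profiling measurements of
translation. It is aimed at computational biologists who have
per-nucleotide reactivity tracks and Ribo-seq/RNA-seq counts for the
same transcripts and want a reproducible, end-to-end analysis of where
along the mRNA structure matters for translation.

## What it computes

**Translation efficiency.** For each transcript, TE is the log2 ratio of
ribosome-footprint abundance to mRNA abundance:

    RPKM = count x 10^9 / (length x library size)
    TE   = log2(RPKM_ribo / RPKM_rna)

Transcripts with RNA-seq RPKM <= 1 are excluded (low expression makes TE
unstable). The top and bottom 25% of the TE distribution become the
*high* and *low* classes; intermediate transcripts are dropped.

**Features.** Each transcript contributes 243 named features in four
groups:

* *sequence* (111): nucleotide frequency and GC content in four scopes
  (whole / 5'UTR / CDS / 3'UTR), in-frame codon and amino-acid
  frequencies, codon and amino-acid repetitive rates, region lengths.
* *vivo* and *vitro* (61 each): the reactivity track of each probing
  condition compressed to a 60-bin meta-gene profile — 20 bins per
  region, so bins 0–19 are the 5'UTR, 20–39 the CDS, 40–59 the 3'UTR —
  plus the mean reactivity of the CDS head (first six codons).
* *insilico* (10): folding energies of five scopes (whole transcript,
  three regions, CDS head), raw and per nucleotide, from a built-in
  base-pair-maximization folder (an external thermodynamic folder's
  energies can be imported instead).

**Classification.** 100 stratified random 70/30 splits; within each
split, hyper-parameters of a random forest and an elastic-net logistic
regression are tuned by stratified ten-fold cross-validation maximizing
mean AUC, refit on the training partition, and scored on the test
partition. Impurity-based forest importances (normalized to sum 1 per
split) are summed within the four feature groups and averaged per
meta-gene bin. Models sharing splits are compared with a paired t-test.

**Per-bin statistics.** For every bin and condition, high vs low TE
reactivities are compared with a two-sample Kolmogorov–Smirnov test
(exact p for small samples), Benjamini–Hochberg-adjusted within each
condition's 60-bin family; the *delta profile* (in vivo minus in vitro
group mean per bin) quantifies structural rearrangement inside cells.

A fully specified synthetic generator (`ribofold_te.synthetic_data`)
emulates the data structure of such a study — three-region transcripts,
negative-binomial count pairs encoding a planted TE, Beta-distributed
reactivities with plantable region/condition/class-specific effects —
so the entire pipeline is testable without any downloads. Scenarios:
`mesc_like` (in vivo 3'UTR unfolding in high-TE transcripts, peaking
just after the stop codon), `zebrafish_like` (3'UTR effect present in
both conditions, so delta ~ 0), and `null` (negative control).

## Worked example

```python
import numpy as np
from ribofold_te import pipeline, synthetic_data as sd

cfg = sd.scenario_config("mesc_like", n_transcripts=400, seed=7)
dataset = sd.generate_dataset(cfg)
result = pipeline.run_study(
    dataset, n_splits=20, base_seed=7,
    rf_grid={"n_estimators": [100], "max_features": ["sqrt"], "min_samples_leaf": [1, 5]},
    models=("rf",),
)

aucs = [r.auc_rf for r in result.splits]
print(f"mean test AUC (random forest): {np.mean(aucs):.3f}")
print("mean importance share per feature group:")
print(result.importance.group_sums.mean().round(3).to_string())
sig = result.bin_summary.query("p_adj < 0.05")
print(f"bins with adjusted p < 0.05: {len(sig)}, "
      f"of which in the 3'UTR: {(sig.bin_index >= 40).sum()}")
```

prints

```
mean test AUC (random forest): 0.992
mean importance share per feature group:
sequence    0.167
vivo        0.489
vitro       0.328
insilico    0.016
bins with adjusted p < 0.05: 23, of which in the 3'UTR: 23
```

The planted coupling is recovered: the classes separate almost
perfectly, in vivo structural features carry more importance than in
vitro ones (and far more than in silico folding energies), and every
significantly different bin lies in the 3'UTR, where the effect was
planted.

The same analysis is available from the shell:

```sh
ribofold-te simulate --scenario mesc_like --n 400 --seed 7 -o sim/
ribofold-te te --counts sim/counts.tsv --fasta sim/tx.fa --regions sim/regions.tsv -o te.tsv
ribofold-te features --fasta sim/tx.fa --regions sim/regions.tsv -o seqfeat.tsv
ribofold-te structfeat --fasta sim/tx.fa --regions sim/regions.tsv \
    --vivo sim/vivo.tsv --vitro sim/vitro.tsv -o structfeat.tsv
ribofold-te train --features feat.tsv --labels te.tsv --seed 17 -o results/
ribofold-te compare --fasta sim/tx.fa --regions sim/regions.tsv \
    --vivo sim/vivo.tsv --vitro sim/vitro.tsv --labels te.tsv -o binstats.tsv
```

## Input formats

All inputs are plain text: FASTA sequences; a tab-delimited region
table (`transcript_id, len_utr5, len_cds, len_utr3`; regions are
contiguous 5'UTR → CDS → 3'UTR in transcript coordinates); reactivity
tracks as `transcript_id TAB v1,v2,...` with `NA` for missing
nucleotides; and a count table (`transcript_id, ribo_count, rna_count`)
with library sizes in a `#ribo_total=... rna_total=...` header line.
See `docs/methods.md` for the model details and design decisions.
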