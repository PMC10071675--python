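# comparthic

Hi-C A/B compartment dynamics, intra-TAD activity, and multi-omic
concordance analysis for paired-condition experiments.

`comparthic` is aimed at chromatin-organization studies that ask how a
perturbation (a mutation, a knockdown, a treatment) reshapes the Mb-scale
A/B compartment structure of the genome, whether topologically associating
domains (TADs) change their internal interactivity, and whether those 3D
changes are concordant with differential gene expression, chromatin
accessibility, or histone-mark tables produced by the usual upstream
pipelines. It consumes binned intra-chromosomal contact matrices (text COO),
TAD intervals (BED), and differential feature tables (TSV) and produces
per-bin compartment tracks, switch/shift calls, differential-TAD tables, and
concordance statistics. A synthetic-data generator with planted ground truth
makes every stage testable end to end without any sequencing data.

## The model

**Compartment scoring.** Each genomic bin *i* carries a probability *P*ᵢ of
belonging to the active A compartment, reported as the compartment score
*C*ᵢ = 2*P*ᵢ − 1 ∈ [−1, 1] (positive = A, negative = B). Contact counts
*n*ᵢⱼ are modeled as independent Poisson draws with rate

```
λ_ij = B_i · B_j · H(d_ij) · (1 + C_i C_j) / 2
```

where *B*ᵢ are experimental bias factors, *H*(*d*) is a distance-decay
scaling function of the genomic separation *d*ᵢⱼ = |i − j|·resolution, and
(1 + *C*ᵢ*C*ⱼ)/2 = *P*ᵢ*P*ⱼ + (1 − *P*ᵢ)(1 − *P*ⱼ) is the probability that
the two bins occupy the same compartment. *B*, *C*, and *H* are estimated by
blockwise coordinate ascent on the Poisson log-likelihood (closed-form
updates for *H* and *B*, damped per-coordinate Newton for *C*), with the
leading eigenvector of the O/E correlation matrix as initializer. The
likelihood is invariant under a global sign flip of *C*, so the A/B polarity
is fixed against an external activity proxy (`orient_track`).

**Switch/shift classification.** With *X* the score of a bin in the
reference condition and *Y* in the comparison condition, the change measure
is the relative delta `delta = (Y − X) / |Y|`. A sign flip with
|delta| > 1.2 is a switch (A→B or B→A); an unchanged sign with
|delta| > 0.2 is a shift (A to more/less A, B to more/less B); anything else
is stable. Percent change is the number of switching (optionally also
shifting) bins over all classified bins.

**Intra-TAD activity.** The mean normalized interaction score over all
distinct within-TAD bin pairs. Condition pairs are normalized with a shared
bias vector (ICE on the reference matrix), each condition is
distance-normalized (O/E), and per TAD the two within-TAD value sets are
compared with a Wilcoxon two-sided rank-sum test, Benjamini–Hochberg
adjusted across TADs; significant means |log2FC| > 0.25 and FDR < 0.01.

**Integration.** Differential features are categorized
increased/decreased/stable (genes: |log2FC| > 0.32 and p < 0.05; peaks:
|log2FC| > 1.0 and FDR < 0.01), assigned to the compartment bin with the
largest overlap, and summarized by association fractions, the concordance
score of a compartment-change class (% of its features moving the same
direction), the rate of concordance of up/down features explained by
decompacting/compacting changes, Welch/rank-sum group tests, and a one-tailed
hypergeometric gene-set overlap test.

## Worked example

```python
import numpy as np
from comparthic import (
    simulate_study, estimate_cscore, orient_track, classify_tracks,
    percent_changed, categorize_features, assign_features_to_bins,
    concordance_score,
)
from comparthic.dynamics import category_counts

truth, cm_low, cm_high, features = simulate_study(
    seed=1, n_bins=500, depth=1e6, n_switch=20, n_shift=30, n_features=1000
)
tracks = {}
for name, cm in (("low", cm_low), ("high", cm_high)):
    model = estimate_cscore(cm)
    tracks[name] = orient_track(model, truth.c_low).cscore
calls = classify_tracks(tracks["low"], tracks["high"])
print(category_counts(calls).to_string())
print(f"percent switching:           {percent_changed(calls):.2f}%")
print(f"percent switching+shifting:  {percent_changed(calls, include_shifts=True):.2f}%")
feats = categorize_features(features.drop(columns="truth_direction"))
joined = assign_features_to_bins(feats, calls, cm_low.bins)
print(f"concordance at B->A bins:    {concordance_score(joined, 'B_to_A'):.1f}%")
```

prints

```
category
A_to_B          10
B_to_A          10
A_to_more_A      8
A_to_less_A      8
B_to_more_B      7
B_to_less_B      7
stable         450
percent switching:           4.00%
percent switching+shifting:  10.00%
concordance at B->A bins:    75.0%
```

The simulated study planted 20 switches and 30 shifts into 500 bins; the
estimated scores recover every planted category (20/500 = 4.00% switching,
50/500 = 10.00% with shifts), and three quarters of the differential genes
landing in B→A bins are upregulated, close to the 80% concordance rate the
generator planted (47 features is a small sample).

The same stages are available from the shell:

```sh
comparthic simulate all --out-dir demo --n-bins 500 --seed 1
comparthic compartments call --matrix demo/matrix_low.tsv --res 40000 --out low.bedgraph
comparthic dynamics classify --ref low.bedgraph --alt high.bedgraph --out calls.bed
comparthic run --config run.cfg          # full pipeline with a report bundle
```

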