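# autoqsp

Quantitative systems pharmacology (QSP) analysis of drug–target networks,
built around the study design used for autophagy modulators: a curated set
of drugs labelled as autophagy **activators**, **inhibitors**, or
**dual-modulators**, their known protein targets, and the pathways those
targets populate. The package is aimed at computational pharmacologists who
want to run the full analysis — interaction prediction, similarity,
enrichment, network summaries — on their own drug–target tables, or to
study the method's behaviour on synthetic data with known ground truth.

## What it computes

**Drug–target interaction prediction (PMF).** Known interactions between
N drugs and M targets form a sparse 0/1 matrix R, factorized as
R ≈ UᵀV with D latent variables per drug and per target. Training
minimises Σ(R_ij − U_i·V_j)² + λ_u‖U‖² + λ_v‖V‖² by SGD, sampling fresh
soft negatives each epoch (positive-only data). The clamped reconstruction
c_ij = min(max(U_i·V_j, 0), 1) is the confidence score of an unobserved
pair; candidate interactions keep pairs with confidence strictly above 0.6
within each drug's top-40 ranked unknown pairs.

**Drug–drug similarity.** Structural: Tanimoto coefficient
|a∧b|/|a∨b| between binary 2D fingerprints (computed from SMILES with a
2048-bit radius-2 circular fingerprint when no fingerprint is supplied).
Functional: each drug i is its 0/1 target-membership vector d_i and the
cosine distance 1 − (d_i·d_j)/(|d_i||d_j|) is reported as similarity
1 − distance. `heatmap_order` returns the average-linkage leaf order for
clustered-heatmap presentation.

**Pathway enrichment.** Upper-tail hypergeometric probability that a query
of m targets contains k₀ or more members of a K-sized set within an
M-sized universe, BH-adjusted across the collection (GMT input; the
universe is an explicit input). Enrichment runs pooled and per modulator
category, with or without predicted edges.

**Network summaries.** Modulator degree (promiscuity) tables and binned
histograms (1, 2–4, 5–9, ≥10 targets), frequent targets (≥5 known
modulators), and the seven-region overlap partition of the three category
target sets.

**Synthetic worlds.** `autoqsp.synthetic` generates DrugBank-like inputs
from low-rank latent factors with a logistic observation link, category
labels, latent-correlated fingerprints, and pathway collections with
optional planted category-specific enrichment — fully reproducible from a
single seed, so every stage of the pipeline is testable without licensed
databases.

## Worked example

Generate a small synthetic world and run the full pipeline:

```sh
printf 'n_drugs = 60\nn_targets = 120\nlatent_dim = 4\ndensity = 0.02\nn_pathways = 20\nfingerprint_length = 64\nseed = 11\n' > world.cfg
autoqsp simulate --config world.cfg --out small
autoqsp run --drugs small/drugs.tsv --interactions small/edges.tsv \
    --gmt small/pathways.gmt --universe small/universe.txt \
    --dim 4 --seed 9 --out out
```

which prints `wrote 138 known edges to small/edges.tsv` and
`17 output files under out`. The prediction table ranks novel candidate
interactions per drug with their confidence scores:

```
$ head -4 out/predictions.tsv
drug_id target_id confidence   rank
D0004   T0037     0.637920467  1
D0006   T0076     0.9036235115 1
D0006   T0080     0.7279709733 2
```

`category_overlap.tsv` partitions the 55 targeted proteins by which
modulator categories reach them (38 are touched only by activators, 8 by
both activators and inhibitors, none by all three in this small world),
and `promiscuity_histogram.tsv` bins each category's drugs by degree —
here 17.2% of activators have ≥10 targets. Enrichment tables
(`enrichment_known_pooled.tsv` etc.) report `set_id, k0, K, m, M, p,
p_adj, rank` per gene set; in this unplanted world no set reaches
BH-adjusted significance, as it should be.

The same commands work on real inputs: a TSV drug catalog
(`drug_id, name, category[, smiles][, fingerprint]`), a TSV edge list
(`drug_id, target_id`), and standard GMT gene sets.

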