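# Methods

## The analysis in brief

The package treats a curated drug–target relation as a bipartite network
and runs four coupled analyses: (1) low-rank matrix-factorization
prediction of unobserved drug–target interactions, (2) structural and
functional drug–drug similarity, (3) hypergeometric over-representation
of target sets in pathway collections with FDR control, and (4) degree /
overlap summaries of the network. Drugs carry exactly one modulator
category (activator, inhibitor, dual-modulator); "dual" is its own class,
not a double membership.

## Interaction prediction

**Model.** R (N×M, 0/1) ≈ UᵀV with D latent factors. The loss is the
regularized squared reconstruction error over an observed set consisting
of all known positives (value 1), any explicitly supplied negatives
(value 0), and `neg_ratio` × |positives| unobserved pairs resampled every
epoch as soft negatives. Resampling avoids committing to any fixed set of
presumed non-interactions, which matters because the input is
positive-only: an absent edge is unmeasured, not refuted.

**Optimization.** Per-sample SGD, learning rate 0.01, 200 epochs,
λ_u = λ_v = 0.05, default D = 50 (D is not identifiable from first
principles; a grid over D scored by held-out AUC is the supported way to
choose it for real data). Factors start from a truncated SVD of the
observed 0/1 matrix (seeded start vector, hence deterministic); SGD then
refines against the resampled negatives. The warm start matters at sparse
regimes: with ~4 positives per drug, randomly initialized SGD needs far
more than the default budget to find the subspace the SVD provides
directly.

**Convergence and the training log.** The logged objective is evaluated
on a *fixed* set (positives, explicit negatives, and one seed-fixed
negative sample) so the trace is a stationary quantity; with per-epoch
resampled negatives the raw epoch loss would fluctuate by construction.
Training stops early when the relative change stays below 1e-5 for 10
epochs. A non-finite objective aborts with advice to lower the learning
rate.

**Confidence and selection.** Confidence is the reconstruction clamped to
[0, 1] (a logistic mapping is available but not default; the clamp
matches the reconstruction-as-confidence framing and keeps known entries
at their literal values). Per drug, unknown pairs are ranked by
confidence (ties broken lexicographically by target id) and kept when
rank ≤ 40 and confidence > 0.6 strictly. Known pairs are never re-emitted.

**Evaluation.** Held-out AUC is the Mann–Whitney statistic of clamped
confidences, positives vs sampled non-edges, ties counted 0.5. The
negative control permutes the 0/1 labels across all matrix positions
(uniform relocation of the training edges). A control that merely
shuffles target ids per edge preserves drug degrees, and a
popularity-only model already ranks held-out edges at AUC ≈ 0.8; the
full entry permutation destroys that margin information and sits at
chance, which is what a null control should measure.

## Similarity

Tanimoto |a∧b|/|a∨b| on binary fingerprints; undefined (error) for
all-zero fingerprints. "Distance" always means 1 − similarity. Functional
similarity is 1 − cosine distance between 0/1 target-membership vectors
over known edges; drugs with no known target are excluded with a logged
count, never imputed. Matrices are symmetrized ((S + Sᵀ)/2, then clipped
to [0, 1], diagonal set to exactly 1) so the symmetry invariant holds to
1e-12 regardless of floating-point summation order. Heatmap ordering is
the leaf order of average-linkage clustering on 1 − similarity.

## Enrichment

Upper-tail hypergeometric probability P(X ≥ k₀) for X ~
Hypergeom(M, K, m), evaluated through a numerically stable survival
function; k₀ = 0 returns exactly 1, impossible events exactly 0. The
universe M is always the explicit target universe of the collection — an
over-representation background is a modelling decision, so it is a
mandatory input rather than a guess. BH adjustment is the standard
step-up p*₍ᵢ₎ = min_{k≥i} min(p₍ₖ₎·n/k, 1), applied across *all* sets of
the collection, with p_adj clipped to ≥ p elementwise (p·n/k at k = n can
round one ulp below p). Two reporting conventions are emitted: tables
ranked by ascending raw p, and a filtered view at raw p < 0.05.

Category-stratified enrichment queries the union of targets of each
category's drugs, over known edges by default and optionally including
predicted edges; the pooled query is the union of the three.

## Synthetic worlds

**What it emulates.** The study-scale defaults are 225 drugs in
proportions 174/31/20 (largest-remainder apportionment, then a seeded
permutation, so the counts are exact), 993 targets, edge density
1831/(225·993) ≈ 0.8%, and 294 pathway-style sets. Drug and target latent
factors are i.i.d. standard normal with D_true = 5.

**Observation link.** The propensity of pair (i, j) is
σ(s·(uᵢ·vⱼ + ε + b)) with noise ε ~ N(0, noise_sd²), sharpness s = 3 and
baseline b = −6. The negative baseline makes high propensity rare and the
sharpness makes it nearly binary — binding, as recorded in curated
databases, is a rare and essentially deterministic fact, not a smooth
probability. Under a plain logistic link (b = 0, s = 1) even the true
propensity ranks held-out edges at only AUC ≈ 0.68, i.e. the world would
carry no recoverable structure; with the defaults the true-model AUC is
≈ 0.99 and a matched-dimension fit reaches 0.90–0.94. Per-pair inclusion
probabilities are the propensities rescaled to the requested expected
edge count by iterative water-filling (top probabilities saturate at 1).

**Fingerprints.** Bit b of drug i fires with probability σ(w_b·uᵢ) for
fixed random projections w_b (entries N(0, 1/D)), so drugs with similar
latent profiles share more bits; an all-zero fingerprint (vanishingly
rare) gets its most probable bit forced on. Synthetic drugs carry
fingerprints only — no SMILES, no real chemistry.

**Pathways and plants.** Each target joins each set with probability
0.08; a plant (set index, category, odds multiplier ρ) multiplies that
probability by ρ for targets reached by the planted category's realized
edges. Plants are infeasible (error) if base·ρ > 1. The realized edge set
is generated inside the world (and stored on it) precisely so the plant
is defined against the same edges every downstream analysis sees.

**Randomness.** One master seed is split into five named sub-streams
(factors, categories, fingerprints, interactions, pathways); every
artifact is a pure function of (config, seed), and resampling
interactions with the world's own seed reproduces the stored edge set
bit for bit.

**What passing on synthetic worlds does not show.** The generator makes
no attempt at valid chemistry, target family structure, literature-biased
degree distributions, or correlated pathway membership; results on these
worlds demonstrate that the machinery recovers the signals it is designed
for, not that any particular biological conclusion transfers.

## Problem sizes used in tests and the acceptance script

Recovery benchmarks run at 200 drugs × 400 targets (1% density, D = 5,
10% held-out positives); enrichment recovery uses 50 study-scale replicate
worlds with an inhibitor-category plant at odds multiplier 3 (planted set
sizes ≈ 85–140), and calibration uses 40 unplanted worlds scored on the
pooled query. These sizes give stable statistics in seconds while
preserving the sparsity regime of the real data. Null calibration is
checked on the pooled query because its larger counts make the
hypergeometric p nearly continuous; small-category queries are mildly
conservative (observed ≈ 0.033 vs nominal 0.05) purely through the
discreteness of the test statistic, which is a property of exact tests,
not an implementation artifact.

## Numerical and design notes

- Identifiers are opaque, case-sensitive strings; no symbol normalization.
- TSV dialect: tab-separated UTF-8, `#` comments ignored, header required;
  fingerprints serialized as 0/1 strings of fixed per-catalog length.
- Edge lists are deduplicated on load with a logged count; unresolvable
  ids are hard errors listing the offenders.
- `build_matrix` observes positives only by default; explicit negative
  pairs may be supplied and enter the observation mask as zeros.
- Degree histograms bin drugs at 1, 2–4, 5–9, ≥10 targets; degree-0 drugs
  fall outside the bins and are excluded from percentages. Mean degrees
  are reported to one decimal place. The frequent-target threshold (≥5
  known modulators) and the ≥10 promiscuity breakpoint are configurable
  with these defaults.
- The pipeline writes TSVs with a fixed float format and a manifest
  without timestamps, so identical config + seed gives byte-identical
  bundles.
- Edge counts and node counts are always reported separately (an
  "interaction" is a drug–target pair; a "target" is a protein).

## Known limitations

- The factorization offers no posterior uncertainty; confidence scores
  are clamped reconstructions, not calibrated probabilities.
- No side information (chemical similarity, sequence features) enters the
  factorization.
- Structural similarity silently excludes drugs without usable
  structures; with fewer than two eligible drugs it errors.
- The hypergeometric test is exact and therefore conservative at small
  counts; raw p < 0.05 fractions below 5% on small queries are expected.
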