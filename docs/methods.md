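# Methods

## The model

`fabrynet` treats a disease model as an ensemble of *solutions* over a
signed protein–protein interaction network. A solution assigns every
protein a predicted activity v ∈ [−1, 1]; the ensemble plays the role of a
cohort of virtual individuals whose inter-individual variability comes from
uncertainty about interaction strengths.

The original study built its ensembles with a proprietary system (a
multilayer perceptron trained on drug–condition input–output corpora over a
curated interactome). That training corpus is not public, so this package
implements the observable contract directly with an accept/reject sampler:

- **Weight prior.** Each interaction draws a magnitude uniformly from
  [0.1, 1.0], multiplied by the curated edge sign (+1 activating,
  −1 inhibiting). Undirected (physical) edges carry the same weight in both
  directions; directed (regulatory) edges act only source→target.
- **Propagation.** Non-clamped nodes update synchronously as
  `a_i ← transfer(damping · Σ_j w_ji a_j)` until the maximum change falls
  below 1e−12 or 100 sweeps elapse. `transfer` is tanh (default) or a hard
  clip; damping defaults to 0.9. Both keep activities in [−1, 1] at every
  sweep. Propagation is breadth-limited to 3 hops from the stimulus set;
  unreached nodes keep activity exactly 0 and never count as modulated
  (modulation threshold 1e−6).
- **Acceptance.** A draw is kept iff sign(v_i) matches the characterization
  direction y_i for at least `acceptance_fraction` (default 0.75) of the
  effectors reachable within 3 hops. If the attempt budget (50× the
  requested ensemble size by default) runs out, the best rejected draws
  fill the gap with a warning; zero acceptances raise an error carrying
  diagnostics.

The stimulus is the α-Gal A-deficiency node clamped to −1 (loss of
function), optionally joined by effectors passing the stimulus screen,
clamped to their characterized directions.

## tSignal and cohorts

For one solution, `tSignal = (1/n) Σ v_i·y_i` over the n effectors with
|v_i| > 1e−6. The package defaults to this *agreement* convention, under
which a higher tSignal means the stimulus induces more of the disease; the
published formula carries a leading minus sign, which contradicts that
verbal reading under the natural interpretation of y, so the negated form
remains available as the `printed-minus` convention and simply flips the
cohort orientation. Solutions with no modulated effector are flagged and
excluded from stratification. Cohorts are the floor(q·N) smallest and
largest tSignals (q = 0.10), with ties broken by solution index; a tie
spanning a cohort boundary sets a degeneracy flag.

## Classifier screen

Variables are the per-protein activities of the cohort solutions. Cleaning
drops variables with variance below 1e−12 (duplicates are kept — removing
redundancy is feature selection's job, not cleaning's).

**1-variable classifiers.** The optimal linear threshold (one cut plus an
orientation) and quadratic threshold (one interval, inside-vs-outside) are
found by exhaustive search over the midpoints between consecutive distinct
sample values, plus one cut below and one above the sample range. Ties
resolve to the smallest threshold, then the narrowest interval, then the
class-1-above/inside orientation, making the fit fully deterministic.

**2-variable classifiers.** Feature selection proposes candidate variables
(top-k per method, paired among themselves, union over methods) rather than
enumerating all ordered pairs, to bound cost; an `exhaustive_pairs` flag
restores the full p·(p−1) evaluation at small p. The six rankers:

- *Chow–Liu*: maximum mutual-information spanning tree over variables plus
  the class label (4-bin quantile discretization, plug-in MI); variables
  closest to the label in the tree rank first.
- *mRMR*: greedy max-relevance (ANOVA F, normalized) minus mean absolute
  Pearson correlation with already-selected variables.
- *ReliefF*: k-nearest hits/misses (k = 10) margin weights on
  range-normalized features.
- *RFE-SVM*: recursive feature elimination around a linear SVM.
- *SFFS*: sequential floating forward selection with conditional exclusion,
  wrapped around 3-fold LDA accuracy.
- *Wilcoxon-with-correlation*: rank-sum p-value order with a 0.9 absolute
  correlation cap against already-kept variables.

Pairs are fit as GLM-binomial (logistic regression), Gaussian naive Bayes,
or an MLP with one 3-unit hidden layer (500 iterations, seeded init); the
best family per pair is kept.

**Cross-validation.** Stratified seeded 10-fold CV. Per fold, the
classifier is fit on the training split and scored on the held-out split;
the reported classifier is the parameter-wise arithmetic mean of the
per-fold fits (threshold averaging), and the CV accuracy is the exact mean
of fold accuracies.

**CV p-value.** The screen tests the pooled held-out correct count against
the majority-class rate, one-sided. Held-out predictions from k-fold CV are
not independent — every pair of folds shares most of its training data —
and the pooled count's variance is inflated by ≈ 1 + k/(k−1) relative to a
binomial (the Nadeau–Bengio correction; measured empirically at ×2.02 for
k = 10, n = 200). A naive exact binomial is therefore anti-conservative
(≈11% type-I at the nominal 5% level, ≈17% after best-of-two-modes
selection), so the p-value uses the inflation-corrected normal tail of the
pooled rate. Under label permutation this keeps the fraction of variables
reaching p < 0.05 at ≈7% including the selection over threshold modes.

## Candidate cascade

- Stage 1 keeps candidates with CV accuracy **strictly above** the
  reference threshold (the wording "higher accuracy than" is strict); the
  reference is the top-ranked plasma-measurable known biomarker. The
  published threshold value 70.5% cannot be re-derived from the rounded
  table accuracy (71) and ships only as a fixture constant.
- Stage 2 keeps candidates whose **every** variable protein is measurable
  in plasma and/or urine — a multi-protein classifier is clinically usable
  only if all its analytes are.
- Stage 3 keeps candidates whose every variable has a location code other
  than none. Location codes come from exact matching of lowercase terms
  against the closed neuronal/vascular vocabulary; atlas-sourced tissue
  terms count only for records with "enhanced" or "supported" evidence,
  curated terms always count. A multi-protein candidate's code is the code
  all its members share.
- Prioritization keeps candidates with accuracy **≥ 90% (inclusive)** and
  code NV, sorted by accuracy then id.

## Synthetic data

The generator emulates the study inputs; its study-scale preset mirrors
every printed dimension (9226 proteins, 83,011 relationships, motive sizes
13/16/8/10/4/17/27 sharing exactly 92 unique effectors, 1000 solutions).

- **Network**: preferential attachment (heavy-tailed, like real
  interactomes) or G(n, m), adjusted by seeded edge insertion/removal to
  the exact edge count; 70% of edges activating and 30% directed by
  default, configurable. The giant component covers ≥90% of nodes.
- **Disease definition**: effectors sampled degree-biased (literature
  favours well-connected proteins); each motive gets disjoint "home"
  proteins and the Σsizes − unique surplus memberships are assigned as
  overlaps, so the deduplicated count is exact by construction. Which
  proteins overlap is seed-dependent (the study never names them).
  Directions default to +1; `align_directions` optionally resets them to
  the signs a mid-prior propagation from the clamped anchor actually
  produces — emulating that characterized directions describe what the
  disease mechanism does, without which no sampled solution could
  reproduce the definition.
- **Annotations**: plasma/urine flags and neuronal/vascular terms drawn
  i.i.d. at configured fractions (defaults 0.30/0.15/0.25/0.20 — roughly
  the plasma-detectable fraction of the proteome and generous location
  fractions so the cascade keeps non-trivial candidate sets at demo scale);
  terms are drawn from the curated (evidence-ungated) vocabularies so the
  configured fractions translate directly into location-code rates.
- **Planted screens**: two balanced cohorts with k informative proteins
  shifted by `effect_size` standardized units over Gaussian noise, clipped
  to [−1, 1] — the benchmark for screen recovery and null calibration.

What the synthetic data does *not* emulate: the true topology and curation
biases of the proprietary interactome, correlated annotation structure
(e.g. secreted proteins being jointly plasma-measurable and vascular), and
disease-realistic effector identities. Passing tests therefore demonstrate
that the machinery is correct and calibrated, not that it would rediscover
the published candidate genes; the published-table fixtures cover the
worked examples that are checkable exactly.

## Problem sizes and determinism

The analysis drivers and tests run the demo preset (200 proteins, 800
interactions, 100 solutions) and simulation studies at n = 200 samples
(50 permutation reps; 20 recovery seeds), sizes chosen so the full suite
completes in a few minutes on one CPU while leaving the statistical checks
well-powered. Every stochastic component takes an explicit seed; reruns
with the same configuration are bit-identical (the pipeline manifest
records SHA-256 checksums of all artifacts).

## Known limitations

- The sampler explores weight uncertainty only; it does not learn from
  drug–condition training data, so solution diversity is narrower than a
  trained model's and the modulated-protein count tracks the stimulus
  neighbourhood size rather than training signal.
- With dense demo-scale networks most effectors sit within 3 hops of each
  other, so the stimulus screen passes many more candidates than the three
  the original study reported at interactome scale.
- The activity interval is closed ([−1, 1]); whether the original system
  could attain the boundary is unknown (it reports the open interval).
- Whether the stimulus-screen normalizer was global or per-distance is not
  documented; this implementation normalizes globally.
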